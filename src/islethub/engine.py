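"""Coupled-islet integration through the silencing protocol.

The islet is one stiff ODE system: every cell contributes its six state
variables, and membranes are coupled through ohmic gap-junction currents
I_coup,i = Σ_j g_ij (Vm_i − Vm_j) over the contact graph (pS·mV = fA, i.e.
a factor 10⁻³ to pA).  A protocol runs up to four epochs — equilibration
(discarded by the analysis), baseline, inhibition and recovery.  During the
inhibition epoch a selected cell set is voltage-clamped: their Vm equation
is replaced by Vm ≡ clamp voltage (algebraic substitution, mimicking
optogenetic silencing by a hyperpolarising pump), their internal Ca²⁺ and
gating state keeps evolving, and neighbours see the clamped potential
through the coupling term.  Integration uses an adaptive implicit (BDF)
method with the Jacobian sparsity implied by the contact graph.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .assembly import GapJunctionTable, IsletNetwork
from .cell_model import fast_rhs_factory, get_backend

__all__ = [
    "SimulationProtocol",
    "SimulationResult",
    "coupling_current",
    "coupling_currents",
    "run_protocol",
    "run_inhibition_series",
]

EPOCH_NAMES = ("equilibration", "baseline", "inhibition", "recovery")

#: Default absolute tolerances per state variable (vm, n, h, ca_i, ca_er, a):
#: scaled to each variable's magnitude (mV, unit gates, µM).
ATOL_TEMPLATE = np.array([1e-4, 1e-7, 1e-7, 1e-8, 1e-4, 1e-8])


@dataclass(frozen=True)
class SimulationProtocol:
    """Epoch durations (s), inhibited set, clamp level and solver settings."""

    equilibration_s: float = 100.0
    baseline_s: float = 60.0
    inhibition_s: float = 60.0
    recovery_s: float = 60.0
    inhibited: tuple = ()
    clamp_mv: float = -100.0
    sample_ms: float = 100.0
    rtol: float = 1e-6
    atol: float | None = None   # None -> per-variable defaults

    def __post_init__(self):
        for name in ("equilibration_s", "baseline_s", "inhibition_s",
                     "recovery_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sample_ms <= 0:
            raise ValueError("sample_ms must be positive")

    def with_(self, **kw) -> "SimulationProtocol":
        return replace(self, **kw)

    def durations_s(self) -> dict:
        return {
            "equilibration": self.equilibration_s,
            "baseline": self.baseline_s,
            "inhibition": self.inhibition_s,
            "recovery": self.recovery_s,
        }


@dataclass
class SimulationResult:
    """Sampled per-cell trajectories with epoch annotations."""

    time_s: np.ndarray                  # (n_t,)
    vm: np.ndarray                      # (n_t, n_cells), mV
    ca: np.ndarray                      # (n_t, n_cells), µM
    epochs: dict                        # name -> (t_start_s, t_end_s)
    inhibited: np.ndarray               # cell indices clamped in 'inhibition'
    clamp_mv: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.vm.shape[1]

    def epoch_mask(self, name: str) -> np.ndarray:
        t0, t1 = self.epochs[name]
        return (self.time_s >= t0) & (self.time_s < t1)

    def epoch_trace(self, name: str, which: str = "ca") -> np.ndarray:
        arr = getattr(self, which)
        return arr[self.epoch_mask(name)]

    def mean_ca(self) -> np.ndarray:
        """Islet-average Ca²⁺ trace (µM)."""
        return self.ca.mean(axis=1)

    def save(self, path) -> None:
        """Persist to a chunked HDF5 container with metadata."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_s", data=self.time_s)
            fh.create_dataset("vm", data=self.vm.astype(np.float32),
                              chunks=True, compression="gzip")
            fh.create_dataset("ca", data=self.ca.astype(np.float32),
                              chunks=True, compression="gzip")
            fh.create_dataset("inhibited", data=self.inhibited)
            fh.attrs["clamp_mv"] = self.clamp_mv
            for name, (t0, t1) in self.epochs.items():
                fh.attrs[f"epoch_{name}"] = (t0, t1)
            for k, v in self.diagnostics.items():
                if np.isscalar(v):
                    fh.attrs[f"diag_{k}"] = v

    @classmethod
    def load(cls, path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as fh:
            epochs = {k[len("epoch_"):]: tuple(v)
                      for k, v in fh.attrs.items() if k.startswith("epoch_")}
            diags = {k[len("diag_"):]: v
                     for k, v in fh.attrs.items() if k.startswith("diag_")}
            return cls(time_s=fh["time_s"][:],
                       vm=fh["vm"][:].astype(float),
                       ca=fh["ca"][:].astype(float),
                       epochs=epochs,
                       inhibited=fh["inhibited"][:],
                       clamp_mv=float(fh.attrs["clamp_mv"]),
                       diagnostics=diags)

    def summary_frame(self):
        """Mean-Ca trace with epoch labels as a DataFrame (delimited export)."""
        import pandas as pd

        label = np.empty(self.time_s.shape, dtype=object)
        for name, (t0, t1) in self.epochs.items():
            label[(self.time_s >= t0) & (self.time_s < t1)] = name
        return pd.DataFrame({"time_s": self.time_s,
                             "mean_ca_uM": self.mean_ca(),
                             "epoch": label})


def _laplacian(gj: GapJunctionTable, n_cells: int) -> sp.csr_matrix:
    """Weighted graph Laplacian L with I_coup = 1e-3 · L @ Vm (pA)."""
    i, j = gj.edges[:, 0], gj.edges[:, 1]
    g = gj.conductances
    w = sp.coo_matrix((np.concatenate([g, g]),
                       (np.concatenate([i, j]), np.concatenate([j, i]))),
                      shape=(n_cells, n_cells))
    d = sp.diags(np.asarray(w.sum(axis=1)).ravel())
    return (d - w).tocsr()


def coupling_current(i: int, vm_all: np.ndarray, gj: GapJunctionTable,
                     ) -> float:
    """Gap-junction current (pA) into the membrane equation of cell ``i``.

    ``I_coup,i = 1e-3 · Σ_j g_ij (Vm_i − Vm_j)`` with g in pS and Vm in mV
    (pS·mV = fA).  Positive values hyperpolarise the cell (the current
    appears with a minus sign in dVm/dt).
    """
    vm_all = np.asarray(vm_all, dtype=float)
    mask_i = gj.edges[:, 0] == i
    mask_j = gj.edges[:, 1] == i
    partners = np.concatenate([gj.edges[mask_i, 1], gj.edges[mask_j, 0]])
    gs = np.concatenate([gj.conductances[mask_i], gj.conductances[mask_j]])
    return float(1e-3 * np.sum(gs * (vm_all[i] - vm_all[partners])))


def coupling_currents(vm_all: np.ndarray, gj: GapJunctionTable,
                      ) -> np.ndarray:
    """Vector of gap-junction currents (pA) for all cells at once."""
    n = vm_all.shape[0]
    return 1e-3 * (_laplacian(gj, n) @ vm_all)


def _jacobian_sparsity(network: IsletNetwork, n_state: int) -> sp.csr_matrix:
    """Block sparsity: dense 6×6 per cell plus Vm–Vm coupling entries."""
    n = network.n_cells
    rows, cols = [], []
    base = np.arange(n) * n_state
    for a in range(n_state):
        for b in range(n_state):
            rows.append(base + a)
            cols.append(base + b)
    e = network.gap_junctions.edges
    if e.size:
        rows.append(e[:, 0] * n_state)
        cols.append(e[:, 1] * n_state)
        rows.append(e[:, 1] * n_state)
        cols.append(e[:, 0] * n_state)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(rows.shape[0], dtype=np.int8)
    return sp.coo_matrix((data, (rows, cols)),
                         shape=(n * n_state, n * n_state)).tocsr()


def run_protocol(network: IsletNetwork, protocol: SimulationProtocol,
                 backend: str = "reference",
                 y0: np.ndarray | None = None,
                 record_equilibration: bool = False) -> SimulationResult:
    """Integrate an islet through the epoch protocol.

    Clamped cells have their Vm pinned to ``protocol.clamp_mv`` for the
    whole inhibition epoch while their interior state continues to evolve;
    on release they resume free dynamics from wherever the clamp left them.
    """
    be = get_backend(backend)
    n = network.n_cells
    ns = be.n_state
    inhibited = np.asarray(sorted(int(c) for c in protocol.inhibited),
                           dtype=int)
    if inhibited.size and (inhibited.min() < 0 or inhibited.max() >= n):
        raise ValueError("inhibited set contains out-of-range cell indices")

    p = be.pack_params(list(network.cells))
    lap = _laplacian(network.gap_junctions, n)
    sparsity = _jacobian_sparsity(network, ns)

    clamp_mask = np.zeros(n, dtype=bool)
    clamp_mask[inhibited] = True

    fast = fast_rhs_factory(p)
    no_clamp = np.zeros(n, dtype=bool)

    def make_rhs(clamped: bool):
        mask = clamp_mask if clamped else no_clamp

        def f(t, yflat):
            y = yflat.reshape(n, ns)
            i_coup = 1e-3 * (lap @ np.ascontiguousarray(y[:, 0]))
            return fast(t, y, i_coup, mask).ravel()

        return f

    y = (be.rest_state(n) if y0 is None else np.array(y0, dtype=float))
    y = y.reshape(n, ns)

    times, vms, cas = [], [], []
    epochs = {}
    diags = {"nfev": 0, "njev": 0, "wall_s": 0.0}
    t_offset_s = 0.0
    for name, dur_s in protocol.durations_s().items():
        if dur_s <= 0:
            continue
        clamped = name == "inhibition" and inhibited.size > 0
        if clamped:
            y[inhibited, 0] = protocol.clamp_mv
        f = make_rhs(clamped)
        t_end = dur_s * 1e3
        t_eval = np.arange(0.0, t_end, protocol.sample_ms)
        wall0 = time.time()
        atol = protocol.atol
        if atol is None:
            atol = np.tile(ATOL_TEMPLATE[:ns], n)
        sol = solve_ivp(f, (0.0, t_end), y.ravel(), method="BDF",
                        rtol=protocol.rtol, atol=atol,
                        t_eval=t_eval, jac_sparsity=sparsity)
        diags["wall_s"] += time.time() - wall0
        diags["nfev"] += sol.nfev
        diags["njev"] += sol.njev
        if not sol.success:
            ylast = sol.y[:, -1].reshape(n, ns) if sol.y.size else y
            worst = int(np.nanargmax(np.abs(ylast[:, 0])))
            raise RuntimeError(
                f"solver failed in epoch '{name}' at t≈"
                f"{t_offset_s + (sol.t[-1] if sol.t.size else 0)/1e3:.1f} s "
                f"(worst cell {worst}): {sol.message}")
        traj = sol.y.T.reshape(-1, n, ns)
        if clamped:
            traj[:, inhibited, 0] = protocol.clamp_mv
        keep = record_equilibration or name != "equilibration"
        if keep:
            times.append(t_offset_s + sol.t / 1e3)
            vms.append(traj[:, :, 0])
            cas.append(traj[:, :, be.state_names.index("ca_i")])
        epochs[name] = (t_offset_s, t_offset_s + dur_s)
        y = traj[-1].copy()
        t_offset_s += dur_s

    result = SimulationResult(
        time_s=np.concatenate(times),
        vm=np.concatenate(vms, axis=0),
        ca=np.concatenate(cas, axis=0),
        epochs=epochs,
        inhibited=inhibited,
        clamp_mv=protocol.clamp_mv,
        diagnostics=diags,
    )
    if np.any(~np.isfinite(result.ca)) or np.any(~np.isfinite(result.vm)):
        raise FloatingPointError("non-finite values in recorded trajectories")
    return result


def nested_inhibition_sets(network: IsletNetwork, fractions_pct,
                           target: str = "hub",
                           rng: np.random.Generator | int | None = None,
                           ) -> list[np.ndarray]:
    """Nested inhibited sets, one per requested fraction of the islet.

    The target pool (hubs or non-hubs) is permuted once; the set for a
    larger fraction contains every smaller set, which removes spurious
    Monte-Carlo jitter between dose levels.
    """
    if target not in ("hub", "nonhub"):
        raise ValueError("target must be 'hub' or 'nonhub'")
    pool = network.hubs if target == "hub" else network.nonhubs
    rng = np.random.default_rng(rng)
    order = rng.permutation(pool)
    sets = []
    for frac in fractions_pct:
        size = int(np.floor(frac / 100.0 * network.n_cells + 0.5))
        if size > pool.size:
            raise ValueError(
                f"fraction {frac}% of the islet needs {size} cells but the "
                f"{target} pool only has {pool.size}")
        sets.append(np.sort(order[:size]))
    return sets


def run_inhibition_series(network: IsletNetwork, fractions_pct,
                          target: str = "hub",
                          rng_seed: int | None = None,
                          protocol: SimulationProtocol | None = None,
                          backend: str = "reference",
                          ) -> list[SimulationResult]:
    """One protocol run per inhibited fraction (nested sets, shared seed)."""
    proto = protocol or SimulationProtocol()
    sets = nested_inhibition_sets(network, fractions_pct, target, rng_seed)
    results = []
    for cells in sets:
        results.append(run_protocol(
            network, proto.with_(inhibited=tuple(int(c) for c in cells)),
            backend=backend))
    return results
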