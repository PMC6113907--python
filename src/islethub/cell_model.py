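"""Single β-cell electrophysiology and Ca²⁺ handling.

The per-cell dynamics follow the current complement of the Cha–Noma class of
β-cell models: the membrane equation collects ten ionic currents

    Cm dVm/dt = −(I_CaV + I_TRPM + I_SOC + I_bNSC + I_KDr + I_KCa + I_KATP
                  + I_NaK + I_NaCa + I_PMCA + I_coup + I_NpHR)

and cytosolic Ca²⁺ obeys a flux balance over the Ca²⁺-carrying pathways

    d[Ca²⁺]i/dt = (f/v) · (−ΣI_Ca/(2F) − J_SERCA + J_rel)

with ER uptake through SERCA modelled as a Hill flux,
J_SERCA = P_SERCA·[Ca²⁺]i² / ([Ca²⁺]i² + K²).

Glucose enters through a lumped metabolic activity variable that gates the
ATP-sensitive K⁺ conductance: a glucokinase-like Hill function sets the
drive, and Ca²⁺-dependent ATP consumption provides slow negative feedback.
The voltage subsystem is bistable between a hyperpolarised rest state and a
depolarised plateau; slow inactivation of the Ca²⁺ current and the metabolic
variable sweep the cell between the two, producing square-wave bursts of
Ca²⁺ with periods of order ten seconds at stimulatory glucose.  With the
default (unsampled) parameters the cell is silent below ≈6.9 mM glucose and
bursts continuously at 11 mM, which is the behavioural contract every
backend registered here must satisfy.

Units: mV, ms, pA, pS, µM, pL; fluxes in amole/ms (1 amole/ms over 1 pL
changes concentration by 1 µM/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "FARADAY",
    "CellParameters",
    "CellState",
    "ReferenceBackend",
    "get_backend",
    "serca_flux",
    "cell_rhs",
    "sample_heterogeneous_params",
    "find_firing_threshold",
]

#: Faraday constant, C/mol.
FARADAY = 96485.33212

#: amole/ms carried by 1 pA of divalent (Ca²⁺) current.
PA_TO_AMOL_DIVALENT = 1e3 / (2.0 * FARADAY)
#: amole/ms of ion transported per pA at unit net charge (pumps, exchangers).
PA_TO_AMOL_MONOVALENT = 1e3 / FARADAY

#: Names of the per-cell maximal conductances / transport rates that are
#: resampled when modelling cell-to-cell heterogeneity.
HETEROGENEOUS_FIELDS = (
    "g_cav", "g_kdr", "g_kca", "g_katp", "g_bnsc", "g_trpm", "g_soc",
    "i_nak", "i_naca", "p_pmca",
)


@dataclass(frozen=True)
class CellParameters:
    """Biophysical parameters of one β-cell.

    The ten current magnitudes correspond, in order, to the voltage-gated
    Ca²⁺ channel, delayed-rectifier K⁺, Ca²⁺-activated K⁺ (SK), ATP-sensitive
    K⁺, background non-selective cation, melastatin-related TRP, store-operated
    channel, Na⁺/K⁺ pump, Na⁺/Ca²⁺ exchanger and plasma-membrane Ca²⁺ pump.
    ``glucose`` is the cell's (constant) bath glucose in mM; ``p_serca`` the
    maximal SERCA flux in amole/ms.
    """

    cm: float = 6.2                 # membrane capacitance, pF
    g_cav: float = 1700.0           # pS
    g_kdr: float = 3000.0           # pS
    g_kca: float = 100.0            # pS
    g_katp: float = 300.0           # pS (fully-open maximum)
    g_bnsc: float = 35.0            # pS
    g_trpm: float = 25.0            # pS
    g_soc: float = 20.0             # pS
    i_nak: float = 2.0              # pA, maximal pump current
    i_naca: float = 10.0            # pA, maximal exchanger current
    p_pmca: float = 0.03            # amole/ms
    p_serca: float = 0.096          # amole/ms, maximal SERCA flux
    k_serca: float = 0.5            # µM, SERCA half-activation
    f_buf: float = 0.01             # cytosolic buffer strength (free fraction)
    volume: float = 0.764           # cytosolic volume, pL
    glucose: float = 5.0            # mM
    i_nphr: float = 0.0             # pA, halorhodopsin pump current when active
    is_hub: bool = False
    nphr_active: bool = False

    def __post_init__(self) -> None:
        for name in HETEROGENEOUS_FIELDS + ("p_serca",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.glucose <= 0:
            raise ValueError("glucose must be positive")
        if not 0 < self.f_buf <= 1:
            raise ValueError("buffer strength f must be in (0, 1]")

    def with_(self, **kwargs) -> "CellParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_config(self, backend: str = "reference") -> str:
        """Serialise as flat ``key = value`` text (backend selected by
        name on the first line)."""
        lines = [f"backend = {backend}"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "tuple[CellParameters, str]":
        """Parse ``key = value`` text; returns (parameters, backend name)."""
        backend = "reference"
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        for ln in text.splitlines():
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise ValueError(f"malformed config line: {ln!r}")
            key, val = (part.strip() for part in ln.split("=", 1))
            if key == "backend":
                backend = val
            elif key in ("is_hub", "nphr_active"):
                kwargs[key] = val.lower() in ("true", "1", "yes")
            elif key in valid:
                kwargs[key] = float(val)
            else:
                raise ValueError(f"unknown parameter {key!r}")
        get_backend(backend)          # validate the backend name
        return cls(**kwargs), backend


@dataclass
class CellState:
    """Dynamical state of one β-cell.

    ``vm`` (mV), ``ca_i`` and ``ca_er`` (µM) are named; the remaining
    entries of :attr:`vector` are backend-specific gating/metabolic
    variables (for the reference backend: K⁺-channel activation ``n``,
    Ca²⁺-channel slow inactivation ``h`` and metabolic activity ``a``).
    """

    vector: np.ndarray

    # index map for the reference backend state layout
    IDX_V = 0
    IDX_N = 1
    IDX_H = 2
    IDX_CA = 3
    IDX_CAER = 4
    IDX_A = 5

    @property
    def vm(self) -> float:
        return float(self.vector[self.IDX_V])

    @property
    def ca_i(self) -> float:
        return float(self.vector[self.IDX_CA])

    @property
    def ca_er(self) -> float:
        return float(self.vector[self.IDX_CAER])


def serca_flux(ca_i, p_serca, k_half):
    """SERCA ER-uptake flux (amole/ms) as a second-order Hill function.

    ``J = p_serca · ca_i² / (ca_i² + k_half²)``; monotone in ``ca_i`` and
    saturating at ``p_serca``.  Accepts scalars or arrays.
    """
    ca_i = np.asarray(ca_i, dtype=float)
    if np.any(ca_i < 0):
        raise ValueError("ca_i must be non-negative")
    if np.any(np.asarray(p_serca) < 0):
        raise ValueError("p_serca must be non-negative")
    if np.any(np.asarray(k_half) <= 0):
        raise ValueError("k_half must be positive")
    ca2 = ca_i * ca_i
    out = p_serca * ca2 / (ca2 + np.asarray(k_half) ** 2)
    return out if out.ndim else float(out)


class ReferenceBackend:
    """Reference ten-current bursting β-cell backend.

    Gating and metabolic constants below are shared by all cells; the
    per-cell magnitudes live in :class:`CellParameters`.  The backend
    operates on struct-of-array parameter sets so that a whole islet is
    advanced with vectorised numpy expressions.
    """

    name = "reference"
    n_state = 6
    state_names = ("vm", "n", "h", "ca_i", "ca_er", "a")

    # reversal potentials (mV); E_CA is an effective value for the
    # high-threshold Ca²⁺ current, not a Nernst potential
    E_K = -75.0
    E_CA = 25.0
    E_NS = 0.0

    # CaV gating
    VM_M, SM_M = -24.0, 7.0          # activation midpoint/slope
    VM_H, SM_H = -36.0, 6.0          # slow inactivation midpoint/slope
    TAU_H = 6000.0                   # ms
    K_ICA = 1.5                      # µM, Ca²⁺-dependent inactivation
    # KDr gating
    VM_N, SM_N = -10.0, 5.0
    TAU_N = 20.0                     # ms
    # KCa, TRPM, SOC half-activations
    K_KCA = 0.5                      # µM
    K_TRPM = 0.8                     # µM
    K_SOC = 200.0                    # µM ER Ca²⁺ (channel opens as ER empties)
    # NCX / PMCA
    K_NCX = 1.5                      # µM
    K_PMCA = 0.5                     # µM
    # ER leak/release and compartment
    P_REL = 1e-4                     # pL/ms
    F_ER = 0.025                     # ER buffer strength
    V_ER = 0.28                      # pL
    # metabolism: glucokinase-like drive and Ca²⁺-dependent consumption
    K_GLC, H_GLC = 7.0, 6.0          # mM, Hill midpoint/coefficient
    K_ACA, H_ACA = 0.26, 4.0         # µM, Hill midpoint/coefficient
    TAU_A = 8000.0                   # ms
    # KATP gating by metabolic activity
    K_KATP, H_KATP = 0.45, 6.0

    PARAM_FIELDS = tuple(f.name for f in fields(CellParameters)
                         if f.name not in ("is_hub", "nphr_active"))

    @classmethod
    def pack_params(cls, cells: "list[CellParameters]") -> dict:
        """Convert a list of per-cell parameters to a struct of arrays."""
        out = {name: np.array([getattr(c, name) for c in cells], dtype=float)
               for name in cls.PARAM_FIELDS}
        out["nphr_active"] = np.array([c.nphr_active for c in cells],
                                      dtype=bool)
        return out

    @classmethod
    def rest_state(cls, n_cells: int = 1) -> np.ndarray:
        """Generic hyperpolarised initial condition, shape (n_cells, 6)."""
        y = np.empty((n_cells, cls.n_state))
        y[:] = (-68.0, 0.0, 1.0, 0.08, 120.0, 0.2)
        return y

    @classmethod
    def currents(cls, y: np.ndarray, p: dict) -> dict:
        """All ten membrane currents (pA) at state ``y`` of shape (n, 6)."""
        vm, n, h = y[..., 0], y[..., 1], y[..., 2]
        ca, ca_er, a = y[..., 3], y[..., 4], y[..., 5]
        m_inf = 1.0 / (1.0 + np.exp(-(vm - cls.VM_M) / cls.SM_M))
        f_ca = 1.0 / (1.0 + (ca / cls.K_ICA) ** 2)
        ca2 = ca * ca
        o_katp = 1.0 / (1.0 + (a / cls.K_KATP) ** cls.H_KATP)
        i = {
            "i_cav": p["g_cav"] * m_inf * h * f_ca * (vm - cls.E_CA) * 1e-3,
            "i_kdr": p["g_kdr"] * n * (vm - cls.E_K) * 1e-3,
            "i_kca": p["g_kca"] * ca2 / (ca2 + cls.K_KCA ** 2)
                     * (vm - cls.E_K) * 1e-3,
            "i_katp": p["g_katp"] * o_katp * (vm - cls.E_K) * 1e-3,
            "i_bnsc": p["g_bnsc"] * (vm - cls.E_NS) * 1e-3,
            "i_trpm": p["g_trpm"] * ca2 / (ca2 + cls.K_TRPM ** 2)
                      * (vm - cls.E_NS) * 1e-3,
            "i_soc": p["g_soc"] / (1.0 + (ca_er / cls.K_SOC) ** 4)
                     * (vm - cls.E_NS) * 1e-3,
            "i_nak": p["i_nak"] * np.ones_like(vm),
            "i_naca": -p["i_naca"] * ca / (ca + cls.K_NCX),
            "i_pmca": 96.485 * p["p_pmca"] * ca2 / (ca2 + cls.K_PMCA ** 2),
        }
        i["i_nphr"] = np.where(p["nphr_active"], p["i_nphr"], 0.0)
        return i

    @classmethod
    def rhs(cls, t: float, y: np.ndarray, p: dict,
            i_coup: np.ndarray | float = 0.0,
            clamp_mask: np.ndarray | None = None) -> np.ndarray:
        """Time derivatives for an array of cells.

        ``y`` has shape (n_cells, 6); ``i_coup`` is the gap-junction current
        in pA (positive = outward).  Cells flagged in ``clamp_mask`` have
        dVm/dt forced to zero (their Vm is held by the caller); all their
        internal variables keep evolving under the clamped potential.
        """
        if not np.all(np.isfinite(y)):
            bad = np.argwhere(~np.isfinite(np.atleast_2d(y)))
            c, v = bad[0]
            raise FloatingPointError(
                f"non-finite state: cell {c}, variable "
                f"'{cls.state_names[v]}' at t={t:.1f} ms")
        vm, n, h = y[..., 0], y[..., 1], y[..., 2]
        ca, ca_er, a = y[..., 3], y[..., 4], y[..., 5]
        cur = cls.currents(y, p)
        i_total = sum(cur.values()) + i_coup
        dvm = -i_total / p["cm"]
        if clamp_mask is not None:
            dvm = np.where(clamp_mask, 0.0, dvm)

        n_inf = 1.0 / (1.0 + np.exp(-(vm - cls.VM_N) / cls.SM_N))
        h_inf = 1.0 / (1.0 + np.exp((vm - cls.VM_H) / cls.SM_H))
        dn = (n_inf - n) / cls.TAU_N
        dh = (h_inf - h) / cls.TAU_H

        j_serca = p["p_serca"] * ca * ca / (ca * ca + p["k_serca"] ** 2)
        j_rel = cls.P_REL * (ca_er - ca)
        j_pmca = p["p_pmca"] * ca * ca / (ca * ca + cls.K_PMCA ** 2)
        j_ncx = PA_TO_AMOL_MONOVALENT * p["i_naca"] * ca / (ca + cls.K_NCX)
        # Ca²⁺ balance: CaV influx (inward current is negative), SERCA uptake,
        # ER release, extrusion by PMCA and NCX
        dca = (p["f_buf"] / p["volume"]) * (
            -PA_TO_AMOL_DIVALENT * cur["i_cav"]
            - j_serca + j_rel - j_pmca - j_ncx)
        dca_er = (cls.F_ER / cls.V_ER) * (j_serca - j_rel)

        glc = p["glucose"]
        drive = glc ** cls.H_GLC / (glc ** cls.H_GLC + cls.K_GLC ** cls.H_GLC)
        a_inf = drive / (1.0 + (ca / cls.K_ACA) ** cls.H_ACA)
        da = (a_inf - a) / cls.TAU_A

        return np.stack([dvm, dn, dh, dca, dca_er, da], axis=-1)


def _build_numba_kernel():
    """Compile a numba RHS kernel mirroring :meth:`ReferenceBackend.rhs`.

    Returns ``None`` when numba is unavailable; the numpy path is used
    instead.  The kernel is exact — it implements the same expressions —
    so results are identical up to floating-point associativity.
    """
    try:
        from numba import njit
    except ImportError:            # pragma: no cover - numba is optional
        return None

    B = ReferenceBackend
    E_K, E_CA, E_NS = B.E_K, B.E_CA, B.E_NS
    VM_M, SM_M = B.VM_M, B.SM_M
    VM_H, SM_H, TAU_H = B.VM_H, B.SM_H, B.TAU_H
    K_ICA = B.K_ICA
    VM_N, SM_N, TAU_N = B.VM_N, B.SM_N, B.TAU_N
    K_KCA, K_TRPM, K_SOC = B.K_KCA, B.K_TRPM, B.K_SOC
    K_NCX, K_PMCA = B.K_NCX, B.K_PMCA
    P_REL, F_ER, V_ER = B.P_REL, B.F_ER, B.V_ER
    K_GLC, H_GLC = B.K_GLC, B.H_GLC
    K_ACA, H_ACA = B.K_ACA, B.H_ACA
    TAU_A = B.TAU_A
    K_KATP, H_KATP = B.K_KATP, B.H_KATP
    PAQ, PAM = PA_TO_AMOL_DIVALENT, PA_TO_AMOL_MONOVALENT

    @njit(cache=True, fastmath=False)
    def kernel(y, cm, g_cav, g_kdr, g_kca, g_katp, g_bnsc, g_trpm, g_soc,
               i_nak, i_naca, p_pmca, p_serca, k_serca, f_buf, volume,
               glucose, i_nphr, nphr_active, i_coup, clamped):
        n = y.shape[0]
        out = np.empty_like(y)
        for c in range(n):
            vm, nn, h = y[c, 0], y[c, 1], y[c, 2]
            ca, ca_er, a = y[c, 3], y[c, 4], y[c, 5]
            m_inf = 1.0 / (1.0 + np.exp(-(vm - VM_M) / SM_M))
            f_ca = 1.0 / (1.0 + (ca / K_ICA) ** 2)
            ca2 = ca * ca
            icav = g_cav[c] * m_inf * h * f_ca * (vm - E_CA) * 1e-3
            ikdr = g_kdr[c] * nn * (vm - E_K) * 1e-3
            ikca = g_kca[c] * ca2 / (ca2 + K_KCA * K_KCA) * (vm - E_K) * 1e-3
            o_katp = 1.0 / (1.0 + (a / K_KATP) ** H_KATP)
            ikatp = g_katp[c] * o_katp * (vm - E_K) * 1e-3
            ibnsc = g_bnsc[c] * (vm - E_NS) * 1e-3
            itrpm = g_trpm[c] * ca2 / (ca2 + K_TRPM * K_TRPM) \
                * (vm - E_NS) * 1e-3
            er4 = (ca_er / K_SOC) ** 4
            isoc = g_soc[c] / (1.0 + er4) * (vm - E_NS) * 1e-3
            inak = i_nak[c]
            inaca = -i_naca[c] * ca / (ca + K_NCX)
            j_pmca = p_pmca[c] * ca2 / (ca2 + K_PMCA * K_PMCA)
            ipmca = 96.485 * j_pmca
            inphr = i_nphr[c] if nphr_active[c] else 0.0
            itot = (icav + ikdr + ikca + ikatp + ibnsc + itrpm + isoc
                    + inak + inaca + ipmca + inphr + i_coup[c])
            dvm = 0.0 if clamped[c] else -itot / cm[c]
            n_inf = 1.0 / (1.0 + np.exp(-(vm - VM_N) / SM_N))
            h_inf = 1.0 / (1.0 + np.exp((vm - VM_H) / SM_H))
            j_serca = p_serca[c] * ca2 / (ca2 + k_serca[c] * k_serca[c])
            j_rel = P_REL * (ca_er - ca)
            j_ncx = PAM * i_naca[c] * ca / (ca + K_NCX)
            dca = (f_buf[c] / volume[c]) * (
                -PAQ * icav - j_serca + j_rel - j_pmca - j_ncx)
            dca_er = (F_ER / V_ER) * (j_serca - j_rel)
            g6 = glucose[c] ** H_GLC
            drive = g6 / (g6 + K_GLC ** H_GLC)
            a_inf = drive / (1.0 + (ca / K_ACA) ** H_ACA)
            out[c, 0] = dvm
            out[c, 1] = (n_inf - nn) / TAU_N
            out[c, 2] = (h_inf - h) / TAU_H
            out[c, 3] = dca
            out[c, 4] = dca_er
            out[c, 5] = (a_inf - a) / TAU_A
        return out

    return kernel


_NUMBA_KERNEL = None
_NUMBA_TRIED = False


def fast_rhs_factory(p: dict):
    """Return a ``(t, y2d, i_coup, clamped) -> dy2d`` callable.

    Uses the numba kernel when available, otherwise the numpy
    implementation.  ``p`` is a packed struct-of-arrays parameter set.
    """
    global _NUMBA_KERNEL, _NUMBA_TRIED
    if not _NUMBA_TRIED:
        _NUMBA_KERNEL = _build_numba_kernel()
        _NUMBA_TRIED = True
    if _NUMBA_KERNEL is None:
        def f(t, y, i_coup, clamped):
            mask = clamped if clamped.any() else None
            return ReferenceBackend.rhs(t, y, p, i_coup=i_coup,
                                        clamp_mask=mask)
        return f
    args = tuple(np.ascontiguousarray(p[name]) for name in
                 ("cm", "g_cav", "g_kdr", "g_kca", "g_katp", "g_bnsc",
                  "g_trpm", "g_soc", "i_nak", "i_naca", "p_pmca",
                  "p_serca", "k_serca", "f_buf", "volume", "glucose",
                  "i_nphr"))
    nphr = np.ascontiguousarray(p["nphr_active"])
    kernel = _NUMBA_KERNEL

    def f(t, y, i_coup, clamped):
        return kernel(y, *args, nphr, i_coup, clamped)

    return f


_BACKENDS = {ReferenceBackend.name: ReferenceBackend}


def get_backend(name: str = "reference"):
    """Look up a registered cell-model backend by name."""
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(f"unknown backend {name!r}; "
                       f"available: {sorted(_BACKENDS)}") from None


def cell_rhs(state: CellState | np.ndarray, params: CellParameters,
             i_coup: float = 0.0, t: float = 0.0,
             backend: str = "reference") -> np.ndarray:
    """Derivative of a single cell's state vector.

    ``i_coup`` is the gap-junction current in pA delivered by the network
    layer (zero for an isolated cell).
    """
    be = get_backend(backend)
    y = state.vector if isinstance(state, CellState) else np.asarray(state)
    p = be.pack_params([params])
    return be.rhs(t, y.reshape(1, -1), p, i_coup=np.asarray([i_coup]))[0]


def sample_heterogeneous_params(base: CellParameters, cv: float = 0.2,
                                rng: np.random.Generator | int | None = None,
                                ) -> CellParameters:
    """Draw one heterogeneous parameter set.

    Every maximal conductance/transport magnitude is drawn from
    Normal(µ, cv·µ) around the base value; non-positive draws are rejected
    and redrawn (vanishingly rare at cv = 0.2).  ``cv=0`` returns the base
    unchanged.  Deterministic for a fixed seed or Generator.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return base
    rng = np.random.default_rng(rng)
    draws = {}
    for name in HETEROGENEOUS_FIELDS:
        mu = getattr(base, name)
        if mu == 0.0:
            draws[name] = 0.0
            continue
        val = rng.normal(mu, cv * mu)
        while val <= 0.0:
            val = rng.normal(mu, cv * mu)
        draws[name] = float(val)
    return base.with_(**draws)


def _single_cell_trace(params: CellParameters, t_total_s: float,
                       sample_ms: float = 100.0, backend: str = "reference",
                       rtol: float = 1e-6, atol: float = 1e-8):
    """Integrate one uncoupled cell; returns (t_ms, Y) sampled traces."""
    from scipy.integrate import solve_ivp

    be = get_backend(backend)
    p = be.pack_params([params])
    y0 = be.rest_state(1).ravel()

    def f(t, y):
        return be.rhs(t, y.reshape(1, -1), p).ravel()

    t_end = t_total_s * 1e3
    sol = solve_ivp(f, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=np.arange(0.0, t_end, sample_ms), max_step=2000.0)
    if not sol.success:
        raise RuntimeError(f"single-cell integration failed: {sol.message}")
    return sol.t, sol.y.T.reshape(-1, 1, be.n_state)


def _is_oscillating(t_ms: np.ndarray, ca: np.ndarray,
                    discard_s: float = 100.0, min_excursion: float = 0.05,
                    min_peaks: int = 2) -> bool:
    """Sustained-oscillation criterion on a Ca²⁺ trace.

    After discarding the first ``discard_s`` seconds, the trace must show a
    peak-to-trough excursion above ``min_excursion`` µM and at least
    ``min_peaks`` upward crossings of the mid-level.
    """
    keep = t_ms >= discard_s * 1e3
    x = ca[keep]
    if x.size < 4:
        return False
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= min_excursion:
        return False
    mid = 0.5 * (lo + hi)
    above = x > mid
    ups = int(np.count_nonzero(np.diff(above.astype(np.int8)) == 1))
    return ups >= min_peaks


def find_firing_threshold(params: CellParameters,
                          glucose_grid, *, t_total_s: float = 200.0,
                          discard_s: float = 100.0,
                          backend: str = "reference") -> float | None:
    """Smallest glucose on the grid with sustained single-cell oscillations.

    Scans the (sorted) glucose grid; each point is simulated for
    ``t_total_s`` seconds from rest with the first ``discard_s`` seconds
    discarded as transient.  Returns ``None`` if no grid point oscillates
    ("no threshold found").  With the default (unsampled) parameters and a
    0.1 mM grid over 6–8 mM, the transition sits at the bursting onset near
    6.9 mM glucose.
    """
    for glc in sorted(float(g) for g in np.atleast_1d(glucose_grid)):
        t_ms, y = _single_cell_trace(params.with_(glucose=glc), t_total_s)
        if _is_oscillating(t_ms, y[:, 0, CellState.IDX_CA],
                           discard_s=discard_s):
            return glc
    return None
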