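"""Network assembly: hubs, per-cell glucose, heterogeneity, gap junctions.

Turns a geometric architecture into a runnable islet.  A random 10% of
cells are designated hubs: highly metabolic cells whose doubled
glucokinase expression is mimicked by exposing them to a higher effective
glucose (11 mM) than the remaining cells, which draw theirs uniformly from
a near-threshold interval (6.0–7.0 mM by default).  Gap-junction
conductances are assigned per contact edge, either from a single Gaussian,
a unimodal low-mean Gaussian, or a bimodal scheme in which any edge
touching a hub uses a stronger distribution (hubs are preferentially
coupled).  All randomness flows from one master seed through independent
sub-streams, so changing e.g. the hub fraction does not perturb the
conductance draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import ContactGraph, IsletArchitecture, build_contact_graph
from .cell_model import CellParameters, sample_heterogeneous_params

__all__ = [
    "GJ_MODES",
    "GapJunctionTable",
    "IsletNetwork",
    "assign_hubs",
    "assign_glucose",
    "assign_gap_junctions",
    "assemble_network",
]

#: Gap-junction distribution modes: (hub-edge mean/sd, non-hub-edge mean/sd),
#: in pS.  In the two unimodal modes both entries coincide.
GJ_MODES = {
    "single-gaussian": ((50.0, 35.0), (50.0, 35.0)),   # N(50, 0.7·50)
    "unimodal": ((20.0, 14.0), (20.0, 14.0)),          # N(20, 0.7·20)
    "bimodal": ((50.0, 10.0), (10.0, 2.0)),            # hubs strong
}


@dataclass(frozen=True)
class GapJunctionTable:
    """Per-edge gap-junction conductances (pS) for an undirected graph."""

    edges: np.ndarray           # (n_edges, 2) int, i < j
    conductances: np.ndarray    # (n_edges,) pS, all > 0
    mode: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        g = np.asarray(self.conductances, dtype=float)
        if g.shape[0] != self.edges.shape[0]:
            raise ValueError("one conductance per edge required")
        if np.any(g <= 0):
            raise ValueError("gap-junction conductances must be positive")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def total_conductance_per_cell(self, n_cells: int) -> np.ndarray:
        """Summed conductance (pS) over each cell's contacts."""
        tot = np.zeros(n_cells)
        if self.n_edges:
            np.add.at(tot, self.edges[:, 0], self.conductances)
            np.add.at(tot, self.edges[:, 1], self.conductances)
        return tot


@dataclass(frozen=True)
class IsletNetwork:
    """A fully parameterised, seeded islet ready for simulation."""

    architecture: IsletArchitecture
    graph: ContactGraph
    hubs: np.ndarray                    # sorted hub indices
    cells: tuple                        # tuple[CellParameters], len n_cells
    gap_junctions: GapJunctionTable
    master_seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.architecture.n_cells

    @property
    def hub_mask(self) -> np.ndarray:
        m = np.zeros(self.n_cells, dtype=bool)
        m[self.hubs] = True
        return m

    @property
    def nonhubs(self) -> np.ndarray:
        return np.where(~self.hub_mask)[0]

    @property
    def glucose(self) -> np.ndarray:
        return np.array([c.glucose for c in self.cells])

    def cell_table(self) -> pd.DataFrame:
        """Snapshot of per-cell attributes as a DataFrame."""
        xyz = self.architecture.coords
        return pd.DataFrame({
            "id": np.arange(self.n_cells),
            "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
            "is_hub": self.hub_mask,
            "glucose": self.glucose,
        })

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "i": self.gap_junctions.edges[:, 0],
            "j": self.gap_junctions.edges[:, 1],
            "distance_um": self.graph.distances,
            "g_pS": self.gap_junctions.conductances,
        })

    def export(self, cell_path, edge_path) -> None:
        """Write the cell and edge tables as delimited text."""
        self.cell_table().to_csv(cell_path, index=False)
        self.edge_table().to_csv(edge_path, index=False)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def assign_hubs(arch: IsletArchitecture, hub_fraction: float = 0.10,
                rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Uniformly random hub subset of size round(hub_fraction · n).

    Ties at .5 round up.  Raises if the rounded count is zero.
    """
    if not 0 < hub_fraction < 1:
        raise ValueError("hub_fraction must be in (0, 1)")
    n_hubs = _round_half_up(hub_fraction * arch.n_cells)
    if n_hubs == 0:
        raise ValueError(
            f"hub_fraction={hub_fraction} yields zero hubs for "
            f"{arch.n_cells} cells")
    rng = np.random.default_rng(rng)
    hubs = rng.choice(arch.n_cells, size=n_hubs, replace=False)
    return np.sort(hubs)


def assign_glucose(n_cells: int, hubs: np.ndarray, g_hub: float = 11.0,
                   g_nonhub_interval: tuple[float, float] = (6.0, 7.0),
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Per-cell glucose: hubs get exactly ``g_hub``, others U(lo, hi)."""
    lo, hi = g_nonhub_interval
    if not (0 < lo <= hi):
        raise ValueError("glucose interval must be ordered and positive")
    rng = np.random.default_rng(rng)
    glucose = rng.uniform(lo, hi, size=n_cells)
    glucose[np.asarray(hubs, dtype=int)] = g_hub
    return glucose


def _positive_normal(rng, mu, sigma, size):
    """Normal draws redrawn until positive."""
    out = rng.normal(mu, sigma, size=size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = out <= 0
    return out


def assign_gap_junctions(graph: ContactGraph, mode: str = "bimodal",
                         hubs: np.ndarray | None = None,
                         rng: np.random.Generator | int | None = None,
                         swap_bimodal_means: bool = False,
                         ) -> GapJunctionTable:
    """Draw one positive conductance per contact edge.

    In ``bimodal`` mode an edge uses the strong (hub) distribution iff at
    least one endpoint is a hub — hubs are preferentially coupled to every
    cell they touch.  ``swap_bimodal_means`` exchanges the hub and non-hub
    distributions (sensitivity analysis of the opposite assignment).
    """
    if mode not in GJ_MODES:
        raise ValueError(f"unknown gap-junction mode {mode!r}; "
                         f"available: {sorted(GJ_MODES)}")
    (mu_h, sd_h), (mu_n, sd_n) = GJ_MODES[mode]
    if swap_bimodal_means:
        (mu_h, sd_h), (mu_n, sd_n) = (mu_n, sd_n), (mu_h, sd_h)
    rng = np.random.default_rng(rng)
    n_edges = graph.n_edges
    if mode == "bimodal":
        if hubs is None:
            raise ValueError("bimodal mode requires the hub index set")
        hub_mask = np.zeros(graph.n_cells, dtype=bool)
        hub_mask[np.asarray(hubs, dtype=int)] = True
        edge_is_hub = (hub_mask[graph.edges[:, 0]]
                       | hub_mask[graph.edges[:, 1]]) if n_edges else \
            np.zeros(0, dtype=bool)
        g = np.empty(n_edges)
        g[edge_is_hub] = _positive_normal(rng, mu_h, sd_h,
                                          int(edge_is_hub.sum()))
        g[~edge_is_hub] = _positive_normal(rng, mu_n, sd_n,
                                           int((~edge_is_hub).sum()))
        params = {"hub_mu": mu_h, "hub_sigma": sd_h,
                  "nonhub_mu": mu_n, "nonhub_sigma": sd_n}
    else:
        g = _positive_normal(rng, mu_h, sd_h, n_edges)
        params = {"mu": mu_h, "sigma": sd_h}
    return GapJunctionTable(graph.edges, g, mode, params)


def assemble_network(arch: IsletArchitecture, *, master_seed: int = 0,
                     hub_fraction: float = 0.10, g_hub: float = 11.0,
                     g_nonhub_interval: tuple[float, float] = (6.0, 7.0),
                     gj_mode: str = "bimodal", heterogeneity_cv: float = 0.2,
                     base_params: CellParameters | None = None,
                     dthr: float | None = None,
                     p_serca_scale: float = 1.0,
                     swap_bimodal_means: bool = False) -> IsletNetwork:
    """Build a complete islet network from an architecture.

    Hub assignment, glucose draws, gap-junction draws and cell-parameter
    heterogeneity each consume an independent sub-stream spawned from
    ``master_seed``, making the assembly bit-reproducible and its parts
    independently perturbable.  ``p_serca_scale`` scales the maximal SERCA
    flux of the hub cells (hubs express less SERCA2; non-hubs keep the
    default flux).
    """
    base = base_params if base_params is not None else CellParameters()
    if p_serca_scale <= 0:
        raise ValueError("p_serca_scale must be positive")
    graph = build_contact_graph(arch, dthr) if dthr is not None \
        else build_contact_graph(arch)
    ss = np.random.SeedSequence(master_seed)
    s_hub, s_glc, s_gj, s_het = ss.spawn(4)

    hubs = assign_hubs(arch, hub_fraction, np.random.default_rng(s_hub))
    glucose = assign_glucose(arch.n_cells, hubs, g_hub, g_nonhub_interval,
                             np.random.default_rng(s_glc))
    gj = assign_gap_junctions(graph, gj_mode, hubs,
                              np.random.default_rng(s_gj),
                              swap_bimodal_means=swap_bimodal_means)
    rng_het = np.random.default_rng(s_het)
    hub_mask = np.zeros(arch.n_cells, dtype=bool)
    hub_mask[hubs] = True
    cells = []
    for i in range(arch.n_cells):
        p = sample_heterogeneous_params(base, heterogeneity_cv, rng_het)
        scale = p_serca_scale if hub_mask[i] else 1.0
        cells.append(p.with_(glucose=float(glucose[i]),
                             is_hub=bool(hub_mask[i]),
                             p_serca=base.p_serca * scale))
    return IsletNetwork(arch, graph, hubs, tuple(cells), gj,
                        master_seed=master_seed)
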