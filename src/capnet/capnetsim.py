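"""Random-topology capillary networks and the Kirchhoff flow solve.

The cerebral capillary bed is represented as a random graph on a 3-D
integer lattice.  Each node considers its three forward neighbours
(+x, +y, +z) and connects to a random subset of them; choosing two of
the three yields on average a 4-edge topology (every node also receives
edges from its backward neighbours), choosing one or two with equal
probability yields a 3-edge topology, and so on.  Capillary lengths and
radii are drawn independently per edge from truncated normal
distributions around the morphometric means (57.4 um length, 5.9 um
diameter); the hematocrit-dependent effective specific resistance of
:mod:`capnet.hemres` converts geometry to an edge resistance.

Flow through the network is the nodal Kirchhoff problem: prescribed
pressures on randomly placed inlet (arteriolar) and outlet (venular)
nodes, mass balance everywhere else, i.e. a sparse conductance-Laplacian
system solved for nodal pressures.  The total network resistance is the
applied pressure difference over the total inflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from scipy.stats import truncnorm

from .errors import ConfigError, DegenerateGeometry, SingularSystem
from .hemres import ViscosityModel, effective_specific_resistance
from .units import UM

__all__ = [
    "TopologySpec",
    "GeometrySampler",
    "CapillaryNetwork",
    "FlowSolution",
    "generate_topology",
    "sample_geometry",
    "assign_resistances",
    "place_sources_sinks",
    "solve_flow",
    "total_resistance_vs_H",
    "dims_for_edges",
    "write_network",
    "read_network",
]

#: direct sparse factorisation below this many unknowns, iterative above
_DIRECT_LIMIT = 200_000


@dataclass(frozen=True)
class TopologySpec:
    """Lattice extents, target mean node degree and RNG seed."""

    dims: tuple[int, int, int]
    mean_degree: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dims):
            raise ConfigError("lattice dimensions must be positive")
        if not (2.0 <= self.mean_degree <= 6.0):
            raise ConfigError("mean degree must lie in [2, 6]")

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz


@dataclass(frozen=True)
class GeometrySampler:
    """Per-edge capillary geometry distributions.

    Truncated normals with configurable coefficient of variation;
    defaults reproduce the morphometric means (length 57.4 um, diameter
    5.9 um).  The radius truncation keeps every vessel above the
    degenerate 1.5 um core-law limit.
    """

    mean_length: float = 57.4e-6
    mean_diameter: float = 5.9e-6
    cv: float = 0.2
    length_bounds: tuple[float, float] = (20e-6, 120e-6)
    radius_bounds: tuple[float, float] = (1.7e-6, 4.5e-6)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_bounds
        if not (lo < self.mean_length < hi):
            raise ConfigError("length truncation bounds exclude the mean")
        rlo, rhi = self.radius_bounds
        if not (rlo < self.mean_diameter / 2 < rhi):
            raise ConfigError("radius truncation bounds exclude the mean")
        if rlo <= 1.6e-6:
            raise ConfigError("radius truncation must stay above 1.6 um")
        if self.cv < 0:
            raise ConfigError("coefficient of variation must be nonnegative")


@dataclass(frozen=True)
class CapillaryNetwork:
    """Lattice graph with optional per-edge geometry and resistances.

    ``edges`` is an ``(n_edges, 2)`` integer array of node indices
    (node ``x + nx*(y + ny*z)`` sits at lattice point ``(x, y, z)``).
    Geometry, hematocrit, resistances and boundary roles are filled in
    by the pipeline stages and ``None`` beforehand.
    """

    dims: tuple[int, int, int]
    edges: np.ndarray
    length: np.ndarray | None = None
    radius: np.ndarray | None = None
    hematocrit: float | None = None
    resistance: np.ndarray | None = None
    inlets: np.ndarray | None = None
    outlets: np.ndarray | None = None
    p_in: float = 1.0
    p_out: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def node_positions(self) -> np.ndarray:
        """Lattice coordinates, shape (n_nodes, 3)."""
        nx, ny, nz = self.dims
        idx = np.arange(self.n_nodes)
        x = idx % nx
        y = (idx // nx) % ny
        z = idx // (nx * ny)
        return np.column_stack([x, y, z])


@dataclass(frozen=True)
class FlowSolution:
    """Nodal pressures and edge fluxes of one Kirchhoff solve.

    ``pressure`` is NaN on nodes excluded from the solve (components
    with no boundary node).  Fluxes are signed from the lower- to the
    higher-indexed endpoint of each edge.
    """

    pressure: np.ndarray  # Pa
    edge_flux: np.ndarray  # m^3/s
    total_inflow: float  # m^3/s
    total_resistance: float  # Pa*s/m^3
    included: np.ndarray  # bool mask over nodes

    def kirchhoff_residual(self, network: CapillaryNetwork) -> float:
        """Largest interior-node flux imbalance relative to the local
        flux scale (machine-level for a converged solve)."""
        n = network.n_nodes
        net = np.zeros(n)
        scale = np.zeros(n)
        i, j = network.edges[:, 0], network.edges[:, 1]
        np.add.at(net, i, -self.edge_flux)
        np.add.at(net, j, self.edge_flux)
        np.add.at(scale, i, np.abs(self.edge_flux))
        np.add.at(scale, j, np.abs(self.edge_flux))
        interior = self.included.copy()
        for nodes in (network.inlets, network.outlets):
            if nodes is not None:
                interior[nodes] = False
        # dead-end branches carry only round-off flux: no-flow nodes
        # (local scale negligible against the network's flux scale) are
        # balanced by construction and excluded from the relative metric
        interior &= scale > 1e-12 * scale.max()
        if not interior.any():
            return 0.0
        return float(np.max(np.abs(net[interior]) / scale[interior]))


def _forward_neighbors(dims: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """For every node, its up-to-three forward lattice neighbours.

    Returns (neighbor indices (n, 3), availability mask (n, 3)); the
    index is undefined where the mask is False.
    """
    nx, ny, nz = dims
    n = nx * ny * nz
    idx = np.arange(n)
    x = idx % nx
    y = (idx // nx) % ny
    z = idx // (nx * ny)
    nbr = np.stack([idx + 1, idx + nx, idx + nx * ny], axis=1)
    ok = np.stack([x + 1 < nx, y + 1 < ny, z + 1 < nz], axis=1)
    return nbr, ok


def generate_topology(spec: TopologySpec) -> CapillaryNetwork:
    """Draw a random k-edge lattice topology.

    Each node connects to ``m`` of its available forward neighbours,
    where ``m`` alternates between ``floor(k/2)`` and ``ceil(k/2)`` with
    the probability that makes the expected degree equal ``k`` (interior
    nodes; boundary nodes use what is available).  Deterministic for a
    fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    nbr, ok = _forward_neighbors(spec.dims)
    n = spec.n_nodes

    half = spec.mean_degree / 2.0
    m_lo = int(np.floor(half))
    frac = half - m_lo
    m = m_lo + (rng.random(n) < frac).astype(int)

    # rank the (up to 3) forward candidates by a random key and keep the
    # m smallest; unavailable directions get an infinite key
    keys = rng.random((n, 3))
    keys[~ok] = np.inf
    order = np.argsort(keys, axis=1)
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.broadcast_to(np.arange(3), (n, 3)).copy(), axis=1)
    n_avail = ok.sum(axis=1)
    take = rank < np.minimum(m, n_avail)[:, None]

    src = np.repeat(np.arange(n), 3).reshape(n, 3)[take]
    dst = nbr[take]
    edges = np.column_stack([src, dst]).astype(np.int64)
    return CapillaryNetwork(
        dims=spec.dims,
        edges=edges,
        provenance={"topology": {"dims": list(spec.dims), "mean_degree": spec.mean_degree, "seed": spec.seed}},
    )


def sample_geometry(network: CapillaryNetwork, sampler: GeometrySampler) -> CapillaryNetwork:
    """Attach i.i.d. truncated-normal lengths and radii to every edge."""
    if network.n_edges == 0:
        raise ConfigError("network has no edges to sample geometry for")
    rng = np.random.default_rng(sampler.seed)
    ne = network.n_edges

    def draw(mean: float, bounds: tuple[float, float], size: int) -> np.ndarray:
        if sampler.cv == 0:
            return np.full(size, mean)
        sd = sampler.cv * mean
        a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    length = draw(sampler.mean_length, sampler.length_bounds, ne)
    radius = draw(sampler.mean_diameter / 2.0, sampler.radius_bounds, ne)
    prov = dict(network.provenance)
    prov["sampler"] = {
        "mean_length_um": sampler.mean_length / UM,
        "mean_diameter_um": sampler.mean_diameter / UM,
        "cv": sampler.cv,
        "seed": sampler.seed,
    }
    return replace(network, length=length, radius=radius, provenance=prov)


def assign_resistances(
    network: CapillaryNetwork, H: float, visc: ViscosityModel | None = None
) -> CapillaryNetwork:
    """Edge resistances from the effective specific resistance at tube
    hematocrit ``H`` times the edge length."""
    if network.length is None or network.radius is None:
        raise ConfigError("sample geometry before assigning resistances")
    try:
        r_eff = effective_specific_resistance(network.radius, H, visc)
    except DegenerateGeometry:
        bad = int(np.argmin(network.radius))
        raise DegenerateGeometry(
            f"edge {bad} has radius {network.radius[bad] / UM:.3f} um, too "
            "narrow for the two-phase resistance model"
        ) from None
    return replace(network, hematocrit=float(H), resistance=r_eff * network.length)


def place_sources_sinks(
    network: CapillaryNetwork,
    inlet_fraction: float = 0.02,
    outlet_fraction: float = 0.02,
    p_in: float = 1.0,
    p_out: float = 0.0,
    seed: int = 0,
) -> CapillaryNetwork:
    """Mark disjoint random node subsets as pressure inlets/outlets."""
    for name, f in (("inlet", inlet_fraction), ("outlet", outlet_fraction)):
        if not (0 < f <= 0.5):
            raise ConfigError(f"{name} fraction must lie in (0, 0.5]")
    n = network.n_nodes
    k_in = max(1, int(round(inlet_fraction * n)))
    k_out = max(1, int(round(outlet_fraction * n)))
    if k_in + k_out > n:
        raise ConfigError("inlet and outlet fractions exhaust the node set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    prov = dict(network.provenance)
    prov["boundary"] = {
        "inlet_fraction": inlet_fraction,
        "outlet_fraction": outlet_fraction,
        "seed": seed,
    }
    return replace(
        network,
        inlets=np.sort(perm[:k_in]),
        outlets=np.sort(perm[k_in : k_in + k_out]),
        p_in=float(p_in),
        p_out=float(p_out),
        provenance=prov,
    )


def solve_flow(network: CapillaryNetwork) -> FlowSolution:
    """Solve the nodal Kirchhoff system for pressures and fluxes.

    Components without any boundary node are excluded from the solve
    (their pressures are NaN).  Raises :class:`SingularSystem` when no
    flow path exists (no inlet or no outlet among the included nodes).
    """
    if network.resistance is None:
        raise ConfigError("assign resistances before solving")
    if network.inlets is None or network.outlets is None:
        raise ConfigError("place sources and sinks before solving")
    if len(network.inlets) == 0 or len(network.outlets) == 0:
        raise SingularSystem("need at least one inlet and one outlet")

    n = network.n_nodes
    i, j = network.edges[:, 0], network.edges[:, 1]
    g = 1.0 / network.resistance

    adj = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    boundary = np.zeros(n, dtype=bool)
    boundary[network.inlets] = True
    boundary[network.outlets] = True
    keep_comp = np.zeros(comp.max() + 1, dtype=bool)
    keep_comp[comp[boundary]] = True
    included = keep_comp[comp]

    # components that can actually carry flow need both roles; warn-free
    # contract: at least one component holds an inlet and an outlet
    in_comp = set(comp[network.inlets])
    out_comp = set(comp[network.outlets])
    if not (in_comp & out_comp):
        raise SingularSystem(
            "no connected component contains both an inlet and an outlet"
        )

    lap = sp.coo_matrix(
        (np.concatenate([g, g, -g, -g]), (np.concatenate([i, j, i, j]), np.concatenate([i, j, j, i]))),
        shape=(n, n),
    ).tocsr()

    pressure = np.full(n, np.nan)
    fixed = boundary.copy()
    pvals = np.zeros(n)
    pvals[network.inlets] = network.p_in
    pvals[network.outlets] = network.p_out

    free = included & ~fixed
    free_idx = np.flatnonzero(free)
    if free_idx.size:
        A = lap[free_idx][:, free_idx].tocsc()
        rhs = -lap[free_idx][:, np.flatnonzero(fixed)] @ pvals[np.flatnonzero(fixed)]
        if free_idx.size <= _DIRECT_LIMIT:
            sol = spla.spsolve(A, rhs)
        else:
            # Jacobi-preconditioned CG on the SPD reduced Laplacian
            M = sp.diags(1.0 / A.diagonal())
            sol, info = spla.cg(A, rhs, M=M, rtol=1e-12, maxiter=20_000)
            if info != 0:
                raise SingularSystem(f"iterative Kirchhoff solve failed (info={info})")
        if not np.all(np.isfinite(sol)):
            raise SingularSystem("Kirchhoff solve produced non-finite pressures")
        pressure[free_idx] = sol
    pressure[fixed] = pvals[fixed]
    pressure[~included] = np.nan

    pi = np.where(np.isnan(pressure[i]), 0.0, pressure[i])
    pj = np.where(np.isnan(pressure[j]), 0.0, pressure[j])
    edge_flux = g * (pi - pj)
    dead = ~included[i]
    edge_flux[dead] = 0.0

    net_out = np.zeros(n)
    np.add.at(net_out, i, edge_flux)
    np.add.at(net_out, j, -edge_flux)
    inflow = float(net_out[network.inlets].sum())
    dp = network.p_in - network.p_out
    total_resistance = dp / inflow if inflow != 0 else np.inf
    return FlowSolution(
        pressure=pressure,
        edge_flux=edge_flux,
        total_inflow=float(inflow),
        total_resistance=float(total_resistance),
        included=included,
    )


def dims_for_edges(n_edges: int, mean_degree: float, aspect: float = 1.0) -> tuple[int, int, int]:
    """Cubic-ish lattice dims giving approximately ``n_edges`` edges at
    the requested mean degree (edges ~ nodes * k/2)."""
    n_nodes = n_edges / (mean_degree / 2.0)
    side = max(2, int(round(n_nodes ** (1.0 / 3.0) * aspect)))
    return (side, side, max(2, int(round(n_nodes / side**2))))


def build_network(
    spec: TopologySpec,
    sampler: GeometrySampler,
    H: float,
    inlet_fraction: float = 0.02,
    outlet_fraction: float = 0.02,
    p_in: float = 1.0,
    p_out: float = 0.0,
    visc: ViscosityModel | None = None,
) -> CapillaryNetwork:
    """End-to-end pipeline: topology, geometry, resistances, boundaries.

    All randomness derives from ``spec.seed`` and ``sampler.seed``; the
    boundary placement reuses ``spec.seed`` offset by a fixed stride so
    the three stages stay independently reproducible.
    """
    net = generate_topology(spec)
    net = sample_geometry(net, sampler)
    net = assign_resistances(net, H, visc)
    return place_sources_sinks(
        net, inlet_fraction, outlet_fraction, p_in, p_out, seed=spec.seed + 10_007
    )


def total_resistance_vs_H(
    spec: TopologySpec,
    sampler: GeometrySampler,
    H_list: Sequence[float],
    replicates: int = 5,
    visc: ViscosityModel | None = None,
    inlet_fraction: float = 0.02,
    outlet_fraction: float = 0.02,
) -> tuple[pd.DataFrame, float]:
    """Mean and spread of total network resistance per hematocrit.

    Each replicate regenerates topology, geometry and boundary placement
    from ``spec.seed + r`` / ``sampler.seed + r`` and solves at every
    ``H``.  Returns the per-H summary table and the least-squares slope
    of mean resistance versus H.
    """
    records = []
    for r in range(replicates):
        sp_r = replace(spec, seed=spec.seed + r)
        sa_r = replace(sampler, seed=sampler.seed + r)
        net = generate_topology(sp_r)
        net = sample_geometry(net, sa_r)
        net = place_sources_sinks(
            net, inlet_fraction, outlet_fraction, seed=sp_r.seed + 10_007
        )
        for H in H_list:
            net_h = assign_resistances(net, H, visc)
            sol = solve_flow(net_h)
            records.append(
                {"H": H, "replicate": r, "resistance": sol.total_resistance}
            )
    df = pd.DataFrame.from_records(records)
    table = (
        df.groupby("H")["resistance"].agg(mean="mean", sd="std").reset_index()
    )
    slope = float(np.polyfit(table["H"], table["mean"], 1)[0])
    return table, slope


# ---------------------------------------------------------------------------
# serialization: CSV edge list + JSON sidecar for roles and provenance

_CSV_COLUMNS = [
    "node_i",
    "node_j",
    "length_um",
    "radius_um",
    "hematocrit",
    "resistance_pa_s_per_m3",
]


def write_network(network: CapillaryNetwork, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write the edge list as CSV and node roles/provenance as JSON.

    Floats carry 12 significant digits so a read/write round trip is
    lossless at that precision.
    """
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "node_i": network.edges[:, 0],
            "node_j": network.edges[:, 1],
            "length_um": np.nan if network.length is None else network.length / UM,
            "radius_um": np.nan if network.radius is None else network.radius / UM,
            "hematocrit": np.nan if network.hematocrit is None else network.hematocrit,
            "resistance_pa_s_per_m3": np.nan
            if network.resistance is None
            else network.resistance,
        },
        columns=_CSV_COLUMNS,
    )
    df.to_csv(csv_path, index=False, float_format="%.12g")
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    sidecar = {
        "dims": list(network.dims),
        "p_in": network.p_in,
        "p_out": network.p_out,
        "inlets": [] if network.inlets is None else network.inlets.tolist(),
        "outlets": [] if network.outlets is None else network.outlets.tolist(),
        "provenance": network.provenance,
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=1))


def read_network(csv_path: str | Path, json_path: str | Path | None = None) -> CapillaryNetwork:
    """Inverse of :func:`write_network`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"network CSV missing columns: {missing}")
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    sidecar = json.loads(Path(json_path).read_text())

    def col(name: str, scale: float = 1.0) -> np.ndarray | None:
        v = df[name].to_numpy(dtype=float)
        return None if np.all(np.isnan(v)) else v * scale

    h = df["hematocrit"].to_numpy(dtype=float)
    inlets = np.asarray(sidecar["inlets"], dtype=np.int64)
    outlets = np.asarray(sidecar["outlets"], dtype=np.int64)
    return CapillaryNetwork(
        dims=tuple(sidecar["dims"]),
        edges=df[["node_i", "node_j"]].to_numpy(dtype=np.int64),
        length=col("length_um", UM),
        radius=col("radius_um", UM),
        hematocrit=None if np.all(np.isnan(h)) else float(h[0]),
        resistance=col("resistance_pa_s_per_m3"),
        inlets=inlets if inlets.size else None,
        outlets=outlets if outlets.size else None,
        p_in=float(sidecar["p_in"]),
        p_out=float(sidecar["p_out"]),
        provenance=sidecar.get("provenance", {}),
    )


def export_pressures(network: CapillaryNetwork, solution: FlowSolution, path: str | Path) -> None:
    """CSV ``node,x,y,z,pressure_pa`` for external visualisation."""
    pos = network.node_positions()
    df = pd.DataFrame(
        {
            "node": np.arange(network.n_nodes),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "pressure_pa": solution.pressure,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
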