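"""Axisymmetric Stokes finite elements for single-file RBC trains.

The flow of a train of red blood cells through a capillary is modelled
as steady Stokes flow of a single fluid with a discontinuous viscosity:
plasma viscosity ``mu1`` outside the cells, and a much larger viscosity
``mu2`` inside them, which renders the cells effectively rigid.  The
domain is the axial section ``(0, rc) x (0, L)`` in cylindrical
coordinates ``(r, z)``; the flow is assumed axisymmetric with no swirl.

The discretisation is equal-order P1/P1 on a structured triangulated
grid, stabilised by a weak-compressibility penalty ``eps * (p, q)``.
Pressure Dirichlet values drive the flow: ``p = p0`` on the inlet plane
``z = 0`` and ``p = 0`` on the outlet ``z = L``; no slip on the wall
``r = rc``; symmetry (``u_r = 0``) on the axis.  The weak form carries
the cylindrical volume element ``r dr dz``, the hoop-strain term
``u_r v_r / r`` and the cylindrical divergence ``u_r/r + du_r/dr +
du_z/dz``.

Internally lengths are expressed in micrometres (pressures in Pa,
viscosities in Pa*s), which keeps matrix entries well scaled; the
Stokes equations are form-invariant under this rescaling, so velocities
emerge in um/s and fluxes in um^3/s.  Public functions accept and
return SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DegenerateGeometry, FitUnderdetermined, SingularSystem
from .hemres import rbc_core_radius
from .units import UM, MMHG

__all__ = [
    "RBCShapeSpec",
    "RBCTrainDomain",
    "StructuredMesh",
    "StokesSolution",
    "build_rbc_train",
    "solve_stokes",
    "fem_specific_resistance",
    "sweep_and_fit",
]

#: default inlet pressure (Pa); resistance is independent of its value
DEFAULT_P0 = 0.63 * MMHG

#: default weak-compressibility penalty, 1/(Pa*s)
DEFAULT_EPS = 1e-8


@dataclass(frozen=True)
class RBCShapeSpec:
    """Axial shape of one red blood cell.

    ``cylindrical`` cells are flat-ended cylinders of radius ``r0`` and
    length ``l`` (default 3 um, the average axial extent of an RBC in
    single file).  ``parabolic-capped`` cells replace the flat front and
    back by paraboloidal caps of depth ``h`` (default ``l/3``), a simple
    proxy for the deformed bullet shape observed in narrow capillaries.
    """

    kind: Literal["cylindrical", "parabolic-capped"] = "cylindrical"
    l: float = 3e-6
    h: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cylindrical", "parabolic-capped"):
            raise ValueError(f"unknown RBC shape kind {self.kind!r}")
        if self.l <= 0:
            raise ValueError("RBC length must be positive")
        if self.kind == "parabolic-capped":
            h = self.l / 3.0 if self.h is None else self.h
            if not (0 < h < self.l / 2):
                raise ValueError("cap depth must satisfy 0 < h < l/2")
            object.__setattr__(self, "h", h)
        elif self.h is not None:
            raise ValueError("cap depth applies to parabolic-capped cells only")


@dataclass(frozen=True)
class RBCTrainDomain:
    """Axisymmetric rectangle ``(0, rc) x (0, L)`` with RBC subregions.

    ``regions`` holds the axial intervals occupied by cells; membership
    of a point additionally requires ``r <= r0`` (shrunk inside the
    caps for parabolic-capped cells).  All lengths in metres.
    """

    rc: float
    L: float
    r0: float
    regions: tuple[tuple[float, float], ...]
    shape: RBCShapeSpec

    @property
    def realized_H(self) -> float:
        """Axial RBC occupancy actually laid out (may differ from the
        requested hematocrit by one-cell rounding)."""
        return sum(z1 - z0 for z0, z1 in self.regions) / self.L

    def in_rbc(self, r: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Vectorised membership test for points ``(r, z)``."""
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        inside = np.zeros(np.broadcast(r, z).shape, dtype=bool)
        for z0, z1 in self.regions:
            if self.shape.kind == "cylindrical":
                inside |= (z >= z0) & (z <= z1) & (r <= self.r0)
            else:
                h = self.shape.h
                assert h is not None
                zm0, zm1 = z0 + h, z1 - h
                rloc = np.full_like(r, -1.0)
                front = (z >= z0) & (z < zm0)
                mid = (z >= zm0) & (z <= zm1)
                back = (z > zm1) & (z <= z1)
                with np.errstate(invalid="ignore"):
                    rloc = np.where(front, self.r0 * np.sqrt(np.clip(z - z0, 0, None) / h), rloc)
                    rloc = np.where(back, self.r0 * np.sqrt(np.clip(z1 - z, 0, None) / h), rloc)
                rloc = np.where(mid, self.r0, rloc)
                inside |= r <= rloc
        return inside


def build_rbc_train(
    rc: float, L: float, H: float, shape: RBCShapeSpec | None = None
) -> RBCTrainDomain:
    """Lay out an RBC train realizing tube hematocrit ``H``, cells
    evenly spaced with equal plasma gaps and a half-gap at each end
    (approximately periodic).

    ``H`` follows the axial single-file convention ``L_hat / L``.  For
    flat-ended cylinders the cell count is ``n = round(H L / l)``.
    Paraboloidal caps carry only half the volume of the cylinder they
    replace, so one parabolic-capped cell holds the core volume of a
    cylinder of length ``l - h``; the count becomes
    ``n = round(H L / (l - h))`` so that the realized core volume (what
    tube hematocrit measures) still matches ``H``.  ``H = 1`` yields a
    single region spanning the whole vessel; raises
    :class:`DegenerateGeometry` for ``rc <= 1.5 um``.
    """
    if not (0 <= H <= 1):
        raise ValueError("tube hematocrit must lie in [0, 1]")
    if shape is None:
        shape = RBCShapeSpec()
    if L < shape.l:
        raise ValueError("vessel shorter than a single RBC")
    r0 = rbc_core_radius(rc)  # raises DegenerateGeometry when rc <= 1.5 um
    l_vol = shape.l if shape.h is None else shape.l - shape.h
    n_max = int(math.floor(L / shape.l + 1e-9))
    n = min(int(round(H * L / l_vol)), n_max)
    if n == 0:
        regions: tuple[tuple[float, float], ...] = ()
    elif n * shape.l >= L:
        regions = ((0.0, L),)
    else:
        gap = (L - n * shape.l) / n
        starts = gap / 2.0 + np.arange(n) * (shape.l + gap)
        regions = tuple((float(s), float(s + shape.l)) for s in starts)
    return RBCTrainDomain(rc=rc, L=L, r0=r0, regions=regions, shape=shape)


@dataclass(frozen=True)
class StructuredMesh:
    """Structured triangulation of the axial section.

    ``nr x nz`` rectangles (default 50 x 1000), each split into two
    triangles; nodes are numbered radially-fastest.
    """

    nr: int = 50
    nz: int = 1000

    def __post_init__(self) -> None:
        if self.nr < 2 or self.nz < 2:
            raise ValueError("mesh must have at least 2 cells per direction")

    @property
    def n_nodes(self) -> int:
        return (self.nr + 1) * (self.nz + 1)

    def nodes(self, rc: float, L: float) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinates (r, z) in the units of ``rc`` and ``L``."""
        r = np.linspace(0.0, rc, self.nr + 1)
        z = np.linspace(0.0, L, self.nz + 1)
        Z, R = np.meshgrid(z, r, indexing="ij")
        return R.ravel(), Z.ravel()

    def triangles(self) -> np.ndarray:
        """Connectivity (n_tri, 3); each grid cell split along its
        up-right diagonal."""
        nr1 = self.nr + 1
        i = np.arange(self.nr)
        j = np.arange(self.nz)
        J, I = np.meshgrid(j, i, indexing="ij")
        a = (J * nr1 + I).ravel()  # (i, j)
        b = a + 1  # (i+1, j)
        c = a + nr1  # (i, j+1)
        d = c + 1  # (i+1, j+1)
        t1 = np.stack([a, b, d], axis=1)
        t2 = np.stack([a, d, c], axis=1)
        return np.concatenate([t1, t2], axis=0)


@dataclass
class StokesSolution:
    """Nodal velocity/pressure fields of one Stokes solve (SI units)."""

    mesh: StructuredMesh
    domain: RBCTrainDomain
    u_r: np.ndarray  # m/s, shape (n_nodes,)
    u_z: np.ndarray  # m/s
    p: np.ndarray  # Pa
    epsilon: float  # accepted penalty, 1/(Pa*s)
    p0: float  # inlet pressure, Pa

    def _plane(self, j: int) -> slice:
        nr1 = self.mesh.nr + 1
        return slice(j * nr1, (j + 1) * nr1)

    def flux_at_plane(self, j: int) -> float:
        """Volumetric flux ``2 pi int u_z r dr`` (m^3/s) through the
        cross-section at axial node row ``j``; exact for the P1 field."""
        r = np.linspace(0.0, self.domain.rc, self.mesh.nr + 1)
        u = self.u_z[self._plane(j)]
        ra, rb = r[:-1], r[1:]
        ua, ub = u[:-1], u[1:]
        h = rb - ra
        seg = h / 6.0 * (ua * (2.0 * ra + rb) + ub * (ra + 2.0 * rb))
        return float(2.0 * np.pi * seg.sum())

    @property
    def inlet_flux(self) -> float:
        return self.flux_at_plane(0)

    @property
    def outlet_flux(self) -> float:
        return self.flux_at_plane(self.mesh.nz)

    @property
    def flux_imbalance(self) -> float:
        """Relative inlet/outlet flux mismatch, the compressibility-error
        indicator used to accept the penalty parameter."""
        q0, q1 = self.inlet_flux, self.outlet_flux
        return abs(q0 - q1) / max(abs(q0), abs(q1), 1e-300)

    def field_table(self) -> np.ndarray:
        """Columns (r, z, u_r, u_z, p) in SI for export."""
        r, z = self.mesh.nodes(self.domain.rc, self.domain.L)
        return np.column_stack([r, z, self.u_r, self.u_z, self.p])


# Centroids of the 16 congruent subtriangles of a 4-fold barycentric
# refinement, as barycentric coordinates: area-fraction sampling of the
# RBC indicator at 1/16 resolution.
def _subtriangle_centroids(levels: int = 4) -> np.ndarray:
    pts = []
    h = 1.0 / levels
    for row in range(levels):
        for k in range(levels - row):
            # upward subtriangle with lattice corner (k, row)
            pts.append(((k + 1 / 3) * h, (row + 1 / 3) * h))
            if k < levels - row - 1:
                # downward subtriangle
                pts.append(((k + 2 / 3) * h, (row + 2 / 3) * h))
    bary = [(1.0 - a - b, a, b) for a, b in pts]
    return np.asarray(bary)


_SUBC = _subtriangle_centroids(8)

# Degree-2 triangle quadrature (edge-interior points), used for the
# hoop term phi_i phi_j / r which is rational in r.
_QPTS = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6], [1 / 6, 1 / 6, 2 / 3]])
_QW = np.full(3, 1.0 / 3.0)

# Exact integrals int phi_i phi_j phi_m = A * 2 a! b! c! / (a+b+c+2)!
# where (a, b, c) are the multiplicities of each vertex among (i, j, m).
_C3 = np.empty((3, 3, 3))
for _i in range(3):
    for _j in range(3):
        for _m in range(3):
            _counts = np.bincount([_i, _j, _m], minlength=3)
            _num = 2.0 * float(np.prod([math.factorial(int(a)) for a in _counts]))
            _C3[_i, _j, _m] = _num / math.factorial(int(_counts.sum()) + 2)


def _assemble(
    domain_um: RBCTrainDomain,
    mesh: StructuredMesh,
    mu1: float,
    mu2: float,
    eps: float,
    p0: float,
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the stabilised system in micrometre units.

    Returns (matrix, rhs, known-dof mask, known values); dof layout is
    ``[u_r | u_z | p]`` blocks of ``n_nodes`` each.
    """
    nr, nz = mesh.nr, mesh.nz
    N = mesh.n_nodes
    rcoord, zcoord = mesh.nodes(domain_um.rc, domain_um.L)
    tri = mesh.triangles()

    xr = rcoord[tri]  # (ne, 3)
    xz = zcoord[tri]

    # P1 gradients: area and shape-function derivatives
    det = (xr[:, 1] - xr[:, 0]) * (xz[:, 2] - xz[:, 0]) - (xr[:, 2] - xr[:, 0]) * (
        xz[:, 1] - xz[:, 0]
    )
    area = 0.5 * np.abs(det)
    b = np.stack(
        [xz[:, 1] - xz[:, 2], xz[:, 2] - xz[:, 0], xz[:, 0] - xz[:, 1]], axis=1
    ) / det[:, None]
    c = np.stack(
        [xr[:, 2] - xr[:, 1], xr[:, 0] - xr[:, 2], xr[:, 1] - xr[:, 0]], axis=1
    ) / det[:, None]

    rbar = xr.mean(axis=1)

    # Element viscosity from the RBC area fraction with orientation-aware
    # averaging.  A binary centroid assignment staircases the core/sleeve
    # interface by up to one radial cell, and the resistance responds to
    # the core radius like r0^4, so that bias is several percent at the
    # default mesh.  Instead, each element is sub-sampled on a 4-fold
    # barycentric refinement and mixed according to the local interface
    # orientation: shear across a radially layered interface (cell
    # flank) is soft-dominated -- harmonic mean -- while flow in series
    # through an axially layered interface (cell end face) is
    # stiff-dominated -- arithmetic mean.  The normal direction is
    # estimated from the covariance of the indicator with position.
    rs = _SUBC @ xr.T  # (n_sub, ne)
    zs = _SUBC @ xz.T
    ind = domain_um.in_rbc(rs, zs).astype(float)
    frac = ind.mean(axis=0)
    dev = ind - frac
    # least-squares indicator gradient (the sample cloud's own r-z
    # correlation is removed through the 2x2 position covariance)
    dr = rs - rs.mean(axis=0)
    dz = zs - zs.mean(axis=0)
    srr = np.mean(dr * dr, axis=0)
    srz = np.mean(dr * dz, axis=0)
    szz = np.mean(dz * dz, axis=0)
    cr = np.mean(dev * dr, axis=0)
    cz = np.mean(dev * dz, axis=0)
    det2 = srr * szz - srz**2
    g_r = np.abs(szz * cr - srz * cz) / det2
    g_z = np.abs(srr * cz - srz * cr) / det2
    w_radial = np.divide(
        g_r, g_r + g_z, out=np.full_like(g_r, 1.0), where=(g_r + g_z) > 0
    )
    mu_harm = 1.0 / (frac / mu2 + (1.0 - frac) / mu1)
    mu_arith = frac * mu2 + (1.0 - frac) * mu1
    mu = w_radial * mu_harm + (1.0 - w_radial) * mu_arith

    # int_T r phi_i dx = (A/12)(sum r + r_i)
    Sr = area[:, None] / 12.0 * (xr.sum(axis=1)[:, None] + xr)

    # hoop term int phi_i phi_j / r by 3-point quadrature
    rq = _QPTS @ xr.T  # (3q, ne)
    hoop = np.einsum("qi,qj,qe->eij", _QPTS, _QPTS, (_QW[:, None] * area) / rq)

    muA = (mu * area * rbar)[:, None, None]
    bb = b[:, :, None] * b[:, None, :]
    cc = c[:, :, None] * c[:, None, :]
    bc = b[:, :, None] * c[:, None, :]  # bc[e,i,j] = b_i c_j

    a11 = 2.0 * muA * (bb + 0.5 * cc) + 2.0 * mu[:, None, None] * hoop
    a12 = muA * bc.transpose(0, 2, 1)  # b_j c_i
    a21 = muA * bc  # b_i c_j
    a22 = 2.0 * muA * (cc + 0.5 * bb)

    # pressure gradient rows: int r dphi_j/dx_k phi_i
    g1 = Sr[:, :, None] * b[:, None, :]  # (e, i, j)
    g2 = Sr[:, :, None] * c[:, None, :]

    # continuity: eps * int r p q - int r div(u) q, with the cylindrical
    # divergence u_r/r + du_r/dr + du_z/dz (the u_r/r term cancels the
    # r weight, leaving a plain phi_i phi_j mass block)
    mass_r = area[:, None, None] * np.einsum("ijm,em->eij", _C3, xr)
    phiphi = area[:, None, None] / 12.0 * (np.ones((3, 3)) + np.eye(3))
    b1 = phiphi + b[:, None, :] * Sr[:, :, None]
    b2 = c[:, None, :] * Sr[:, :, None]

    rows_i = np.broadcast_to(tri[:, :, None], a11.shape)
    cols_j = np.broadcast_to(tri[:, None, :], a11.shape)

    def block(vals: np.ndarray, roff: int, coff: int):
        return (
            (rows_i + roff).ravel(),
            (cols_j + coff).ravel(),
            vals.ravel(),
        )

    parts = [
        block(a11, 0, 0),
        block(a12, 0, N),
        block(g1, 0, 2 * N),
        block(a21, N, 0),
        block(a22, N, N),
        block(g2, N, 2 * N),
        block(-b1, 2 * N, 0),
        block(-b2, 2 * N, N),
        block(eps * mass_r, 2 * N, 2 * N),
    ]
    rows = np.concatenate([p[0] for p in parts])
    cols = np.concatenate([p[1] for p in parts])
    vals = np.concatenate([p[2] for p in parts])
    K = sp.coo_matrix((vals, (rows, cols)), shape=(3 * N, 3 * N)).tocsr()

    # Dirichlet data
    nr1 = nr + 1
    node_i = np.tile(np.arange(nr1), nz + 1)
    node_j = np.repeat(np.arange(nz + 1), nr1)
    known = np.zeros(3 * N, dtype=bool)
    gvals = np.zeros(3 * N)
    wall = node_i == nr
    axis = node_i == 0
    known[np.flatnonzero(wall)] = True  # u_r = 0 on wall
    known[np.flatnonzero(wall) + N] = True  # u_z = 0 on wall
    known[np.flatnonzero(axis)] = True  # u_r = 0 on axis (symmetry)
    inlet = np.flatnonzero(node_j == 0)
    outlet = np.flatnonzero(node_j == nz)
    known[inlet + 2 * N] = True
    gvals[inlet + 2 * N] = p0
    known[outlet + 2 * N] = True
    gvals[outlet + 2 * N] = 0.0

    rhs = np.zeros(3 * N)
    return K, rhs, known, gvals


def solve_stokes(
    domain: RBCTrainDomain,
    mesh: StructuredMesh | None = None,
    p0: float = DEFAULT_P0,
    mu1: float = 1e-3,
    mu2: float = 0.1,
    eps: float = DEFAULT_EPS,
    adapt: bool = True,
    flux_tol: float = 1e-4,
    max_halvings: int = 6,
) -> StokesSolution:
    """Solve the stabilised axisymmetric Stokes problem on ``domain``.

    The penalty ``eps`` trades stability against spurious
    compressibility.  It is accepted when the inlet/outlet flux
    imbalance drops below ``flux_tol``, or -- on coarse meshes where a
    residual imbalance from the inlet/outlet natural boundary layers
    persists independently of the penalty -- when halving ``eps`` no
    longer moves the computed flux (relative change below 1e-4).
    Raises :class:`SingularSystem`, reporting the attempted penalty, if
    the factorisation fails or the flux never stabilises within
    ``max_halvings`` halvings.
    """
    if mesh is None:
        mesh = StructuredMesh()
    if p0 <= 0:
        raise ValueError("inlet pressure must be positive")

    # work in micrometres: Stokes is form-invariant, entries well scaled
    # (cap geometry must rescale with the regions)
    shape_um = RBCShapeSpec(
        kind=domain.shape.kind,
        l=domain.shape.l / UM,
        h=None if domain.shape.h is None else domain.shape.h / UM,
    )
    dom_um = RBCTrainDomain(
        rc=domain.rc / UM,
        L=domain.L / UM,
        r0=domain.r0 / UM,
        regions=tuple((z0 / UM, z1 / UM) for z0, z1 in domain.regions),
        shape=shape_um,
    )
    N = mesh.n_nodes

    attempt = eps
    last_exc: Exception | None = None
    prev_sol: StokesSolution | None = None
    for _ in range(max_halvings + 1):
        K, rhs, known, gvals = _assemble(dom_um, mesh, mu1, mu2, attempt, p0)
        free = ~known
        rhs_f = rhs[free] - K[free][:, known] @ gvals[known]
        Kff = K[free][:, free].tocsc()
        try:
            lu = spla.splu(Kff)
            xf = lu.solve(rhs_f)
        except RuntimeError as exc:  # singular factorisation
            last_exc = exc
            attempt *= 0.5
            continue
        if not np.all(np.isfinite(xf)):
            attempt *= 0.5
            continue
        x = gvals.copy()
        x[free] = xf
        sol = StokesSolution(
            mesh=mesh,
            domain=domain,
            u_r=x[:N] * UM,  # um/s -> m/s
            u_z=x[N : 2 * N] * UM,
            p=x[2 * N :],
            epsilon=attempt,
            p0=p0,
        )
        if not adapt or sol.flux_imbalance <= flux_tol:
            return sol
        if prev_sol is not None:
            stable = abs(sol.outlet_flux / prev_sol.outlet_flux - 1.0) <= 1e-4
            if stable:
                return sol
        prev_sol = sol
        attempt *= 0.5
    raise SingularSystem(
        f"no stable penalty found down to eps={attempt:g} 1/(Pa*s)"
        + (f" (last solver error: {last_exc})" if last_exc else "")
    )


def fem_specific_resistance(
    rc: float,
    H: float,
    shape: RBCShapeSpec | None = None,
    L: float = 60e-6,
    mesh: StructuredMesh | None = None,
    p0: float = DEFAULT_P0,
    mu1: float = 1e-3,
    mu2: float = 0.1,
    **solver_opts,
) -> float:
    """Specific resistance (Pa*s/m^4) of a capillary from one FEM solve:
    ``(p0 / q) / L`` with ``q`` the outlet flux."""
    dom = build_rbc_train(rc, L, H, shape)
    sol = solve_stokes(dom, mesh=mesh, p0=p0, mu1=mu1, mu2=mu2, **solver_opts)
    return (p0 / sol.outlet_flux) / L


def sweep_and_fit(
    rc: float,
    H_grid: Sequence[float],
    shape: RBCShapeSpec | None = None,
    values: Sequence[float] | None = None,
    **fem_opts,
) -> tuple[float, float, np.ndarray]:
    """Least-squares line through specific resistance versus hematocrit.

    Runs one FEM solve per ``H`` (or fits externally supplied
    ``values``), expresses resistances in the conventional
    ``1e20 Pa*s/m^4`` unit, and returns ``(slope, intercept,
    residuals)``.  Raises :class:`FitUnderdetermined` for fewer than two
    distinct hematocrit values.
    """
    H_arr = np.asarray(list(H_grid), dtype=float)
    if np.unique(H_arr).size < 2:
        raise FitUnderdetermined("need at least two distinct H values to fit a line")
    if values is None:
        y = np.array([fem_specific_resistance(rc, h, shape, **fem_opts) for h in H_arr])
    else:
        y = np.asarray(list(values), dtype=float)
        if y.shape != H_arr.shape:
            raise ValueError("values must match the H grid")
    y = y / 1e20
    slope, intercept = np.polyfit(H_arr, y, 1)
    resid = y - (slope * H_arr + intercept)
    return float(slope), float(intercept), resid
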