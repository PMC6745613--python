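"""Latent spatial fields: the Matérn Gaussian process and the Leroux CAR field.

Two random effects carry the spatial structure of the disaggregation model:

* ``eta``, a zero-mean stationary Gaussian process on the prediction grid
  with a Matérn (nu = 1) covariance.  It exists in two interchangeable
  representations — a dense exact form (default up to a few thousand
  points) and a sparse GMRF built by the SPDE finite-element approximation
  on a triangulation, for larger problems.  An oracle-equivalence test binds
  the two.
* ``phi``, an area-level Leroux CAR field whose precision
  ``Q(W) = rho * (diag(W 1) - W) + (1 - rho) * I`` interpolates between
  independence (rho = 0) and the intrinsic CAR (rho = 1).

The practical range of the Matérn field is ``r = sqrt(8 nu) / kappa`` — the
distance at which correlation has dropped to ~0.14 for nu = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cholesky, LinAlgError
from scipy.spatial import Delaunay
from scipy.spatial.distance import squareform, pdist
from scipy.special import gamma as gamma_fn, kv

from .geometry import AreaPartition, GridDomain, assign_membership

__all__ = [
    "MaternParams",
    "LerouxParams",
    "Mesh",
    "range_to_kappa",
    "kappa_to_range",
    "matern_cov",
    "matern_correlation",
    "sample_gp",
    "leroux_precision",
    "sample_car",
    "build_mesh",
    "spde_precision",
    "chol_with_jitter",
]

# Jitter ladder for near-singular covariance factorizations, as fractions of
# the marginal variance.
_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


# ---------------------------------------------------------------------------
# Parameter bundles
# ---------------------------------------------------------------------------


@dataclass
class MaternParams:
    """Matérn covariance parameters (marginal variance, scale, smoothness).

    ``nu`` is fixed at 1 (identifiability); the SPDE machinery below only
    supports this value.
    """

    sigma2_eta: float = 1.0
    kappa: float = 4.0
    nu: float = 1.0

    def __post_init__(self):
        if self.sigma2_eta < 0:
            raise ValueError("sigma2_eta must be nonnegative")
        if self.kappa <= 0 or self.nu <= 0:
            raise ValueError("kappa and nu must be positive")

    @property
    def range(self) -> float:
        return kappa_to_range(self.kappa, self.nu)

    @classmethod
    def from_range(cls, r: float, sigma2_eta: float = 1.0, nu: float = 1.0) -> "MaternParams":
        return cls(sigma2_eta=sigma2_eta, kappa=range_to_kappa(r, nu), nu=nu)


@dataclass
class LerouxParams:
    """Leroux CAR parameters: variance and spatial autocorrelation rho in [0, 1)."""

    sigma2_phi: float = 1.0
    rho: float = 0.6

    def __post_init__(self):
        if self.sigma2_phi < 0:
            raise ValueError("sigma2_phi must be nonnegative")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")


def range_to_kappa(r: float, nu: float = 1.0) -> float:
    """Scale parameter kappa implied by a practical range r: kappa = sqrt(8 nu) / r."""
    if r <= 0 or nu <= 0:
        raise ValueError("r and nu must be positive")
    return float(np.sqrt(8.0 * nu) / r)


def kappa_to_range(kappa: float, nu: float = 1.0) -> float:
    """Practical range implied by kappa: r = sqrt(8 nu) / kappa (round-trip inverse)."""
    if kappa <= 0 or nu <= 0:
        raise ValueError("kappa and nu must be positive")
    return float(np.sqrt(8.0 * nu) / kappa)


# ---------------------------------------------------------------------------
# Dense Matérn representation
# ---------------------------------------------------------------------------


def matern_correlation(d, kappa: float, nu: float = 1.0) -> np.ndarray:
    """Matérn correlation 2^(1-nu)/Gamma(nu) * (kappa d)^nu K_nu(kappa d); 1 at d = 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    kd = kappa * d
    with np.errstate(invalid="ignore"):
        corr = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * (kd**nu) * kv(nu, kd)
    corr = np.where(kd == 0.0, 1.0, corr)
    return np.nan_to_num(corr, nan=0.0)  # kv underflows to nan at huge kd


def matern_cov(D: np.ndarray, params: MaternParams) -> np.ndarray:
    """Matérn covariance matrix from a pairwise-distance matrix.

    The diagonal equals the marginal variance exactly; the result is
    symmetric and positive semidefinite up to rounding.
    """
    D = np.asarray(D, dtype=float)
    S = params.sigma2_eta * matern_correlation(D, params.kappa, params.nu)
    return 0.5 * (S + S.T)


def chol_with_jitter(S: np.ndarray, scale: float = None) -> np.ndarray:
    """Lower Cholesky factor with an escalating diagonal jitter ladder.

    Jitter steps are 1e-10 -> 1e-6 of ``scale`` (default: mean diagonal).
    Raises after the ladder is exhausted.
    """
    if scale is None:
        scale = float(np.mean(np.diag(S))) or 1.0
    for j in _JITTERS:
        try:
            return cholesky(S + j * scale * np.eye(S.shape[0]), lower=True)
        except LinAlgError:
            continue
    raise LinAlgError("covariance factorization failed after jitter escalation")


def sample_gp(
    grid: GridDomain,
    params: MaternParams,
    seed=None,
    chol: np.ndarray = None,
) -> np.ndarray:
    """One seeded draw of the Matérn GP at all grid points (dense exact form).

    ``chol`` may carry a precomputed correlation Cholesky factor (from
    :func:`gp_correlation_cholesky`) so repeated draws at the same kappa cost
    one matvec each — the simulation study exploits this.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = grid.n_points
    if params.sigma2_eta == 0.0:
        rng.standard_normal(n)  # keep the stream aligned with the sigma2>0 path
        return np.zeros(n)
    if chol is None:
        chol = gp_correlation_cholesky(grid, params)
    return np.sqrt(params.sigma2_eta) * (chol @ rng.standard_normal(n))


def gp_correlation_cholesky(grid: GridDomain, params: MaternParams) -> np.ndarray:
    """Cholesky factor of the unit-variance Matérn correlation over grid points."""
    D = squareform(pdist(grid.points))
    C = matern_correlation(D, params.kappa, params.nu)
    return chol_with_jitter(C, scale=1.0)


# ---------------------------------------------------------------------------
# Leroux CAR representation
# ---------------------------------------------------------------------------


def leroux_precision(W: np.ndarray, rho: float) -> np.ndarray:
    """Leroux CAR precision Q(W) = rho (diag(W 1) - W) + (1 - rho) I.

    Positive definite for rho < 1 (smallest eigenvalue at least 1 - rho);
    the rho = 1 limit is the singular intrinsic CAR precision.
    """
    W = np.asarray(W, dtype=float)
    if not np.array_equal(W, W.T):
        raise ValueError("W must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    n = W.shape[0]
    return rho * (np.diag(W.sum(axis=1)) - W) + (1.0 - rho) * np.eye(n)


def sample_car(W: np.ndarray, params: LerouxParams, seed=None) -> np.ndarray:
    """One seeded draw of phi ~ N(0, sigma2_phi * Q(W)^-1)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = np.asarray(W).shape[0]
    if params.sigma2_phi == 0.0:
        rng.standard_normal(n)
        return np.zeros(n)
    if params.rho >= 1.0:
        raise ValueError("rho = 1 gives a singular (intrinsic CAR) precision")
    Q = leroux_precision(W, params.rho)
    # draw via the precision Cholesky: solve L' x = z gives cov Q^{-1}
    L = cholesky(Q, lower=True)
    z = rng.standard_normal(n)
    from scipy.linalg import solve_triangular

    x = solve_triangular(L.T, z, lower=False)
    return np.sqrt(params.sigma2_phi) * x


# ---------------------------------------------------------------------------
# Mesh and SPDE-GMRF representation
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Triangulation of the domain plus its two sparse projection matrices.

    ``A_points`` maps mesh-vertex weights to point locations by barycentric
    interpolation (each row sums to 1; an indicator row when the point sits
    on a vertex).  ``A_areas`` maps vertex weights to area averages with the
    vertex-counting rule: entry ``1 / V_i`` for each of the ``V_i`` vertices
    inside area i.
    """

    vertices: np.ndarray  # (G, 2)
    triangles: np.ndarray  # (T, 3) vertex indices
    A_points: sp.csr_matrix = None
    A_areas: sp.csr_matrix = None

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def save(self, vertices_path, triangles_path):
        np.savetxt(vertices_path, self.vertices, fmt="%.12g")
        np.savetxt(triangles_path, self.triangles, fmt="%d")

    @classmethod
    def load(cls, vertices_path, triangles_path) -> "Mesh":
        v = np.loadtxt(vertices_path, ndmin=2)
        t = np.loadtxt(triangles_path, dtype=int, ndmin=2)
        return cls(vertices=v, triangles=t)


def _lattice(bbox, spacing):
    xmin, ymin, xmax, ymax = bbox
    nx = max(int(np.ceil((xmax - xmin) / spacing)) + 1, 2)
    ny = max(int(np.ceil((ymax - ymin) / spacing)) + 1, 2)
    xs = np.linspace(xmin, xmax, nx)
    ys = np.linspace(ymin, ymax, ny)
    XX, YY = np.meshgrid(xs, ys)
    return np.column_stack([XX.ravel(), YY.ravel()])


def build_mesh(
    partition: AreaPartition = None,
    max_edge: float = None,
    offset: float = None,
    bbox=None,
    points: np.ndarray = None,
) -> Mesh:
    """Triangulate the study region plus an outer buffer ring.

    A structured inner lattice (spacing ``max_edge``) covers the domain
    bounding box; a coarser lattice (spacing ``3 * max_edge``) fills an outer
    ring of width ``offset`` that absorbs the boundary effect of the SPDE
    approximation.  Delaunay triangulation joins the two point sets.

    Defaults follow common SPDE practice: ``max_edge = diameter / 25`` and
    ``offset = 0.15 * diameter`` where diameter is the bbox diagonal.

    If ``points`` is given, ``A_points`` is built for those locations; if
    ``partition`` is given, ``A_areas`` is built with the ``1 / V_i`` rule.
    """
    if bbox is None:
        if partition is None:
            raise ValueError("need a partition or an explicit bbox")
        xs = np.concatenate([np.asarray(p.exterior.coords)[:, 0] for p in partition.polygons])
        ys = np.concatenate([np.asarray(p.exterior.coords)[:, 1] for p in partition.polygons])
        bbox = (xs.min(), ys.min(), xs.max(), ys.max())
    xmin, ymin, xmax, ymax = map(float, bbox)
    diam = float(np.hypot(xmax - xmin, ymax - ymin))
    if max_edge is None:
        max_edge = diam / 25.0
    if offset is None:
        offset = 0.15 * diam
    if max_edge <= 0:
        raise ValueError("max_edge must be positive")

    inner = _lattice((xmin, ymin, xmax, ymax), max_edge)
    verts = inner
    if offset > 0:
        outer = _lattice(
            (xmin - offset, ymin - offset, xmax + offset, ymax + offset), 3.0 * max_edge
        )
        ring = outer[
            (outer[:, 0] < xmin - 1e-9)
            | (outer[:, 0] > xmax + 1e-9)
            | (outer[:, 1] < ymin - 1e-9)
            | (outer[:, 1] > ymax + 1e-9)
        ]
        verts = np.vstack([inner, ring])
    tri = Delaunay(verts)
    mesh = Mesh(vertices=verts, triangles=tri.simplices)
    mesh._delaunay = tri
    if points is not None:
        mesh.A_points = point_projector(mesh, points)
    if partition is not None:
        mesh.A_areas = area_projector(mesh, partition)
    return mesh


def point_projector(mesh: Mesh, points: np.ndarray) -> sp.csr_matrix:
    """Sparse barycentric projection matrix mapping vertex weights to points."""
    tri = getattr(mesh, "_delaunay", None)
    if tri is None:
        tri = Delaunay(mesh.vertices)
        mesh._delaunay = tri
    points = np.atleast_2d(points)
    simplex = tri.find_simplex(points)
    if np.any(simplex < 0):
        raise ValueError("points outside the mesh hull; increase the offset ring")
    T = tri.transform[simplex]
    b2 = np.einsum("ijk,ik->ij", T[:, :2, :], points - T[:, 2, :])
    bary = np.column_stack([b2, 1.0 - b2.sum(axis=1)])
    rows = np.repeat(np.arange(points.shape[0]), 3)
    cols = tri.simplices[simplex].ravel()
    vals = np.clip(bary, 0.0, 1.0).ravel()
    A = sp.csr_matrix((vals, (rows, cols)), shape=(points.shape[0], mesh.n_vertices))
    # renormalize away the clipping fuzz so each row sums to exactly 1
    A = sp.diags(1.0 / np.asarray(A.sum(axis=1)).ravel()) @ A
    return A.tocsr()


def area_projector(mesh: Mesh, partition: AreaPartition) -> sp.csr_matrix:
    """Sparse area-averaging matrix: row i has V_i entries equal to 1 / V_i.

    V_i counts the mesh vertices inside area i (boundary vertices go to the
    lowest-index area, matching the grid membership tie-break).  Approximates
    the block average of the GP over each area; errors shrink as the mesh is
    refined.
    """
    vgrid = GridDomain(points=mesh.vertices, resolution=0.0)
    member = assign_membership(vgrid, partition)
    nA = partition.n_areas
    counts = np.bincount(member[member >= 0], minlength=nA)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"areas containing no mesh vertices: {empty.tolist()}")
    inside = np.flatnonzero(member >= 0)
    rows = member[inside]
    vals = 1.0 / counts[rows]
    return sp.csr_matrix((vals, (rows, inside)), shape=(nA, mesh.n_vertices))


def _fem_matrices(mesh: Mesh):
    """Finite-element mass (lumped, diagonal) and stiffness matrices."""
    v = mesh.vertices
    t = mesh.triangles
    G = mesh.n_vertices
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    e0, e1, e2 = p2 - p1, p0 - p2, p1 - p0
    area2 = e2[:, 0] * (-e1[:, 1]) - e2[:, 1] * (-e1[:, 0])  # 2 * signed area
    area = 0.5 * np.abs(area2)
    ok = area > 1e-14
    t, area = t[ok], area[ok]
    e = np.stack([e0[ok], e1[ok], e2[ok]], axis=1)  # (T, 3, 2) opposite edges
    # lumped mass: a third of each triangle's area to each vertex
    c_diag = np.zeros(G)
    np.add.at(c_diag, t.ravel(), np.repeat(area / 3.0, 3))
    # stiffness: K_ij = (e_i . e_j) / (4 area)
    rows, cols, vals = [], [], []
    dots = np.einsum("tik,tjk->tij", e, e) / (4.0 * area)[:, None, None]
    for i in range(3):
        for j in range(3):
            rows.append(t[:, i])
            cols.append(t[:, j])
            vals.append(dots[:, i, j])
    K = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(G, G)
    )
    C = sp.diags(c_diag)
    return C, K


def spde_precision(mesh: Mesh, params: MaternParams) -> sp.csr_matrix:
    """Sparse GMRF precision approximating the Matérn (nu = 1) field on the mesh.

    Finite-element discretization of the linear fractional SPDE with alpha =
    nu + d/2 = 2: ``Q = tau^2 (kappa^4 C + 2 kappa^2 K + K C^-1 K)`` with
    mass-lumped C (keeping ``C^-1`` diagonal and Q sparse), and ``tau^2 =
    1 / (4 pi kappa^2 sigma2)`` so that the implied marginal variance matches
    the requested one away from the mesh boundary.
    """
    if not np.isclose(params.nu, 1.0):
        raise ValueError("the SPDE representation supports nu = 1 only")
    C, K = _fem_matrices(mesh)
    cinv = sp.diags(1.0 / C.diagonal())
    kap2 = params.kappa**2
    tau2 = 1.0 / (4.0 * np.pi * kap2 * params.sigma2_eta)
    Q = tau2 * (kap2**2 * C + 2.0 * kap2 * K + K @ cinv @ K)
    return Q.tocsr()
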