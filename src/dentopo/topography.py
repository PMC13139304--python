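"""Three-dimensional dental topographic metrics.

Implements the crown-shape descriptors used throughout comparative dental
ecology, all evaluated on a validated, occlusally oriented tooth mesh:

* **RFI** (relief index): ln of the ratio of the square roots of the 3D
  crown surface area and the 2D occlusal outline area.  Higher = taller,
  steeper crown.  Scale invariant.
* **DNE** (Dirichlet normal energy): the discrete Dirichlet energy of the
  vertex-normal map summed over faces, an estimator of the integral of
  (k1^2 + k2^2) over the surface.  The **convex** variant restricts the sum
  to outward-curving faces (the cutting surfaces).
* **ariaDNE**: a bandwidth-controlled variant: per-vertex curvature from a
  Gaussian-weighted quadric fit with kernel width ``epsilon`` expressed as
  a fraction of the square root of total surface area (the mesh is rescaled
  to unit surface area first, which is what makes epsilon comparable
  across specimens).  Its area-weighted coefficient of variation
  (**ariaDNE CV**) measures how unevenly curvature is distributed over the
  crown.
* **OPCR** (orientation patch count rotated): the number of contiguous
  face patches sharing one of eight 45-degree azimuthal orientations,
  averaged over eight small rotations about the vertical; a complexity
  proxy.
* **lnOA**: natural log of the occlusal outline area (alpha-shape of the
  projected vertices), the size proxy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .mesh_io import ToothMesh, face_areas

log = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Input geometry insufficient for the requested metric."""


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of 2D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


class BandwidthError(ValueError):
    """ariaDNE kernel too narrow: a vertex has an effectively empty neighbourhood."""


@dataclass(frozen=True)
class EnergyField:
    """Per-element energy densities backing a DNE-family metric.

    ``per_element_energy`` has units 1/length^2; elements are faces for DNE
    and vertices for ariaDNE.  Excluded elements (boundary, outliers)
    contribute zero to totals.  ``convexity`` is a per-face convex flag for
    the DNE variants, None for ariaDNE.
    """

    per_element_energy: np.ndarray
    element_area: np.ndarray
    excluded_mask: np.ndarray
    convexity: np.ndarray | None = None


@dataclass(frozen=True)
class AriaDNEParams:
    """epsilon is the Gaussian kernel bandwidth as a fraction of the square
    root of total surface area (recommended range 0.04-0.1)."""

    epsilon: float = 0.08
    cutoff_sigmas: float = 3.0  # neighbourhood truncation, in units of epsilon

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0.04 <= self.epsilon <= 0.1):
            warnings.warn(
                f"epsilon={self.epsilon} outside the recommended range [0.04, 0.1]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class OpcrParams:
    n_bins: int = 8
    n_rotations: int = 8
    rotation_step_deg: float = 5.625
    min_patch_faces: int = 3
    flatness_tolerance: float = 1e-4  # min horizontal magnitude of the unit normal

    def __post_init__(self):
        if self.n_bins * (360.0 / self.n_bins) != 360.0:
            raise ValueError("bins must tile 360 degrees")
        span = self.n_rotations * self.rotation_step_deg
        if abs(span - 360.0 / self.n_bins) > 1e-9:
            raise ValueError(
                "n_rotations * rotation_step must equal one bin width "
                f"({360.0 / self.n_bins} deg), got {span}"
            )


@dataclass(frozen=True)
class OutlineParams:
    """alpha-shape radius for the occlusal outline; "auto" sweeps a grid of
    64 log-spaced radii between 0.01x and 10x the median projected edge
    length and keeps the smallest one producing a single simple hole-free
    polygon enclosing all projected vertices (convex hull fallback)."""

    alpha: float | str = "auto"
    sweep_size: int = 64


@dataclass(frozen=True)
class TopographyProfile:
    """One tooth's vector of crown-shape metrics."""

    rfi: float | None = None
    dne: float | None = None
    convex_dne: float | None = None
    ariadne: float | None = None
    ariadne_cv: float | None = None
    opcr: float | None = None
    lnoa: float | None = None
    tritahi: float | None = None
    failures: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "rfi", "dne", "convex_dne", "ariadne",
                "ariadne_cv", "opcr", "lnoa", "tritahi",
            )
        }
        return d


# ---------------------------------------------------------------------------
# outline area / RFI


def _alpha_shape_polygon(points: np.ndarray, radius: float):
    """Union of Delaunay triangles with circumradius <= radius, or None."""
    tri = Delaunay(points)
    simplices = tri.simplices
    p = points[simplices]
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    area2 = np.abs(_cross2(p[:, 1, :] - p[:, 0, :], p[:, 2, :] - p[:, 0, :]))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum = (a * b * c) / (2.0 * area2)
    keep = np.isfinite(circum) & (circum <= radius)
    if not keep.any():
        return None
    polys = shapely.polygons(p[keep])
    merged = unary_union(shapely.make_valid(polys))
    return merged


def outline_area(mesh: ToothMesh, params: OutlineParams = OutlineParams()) -> float:
    """Area of the occlusal (z = 0 projection) outline of the crown."""
    pts = np.unique(mesh.vertices[:, :2], axis=0)
    if len(pts) < 3 or _collinear(pts):
        raise DegenerateGeometryError(
            "outline needs >= 3 non-collinear projected points"
        )
    hull = MultiPoint(pts).convex_hull
    if params.alpha == "auto":
        edge = _median_projected_edge(mesh)
        radii = np.geomspace(0.01 * edge, 10.0 * edge, params.sweep_size)
        for r in radii:
            poly = _alpha_shape_polygon(pts, r)
            if poly is None or not isinstance(poly, Polygon):
                continue
            if poly.interiors:
                continue
            if poly.buffer(1e-6 * edge).covers(MultiPoint(pts)):
                return float(poly.area)
        log.warning("no alpha on the sweep grid qualified; using convex hull")
        return float(hull.area)
    poly = _alpha_shape_polygon(pts, float(params.alpha))
    if poly is None or not isinstance(poly, Polygon):
        log.warning("alpha=%s gave no simple polygon; using convex hull", params.alpha)
        return float(hull.area)
    return float(poly.area)


def _collinear(pts: np.ndarray) -> bool:
    d = pts - pts[0]
    return np.allclose(_cross2(d[1], d[2:]), 0.0) if len(pts) > 2 else True


def _median_projected_edge(mesh: ToothMesh) -> float:
    f = mesh.faces
    p = mesh.vertices[:, :2]
    e = np.concatenate(
        [p[f[:, 1]] - p[f[:, 0]], p[f[:, 2]] - p[f[:, 1]], p[f[:, 0]] - p[f[:, 2]]]
    )
    lengths = np.linalg.norm(e, axis=1)
    m = float(np.median(lengths[lengths > 0]))
    return m if m > 0 else 1.0


def surface_area(mesh: ToothMesh) -> float:
    return float(face_areas(mesh.vertices, mesh.faces).sum())


def compute_rfi(mesh: ToothMesh, params: OutlineParams = OutlineParams()) -> float:
    """Relief index ln( sqrt(3D area) / sqrt(2D outline area) )."""
    a2 = outline_area(mesh, params)
    if a2 <= 0:
        raise DegenerateGeometryError("zero outline area")
    a3 = surface_area(mesh)
    return float(np.log(np.sqrt(a3) / np.sqrt(a2)))


# ---------------------------------------------------------------------------
# DNE


def vertex_normals_angle_weighted(mesh: ToothMesh) -> np.ndarray:
    """Unit vertex normals as angle-weighted averages of face normals."""
    V, F = mesh.vertices, mesh.faces
    tri = V[F]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(fn, axis=1, keepdims=True)
    fn_unit = fn / np.maximum(norms, 1e-300)
    out = np.zeros_like(V)
    for c in range(3):
        e1 = V[F[:, (c + 1) % 3]] - V[F[:, c]]
        e2 = V[F[:, (c + 2) % 3]] - V[F[:, c]]
        cosang = np.einsum("ij,ij->i", e1, e2) / np.maximum(
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1), 1e-300
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(out, F[:, c], ang[:, None] * fn_unit)
    n = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.maximum(n, 1e-300)


def _boundary_faces(faces: np.ndarray) -> np.ndarray:
    """Mask of faces that have at least one edge on an open boundary."""
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    face_idx = np.concatenate([np.arange(len(faces))] * 3)
    _, inv, counts = np.unique(edges, axis=0, return_inverse=True, return_counts=True)
    mask = np.zeros(len(faces), dtype=bool)
    mask[face_idx[counts[inv] == 1]] = True
    return mask


def compute_dne(
    mesh: ToothMesh,
    boundary_exclude: bool = True,
    outlier_fraction: float = 0.001,
    variant: str = "total",
) -> tuple[float, EnergyField]:
    """Dirichlet normal energy (``variant="total"``) or convex DNE.

    Per-face energy density e(p) = tr(G^-1 H) where G and H are the first
    and second fundamental-form estimates built from the face's edge
    vectors and the differences of its (angle-weighted) vertex normals;
    DNE = sum of e(p) * a(p) over included faces.  Faces on an open
    boundary are excluded when ``boundary_exclude``; the top
    ``outlier_fraction`` of faces by e(p)*a(p) is always excluded.
    A face counts as convex when its discrete mean-curvature estimate is
    non-negative (neighbour normals diverging along outward displacement).
    """
    if variant not in ("total", "convex"):
        raise ValueError(f"unknown DNE variant {variant!r}")
    V, F = mesh.vertices, mesh.faces
    tm = mesh.as_trimesh()
    if not tm.is_winding_consistent:
        raise DegenerateGeometryError("face windings are inconsistent")
    N = vertex_normals_angle_weighted(mesh)

    p1, p2, p3 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    n1, n2, n3 = N[F[:, 0]], N[F[:, 1]], N[F[:, 2]]
    u = p2 - p1
    v = p3 - p1
    nu = n2 - n1
    nv = n3 - n1
    E = np.einsum("ij,ij->i", u, u)
    Ff = np.einsum("ij,ij->i", u, v)
    G = np.einsum("ij,ij->i", v, v)
    L = np.einsum("ij,ij->i", nu, nu)
    M = np.einsum("ij,ij->i", nu, nv)
    Nq = np.einsum("ij,ij->i", nv, nv)
    det = E * G - Ff**2
    # e = tr(G^-1 H); guard near-degenerate metric tensors
    with np.errstate(divide="ignore", invalid="ignore"):
        energy = (G * L - 2.0 * Ff * M + E * Nq) / det
    energy = np.where((det > 1e-300) & np.isfinite(energy), energy, 0.0)
    energy = np.maximum(energy, 0.0)
    areas = face_areas(V, F)

    # convexity: normals diverging along outward displacement => convex
    kappa = (
        np.einsum("ij,ij->i", nu, u)
        + np.einsum("ij,ij->i", nv, v)
        + np.einsum("ij,ij->i", nv - nu, v - u)
    )
    convex = kappa >= -1e-12

    excluded = np.zeros(len(F), dtype=bool)
    if boundary_exclude:
        excluded |= _boundary_faces(F)
    contrib = energy * areas
    n_out = int(np.floor(outlier_fraction * len(F)))
    if n_out > 0:
        order = np.argsort(contrib[~excluded])[::-1]
        idx = np.nonzero(~excluded)[0][order[:n_out]]
        excluded[idx] = True

    include = ~excluded
    if variant == "convex":
        include &= convex
    total = float((contrib[include]).sum())
    return total, EnergyField(energy, areas, excluded, convex)


# ---------------------------------------------------------------------------
# ariaDNE


def compute_ariadne(
    mesh: ToothMesh, params: AriaDNEParams = AriaDNEParams()
) -> tuple[float, float, EnergyField]:
    """Bandwidth-controlled curvature energy and its coefficient of variation.

    The mesh is rescaled to unit total surface area; for each vertex a
    quadric is fitted by weighted least squares over all vertices with
    Gaussian weights w_ij = exp(-||v_i - v_j||^2 / eps^2) (truncated at
    ``cutoff_sigmas * eps``), in a local frame whose z-axis is the
    weighted-PCA normal; the per-vertex density e_i is the sum of squared
    principal curvatures of the fitted quadric at the vertex, and
    ariaDNE = sum e_i * a_i with a_i the barycentric vertex area.
    """
    A = surface_area(mesh)
    if A <= 0:
        raise DegenerateGeometryError("zero surface area")
    V = mesh.vertices / np.sqrt(A)
    F = mesh.faces
    eps = params.epsilon

    areas = face_areas(V, F)
    vert_area = np.zeros(len(V))
    for c in range(3):
        np.add.at(vert_area, F[:, c], areas / 3.0)

    normals = vertex_normals_angle_weighted(ToothMesh(V, F))

    tree = cKDTree(V)
    radius = params.cutoff_sigmas * eps
    energy = np.zeros(len(V))
    neighbour_lists = tree.query_ball_tree(tree, radius)
    for i, idx in enumerate(neighbour_lists):
        idx = np.asarray(idx)
        pts = V[idx] - V[i]
        d2 = np.einsum("ij,ij->i", pts, pts)
        w = np.exp(-d2 / eps**2)
        effective = int((w > 1e-3).sum())
        if effective < 6:
            raise BandwidthError(
                f"vertex {i}: effective neighbourhood has {effective} < 6 points; "
                f"epsilon={eps} too small for this mesh"
            )
        # local frame: weighted PCA, z-axis aligned with the vertex normal
        C = (pts * w[:, None]).T @ pts / w.sum()
        evals, evecs = np.linalg.eigh(C)
        z_axis = evecs[:, 0]
        if z_axis @ normals[i] < 0:
            z_axis = -z_axis
        x_axis = evecs[:, 2]
        y_axis = np.cross(z_axis, x_axis)
        R = np.column_stack([x_axis, y_axis, z_axis])
        local = pts @ R
        x, y, z = local[:, 0], local[:, 1], local[:, 2]
        # weighted LSQ quadric z = a x^2 + b xy + c y^2 + d x + e y + f
        B = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
        Wh = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(B * Wh[:, None], z * Wh, rcond=None)
        a, b, c, d, e, _f = coef
        # shape operator of the graph at the vertex (origin of the frame)
        p, q = d, e
        W2 = 1.0 + p * p + q * q
        Wr = np.sqrt(W2)
        fxx, fxy, fyy = 2 * a, b, 2 * c
        one = np.array([[1 + p * p, p * q], [p * q, 1 + q * q]])
        two = np.array([[fxx, fxy], [fxy, fyy]]) / Wr
        S = np.linalg.solve(one, two)
        k = np.linalg.eigvals(S).real
        energy[i] = float(k[0] ** 2 + k[1] ** 2)

    total_area = vert_area.sum()
    mean = float((energy * vert_area).sum() / total_area)
    aria = float((energy * vert_area).sum())
    if mean <= 1e-300:
        warnings.warn("flat surface: ariaDNE CV undefined, reported as 0")
        cv = 0.0
    else:
        var = float((vert_area * (energy - mean) ** 2).sum() / total_area)
        cv = float(np.sqrt(var) / mean)
    field_ = EnergyField(energy, vert_area, np.zeros(len(V), dtype=bool))
    return aria, cv, field_


# ---------------------------------------------------------------------------
# OPCR


def compute_opcr(mesh: ToothMesh, params: OpcrParams = OpcrParams()) -> float:
    """Orientation patch count rotated.

    For each of ``n_rotations`` rotations about +z by multiples of
    ``rotation_step_deg``, face normals are binned into ``n_bins``
    azimuthal sectors; near-vertical-normal (flat) faces are excluded;
    edge-connected same-bin patches with at least ``min_patch_faces`` faces
    are counted; OPCR is the mean count across rotations.
    """
    V, F = mesh.vertices, mesh.faces
    tri = V[F]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fn = fn / np.maximum(np.linalg.norm(fn, axis=1, keepdims=True), 1e-300)
    horiz = np.hypot(fn[:, 0], fn[:, 1])
    flat = horiz < params.flatness_tolerance
    azimuth = np.degrees(np.arctan2(fn[:, 1], fn[:, 0])) % 360.0

    adjacency = mesh.as_trimesh().face_adjacency
    bin_width = 360.0 / params.n_bins

    counts = []
    for k in range(params.n_rotations):
        theta = k * params.rotation_step_deg
        bins = np.floor(((azimuth + theta) % 360.0) / bin_width).astype(np.int64)
        bins[flat] = -1
        counts.append(_count_patches(bins, adjacency, len(F), params.min_patch_faces))
    return float(np.mean(counts))


def _count_patches(
    bins: np.ndarray, adjacency: np.ndarray, n_faces: int, min_faces: int
) -> int:
    """Connected components of same-bin faces via union-find."""
    parent = np.arange(n_faces)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if len(adjacency):
        same = (bins[adjacency[:, 0]] == bins[adjacency[:, 1]]) & (
            bins[adjacency[:, 0]] >= 0
        )
        for a, b in adjacency[same]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.fromiter((find(i) for i in range(n_faces)), dtype=np.int64)
    valid = bins >= 0
    if not valid.any():
        return 0
    _, sizes = np.unique(roots[valid], return_counts=True)
    return int((sizes >= min_faces).sum())


# ---------------------------------------------------------------------------
# profile assembly


def measure_profile(
    mesh: ToothMesh,
    outline_params: OutlineParams = OutlineParams(),
    aria_params: AriaDNEParams = AriaDNEParams(),
    opcr_params: OpcrParams = OpcrParams(),
    boundary_exclude: bool = True,
    outlier_fraction: float = 0.001,
    silhouette=None,
) -> TopographyProfile:
    """All crown metrics for one tooth, with per-metric failure tagging.

    ``silhouette`` may be a precomputed :class:`~dentopo.silhouette.Silhouette2D`
    to include the trigonid-talonid height index.
    """
    values: dict = {}
    failures: dict = {}

    def attempt(name, fn):
        try:
            values[name] = fn()
        except Exception as exc:  # tagged, not fatal: contract of the profile
            failures[name] = f"{type(exc).__name__}: {exc}"

    attempt("lnoa", lambda: float(np.log(outline_area(mesh, outline_params))))
    attempt("rfi", lambda: compute_rfi(mesh, outline_params))
    attempt(
        "dne",
        lambda: compute_dne(mesh, boundary_exclude, outlier_fraction, "total")[0],
    )
    attempt(
        "convex_dne",
        lambda: compute_dne(mesh, boundary_exclude, outlier_fraction, "convex")[0],
    )

    def _aria():
        a, cv, _ = compute_ariadne(mesh, aria_params)
        values["ariadne_cv"] = cv
        return a

    attempt("ariadne", _aria)
    attempt("opcr", lambda: compute_opcr(mesh, opcr_params))
    if silhouette is not None:
        from .silhouette import compute_tritahi

        attempt("tritahi", lambda: compute_tritahi(silhouette))
    return TopographyProfile(failures=failures, **values)
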