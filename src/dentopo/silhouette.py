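"""Lingual-view silhouette and the trigonid-talonid height index (TriTaHI).

On a tribosphenic lower molar the mesial (anterior) trigonid is typically
taller than the distal talonid in insectivores and faunivores, while the
two are closer in height in folivores.  TriTaHI quantifies this from the
2D lingual silhouette: a cervical baseline is drawn between the mesial and
distal cervical endpoints, the maximum trigonid and talonid heights are
measured perpendicular to that baseline, and

    TriTaHI = (H_trigonid - H_talonid) / L_max,

with L_max the maximum molar length parallel to the baseline.  Positive
values mean a taller trigonid; negative values a taller talonid.

For an occlusally oriented mesh (+z apex, +x mesial, +y buccal) the
lingual view is the orthographic projection onto the x-z plane.  The
cervical endpoints can be supplied explicitly (the measurement is
operator-defined on real specimens) or auto-detected as the lowest-z
outline points within the mesial-most and distal-most 15% of the
silhouette's x-extent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.ops import unary_union

from .mesh_io import ToothMesh
from .topography import DegenerateGeometryError

log = logging.getLogger(__name__)

_EDGE_WINDOW = 0.15  # fraction of x-extent searched for cervical endpoints


class SplitError(ValueError):
    """Trigonid/talonid region contains no outline points."""


@dataclass(frozen=True)
class Silhouette2D:
    """Lingual-view outline with cervical baseline.

    ``outline`` is an (n, 2) array of boundary points in the x-z plane
    (x mesiodistal, z occlusal height); ``baseline`` is a (2, 2) array of
    the mesial and distal cervical endpoints (mesial first);
    ``split_fraction`` places the trigonid/talonid division along the
    baseline (default halfway, overridable per specimen).
    """

    outline: np.ndarray
    baseline: np.ndarray
    split_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if len(self.outline) < 3:
            raise DegenerateGeometryError("outline needs >= 3 points")
        if np.allclose(self.baseline[0], self.baseline[1]):
            raise DegenerateGeometryError("baseline endpoints coincide")

    # -- baseline frame -----------------------------------------------------

    def _frame(self):
        """(unit vector along baseline oriented mesially, unit normal toward
        the occlusal side)."""
        b0, b1 = np.asarray(self.baseline, float)
        u = b1 - b0
        u = u / np.linalg.norm(u)
        # orient u toward +x (mesial)
        if u[0] < 0:
            u = -u
        n = np.array([-u[1], u[0]])
        # occlusal side = side of the baseline where the outline bulges
        h = (self.outline - b0) @ n
        if np.abs(h.min()) > np.abs(h.max()):
            n = -n
        return b0, u, n

    @property
    def l_max(self) -> float:
        """Maximum molar length measured parallel to the baseline."""
        b0, u, _ = self._frame()
        t = (self.outline - b0) @ u
        return float(t.max() - t.min())

    def region_heights(self) -> tuple[float, float]:
        """(H_trigonid, H_talonid): max heights perpendicular to the baseline
        on the mesial and distal sides of the split."""
        b0, u, n = self._frame()
        t = (self.outline - b0) @ u
        h = (self.outline - b0) @ n
        # split measured along the baseline from its distal endpoint, so an
        # operator-supplied baseline controls where the division falls
        t_distal = min((self.baseline - b0) @ u)
        split = t_distal + self.split_fraction * (t.max() - t.min())
        mesial = t >= split  # u points mesially, so larger t = more mesial
        if not mesial.any() or mesial.all():
            raise SplitError(
                f"split at fraction {self.split_fraction} leaves an empty "
                "trigonid or talonid region"
            )
        h_tri = float(np.maximum(h[mesial].max(), 0.0))
        h_tal = float(np.maximum(h[~mesial].max(), 0.0))
        return h_tri, h_tal


def lingual_silhouette(
    mesh: ToothMesh,
    baseline_points: np.ndarray | None = None,
    split_fraction: float = 0.5,
) -> Silhouette2D:
    """Project the crown onto the x-z plane and construct its silhouette.

    ``baseline_points`` may be a pair of 3D points (projected and used
    verbatim); otherwise the cervical endpoints are auto-detected.  Ties in
    auto-detection are broken deterministically toward the lowest x, with a
    warning.
    """
    if mesh.n_faces == 0:
        raise DegenerateGeometryError("empty mesh")
    proj = mesh.vertices[:, [0, 2]]  # lingual view: (x, z)
    tri = proj[mesh.faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    areas = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    polys = shapely.polygons(tri[areas > 1e-14])
    merged = unary_union(shapely.make_valid(polys))
    if merged.is_empty or merged.geom_type not in ("Polygon", "MultiPolygon"):
        raise DegenerateGeometryError("degenerate lingual projection")
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    outline = np.asarray(merged.exterior.coords)[:-1]  # drop closing duplicate

    if baseline_points is not None:
        bp = np.asarray(baseline_points, float)
        if bp.shape == (2, 3):
            bp = bp[:, [0, 2]]
        if bp.shape != (2, 2):
            raise ValueError("baseline_points must be a pair of 3D (or x-z) points")
        baseline = bp
    else:
        baseline = _auto_baseline(outline)
    # mesial endpoint first
    if baseline[0, 0] < baseline[1, 0]:
        baseline = baseline[::-1]
    return Silhouette2D(outline=outline, baseline=baseline,
                        split_fraction=split_fraction)


def _auto_baseline(outline: np.ndarray) -> np.ndarray:
    x = outline[:, 0]
    extent = x.max() - x.min()
    if extent <= 0:
        raise DegenerateGeometryError("outline has zero mesiodistal extent")
    ends = []
    for window in (x <= x.min() + _EDGE_WINDOW * extent,
                   x >= x.max() - _EDGE_WINDOW * extent):
        cand = outline[window]
        zmin = cand[:, 1].min()
        lowest = cand[np.abs(cand[:, 1] - zmin) < 1e-9 * max(1.0, extent)]
        if len(lowest) > 1:
            warnings.warn(
                "ambiguous cervical endpoint: multiple lowest-z candidates; "
                "using the lowest-x one"
            )
            lowest = lowest[np.argsort(lowest[:, 0])]
        ends.append(lowest[0])
    return np.asarray(ends)


def compute_tritahi(sil: Silhouette2D) -> float:
    """(H_trigonid - H_talonid) / L_max for a valid silhouette."""
    h_tri, h_tal = sil.region_heights()
    return float((h_tri - h_tal) / sil.l_max)


def tritahi_from_mesh(
    mesh: ToothMesh,
    baseline_points: np.ndarray | None = None,
    split_fraction: float = 0.5,
) -> float:
    return compute_tritahi(
        lingual_silhouette(mesh, baseline_points, split_fraction)
    )
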