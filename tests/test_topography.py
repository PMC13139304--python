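"""Crown-shape metrics against closed-form oracles and invariance laws."""

import dataclasses

import numpy as np
import pytest

from dentopo.mesh_io import ToothMesh
from dentopo.topography import (
    AriaDNEParams,
    BandwidthError,
    DegenerateGeometryError,
    OutlineParams,
    compute_ariadne,
    compute_dne,
    compute_opcr,
    compute_rfi,
    measure_profile,
    outline_area,
    surface_area,
)
from dentopo.synthetic import CROWN_PRESETS, CrownSpec, generate_tooth

from conftest import grid_mesh


# -- outline area / RFI ------------------------------------------------------


def test_flat_unit_square_outline_and_rfi(flat_patch):
    assert outline_area(flat_patch) == pytest.approx(1.0, rel=1e-9)
    assert compute_rfi(flat_patch) == pytest.approx(0.0, abs=1e-9)


def test_hemisphere_disc_area_and_rfi(hemisphere):
    """Hemisphere of radius r: outline area pi r^2, RFI = ln sqrt(2)."""
    assert outline_area(hemisphere) == pytest.approx(np.pi, rel=0.01)
    assert compute_rfi(hemisphere) == pytest.approx(np.log(np.sqrt(2)), rel=0.01)


def test_outline_degenerate_collinear():
    v = np.array([[0, 0, 0], [1, 0, 1], [2, 0, 0]], float)
    mesh = ToothMesh(v, np.array([[0, 1, 2]]))
    with pytest.raises(DegenerateGeometryError):
        outline_area(mesh)


def test_rfi_scale_invariant():
    mesh = generate_tooth(CrownSpec(grid_resolution=30))
    r0 = compute_rfi(mesh)
    r3 = compute_rfi(mesh.with_vertices(mesh.vertices * 3.0))
    assert r3 == pytest.approx(r0, abs=1e-6)


def test_lnoa_shifts_under_scaling():
    mesh = generate_tooth(CrownSpec(grid_resolution=30))
    a0 = np.log(outline_area(mesh))
    a2 = np.log(outline_area(mesh.with_vertices(mesh.vertices * 2.0)))
    assert a2 - a0 == pytest.approx(2.0 * np.log(2.0), abs=1e-9)


def test_alpha_shape_tighter_than_hull_on_concave_outline():
    """An L-shaped crown footprint: the alpha outline tracks the concavity,
    the convex hull does not."""
    def flat(x, y):
        return np.zeros_like(x)

    # two unit squares sharing a corner region form an L with a reentrant corner
    a = grid_mesh(flat, extent=1.0, n=12)
    b = grid_mesh(flat, extent=1.0, n=12)
    v = np.vstack([a.vertices, b.vertices + [0.5, 0.5, 0]])
    f = np.vstack([a.faces, b.faces + a.n_vertices])
    mesh = ToothMesh(v, f, orientation_flag=True)
    area_alpha = outline_area(mesh)
    from shapely.geometry import MultiPoint

    hull_area = MultiPoint(mesh.vertices[:, :2]).convex_hull.area
    assert area_alpha < hull_area * 0.98


# -- DNE ---------------------------------------------------------------------


def test_flat_patch_dne_zero(flat_patch):
    total, field = compute_dne(flat_patch)
    assert total == 0.0
    assert (field.per_element_energy == 0).all()


def test_sphere_dne_matches_closed_form(unit_sphere):
    """Closed sphere: integral of (k1^2 + k2^2) dA = 8 pi, any radius."""
    total, field = compute_dne(unit_sphere)
    assert total == pytest.approx(8 * np.pi, rel=0.05)
    # sum of element areas = surface area before exclusions
    assert field.element_area.sum() == pytest.approx(surface_area(unit_sphere), rel=1e-6)
    assert (field.per_element_energy >= 0).all()


def test_sphere_all_faces_convex(unit_sphere):
    total, field = compute_dne(unit_sphere)
    convex, _ = compute_dne(unit_sphere, variant="convex")
    assert field.convexity.all()
    assert convex == pytest.approx(total, abs=1e-9)


def test_saddle_convex_dne_below_total():
    """Monkey saddle: half the surface curves inward, so the convex variant
    keeps only part of the energy."""
    saddle = grid_mesh(lambda x, y: 0.5 * (x**3 - 3 * x * y**2), extent=2.0,
                       n=40, x0=-1.0, y0=-1.0)
    total, _ = compute_dne(saddle)
    convex, _ = compute_dne(saddle, variant="convex")
    assert 0 < convex < total


def test_dne_scale_invariant(unit_sphere):
    d0, _ = compute_dne(unit_sphere)
    d2, _ = compute_dne(unit_sphere.with_vertices(unit_sphere.vertices * 2.0))
    assert d2 == pytest.approx(d0, rel=1e-6)


def test_dne_boundary_exclusion_mask():
    mesh = generate_tooth(CrownSpec(grid_resolution=15))  # open cervical rim
    _, field = compute_dne(mesh, boundary_exclude=True)
    assert field.excluded_mask.any()
    _, field_off = compute_dne(mesh, boundary_exclude=False, outlier_fraction=0.0)
    assert not field_off.excluded_mask.any()


# -- ariaDNE -----------------------------------------------------------------


def test_sphere_ariadne_uniform_energy(unit_sphere):
    """Constant-curvature surface: per-vertex energy near-constant, CV small."""
    aria, cv, field = compute_ariadne(unit_sphere)
    assert aria > 0
    assert cv < 0.1
    assert (field.per_element_energy >= 0).all()


def test_flat_ariadne_zero_cv_warns(flat_patch):
    with pytest.warns(UserWarning, match="CV undefined"):
        aria, cv, _ = compute_ariadne(flat_patch)
    assert aria == pytest.approx(0.0, abs=1e-6)
    assert cv == 0.0


def test_ariadne_epsilon_range_warning():
    with pytest.warns(UserWarning, match="recommended range"):
        AriaDNEParams(epsilon=0.2)


def test_ariadne_bandwidth_too_small(unit_sphere):
    with pytest.raises(BandwidthError, match="vertex"):
        compute_ariadne(unit_sphere, AriaDNEParams(epsilon=0.004))


def test_ariadne_scale_invariant(unit_sphere):
    a0, cv0, _ = compute_ariadne(unit_sphere)
    a3, cv3, _ = compute_ariadne(unit_sphere.with_vertices(unit_sphere.vertices * 3.0))
    assert a3 == pytest.approx(a0, rel=1e-9)
    assert cv3 == pytest.approx(cv0, rel=1e-9)


def test_dne_ariadne_agree_on_broad_smooth_crown():
    """Both estimate the same curvature integral; on crowns whose features
    are large relative to the ariaDNE bandwidth they agree within 15%."""
    mesh = generate_tooth(
        CrownSpec(length=10, width=7, cusps=((0, 0, 1.5, 2.5),), wall_depth=0.0,
                  grid_resolution=90)
    )
    dne, _ = compute_dne(mesh)
    aria, _, _ = compute_ariadne(mesh)
    assert aria == pytest.approx(dne, rel=0.15)


# -- OPCR --------------------------------------------------------------------


def test_flat_patch_opcr_zero(flat_patch):
    assert compute_opcr(flat_patch) == 0.0


def test_single_cusp_opcr_eight():
    """A radially symmetric cusp has one patch per 45-degree sector at every
    rotation."""
    mesh = generate_tooth(CrownSpec(cusps=((0.0, 0.0, 3.0, 1.5),), wall_depth=0.0))
    assert compute_opcr(mesh) == pytest.approx(8.0)


def test_quad_cusp_opcr_thirtytwo():
    mesh = generate_tooth(CROWN_PRESETS["quad-cusp-v1"])
    assert compute_opcr(mesh) == pytest.approx(32.0, rel=0.1)


def test_opcr_rotation_stability():
    """Arbitrary rotation about z changes the rotation-averaged count < 5%."""
    mesh = generate_tooth(CROWN_PRESETS["dasyurid-like-v1"])
    o0 = compute_opcr(mesh)
    th = np.radians(17.0)
    R = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    o1 = compute_opcr(mesh.with_vertices(mesh.vertices @ R.T))
    assert abs(o1 - o0) / o0 < 0.05


# -- monotonicity ladders ----------------------------------------------------


def test_sharper_cusps_raise_curvature_metrics():
    values = []
    for width in (2.2, 1.8, 1.4, 1.0):
        m = generate_tooth(CrownSpec(cusps=((0, 0, 3.0, width),), wall_depth=1.0,
                                     grid_resolution=60))
        values.append((compute_dne(m)[0], compute_ariadne(m)[0]))
    dnes, arias = zip(*values)
    assert all(a < b for a, b in zip(dnes, dnes[1:]))
    assert all(a < b for a, b in zip(arias, arias[1:]))


def test_taller_cusps_raise_relief():
    rfis = [
        compute_rfi(generate_tooth(CrownSpec(cusps=((0, 0, h, 1.5),), wall_depth=1.0,
                                             grid_resolution=60)))
        for h in (1.5, 2.5, 3.5, 4.5)
    ]
    assert all(a < b for a, b in zip(rfis, rfis[1:]))


def test_more_cusps_raise_opcr():
    centers = [(-4.5, -4.5), (4.5, 4.5), (-4.5, 4.5), (4.5, -4.5)]
    opcrs = []
    for k in (1, 2, 4):
        spec = CrownSpec(
            length=20, width=20,
            cusps=tuple((x, y, 3.0, 0.85) for x, y in centers[:k]),
            wall_depth=0.0, grid_resolution=110,
        )
        opcrs.append(compute_opcr(generate_tooth(spec)))
    assert all(a < b for a, b in zip(opcrs, opcrs[1:]))


# -- profile assembly --------------------------------------------------------


def test_profile_flat_square(flat_patch):
    prof = measure_profile(flat_patch, boundary_exclude=False)
    assert prof.lnoa == pytest.approx(0.0, abs=1e-9)
    assert prof.rfi == pytest.approx(0.0, abs=1e-9)
    assert prof.dne == 0.0
    assert prof.opcr == 0.0


def test_profile_contains_all_fields_or_failures():
    mesh = generate_tooth(CrownSpec(grid_resolution=40))
    prof = measure_profile(mesh)
    d = prof.as_dict()
    for key in ("rfi", "dne", "convex_dne", "ariadne", "ariadne_cv", "opcr", "lnoa"):
        assert d[key] is not None or key in prof.failures


def test_sharp_tall_preset_in_high_relief_band():
    """The sharp tall-cusped generator preset lands in the high-relief band
    (> 0.56) characteristic of unmodified tribosphenic insectivore molars."""
    mesh = generate_tooth(CROWN_PRESETS["sharp-tall-v1"])
    assert compute_rfi(mesh) > 0.56
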