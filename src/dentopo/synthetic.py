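"""Synthetic tooth crowns and diet-structured feature tables.

Real dental-topography studies measure museum specimens; this module
provides the two stand-ins that make every pipeline stage testable without
any downloads:

* :func:`generate_tooth` builds a parametric crown as a Gaussian-bump
  height field over a rectangular footprint, with cervical side walls
  dropping to a fixed depth.  The walls leave an open boundary at the
  cervix, like a cropped real molar, which exercises the boundary handling
  of the curvature metrics.  Generator parameters drive the metrics
  monotonically: taller cusps raise relief (RFI), narrower cusps raise
  curvature (DNE/ariaDNE), more cusps raise complexity (OPCR).

* :func:`generate_feature_table` draws per-diet multivariate-normal
  feature vectors (RFI, ariaDNE, lnOA, TriTaHI) with a controllable
  class-separation scale.  The named presets encode the qualitative
  contrasts seen in comparative samples: faunivores/folivores large with
  (respectively) high/low trigonid-talonid height index, insectivores and
  frugivore-insectivores small, hard-object feeders blunt and low-relief,
  and a constant between-clade TriTaHI offset available for the
  "same diet, different clade" phenomenon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh_io import ToothMesh

FEATURES = ("rfi", "ariadne", "lnoa", "tritahi")


@dataclass(frozen=True)
class CrownSpec:
    """Parametric description of a synthetic crown.

    cusps are (x, y, height, width) Gaussian bumps; x is mesiodistal
    (+x = mesial), y buccolingual, both within the rectangular footprint
    centred on the origin.
    """

    length: float = 10.0  # mesiodistal extent L_x
    width: float = 7.0  # buccolingual extent L_y
    cusps: tuple = ((0.0, 0.0, 3.0, 1.5),)
    wall_depth: float = 2.0
    grid_resolution: int = 80
    noise: float = 0.0  # vertex jitter amplitude (same units as coordinates)
    seed: int = 0

    def __post_init__(self):
        for (cx, cy, h, s) in self.cusps:
            if h <= 0 or s <= 0:
                raise ValueError("cusp heights and widths must be positive")
            if abs(cx) > self.length / 2 or abs(cy) > self.width / 2:
                raise ValueError(f"cusp centre ({cx}, {cy}) outside footprint")
        if self.wall_depth < 0:
            raise ValueError("wall_depth must be >= 0")
        if self.grid_resolution < 4:
            raise ValueError("grid_resolution must be >= 4")


def _height_field(spec: CrownSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    z = np.zeros_like(x)
    for (cx, cy, h, s) in spec.cusps:
        z += h * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * s**2))
    return z


def generate_tooth(spec: CrownSpec) -> ToothMesh:
    """Triangulated crown surface for ``spec``; deterministic given the seed.

    The top surface is the cusp height field sampled on a regular grid;
    the footprint's boundary ring is extruded down to ``-wall_depth`` to
    form the cervical walls, leaving the bottom open.  The result is
    occlusally oriented by construction (+z apex, +x mesial).
    """
    r = spec.grid_resolution
    xs = np.linspace(-spec.length / 2, spec.length / 2, r)
    ys = np.linspace(-spec.width / 2, spec.width / 2, r)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = _height_field(spec, X, Y)

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        Z = Z + spec.noise * rng.standard_normal(Z.shape)

    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j):
        return i * r + j

    faces = []
    for i in range(r - 1):
        for j in range(r - 1):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            # split quads so upward normals are consistent (counter-clockwise
            # seen from +z)
            faces.append((a, b, c))
            faces.append((a, c, d))

    if spec.wall_depth > 0:
        # boundary ring, counter-clockwise seen from above
        ring = (
            [vid(0, j) for j in range(r)]
            + [vid(i, r - 1) for i in range(1, r)]
            + [vid(r - 1, j) for j in range(r - 2, -1, -1)]
            + [vid(i, 0) for i in range(r - 2, 0, -1)]
        )
        n0 = len(vertices)
        bottom = vertices[ring].copy()
        bottom[:, 2] = -spec.wall_depth
        vertices = np.vstack([vertices, bottom])
        m = len(ring)
        for k in range(m):
            t0, t1 = ring[k], ring[(k + 1) % m]
            b0, b1 = n0 + k, n0 + (k + 1) % m
            faces.append((t0, b1, b0))
            faces.append((t0, t1, b1))

    return ToothMesh(vertices, np.asarray(faces, dtype=np.int64), orientation_flag=True)


# ---------------------------------------------------------------------------
# Named crown presets


CROWN_PRESETS: dict[str, CrownSpec] = {
    # single radially symmetric cusp: the OPCR = 8 oracle shape
    "single-cusp-v1": CrownSpec(cusps=((0.0, 0.0, 3.0, 1.5),)),
    # four cusps separated widely enough that the inter-cusp field flattens
    # below the OPCR flatness tolerance: one 8-sector annulus per cusp
    "quad-cusp-v1": CrownSpec(
        length=20.0,
        width=20.0,
        cusps=(
            (-4.5, -4.5, 3.0, 0.85),
            (-4.5, 4.5, 3.0, 0.85),
            (4.5, -4.5, 3.0, 0.85),
            (4.5, 4.5, 3.0, 0.85),
        ),
        wall_depth=0.0,
        grid_resolution=140,
    ),
    # tall mesial (trigonid) cusp, low distal (talonid) cusp: the
    # generalised-tribosphenic insectivore/faunivore profile (TriTaHI >> 0)
    "dasyurid-like-v1": CrownSpec(
        cusps=((2.5, 0.0, 4.5, 1.2), (-2.5, 0.0, 1.5, 1.4)),
        wall_depth=1.0,
    ),
    # near-equal cusp heights: folivore-like low TriTaHI
    "folivore-like-v1": CrownSpec(
        cusps=((2.5, 0.0, 3.0, 1.5), (-2.5, 0.0, 2.9, 1.5)),
        wall_depth=1.0,
    ),
    # tall, sharp cusps on a small footprint with deep cervical walls:
    # the high-relief (> 0.56 RFI) unmodified-tribosphenic insectivore band
    "sharp-tall-v1": CrownSpec(
        length=6.0,
        width=5.0,
        cusps=((1.5, 0.0, 5.0, 0.7), (-1.5, 0.0, 4.0, 0.75)),
        wall_depth=2.5,
    ),
}


# ---------------------------------------------------------------------------
# Diet-structured feature tables


@dataclass(frozen=True)
class TableSpec:
    """Specification of a per-diet multivariate-normal feature table.

    ``class_means`` maps diet label -> mean vector over ``features``;
    ``class_sds`` gives the per-feature standard deviations (shared across
    classes unless overridden per class).  ``separation`` rescales every
    class mean's deviation from the grand mean: 0 collapses all classes
    onto one distribution, 1 is the preset geometry, large values make
    classes trivially separable.
    """

    class_means: dict
    class_sds: tuple
    n_species_per_class: int = 10
    specimens_per_species: int = 2
    specimen_sd_fraction: float = 0.5  # within-species spread, as a fraction of class SD
    features: tuple = FEATURES
    clade: str = "marsupial"
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.class_sds):
            raise ValueError("class_sds must be positive (diagonal covariance PD)")
        if len(self.class_sds) != len(self.features):
            raise ValueError("class_sds length must match features")
        for diet, mu in self.class_means.items():
            if len(mu) != len(self.features):
                raise ValueError(f"mean vector for {diet!r} has wrong length")


# Class geometry for the presets, features = (rfi, ariadne, lnoa, tritahi).
# Values encode the qualitative comparative pattern: faunivores/folivores
# large (high lnOA), insectivores & frugivore-insectivores small; relief and
# curvature highest in faunivores/insectivores; trigonid-talonid height
# index high in faunivores & insectivores, near zero in folivores, and
# systematically lower in the primate-like clade for matched diets (the
# clade offset applied by `clade_offset_tables`).
_MARSUPIAL_MEANS = {
    "faunivore": (0.55, 0.085, 2.8, 0.28),
    "folivore": (0.47, 0.072, 2.9, 0.02),
    "frugivore": (0.42, 0.058, 2.0, 0.05),
    "frugivore-insectivore": (0.52, 0.082, 1.5, 0.15),
    "insectivore": (0.48, 0.078, 1.3, 0.16),
    "omnivore": (0.55, 0.080, 2.6, 0.12),
}
_PRIMATE_MEANS = {
    "folivore": (0.48, 0.078, 3.0, 0.09),
    "frugivore": (0.42, 0.062, 3.1, 0.00),
    "frugivore-insectivore": (0.46, 0.075, 1.6, 0.03),
    "insectivore": (0.50, 0.082, 1.2, 0.12),
    "hard-object feeder": (0.35, 0.055, 2.9, 0.03),
}
_SDS = (0.045, 0.006, 0.35, 0.06)

TABLE_PRESETS: dict[str, TableSpec] = {
    "marsupial-v1": TableSpec(class_means=_MARSUPIAL_MEANS, class_sds=_SDS,
                              clade="marsupial"),
    "primate-v1": TableSpec(class_means=_PRIMATE_MEANS, class_sds=_SDS,
                            clade="primate"),
}


def generate_feature_table(spec: TableSpec) -> pd.DataFrame:
    """Draw a specimen-level feature table from ``spec``.

    Each class contributes ``n_species_per_class`` species; each species has
    a species-level mean drawn from the class distribution and
    ``specimens_per_species`` specimen observations (loci m2, m3, ...)
    scattered around it.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.features)
    sds = np.asarray(spec.class_sds, float)
    mus = {d: np.asarray(m, float) for d, m in spec.class_means.items()}
    grand = np.mean(list(mus.values()), axis=0)

    loci = ["m2", "m3"]
    rows = []
    sp_counter = 0
    for diet in sorted(mus):
        mu = grand + spec.separation * (mus[diet] - grand)
        for _ in range(spec.n_species_per_class):
            sp_counter += 1
            species = f"{spec.clade[:3]}_sp{sp_counter:03d}"
            sp_mean = rng.normal(mu, sds)
            for j in range(spec.specimens_per_species):
                x = rng.normal(sp_mean, spec.specimen_sd_fraction * sds)
                row = {
                    "specimen_id": f"{species}-{j:02d}",
                    "species": species,
                    "family": f"{spec.clade[:3]}_fam{(sp_counter - 1) % 5 + 1}",
                    "clade": spec.clade,
                    "locus": loci[j % len(loci)],
                    "diet": diet,
                }
                row.update(dict(zip(spec.features, x)))
                rows.append(row)
    return pd.DataFrame(rows)


def clade_offset_tables(
    seed: int = 0,
    tritahi_offset: float = 0.0,
    separation: float = 1.0,
    n_species_per_class: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two matched-diet clade tables differing only by a TriTaHI offset.

    Both clades share the same class geometry (the marsupial-like preset
    restricted to the diets present in both clades); the second table's
    TriTaHI means are shifted down by ``tritahi_offset``.  This isolates the
    phenomenon where a clade-specific offset in one metric degrades
    cross-clade transfer while leaving within-clade structure intact.
    """
    shared = ("folivore", "frugivore-insectivore", "insectivore")
    means = {d: _MARSUPIAL_MEANS[d] for d in shared}
    spec_a = TableSpec(
        class_means=means,
        class_sds=_SDS,
        clade="marsupial",
        separation=separation,
        n_species_per_class=n_species_per_class,
        seed=seed,
    )
    shifted = {
        d: tuple(np.asarray(m) - np.array([0, 0, 0, tritahi_offset]))
        for d, m in means.items()
    }
    spec_b = TableSpec(
        class_means=shifted,
        class_sds=_SDS,
        clade="primate",
        separation=separation,
        n_species_per_class=n_species_per_class,
        seed=seed + 1,
    )
    return generate_feature_table(spec_a), generate_feature_table(spec_b)
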