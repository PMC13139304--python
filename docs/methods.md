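# Methods

This note documents the models, numerical choices and limitations behind
`dentopo`, in the order the pipeline runs.

## Mesh model and conditioning

A tooth is a triangulated crown surface, usually an open mesh cropped at
the cervix. The occlusal convention is +z toward the apex, +x mesial,
+y buccal; the lingual view is the projection onto the x–z plane. I/O is
lossless (no welding at read time); validation requires in-range, distinct
face indices and strictly positive face areas.

Conditioning mirrors the standard crown-preparation chain:

1. *Clean*: duplicate faces (as index sets) removed; only the largest
   edge-connected component kept; vertex centroid translated to origin.
2. *Decimate*: quadric edge collapse to a 10,000-triangle budget
   (±2 faces). Per-vertex quadrics are area-weighted face-plane quadrics
   plus boundary-constraint quadrics (planes through each open edge,
   perpendicular to its face, weighted by squared edge length) so that open
   crown borders do not erode. Collapses that would flip or degenerate a
   face, or violate the link condition, are rejected. Meshes already at or
   below the budget pass through unchanged with a logged flag — the
   standard handling for low-resolution specimens. Measured on a 20k-face
   sphere, a 2:1 reduction changes total area by <0.01% and the bounding
   box by <0.001%.
3. *Smooth*: one pass (default) of HC-Laplacian smoothing — a uniform
   Laplacian step followed by the back-projection correction
   (α = 0, β = 0.5) that subtracts each vertex's displacement blended with
   the mean displacement of its neighbours, suppressing the volume
   shrinkage of plain Laplacian smoothing (<0.001% volume change per pass
   on a closed sphere). Boundary vertices are pinned (their displacement is
   defined as zero inside the correction): the cervical margin of a cropped
   crown stays put, and flat surfaces are exact fixed points. This is a
   deliberate difference from implementations that let the open border
   drift inward.

The whole chain is deterministic: identical input bytes give identical
output bytes.

## Crown metrics

**Outline area / lnOA / RFI.** The occlusal outline is the alpha shape of
the vertices projected to z = 0: Delaunay triangles with circumradius ≤ α,
unioned. In `auto` mode, 64 log-spaced radii between 0.01× and 10× the
median projected edge length are swept and the smallest radius whose shape
is a single simple hole-free polygon covering all projected points wins;
if none qualifies the convex hull is used and logged. RFI is
ln(√A3D / √A2D), zero for a flat sheet, ln √2 for a hemisphere; scale
invariant by construction.

**DNE.** Vertex normals are angle-weighted averages of face normals. For
each face, with edge vectors u, v and normal differences nu, nv, the first
and second fundamental-form estimates are G = [[u·u, u·v], [u·v, v·v]] and
H = [[nu·nu, nu·nv], [nu·nv, nv·nv]]; the energy density is
e = tr(G⁻¹H) and DNE = Σ e·a over included faces. Faces touching an open
boundary are excluded by default (the cropped cervix otherwise dominates),
plus the top 0.1% of faces by e·a (outlier guard, configurable). A face is
*convex* when the summed projection of pairwise normal differences onto
the corresponding edge vectors is non-negative — normals diverging along
outward displacement; ties (|κ| < 1e−12) count as convex. On a 10k-face
unit sphere the estimator is within 0.2% of the analytic ∫(k1²+k2²)dA = 8π.

**ariaDNE.** The mesh is rescaled to unit total surface area, which is
what makes the bandwidth ε (default 0.08, warned outside [0.04, 0.1])
comparable across specimens. For each vertex, all vertices within 3ε
contribute Gaussian weights w = exp(−d²/ε²); a local frame is taken from
the weighted covariance (z-axis = smallest principal direction, oriented
by the vertex normal) and a full quadric z = ax² + bxy + cy² + dx + ey + f
is fitted by weighted least squares. The per-vertex density is the sum of
squared principal curvatures of the fitted graph at the vertex
(eigenvalues of I⁻¹·II with the gradient terms retained), the area weight
is the barycentric vertex area, and the CV is the area-weighted SD over
the area-weighted mean. A vertex whose effective neighbourhood (weights
> 1e−3) has fewer than 6 points raises a bandwidth error naming the
vertex. Flat surfaces give zero energy; the CV is then reported as 0 with
a warning. Note the deliberate smoothing built into the metric: at
ε = 0.08 it captures large structures, so on crowns whose features are
comparable to the bandwidth it reads lower than DNE; on broad smooth
crowns the two agree within ~10%.

**OPCR.** Face normals are binned by azimuth into eight 45° sectors,
faces whose unit normal has horizontal magnitude < 1e−4 are excluded as
flat, edge-connected same-bin patches with ≥ 3 faces are counted, and the
count is averaged over eight rotations of 5.625° about +z (together
spanning one bin width). A radially symmetric cusp yields exactly 8 at
every rotation; four sufficiently separated cusps yield exactly 32. The
separation matters: if the combined far-field of several cusps stays above
the flatness tolerance it forms its own 8-sector periphery annulus and
adds up to 8 patches — the quad-cusp preset is sized so the inter-cusp
field genuinely flattens.

**TriTaHI.** The lingual silhouette is the boundary of the union of the
projected triangles. The cervical baseline is either operator-supplied
(takes precedence, since the measurement is operator-defined on real
specimens) or auto-detected as the lowest-z outline point within the
mesial-most and distal-most 15% of the x-extent (ties broken toward lowest
x, with a warning). Heights are measured from the baseline's infinite
line; the trigonid/talonid division sits at `split_fraction` (default 0.5)
of the maximum molar length, measured along the baseline from its distal
endpoint, so a supplied baseline controls where the division falls.
TriTaHI = (H_tri − H_tal)/L_max is scale-, translation- and (in-plane)
rotation-invariant and exactly antisymmetric under mesiodistal mirroring.
Because the projection is exact given the orientation, small systematic
offsets against hand measurements taken from screenshots are expected.

## Tables and classification

Species tables validate diet labels against a YAML vocabulary (seven
categories: faunivore, folivore, frugivore, frugivore-insectivore,
insectivore, hard-object feeder, omnivore), reject duplicate
specimen+locus rows, and keep missing metric cells missing. Species means
pool m2 and m3 of the same specimen as separate observations — two-tooth
specimens carry double weight, which matches how combined-locus samples
are built but should be kept in mind.

QDA uses per-class sample means and unbiased (n−1) covariances; priors are
equal across classes by default (rare diets are not penalised), with
proportional priors available. Singular classes (n_k ≤ p) raise loudly,
naming the class; an optional ridge exists but defaults off — exclusion of
undersampled categories is an explicit analyst decision, not a silent
shrinkage. Prediction ties are broken lexicographically by label
(deterministic). Leave-one-out refits n times; clade-based
cross-validation fits on one clade's species means, predicts all of the
other's, and scores only test rows whose true category exists in the
training set, returning the full confusion table (including non-shared
true categories) for inspection.

## Group statistics

The gated procedures hard-code the branch rule: Shapiro–Wilk at α = 0.05
per group (paired/two-sample) or on ANOVA residuals (multi-group) selects
the parametric branch (paired t / Welch t / ANOVA + Tukey HSD) or the rank
branch (Wilcoxon signed-rank / rank-sum / Kruskal–Wallis + Dunn). Wilcoxon
procedures use exact nulls for small n (≤ 25 pairs / ≤ 25 pooled),
normal approximation with continuity correction above. Dunn post-hoc
z-tests carry the standard tie correction and are reported both unadjusted
and Bonferroni-adjusted, since adjustment conventions vary. Groups of
n = 1 are excluded with a warning. Every result object records the branch
and the gate p-values. Levene's test is mean-centred. PCA standardises
columns to unit variance (ddof = 1) and decomposes the correlation matrix;
eigenvalues sum to the number of features.

## Synthetic data

`generate_tooth` builds a crown as a height field z(x, y) = Σ hᵢ·
exp(−((x−xᵢ)² + (y−yᵢ)²)/2σᵢ²) over a triangulated grid, with the
footprint's boundary ring extruded to −wall_depth as cervical walls and an
open bottom. This reproduces the properties the metrics care about —
open boundaries like cropped real molars (exercising DNE's boundary
exclusion), monotone control of relief (cusp height), curvature (cusp
width) and complexity (cusp count) — but not enamel texture, wear facets,
crests/lophs, or scan noise beyond optional Gaussian jitter. Passing tests
therefore validate the estimators and the pipeline plumbing, not the
biological discriminability of real diets.

`generate_feature_table` draws per-diet feature vectors (RFI, ariaDNE,
lnOA, TriTaHI) from a two-level normal model: species means around class
means (diagonal covariance), specimens around species means at half the
class SD. The preset class geometries encode the qualitative comparative
pattern: faunivores and folivores large (high lnOA) with respectively high
and near-zero TriTaHI; insectivores and frugivore-insectivores small;
hard-object feeders blunt and low-relief; and a marsupial-like vs
primate-like contrast including a systematically lower TriTaHI in the
primate-like clade for matched diets. A `separation` scale moves every
class mean toward/away from the grand mean (0 = one common distribution,
used for chance-level calibration). `clade_offset_tables` isolates the
transfer phenomenon: two matched-diet clades identical except for a
constant TriTaHI offset, which degrades cross-clade shared-category
accuracy while leaving within-clade leave-one-out accuracy untouched.

Default table sizes (10 species per class, 2 specimens per species) keep
classifier inputs comparable to real species-mean studies while leaving
every class comfortably above the QDA singularity threshold.

## Numerical and size choices

Geometry oracles run at ~5k–40k faces: a subdivision-4 icosphere (5,120
faces) for the DNE oracle, a 60×120 UV hemisphere for RFI, 140-resolution
grids for the OPCR constructions. Calibration uses 1,000 seeded replicates
for type-I rates and 100 for the chance-level leave-one-out band; the
acceptance script re-derives its replicate seeds from the single --seed
argument. Tolerances follow the estimator, not the test: 5% for the
sphere DNE (curvature estimators converge slowly at coarse meshes), 1% for
hemisphere RFI (area ratios converge fast), exact equality for
combinatorial OPCR constructions and for symmetry identities.

## Known limitations

* Decimation is implemented in pure Python; very large meshes (≫100k
  faces) decimate slowly. The intended operating point is the standard
  10k-triangle budget.
* Metric values are not numerically identical to any particular existing
  toolchain; correctness is anchored to closed-form oracles, invariance
  laws, and downstream classification behaviour.
* OPCR and ariaDNE CV are known to be sensitive to specimen material and
  mesh provenance in real data (original specimens vs epoxy casts); no
  computational correction is attempted — mixed-material comparisons
  should simply avoid these metrics.
* Orientation is accepted as given; there is no automatic occlusal
  alignment.
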