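# Methods

This note documents the models, conventions and design choices behind
`mifquant`, in the spirit of a statistical-software methods appendix. It
describes what each stage computes and why the defaults are what they are;
every number quoted here is produced by the test suite or
`scripts/acceptance.py`, not asserted from memory.

## Coordinate and unit conventions

Each slide lives in a Cartesian frame in micrometers with an arbitrary
per-slide origin; y increases toward deeper tissue, and in synthetic slides
the mucosal surface is the line y = 0. A cell is a point (its nucleus
centroid). A cell belongs to a region iff the point is inside, with the
boundary counting as inside; when two compartments share a boundary, the
tie breaks toward the first label in a fixed priority order (TLS, then
parenchyma, stroma, margin, central tumor, tile). Coordinates are snapped
to a 0.001 µm grid before geometric predicates so point-on-boundary
outcomes are stable. Areas are computed in µm² and reported in mm²; all
densities are cells/mm².

## Phenotyping

Gating is hierarchical and pointwise. CD3⁺ cells are T lineage: FoxP3⁺
cells become regulatory ("FoxP3_T") before CD8 is considered, CD8⁺ cells
become cytotoxic ("CD8_T"), and the CD3⁺CD8⁻FoxP3⁻ remainder is labeled
"CD4_T" — a conventional proxy, since CD4 itself is not stained (it is
expressed by macrophages and dendritic cells and is unreliable in this
panel context). Non-T cells fall through CD20 → CD68 → PanCK → Other.
Two conflict classes are counted and reported rather than erased: the rare
CD3⁺CD8⁺FoxP3⁺ cell (assigned the more specific regulatory label) and
T-lineage cells carrying CD20/CD68/PanCK signal (segmentation spillover; T
lineage wins so the partition property holds: the three T subsets always
sum exactly to the CD3⁺ count).

## Compartments, margin, tiles

The central tumor is partitioned into tumor parenchyma and stroma (no
overlapping area); the invasive margin is the outward band
`buffer(tumor, w) − tumor` with w = 250 µm by default — the band hugs the
outermost invasive edge and shares no interior with the tumor. Spatial
heterogeneity is summarized over 30 axis-aligned square tiles (default edge
500 µm) sampled without overlap from a regular candidate lattice by a
seeded draw; a grid pitch equal to the tile edge guarantees disjointness,
and determinism follows from the seed. Tile dispersion is reported as
median and IQR of per-tile densities per phenotype.

The immune-phenotype call is a pure decision rule on CD8 T-cell densities:
*inflamed* iff parenchyma CD8 ≥ `cd8_tumor_high`; otherwise *excluded* iff
max(stroma, margin) CD8 ≥ `cd8_stroma_high`; otherwise *desert*. The
thresholds default to 50 cells/mm² each — an order-of-magnitude choice,
explicitly configurable and echoed into every output, because published
cutoffs for this rule are not standardized. The margin's participation in
the excluded branch can be toggled off. Correctness is tested via the
decision-rule truth table and a monotonicity property (raising parenchyma
CD8 never moves a call away from inflamed), not via the default values.

## TLS detection and architecture

TLS are detected as single-linkage components of lymphocytes (B cells and
the three T subsets) at a link radius of 30 µm; a component is a TLS iff it
holds ≥ 50 lymphocytes with a B-cell fraction ≥ 0.3, and its polygon is the
component's convex hull dilated by half the link radius. Detection operates
on peritumoral tissue: the central tumor and margin are masked, because a
diffuse stromal infiltrate dense enough to percolate at the link radius is
geometrically indistinguishable from an aggregate yet belongs to
compartment quantification, and TLS in this tissue context are peritumoral
structures (muscularis, fat, regression beds). Pre-annotated TLS polygons,
when present in the region set, bypass the detector.

Note one property of single linkage: two aggregates merge only when the
link radius spans their nearest edge-to-edge gap, not any fraction of
center distance.

Composition is the raw five-feature density vector (B, CD4 T, CD8 T,
FoxP3 T, macrophage); the clustering pseudo-count is *not* applied here.
Maturation staging is a truth table on (FDC, GC) presence: FDC present iff
≥ `min_cd21` (default 5) CD21⁺ cells inside the TLS, GC present iff ≥
`min_cd23` (default 5) CD23⁺ cells — a network or zone needs more than a
stray positive. (0,0) → Early, (1,0) → primary-follicle-like, (1,1) →
secondary-follicle-like; the biologically anomalous GC-without-FDC cell of
the table is staged SFL with a logged warning. Without the CD21/CD23 panel
a TLS is "unstaged" and excluded from maturation fractions.

Depth is the Euclidean distance from the TLS centroid to the mucosal
polyline; *superficial* iff depth ≤ 1000 µm (closed boundary, with a 10⁻⁶
µm tolerance absorbing centroid rounding). The 1000 µm default approximates
urothelium-plus-submucosa thickness; the anatomical definition is not
metric, so the threshold is configurable and always reported.

## Composition clustering and cross-cohort assignment

Densities get a pseudo-count ε = 0.01 cells/mm² (so a null density enters
the log scale at ln 0.01 ≈ −4.605), a natural-log transform (the base is
cosmetic — z-scores are base-invariant — but fixed for stored values), and
feature-wise centering/scaling by the mean and sample SD (ddof = 1) of the
*training* cohort. k-means uses k-means++ seeding with 10 restarts and up
to 300 Lloyd iterations per k over k = 1..10; for each k beyond the first,
one extra warm-started run reuses the previous k's centroids plus the point
farthest from its centroid (splitting the loosest cluster), which makes the
WSS curve provably non-increasing in k. The elbow selects the k maximizing
the WSS second difference; a strictly linear curve has no elbow and returns
the smallest k with a warning, and a fixed-k mode exists for confirmatory
runs. Cluster labels are arbitrary in k-means, so clusters are renumbered
deterministically by descending centroid total in scaled space.

Assignment of a new cohort applies the stored ε/log/z transform with the
training means and SDs — never refitted — and takes the nearest centroid in
Euclidean distance, ties to the lowest label. Re-assigning the training
TLS through the stored model reproduces the training labels exactly; the
model JSON (ε, log base, means, SDs, centroids, WSS curve, seed) is
sufficient for bit-exact re-assignment.

## Statistics

Group comparisons use the two-sided Mann-Whitney U test: exact enumeration
when n₁+n₂ ≤ 20 and the pooled sample is tie-free, else the tie-corrected
normal approximation *without* continuity correction — at the sample sizes
this pipeline sees (n ≈ 15–30 per group) the correction makes the test
conservative (attained type-I ≈ 3.9–4.4% at nominal 5%), while the
uncorrected statistic sits at ≈ 4.2–4.8%. A fully tied pooled sample
returns p = 1. Fisher exact tests on 2×2 tables are two-sided by the
probability-mass convention (sum of hypergeometric probabilities ≤ that of
the observed table). Boxplot summaries use linear-interpolation percentile
hinges and whiskers at the most extreme observation within 1.5·IQR of the
hinge. No multiple-comparison adjustment is applied anywhere; every
reported p carries an explicit unadjusted flag.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes and
emits full ground truth. Per slide: a disc-shaped central tumor (default
radius 3 mm, centered 5 mm deep) split into an inner parenchyma disc and a
stroma annulus (stroma fraction 0.45), a 250 µm outward margin, a mucosal
line at y = 0, and background tissue elsewhere. Per-patient densities are
lognormal around literature-scale medians (e.g. parenchyma CD8 35/mm²,
stroma CD4 150/mm², parenchyma tumor cells 800/mm²) with a shared
patient-level "immune tone" (SD 0.5 log-units) correlating compartments;
margin densities are the patient's stroma draw times an enrichment factor
of 2. Optional effect injections exist for power studies: a margin-CD8
multiplier for non-recurring patients, and a latent axis coupling CD8 up /
FoxP3 down to reproduce the low-CD8-ratio → high-FoxP3-fraction pattern.
Cells follow homogeneous Poisson processes per compartment; markers are the
inverse of the gating map.

TLS counts per patient are lognormal-mixed Poisson (rate median 16.5,
log-SD 0.866), giving median ≈ 16.5 and mean ≈ 24 — a pure Poisson cannot
hold that median/mean pair. TLS are discs with lognormal radius (median
150 µm, log-SD 0.25) placed outside tumor+margin, superficial (25%) within
1 mm of the mucosa and the rest deeper, pairwise separated so aggregates
remain distinct. Each TLS draws one of five compositional archetypes with
log-normal dispersion σ = 0.2 around archetype means.

**Archetype geometry.** The five archetype mean vectors form (in log-density
space) a regular 4-simplex built from single-feature "dips": archetype 1 is
uniquely FoxP3-low, 2 low overall (its dip is on the B axis but with a high
B baseline it stays B-rich in fraction terms), 3 CD4-low, 4 CD8-low and
densest overall, 5 macrophage-low; archetypes 2 < 3 < 4 carry a mild
(±0.05 log-unit) overall-density grading. Mixing weights are 19:165:203:
341:26. The simplex-with-axis-aligned-dips shape is deliberate: the elbow
criterion (max WSS second difference) is only a reliable estimator of the
planted k when successive cluster merges cost comparable WSS. A strong
overall-density grading collapses the data onto one dominant axis and moves
the apparent elbow to k = 2–3, which is why the grading is mild; the
archetypes' identities are carried by which subset dips. With these
defaults, 180 TLS per cohort and σ = 0.2, the elbow lands on k = 5 and
k-means at k = 5 recovers the planted archetypes with ARI ≥ 0.9 across 20
seeds (the calibration suite runs exactly this). Superficial TLS get a 3×
CD4 multiplier, and maturation-stage probabilities differ by depth
(superficial: 60/25/15% Early/PFL/SFL; deep: 30/30/40%), reproducing the
superficial-CD4-enrichment and early-stage-enrichment patterns as
directional truths.

Randomness: one master seed; per-slide seeds derive from
`SeedSequence([master, patient_index])`, so cohorts are reproducible and
slides independent. Same spec + seed → byte-identical output files.

**What the generator does not emulate** — and hence what passing tests do
not show about real tissue: real tumor/stroma interdigitation (compartments
are concentric discs), irregular TLS shapes and germinal-center substructure,
segmentation errors and intensity-threshold misclassification (markers are
exact), spatial density gradients within compartments, and any dependence
of outcome on immune features unless explicitly injected. Recovery results
(ARI, elbow) certify the analysis pipeline under its own assumptions, not
performance on real slides.

## Problem sizes and numerical choices

Tests run on scaled-down slides (6×5 mm, tumor radius 1.5 mm, ~8 TLS per
patient) and 4-patient cohorts for end-to-end runs; clustering studies use
180 TLS drawn directly from the archetype model, where the σ = 0.2
dispersion is the operative noise (measuring densities through Poisson cell
counts in small TLS adds count noise on sparse features — that path is
exercised by the pipeline tests, while recovery calibration uses the drawn
densities the condition specifies). Monte-Carlo area oracles use 10⁶
points (≲1% error); margin closed forms are checked on a 2048-gon circle.
Degenerate inputs are first-class: zero-area compartments flag densities
undefined instead of dividing, zero-TLS patients are excluded from
fraction summaries with a log entry, zero-variance features abort scaling
with a named error, and empty slides yield empty TLS lists.

## Known limitations

* The detector's convex hulls overestimate concave aggregates slightly
  (dilated hull vs. true disc), and merged neighboring aggregates under
  permissive link radii are reported as one TLS.
* CD8 thresholds for immune-phenotype calls are defaults, not validated
  cutoffs; calls should be interpreted relative to the configured values.
* The CD3⁺CD8⁻FoxP3⁻ "CD4_T" label is a proxy; double-negative T cells and
  NKT-like cells inflate it.
* Cross-cohort assignment assumes the new cohort's features are measured on
  the same scale (same staining/segmentation pipeline); batch effects are
  not modeled.
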