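# Methods

This note records the models, rules and design choices behind `oligotriage`,
in the package's own terms. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Cohort fixture: a constrained reconstruction

Per-case data for the 145-patient cohort were never deposited, so
`cohort.build_cohort_fixture()` rebuilds a case table that satisfies, as exact
integer constraints, every published group count and cross-tabulation:

- group sizes 45 / 30 / 16 / 54 (oligodendroglioma, IDH-mutant astrocytoma,
  IDH-wild-type astrocytoma, glioblastoma);
- oligodendroglioma IDH subtypes 40 R132H, 1 R132L, 2 R172K, 1 R172S,
  1 R172W; astrocytoma subtypes 29 R132H, 1 R132S;
- H3K27me3 nuclear loss (NL): 36/45 oligos (all within the 40 R132H, i.e.
  36/40), 4/30 IDH-mutant astros (all R132H), 1/16 IDH-wild-type astros,
  5/54 glioblastomas; every non-canonical IDH1/IDH2-mutant case retains the
  mark;
- ATRX retained: 43/45 oligos, 11/30 IDH-mutant astros; among the 69
  IDH1-R132H-positive cases exactly 50 retain ATRX, 39 of them
  oligodendrogliomas (which forces the R132H oligos to split 39 retained /
  1 lost, the second ATRX-lost oligo to be non-canonical, and the single
  R132S astrocytoma to be ATRX-lost);
- male/female counts per group and ages inside each group's published range.

Two aspects are genuinely under-determined and are fixed here as documented
reconstruction choices, not published facts:

1. **Which non-canonical oligo lost ATRX** — assigned to the R132L case
   (deterministic, arbitrary among the five). Because all non-canonical
   oligos retain H3K27me3, this ATRX-lost oligo is NR; the ATRX-lost R132H
   oligo is assigned NL.
2. **ATRX status of the ten H3K27me3-NL non-oligo cases** (4 IDH-mutant
   astros, 1 IDH-wild-type astro, 5 glioblastomas) — co-assigned ATRX-lost.
   This is the only assignment family under which the default fitted tree
   reproduces the published split order (see below): at the H3K27me3-NL node
   the ATRX split then scores G² ≈ 41.5 versus ≈ 22.2 for IDH1-R132H, whereas
   an independent assignment (NL cases ATRX-retained) gives ATRX G² ≈ 9.0 and
   the tree would split on IDH1-R132H instead. The true joint distribution
   sits in unpublished supplementary material.

p53 is not constrained by any published count; the fixture assigns the
lineage-typical pattern (oligos negative, IDH-mutant astros positive,
IDH-wild-type groups not assessed) and no test or target depends on it.
Ages are drawn uniformly within each group's published range under a fixed
documented seed (20210521); published group mean ages are not reproduced
because the raw ages are unpublished, and they are not asserted anywhere.

## Field-image simulator

`simulate.simulate_field` emulates the appearance that the scoring rules
need, not histology: a near-white background (gray 235), non-overlapping
disc nuclei, stain rendered dark (stained mean 90, unstained mean 180),
truncated Gaussian sensor noise (sd 4, capped at ±3 sd so the three gray
populations stay disjoint), and four nucleus classes — stained tumor,
unstained tumor, dot-like tumor (an unstained disc with one interior stained
dot covering < 10% of its area, shrunk as needed after rasterization), and
always-stained internal-control cells standing in for endothelium and
lymphocytes. Exactly `round(stained_fraction × n_tumor_nuclei)` tumor nuclei
are stained, so fraction arithmetic in tests is exact. Default field:
256 × 256 px, 40 tumor nuclei of radius 6–9 px, 4 control cells.

`simulate_case_fields` draws a case's three fields (mirroring three randomly
selected 20× areas per section) at stained fraction 0.05 for NL cases and
0.85 for NR cases — well inside the negative (> 75% loss) and positive
(> 25% diffuse) regions respectively — with per-field seeds derived from the
case seed via a `SeedSequence`.

What the simulator deliberately does not model: RGB DAB/hematoxylin color
physics (scoring runs on a single gray channel), touching or overlapping
nuclei, tissue texture, JPEG re-encoding, scanner formats, and the manual
recognition of control cells on real slides (the simulator marks them in
ground truth; real-slide use would need a human or a classifier to exclude
them). Passing tests therefore demonstrate the correctness of the scoring
chain's logic on images that satisfy its assumptions, not segmentation
robustness on real histology.

## Intensity scoring and NL/NR binarization

`ihc.otsu_threshold` implements Otsu's method directly on the 256-bin
histogram: it returns the integer t maximizing the between-class variance
ω₀(t)·ω₁(t)·(μ₀(t) − μ₁(t))² between classes gray ≤ t and gray > t, breaking
ties toward the smallest t, and raises on a single-occupied-bin histogram
rather than returning an arbitrary cut. A brute-force all-thresholds oracle
backs it in the tests.

`score_field` takes the foreground as gray ≤ t (tissue is darker than
background) and records the mean foreground gray; `score_case` averages the
fields. **Score orientation** was an open choice: nothing in the published
description fixes whether a higher "average intensity" means more or less
stain. On the brightfield proxy the mean foreground gray rises as stain is
lost, so here HIGHER score ⇔ NL; this is also the only orientation under
which a borderline NL score (152) can sit adjacent to the NR cluster while an
NR outlier sits at 65, as the published clustering legend describes.

Because no numeric NR/NL cut-point was published, the cohort's case scores
are binarized by `IntensityBinarizer`: agglomerative clustering (scipy,
average linkage by default; complete/ward exposed as options) on the 1-D
scores, cut at k = 2, with the higher-mean cluster labeled NL. At the
simulator's default separation (≈ 90 vs ≈ 166) this recovers every label;
with overlapping score distributions the cut — like any clustering cut —
would become data-dependent.

## Fraction scoring

`segment_nuclei` must keep pale unstained nuclei in the foreground, which a
two-class Otsu cut does not guarantee on stain-rich fields (the optimal
two-class cut can fall between the stained and unstained modes). The mask
therefore uses the upper threshold of a three-class multi-Otsu split
(stained / unstained / background), followed by connected components and a
`min_nucleus_area` (20 px) debris filter.

`classify_nucleus` compares each nucleus' pixels against a stain cutoff —
the midpoint of the simulator's class means (135) when ground truth is known,
otherwise the field's Otsu threshold re-applied within the mask — and calls
STAINED when the stained-area fraction exceeds `dot_area_fraction_max`
(0.10), DOTLIKE_NEGATIVE when it is positive but at most 0.10 (the dot-like
pattern counts as loss), and NEGATIVE at zero. "Diffuse staining" has no
published pixel-level definition; the 0.10 area bound is this package's
operationalization.

`fraction_score_case` pools nuclei over all fields (controls excluded):
POSITIVE iff stained fraction > 0.25 (p53 variant: > 0.50), NEGATIVE iff
loss fraction > 0.75. The two published rules are complementary only for
strict inequalities; the exactly-25% boundary is undefined by them and is
broken toward NEGATIVE here. The tests verify that the fraction route and
the intensity route agree case-for-case on simulated cohorts, mirroring the
published identical-results comparison of the two procedures.

## FISH calling

Patterns other than 1 red + 2 green (deleted) and 2 red + 2 green (intact)
are excluded from the denominator — the published criterion is silent on
polysomy and truncation artifacts, and scoring there was restricted to
well-defined nuclei, so exclusion is the closest computational analogue.
The deletion criterion is inclusive (fraction ≥ 0.50, "50% or more");
codeletion requires both arms. ~100 nuclei per probe set is the emulated
scale.

## Contingency statistics

Fisher's exact test uses the standard two-sided small-sample convention
(sum of hypergeometric probabilities ≤ the observed table's), delegated to
`scipy.stats.fisher_exact` and verified in tests against an exact
rational-arithmetic enumeration for totals ≤ 40. Chi-squared is the Pearson
statistic without Yates continuity correction (the published methods do not
say; no correction is the common default at these counts), df = (R−1)(C−1),
with an explicit error on zero expected cells. Which test was applied to
which table was not published; both are computed and reported side by side.

## Partition tree

Split quality is the likelihood-ratio statistic G² = 2·Σ O·ln(O/E) over
children × classes, with E from the parent's class proportions — equivalent
to the G-test of the child-by-class table, which is the scipy oracle used in
tests. The published analysis names no criterion, stopping rule or software
internals; the choices here — G², `min_leaf` = 5, no pruning, each predictor
used at most once per path, ties broken in the fixed order H3K27me3, ATRX,
IDH1-R132H — are the simplest ones consistent with the published tree (each
predictor once, depth ≤ 3). On the fixture the default tree splits
H3K27me3 → ATRX → IDH1-R132H.

The alternate tree rooted at IDH1-R132H requires more than overriding the
root: with the fixture's forced marginals the IDH1-positive node's
H3K27me3 split (G² ≈ 44.6) beats ATRX (G² ≈ 33.4) under any valid
reconstruction, so a greedy tree below a forced root will not reproduce the
published IDH1 → ATRX layout. `fit_tree` therefore also accepts a forced
split sequence by depth (`forced_order`), under which the IDH1-positive,
ATRX-retained node contains the published 50-case stratum with 39
oligodendrogliomas.

Leaf probabilities default to prior smoothing, (n_c + prior_c)/(N + 1), one
pseudo-case of the root class proportions. This is a reconstruction of the
style of the published probability scores (0.9835 / 0.9823); the original
software's smoothing formula is unpublished, so numeric agreement is
reported (the fixture's oligo leaf gives ≈ 0.981) but never asserted.

## Assay utilities

In-silico PCR is exact-match only (mismatch tolerance and thermodynamics are
out of scope): the forward primer must occur exactly once, the reverse
primer's reverse complement exactly once and downstream, and the amplicon
spans both primers (0-based half-open coordinates, length in bases). The
published 129 bp (IDH1) and 293 bp (IDH2) lengths are exercised on
constructed templates; checking them against the human genomic reference
would require an external sequence and is left to the user. Codon naming
translates with the standard genetic code (Biopython), labels substitutions
as refAA + codon number + obsAA ("R132H"), synonymous or identical codons as
"wild-type", and stop gains with "*".

## Numerical and scale choices

- All randomness flows from explicit integer seeds; derived seeds come from
  `numpy.random.SeedSequence` and stay below 2³¹. Same config + same seed
  reproduces byte-identical outputs.
- Pixel coordinates are 0-based row/col; gray is 0–255; images are 8-bit
  single-channel PNG (TIFF accepted on read).
- Test problem sizes: the end-to-end recovery test uses 100 simulated cases
  × 3 default-size fields; the two-route agreement test 24 cases; property
  oracles use 1,000 random histograms (Otsu), 500 random 2×2 tables
  (Fisher), and dozens of random small cohorts (tree splits). The full test
  suite runs in well under a minute on one CPU.
- CSV dialect: comma-separated, UTF-8, header row; booleans as true/false;
  missing marker states as empty fields.

## Known limitations

- The fixture's within-group marker joints beyond the published constraints
  are reconstructions; analyses sensitive to those joints (notably tree
  shape below depth 1) reflect the reconstruction choices documented above.
- The scoring chain has no notion of stain color; applying it to real RGB
  slides would require a deconvolution front-end, which is out of scope.
- Segmentation assumes non-overlapping nuclei; there is no watershed
  splitting of touching nuclei.
- The published mean ages, survival outcomes and morphology review are out
  of scope; only the computational chain around the immunostains, FISH and
  the classifier is implemented.
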