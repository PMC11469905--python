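# Methods

This note documents the models, numerical conventions and design choices
behind `nephromet`, in the spirit of a statistical package's model
documentation. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## 1. Scoring model

### Components and bands

Each slide yields four ordinal components (glomerulosclerosis GS,
interstitial fibrosis IF, tubular atrophy TA, arteriosclerosis ART), each
0–3, summed to a 0–12 total. Every component is a banded percentage with
three ascending cut-points held in `ThresholdConfig`, so nothing is
hard-coded:

* **Band openness.** All bands are left-closed half-open:
  [0,b₁), [b₁,b₂), [b₂,b₃), [b₃,∞). Published band descriptions share
  endpoints ("0 = 0–50 %; 1 = 50–80 %; …"), which is ambiguous at the
  boundary; left-closure resolves it consistently with the inclusive
  "≥ 7 discard" rule (a value *on* a threshold earns the more severe
  grade). Continuous inputs are compared to cut-points with a 1e-9
  tolerance; GS percentages are compared as exact rationals of the two
  counts, so 1/5 lands exactly on a 20 % cut-point with no floating-point
  artifact.
* **GS/IF/TA default bands.** The arterial bands (50/80/120 %) and the 5 %
  IFTA censor are the published values. The GS/IF/TA band edges vary
  between local protocols; the shipped defaults are
  the classical profile of the original Remuzzi description (0 = none,
  1 = < 20 %, 2 = 20–50 %, 3 = > 50 %), labelled `band_profile:
  remuzzi-1999` in the config and fully overridable. The GS "any vs none"
  floor is implemented in the GS scorer (zero sclerosed glomeruli always
  scores 0), with the first cut-point at 0 so that any non-zero fraction
  scores at least 1.
* **IFTA censor.** Percentages strictly below 5 % score 0 rather than 1
  (small fibrotic foci are disregarded, as in trial practice). When no
  separate tubular-atrophy percentage is recorded the IFTA percentage is
  scored against both the IF and TA bands — the two assessments track each
  other closely enough to be treated as a single measure of injury — and
  the result is flagged `ta_imputed`.

### Arteriosclerosis

The wall-to-lumen ratio is `100·(wall_a + wall_b)/lumen_diameter`: the
mean of the two opposing wall thicknesses relative to the lumen *radius*,
equivalently the total wall tissue crossed along a diameter over the lumen
diameter. On this scale symmetric walls as thick as the lumen radius read
100 %, and the top ≥ 120 % band is attainable in severely narrowed
vessels; the alternative reading (mean wall over the lumen *diameter*)
would make the upper bands nearly unreachable. Up to two scorable arteries
are considered (ranked by ratio, ties broken toward the lexicographically
lower artery id for determinism) and the worst one sets the score.

For an obliquely cut vessel the lumen outline is an ellipse whose minor
axis is the true cylinder diameter; when both axes are recorded, the minor
axis replaces the measured lumen diameter. No formula for this correction
is published with the scoring system — the minor-axis substitution is this
package's documented choice and can be disabled
(`use_minor_axis_correction: false`).

### Adequacy and decisions

Glomerular (≥ 25 glomeruli) and arterial (≥ 1 scorable artery: ≥ 2
smooth-muscle layers or diameter > 130 µm, strict) adequacy are reported
separately, because they fail for different physical reasons. Inadequate
slides are still scored — the flags travel with the result and downstream
stages can filter on them — matching how such studies report scores
alongside adequacy rather than refusing to score.

Integer totals map to decisions as ≤ 4 single, 5–6 dual, ≥ 7 discard; a
total of 0 maps to single (at least as favourable as 1). Continuous pooled
means use ≤ 4 single, (4, 7) dual, ≥ 7 discard: the open interval (6, 7)
belongs to dual so that discard remains an inclusive ≥ 7 rule on both
axes, and the two mappings agree on every integer total (a tested
invariant).

Components that cannot be assessed (no glomeruli; no scorable artery) are
*missing*, not zero; a slide with any missing component reports no total
and no decision, but its remaining components are still returned.

## 2. Bootstrap uncertainty

Each kidney's observed totals are resampled with replacement, B = 1000 by
default and each subsample the size of the original set. Replicate means
pass through the continuous decision bands; the resulting category
proportions define the decision distribution, and the modal proportion is
the decision **confidence** (1 − boundary-crossing proportion). Replicate
SDs use the population (1/n) convention, the plug-in view of the
bootstrap; the SD of replicate means converges to the closed-form plug-in
standard error √(Σ(xᵢ−x̄)²/n)/√n (tested at B = 10⁵ within 2 %).

**Pair matching.** Within-donor-pair decision agreement has no single
standard construction, so both estimators are isolated behind single
operations with explicit definitions:

* *single-draw*: per replicate, one score drawn uniformly with replacement
  from each kidney; decisions compared on integer totals;
* *pooled*: per replicate, each kidney fully resampled; decisions of the
  two subsample means compared on the continuous bands. Continuous
  decision of the mean (rather than rounding and using the integer rule)
  is used because the pooled estimate lives on the continuous score axis.

Because the kidneys are resampled independently, both match rates equal
Σ_c p_left(c)·p_right(c); an **exact-enumeration mode** evaluates this (and
per-kidney decision distributions) over all nⁿ resamples whenever
nⁿ ≤ 10⁶, replacing Monte Carlo. The test suite uses independent
`itertools.product` enumeration as the oracle against this mode.

**Randomness.** One root seed spawns an independent substream per kidney
(and per pair), keyed by a CRC-32 of the donor id and side through numpy's
`SeedSequence` spawn keys. Adding or removing a kidney therefore never
perturbs another kidney's replicates, and identical seed + config gives
bit-identical results.

## 3. Agreement statistics

Pearson's r delegates to `scipy.stats.pearsonr`; weighted Cohen's κ to
`sklearn.metrics.cohen_kappa_score` (both verified against brute-force
formula evaluation in the tests). Lin's concordance correlation
coefficient is implemented directly with population (1/n) moments per
Lin's original definition; the bias-corrected small-sample variant is out
of scope. Two identical constant vectors are perfectly concordant (ρc = 1)
by convention; any other zero-variance input raises a degenerate-statistic
error rather than returning a misleading number.

The κ weight scheme is linear (|i−j|) by default — reports of weighted
kappa frequently omit the scheme — with quadratic available; every
report records the scheme, since published agreement tables cannot be
exactly recomputed without knowing it. Interpretation bands
(slight/fair/moderate/substantial/perfect at 0.2/0.4/0.6/0.8) are
left-closed like every other band in the package; negative values are
labelled slight with a below-chance flag.

`banding_consistency` summarises continuous injury measurements by
assigned ordinal category: per-category n/median/quartiles, a monotonicity
flag on medians, and for each adjacent pair of non-empty categories the
fraction of each category's values inside the other's min–max range
(reported in both directions plus their mean). The min–max overlap
definition is deliberately simple and sample-size sensitive; it is meant
as a descriptive screen, not an inferential statistic.

## 4. Synthetic cohort generator

The generator emulates the *structure* of a repeat-biopsy study of
discarded allografts — 12 donors, 16 kidneys (4 donor pairs), 3 biopsies
per technique per kidney, 2 stains per biopsy, 288 slide records — with
distributions chosen by this package, not published:

| quantity | family | default calibration |
|---|---|---|
| width, depth, cortex area | truncated normal (floor 0.05) | per-technique published means/SDs |
| glomeruli per slide | Poisson(density · area) | density = published yield / published mean area |
| sclerosed glomeruli | Binomial(n, p_slide) | p_slide = logit-normal around kidney latent |
| IFTA / TA % | logit-normal | donor latent logit mean −1.52 (≈ 18 %), SD 0.8 |
| artery count | negative binomial (k = 1.2), mean ∝ area | per-technique published vessel yields |
| artery wall/lumen ratio | lognormal | donor latent log-mean log 55 %, SD 0.45 |
| GS propensity | Beta(mean 0.10, concentration 12) | donor level |

Key numerical choices:

* **Truncated-normal calibration.** Using the published mean directly as
  the location parameter would inflate the *truncated* mean (by ≈ 3 mm²
  for the wide wedge-area distribution). The location and scale are
  instead moment-matched by root-finding so the truncated mean and SD
  equal the published targets; this is what makes 10⁴-draw sample means
  land within Monte-Carlo error of the targets. A target SD approaching
  (mean − floor) is infeasible for a lower-truncated normal (the
  exponential-tail limit bounds the coefficient of variation at 1) and is
  rejected as a configuration error.
* **Marginal area.** Cortex area is drawn from its own truncated normal,
  not as width × depth: no width–depth covariance is published, and
  preserving the area marginal is what matters downstream (only area
  enters yields). The resulting width·depth ≠ area inconsistency is
  accepted and documented.
* **Latent hierarchy.** Donor-level latents (GS propensity, IFTA fraction,
  arterial ratio) are perturbed per kidney by `within_pair_sd` (0.15 on
  logit/log scales) and per slide by `within_kidney_sd` (0.35). The
  between/within split is unpublished — cross-sectional SDs over slides do
  not identify it — so these are this package's single documented guess,
  chosen so that repeat slides of one kidney scatter visibly across
  decision bands while paired kidneys remain similar. Technique does not
  bias injury at the defaults; a `subcapsular_bias` knob (off by default)
  can add wedge-specific GS overestimation for sensitivity studies.
* **Artery geometry.** Wall asymmetry is drawn mean-preserving
  (a = w(1+δ), b = w(1−δ)), so the measured ratio equals the latent target
  exactly in the zero-noise limit — which is what makes the ground-truth
  recovery harness exact there. Obliquely cut vessels (30 %) record the
  stretched major axis as the apparent lumen with both axes present, so
  the scorer's minor-axis correction is exercised by generated data.
  Smooth-muscle layer counts are Poisson(1.6), giving a realistic mix of
  scorable and unscorable vessels.
* Stain (HE/PAS) is provenance metadata only; sections of one biopsy share
  its geometry but draw slide-level measurements independently.

**What the generator does not emulate:** spatial cortex structure,
image-level artifacts (folds, incomplete sections), needle-gauge effects
beyond the core geometry profile, assessor effects, or the historical
clinical cohort. Tests passing on generated data therefore demonstrate the
*pipeline's* correctness and the internal consistency of the statistical
machinery — not that real biopsies follow these distributions.

`simulate_paired_score_sets` is a lighter harness used for the pooling
analysis: donor mean scores drawn uniformly from the parts of the 0–12
axis at least 0.75 from the 4 and 7 decision boundaries, kidney means
jittered by 0.25, and nine integer scores per kidney (rounded clipped
normal, SD 1.0). On such boundary-distant pairs pooled matching dominates
single-draw matching; a pair constructed with its shared mean *on* the
discard boundary shows the opposite — persistent within-pair disagreement
under pooling — reproducing the qualitative exception seen in real paired
kidneys whose score distribution hugs a threshold.

## 5. Pipeline and I/O

Tables are UTF-8 CSV with mandatory headers; empty cells are missing.
Decisions serialise as lowercase strings, scores as integers, percentages
with up to 6 significant digits. `validate_tables` reports row-level
violations (range breaches, sclerosed > total, duplicate slide ids, orphan
artery rows) with 1-based data line numbers; the CLI exits 2 on schema
errors, 3 on configuration errors, 4 on statistical degeneracy. Every
pipeline run writes a manifest with the resolved configurations, seeds and
SHA-256 digests of inputs and outputs; rerunning with the same
configuration reproduces all data outputs byte-identically (the manifest
itself carries a timestamp).

## 6. Problem sizes used in the checks

The shipped checks run at desk scale, chosen to keep Monte-Carlo error
well inside the asserted tolerances: exhaustive threshold scans at 0.05 –
0.25 step; 100 random small inputs per statistic oracle; exact
nⁿ-enumeration for n ≤ 5; B = 10⁵ for the convergence check on one
4-score kidney; 10⁴ slides per technique for geometry/yield calibration;
200 simulated pairs at B = 1000 for the pooling property.

## 7. Known limitations

* The GS/IF/TA default bands follow the original scoring description and
  vary between transplant centres; users replicating a local protocol
  must set their own bands.
* The single-draw pair-match estimator is one plausible reading of an
  under-specified published quantity; results should be reported together
  with the definition.
* Lin's CCC and κ are returned without confidence intervals.
* The generator's variance decomposition (donor vs kidney vs slide) is a
  modelling assumption; real-data analyses should re-estimate it rather
  than rely on the defaults.
* `banding_consistency`'s min–max overlap grows toward 1 with sample size
  for any overlapping distributions; compare categories of similar n.
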