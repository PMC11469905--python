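# nephromet

Metrological analysis of renal preimplantation biopsy scoring.

Before a deceased-donor kidney is accepted for transplantation it is often
biopsied, and the chronic injury seen on the slide is condensed into a
composite Remuzzi score that drives the implantation decision: implant each
kidney singly, implant both into one recipient ("dual"), or discard.
Repeat biopsies of the same kidney, however, can return scores spanning
more than one decision category — the score from a single slide behaves
like a draw from a distribution, not a definitive measurement. `nephromet`
treats the problem metrologically: it implements the scoring rules with
explicit, configurable thresholds, quantifies per-kidney score uncertainty
and decision confidence by bootstrap resampling, computes the agreement
statistics used to compare biopsy techniques and assessment methods, and
ships a synthetic biopsy-cohort generator so the whole pipeline is testable
end to end without patient data.

It is written for transplant researchers, renal pathologists and
biostatisticians studying sampling variability in histopathological organ
assessment.

## The model

**Remuzzi score.** Each slide contributes four ordinal components, each
scored 0–3:

| component | measurement | default bands (left-closed) |
|---|---|---|
| glomerulosclerosis (GS) | % globally sclerosed glomeruli | 0 = none, then <20, 20–50, ≥50 |
| interstitial fibrosis (IF) | % cortical involvement | <5 censored to 0, <20, 20–50, ≥50 |
| tubular atrophy (TA) | % cortical involvement | as IF |
| arteriosclerosis | wall-to-lumen ratio of the worst scorable artery | <50, 50–80, 80–120, ≥120 % |

The wall-to-lumen ratio is `100·(wall_a + wall_b)/lumen_diameter` (mean of
opposing walls relative to the lumen radius), with an optional minor-axis
correction for obliquely cut vessels. An artery is scorable with ≥2
smooth-muscle layers or overall diameter >130 µm; a slide is *adequate*
with ≥25 glomeruli and ≥1 scorable artery. The total T = GS+IF+TA+ART maps
to a decision: T ≤ 4 single, 5–6 dual, T ≥ 7 discard (continuous pooled
means use ≤4 / (4,7) / ≥7).

**Uncertainty.** For a kidney with observed totals x₁…xₙ, resampling with
replacement (B = 1000 by default) gives the empirical distribution of the
subsample mean x̄*. Mapping each replicate mean through the decision bands
yields decision-category proportions; the modal proportion is the
**confidence** of the recommendation (1 − boundary-crossing proportion).
Within-donor pair agreement is estimated two ways: drawing one slide per
kidney per replicate (single-slide workflow, decisions compared on integer
totals) or comparing decisions of full-resample means (pooled workflow).

**Agreement.** Pearson's r, Lin's concordance correlation coefficient
ρc = 2·s_xy /(s_x² + s_y² + (x̄−ȳ)²), and weighted Cohen's κ (linear |i−j|
weights by default), interpreted on the conventional 0.2/0.4/0.6/0.8 bands.

## Worked example

```python
from nephromet import (ArteryMeasurement, SlideMeasurement, score_slide,
                       KidneyScoreSet, BootstrapConfig, bootstrap_kidney)

slide = SlideMeasurement(
    slide_id="K1-core-1-HE", biopsy_id="K1-core-1", donor_id="D01",
    kidney_side="left", technique="core", stain="HE",
    width=0.9, depth=14.0, cortex_area=10.2,
    n_glomeruli=28, n_sclerosed=6, ifta_pct=22.5,
    arteries=(
        ArteryMeasurement("a1", lumen_diameter=60.0, wall_thickness_a=24.0,
                          wall_thickness_b=30.0, smooth_muscle_layers=3),
        ArteryMeasurement("a2", lumen_diameter=85.0, wall_thickness_a=12.0,
                          wall_thickness_b=14.0, smooth_muscle_layers=2),
    ),
)
r = score_slide(slide)
print(f"components GS={r.score_gs} IF={r.score_if} TA={r.score_ta} ART={r.score_art}")
print(f"total={r.total}  decision={r.decision}  adequate={r.adequate}  worst={r.worst_artery_id}")
```

```
components GS=2 IF=2 TA=2 ART=2
total=8  decision=discard  adequate=True  worst=a1
```

21 % sclerosed glomeruli and 22.5 % IFTA both land in the 20–50 % band
(score 2); artery `a1` has ratio 100·(24+30)/60 = 90 % (band 80–120, score
2) and is worse than `a2` (31 %). The total of 8 crosses the discard
threshold. With 28 glomeruli and two scorable arteries the slide is
adequate.

Bootstrapping a kidney whose nine slides straddle the single/dual boundary:

```python
k = KidneyScoreSet("D01", "left", (2, 5, 3, 6, 4, 7, 3, 5, 4))
res = bootstrap_kidney(k, BootstrapConfig(n_replicates=1000, seed=17))
print(f"mean of replicate means = {res.replicate_means.mean():.3f}")
print(f"decision proportions    = { {k_: round(v, 3) for k_, v in res.decision_proportions.items()} }")
print(f"confidence = {res.confidence:.3f} (modal: {res.modal_decision})")
```

```
mean of replicate means = 4.361
decision proportions    = {'single': 0.283, 'dual': 0.717, 'discard': 0.0}
confidence = 0.717 (modal: dual)
```

(the dual proportion is 0.717; 28 % of resampled means fall at or below 4,
so a single-slide reading of this kidney would recommend single
implantation more than a quarter of the time).

## Command line

```bash
nephromet simulate --seed 42 --out-dir data/          # synthetic cohort CSVs
nephromet score --slides data/slides.csv --arteries data/arteries.csv --out scores.csv
nephromet bootstrap --scores scores.csv --replicates 1000 --seed 17 \
    --pairs data/pairs.csv --out bootstrap.csv
nephromet agree --scores scores.csv --by technique --stat kappa --weights linear \
    --out agreement.csv
nephromet run --out-dir run1 --seed 42                # full pipeline + report.json
```

The generator's defaults emulate a repeat-biopsy study design: 12 donors, 16
kidneys (4 donor pairs), 3 core + 3 punch + 3 wedge biopsies per kidney,
2 stains per biopsy → 288 slide records, with per-technique geometry
calibrated to the published biopsy profiles (mean cortex areas
9.04 / 13.7 / 37.9 mm²; mean glomerular yields 20.2 / 32.0 / 86.4).

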