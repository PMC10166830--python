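# embody — body-map analysis of embodied emotions and schizotypy

People literally feel emotions in the body: happiness as whole-body
activation, sadness and depression as deactivation of the limbs.  A
computerized body-mapping task captures this by letting each participant
paint, on a pair of body silhouettes, where they feel activity increasing
(activation) and decreasing (deactivation) for each of 12 emotional states;
paint intensity per pixel runs from 0 to 100.  This package implements the
full analysis pipeline for such data, aimed at individual-differences
research linking emotional embodiment to *schizotypy* — three z-scored
personality dimensions (interpersonal, cognitive/perceptual, disorganized)
indexing psychosis liability.

The pipeline computes:

* **group bodily maps** — per-emotion, pixel-wise one-sample *t*-tests of
  the signed (activation − deactivation) maps against zero, with
  Benjamini–Hochberg FDR correction at α = 0.05 across the in-silhouette
  pixels, rendered red/blue on the silhouette;
* **five embodiment metrics** per subject:
  * *diffusion* — mean pairwise Manhattan distance
    |x₁−x₂| + |y₁−y₂| between colored pixels within each of five ROIs
    (head, chest, abdomen, arms, legs); 0 when an ROI is unpainted,
  * *size* — proportion of in-silhouette pixels colored (binary),
  * *intensity* — summed paint intensity per emotion,
  * *clarity* — the count of "mixed pixels" painted in both the activation
    and deactivation map of one emotion (more mixed = less clear),
  * *congruency* — summed activation in high-arousal emotions (happiness,
    love, pride, anger, fear) and deactivation in low-arousal ones
    (sadness, depression), plus the two incongruent reversals;
* **association models** matched to each outcome: Spearman correlations
  with Holm correction and Fisher-z CIs; a linear mixed model for
  diffusion z-scores with crossed random intercepts for subject, emotion
  and ROI; a zero-inflated negative binomial (ZINB) regression for mixed
  pixel counts (logit structural-zero part, log-linked NB2 count part);
  and Fisher-z power/minimum-detectable-correlation calculations,
  power = Φ(|atanh r|·√(n−3) − z₁₋α/₂).

Because raw body-map data are not openly redistributable, the package
includes a first-class synthetic generator (`embody.synth`) that paints
Gaussian-blob maps from per-emotion amplitude templates with three
injectable, trait-linked effects (overall intensity, mixed-pixel
propensity, incongruent-polarity amplitude) — so every downstream stage
has a parameter-recovery test bed with known ground truth.

## Worked example

```python
from embody import SynthConfig, generate_collection, make_body_mask
from embody import harmonize_schizotypy, metric_table
from embody.core import subject_z_frame
from embody.metrics import congruency_scores, diffusion_table
from embody.pipeline import association_suite

coll = generate_collection(SynthConfig(n_subjects=419, seed=7),
                           mask=make_body_mask(0.15))
coll.subjects = harmonize_schizotypy(coll.subjects)
zf = subject_z_frame(coll.subjects)
assoc = association_suite(metric_table(coll), diffusion_table(coll),
                          congruency_scores(coll), zf)
row = assoc[(assoc.outcome == "intensity")
            & (assoc.predictor == "z_interpersonal")].iloc[0]
print(f"rho = {row.estimate:.3f}, p = {row.p_raw:.2e}")
```

prints

```
rho = 0.387, p = 2.04e-16
```

— the interpersonal dimension correlates positively with painting
intensity, which is exactly the effect this cohort was generated with.
(The intensity channel alone is calibrated to a population Spearman of
≈ 0.2; the default configuration also injects the mixed-pixel and
incongruency effects, whose extra trait-linked paint pushes the observed
correlation higher.)  The same run
recovers all eight injected association directions, including the
negative interpersonal coefficient in the zero part of the low-arousal
ZINB clarity model (β = −1.36: higher interpersonal schizotypy, fewer
structural zeros, i.e. more mixed pixels).

The numbered drivers under `analysis/` run the whole study narrative:

```bash
cd analysis
python 01_simulate.py      # cohort, harmonization, screening, raster I/O
python 02_group_maps.py    # t-maps + FDR + renders -> results/tmaps/
python 03_metrics.py       # metric tables -> results/
python 04_associations.py  # model battery + sign checks
python 05_power.py         # power analysis table
python 06_validation.py    # FDR null control, power/type-I, ZINB recovery
```

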