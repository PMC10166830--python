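# Methods

## Data model

A *body map* is a raster of paint intensities in [0, 100] over a fixed
body silhouette, one raster per subject × emotion × polarity (activation /
deactivation).  Twelve emotional states are modeled: five basic emotions
(anger, fear, disgust, happiness, sadness), six non-basic (anxiety, love,
depression, pride, shame, jealousy) and a neutral state.  The silhouette
carries five ROI labels — head, chest, abdomen, arms, legs — and records
its own in-silhouette pixel count, which is the denominator of the size
metric.  The original task canvas has 50,364 body pixels and a 12-pixel
brush; since that canvas is not redistributable, `make_body_mask(scale)`
draws a geometrically simple front-facing silhouette (~46,000 body pixels
at scale 1.0) and all metrics use the mask's own count, so the canonical
canvas can be substituted as a plain label grid without code changes.
Left/right limbs share one arms and one legs ROI (the design names exactly
five ROIs).  Each polarity raster shares the single silhouette mask.

Schizotypy is consumed as three factor scores per subject from either of
two questionnaire forms (SPQ, 74-item, or the SPQ-B short form).
`harmonize_schizotypy` z-scores each factor within its instrument
sub-sample (sample SD, n−1), putting both sub-samples on a common scale
with higher = more schizotypal.  Harmonization is idempotent and never
mutates its input.

## Preprocessing

*Screening.*  The original workflow screened responses manually for
writing/drawing and absent painting.  A repository cannot encode human
judgment, so screening is a deterministic heuristic whose rule is logged:
a map is `empty` when it has no colored pixel, and `suspicious_structure`
when any painted connected component of ≥ 20 pixels has a major/minor
axis ratio ≥ 8 (thin elongated strokes are how letters and line drawings
differ from blob-like painting).  With `action="exclude"`, a
subject × emotion pair is dropped when either map is suspicious or when
*both* are empty — a single empty polarity canvas is a legitimate "no felt
change" response and is kept.  The full screening report is always
emitted; nothing is dropped silently.

*Smoothing.*  Gaussian smoothing removes the click-scale spatial
dependencies of mouse painting.  The convolution is mask-normalized —
`G(f·m)/G(m)` with `m` the silhouette indicator — so paint neither bleeds
into the background nor loses mass at the silhouette boundary; constants
are preserved exactly and interior point masses are conserved to float
precision.  The default σ = 6 px is half the 12-px brush diameter (the
scale the smoothing targets); the result is re-clipped to [0, 100].
Smoothing feeds the group maps only; metrics are computed on raw rasters,
whose definitions reference raw colored pixels.  Both choices are
configurable.

## Group maps

For each emotion the two polarity maps are combined per subject into a
signed map (activation − deactivation) and each in-silhouette pixel is
tested against zero with a one-sample t-test (two-sided, df = n−1).
Pixels where every subject reports 0 get t = 0, p = 1: background and
never-painted skin must be well-defined non-discoveries rather than
poison the correction family.  The Benjamini–Hochberg step-up procedure
at α = 0.05 is applied per emotion across that map's in-silhouette pixels
only (the correction is per generated map; whether the original family
included background pixels is not documented — we restrict to the
silhouette).  Significant t-values are rendered on a symmetric diverging
scale, red for activation, blue for deactivation.

## Embodiment metrics

* **Diffusion**: mean pairwise Manhattan distance between colored
  (intensity > 0) pixels within an ROI, computed per axis from sorted
  coordinates in O(k log k) (tested against the O(k²) definition to
  1e-9).  Pixels count binarily — the definition speaks of colored
  pixels, not intensities; an intensity-weighted variant would be a
  different metric and is not provided.  ROIs with < 2 colored pixels
  score 0.  Raw scores are z-scored over the pooled
  subject × emotion × ROI table (the z-scoring reference population is
  otherwise unspecified; pooling preserves between-ROI differences, which
  the mixed model's ROI intercept then absorbs), with an `is_zero`
  indicator supporting a zeros-excluded sensitivity refit.
* **Size**: colored pixels in either polarity map ÷ mask body-pixel
  count; intensity-blind by definition.
* **Intensity**: summed intensity over both polarity maps per emotion
  (activation-only summation is exposed as a per-polarity diffusion
  option would be; the per-subject overall score averages across
  emotions).  Whether the original sums one or both canvases is not
  stated; both-maps is the default as "colored pixels per participant,
  per emotion" reads map-agnostic.
* **Clarity**: count of pixels colored in both polarity maps of one
  emotion ("mixed pixels"; more mixed = lower clarity).
* **Congruency**: per subject, summed activation intensity over the
  high-arousal emotions {happiness, love, pride, anger, fear} and summed
  deactivation over the low-arousal ones {sadness, depression}
  (congruent), plus the two reversed pairings (incongruent).  The
  arousal grouping follows the published hierarchical clustering of map
  similarity.  Note a documented source inconsistency: the metric
  description lists the middle-cluster discards as shame/disgust/jealousy
  while the cluster figure and results also exclude anxiety; we follow
  the five-emotion high-arousal list, so anxiety is excluded from
  congruency scoring.  Aggregation is by sum (per-emotion means are an
  option); the four columns plus excluded-emotion paint partition each
  subject's total paint by polarity, which the tests assert exactly.

## Association models

* **Spearman + Holm** for intensity, size (overall and per arousal
  group) and the four congruency outcomes: mid-rank ties, two-sided p,
  95% CI via Fisher z with the Spearman-specific variance 1.06/(n−3).
  The Holm family is one block per analysis — the 3 predictors of a
  single outcome for intensity/size, the full 3 × 4 grid for congruency
  (the family definition is otherwise unspecified, so `family_size` is
  recorded on every result and both family choices are exposed).
* **Diffusion LMM**: diffusion z on the three schizotypy dimensions
  jointly, with crossed random intercepts for subject, emotion and ROI.
  The solver is a profiled REML implementation written for this package:
  variance ratios γ_k = σ_k²/σ² are optimized (Nelder–Mead, log scale)
  while β and σ² are profiled out via the Woodbury identity, costing one
  q × q Cholesky per evaluation (q = total random-effect levels).  A
  general-purpose mixed-model routine that treats crossed factors as
  dense variance components over one group needs minutes at
  419 × 12 × 5 observations; this solver needs seconds, and is verified
  in the tests against both statsmodels MixedLM and lme4 on small
  crossed designs (agreement to 4 decimals in β, SE and variance
  components).  Fixed-effect tests use the normal approximation and every
  result carries a `df=normal` flag in place of a Satterthwaite
  small-sample correction — immaterial at hundreds of subjects.  Boundary
  fits (a variance ratio at ~0) are flagged `singular`, non-convergence
  `nonconvergence`; with all ratios pinned at zero the fit reduces
  exactly to OLS (tested).  The zeros-excluded refit re-standardizes and
  refits on nonzero-diffusion rows.
* **Clarity ZINB**: zero-inflated negative binomial (NB2,
  variance = μ + μ²/θ; log link on μ, logit link on the structural-zero
  probability), all three predictors in both parts, fitted by maximum
  likelihood (statsmodels) with a warm start — count part from a plain NB
  fit, inflation intercept from the empirical zero fraction — and a
  Nelder–Mead fallback, because the default start values diverge readily
  at small n.  Exponentiated coefficients are reported (rate ratios for
  the count part; multiplicative change in the odds of a structural zero
  for the zero part).  The model is fitted for all emotions, high-arousal
  only and low-arousal only.  Convergence failures are flagged on the
  results, never raised.
* **Power**: two-sided Fisher-z power
  Φ(|atanh r|√(n−3) − z₁₋α/₂) plus the opposite-tail term
  Φ(−|atanh r|√(n−3) − z₁₋α/₂) (negligible except near r = 0, where it
  makes power(0) = α exactly); `detectable_r` inverts by Brent
  root-finding.  At n = 419, α = 0.05 this yields minimum detectable
  correlations of 0.137 (80% power) and 0.158 (90%).

## Synthetic generator

The generator emulates the study conditions: 419 subjects (a 153/266
split across the two questionnaire forms), three latent traits from a
zero-mean multivariate normal with pairwise correlation 0.4 (a typical
inter-factor correlation for the instrument), surfaced as
instrument-scaled raw scores so harmonization has real work to do.

Painting is generated per subject × emotion × polarity from per-emotion
amplitude templates (qualitative matches to the canonical topography:
whole-body activation for happiness, head/chest/arm activation for anger,
limb-emphasized deactivation for sadness and depression, mixed
disjoint-ROI patterns for the middle-cluster emotions, near-zero paint
for neutral; no quantitative template amplitudes are published, so the
defaults are design choices on the 0–100 scale).  Each ROI holds a single
dominant polarity at baseline, so opposite-polarity paint — and hence
mixed pixels — arises only through the injected effects below, keeping
the mixed-pixel distribution zero-inflated as in real data.  Blobs are
isotropic Gaussians (σ = template radius rescaled to the mask height),
Poisson-many per painted ROI, centers jittered uniformly within the ROI
and confined to it; additive N(0, 2) noise perturbs painted pixels only
(noise over the whole silhouette would color every pixel and destroy the
~25% empty-ROI structure), and maps are clipped to [0, 100].  A whole
ROI is left unpainted with probability 0.25 per subject × emotion, drawn
once and shared by both polarity maps so the empty-ROI rate seen by the
diffusion metric matches the reported 25% directly.

Three effects tie painting to the latent traits:

* `gamma_intensity` — all amplitudes scale by exp(γ·z_interpersonal).
  The default 0.031 was calibrated once by Monte Carlo
  (`calibrate_gamma_intensity`, other channels off) to give a population
  trait–intensity Spearman of ≈ 0.2, the benchmark effect size the power
  analysis targets.
* `gamma_mixed` — each subject has a mixed-painting disposition, drawn
  once: in low-arousal emotions its log-odds are
  logit(0.39) + γ·z_interpersonal (baseline presence probability 0.39,
  i.e. baseline odds ≈ 1.57 of *no* mixed pixels; default γ = 0.28, the
  reported coefficient magnitude); in high-arousal emotions mixing
  occurs at the trait-independent base rate, so high-arousal clarity
  models have genuine, trait-free zero variation.  A firing disposition
  paints one identical blob into both polarity maps of the dominant
  non-empty ROI.
* `gamma_incongruent` — incongruent-polarity amplitudes (activation in
  low-arousal, deactivation in high-arousal emotions) are shifted
  additively by γ·(z_interpersonal + z_cognitive_perceptual), clipped at
  zero; default γ = 2 intensity units per z.

With all gammas zero the generator is an exact null for type-I-error
studies.  A `deterministic` mode (fixed blob counts, ROI-midpoint
centers, thresholded dispositions) supports degenerate-case tests where
all subjects must paint identical maps.

What the generator does *not* emulate: mouse trajectories and click-level
dynamics, left/right asymmetries, anatomically realistic silhouettes,
questionnaire item-level structure, and any demographic moderation.
Passing recovery tests therefore show that the statistical machinery
detects effects of the modeled kinds at the modeled sizes — not that the
published human-data coefficients are reproduced, which without the raw
data they cannot be.

## Problem sizes and numerical choices

Repeated-seed simulation studies (power/type-I over 100 cohorts of 419
subjects; the full-pipeline sign check) use a coarse silhouette
(scale 0.12–0.15, a few hundred to ~1,000 body pixels): every statistic
they exercise — rank correlations, rejection rates, regression
coefficients — is invariant to mask resolution, and the coarse canvas
keeps hundreds of simulated cohorts cheap.  The FDR null study uses 200
replicates of 2,000 independent standard-normal pixels × 30 subjects;
ZINB recovery uses 50 fits at n = 2,000.  Random streams derive from a
single root seed via spawned generators, one per subject, so generation
is order-independent and byte-reproducible (asserted by the pipeline
determinism test).

Tie-breaks and degenerate inputs: zero-variance/zero-mean pixels score
t = 0, p = 1 (zero-variance nonzero-mean pixels get infinite t, p = 0);
ROIs with < 2 colored pixels score diffusion 0; z-scoring refuses
zero-variance populations; ZINB refuses all-zero and zero-free outcomes;
the equicorrelation request is validated for positive definiteness
(ρ ∈ (−1/2, 1) in three dimensions).  Optimization tolerances: REML
Nelder–Mead xatol 1e-6 / fatol 1e-8; `detectable_r` Brent xtol 1e-8;
ZINB BFGS maxiter 500 with the warm start described above.

## Known limitations

* Satterthwaite degrees of freedom are not implemented; LMM inference is
  asymptotic (flagged on every result).
* The screening heuristic approximates, but cannot replicate, human
  screening judgment; its thresholds (area ≥ 20, elongation ≥ 8) are
  design constants, configurable per call.
* The high-arousal ZINB inherits a trait correlation through the
  incongruency channel (incongruent deactivation overlapping activation),
  so its zero part is not a pure null even when `gamma_mixed` affects
  only low-arousal emotions.
* Published human-data coefficients (e.g. the r = 0.16
  intensity–interpersonal correlation, the baseline odds 1.57) depend on
  the unavailable raw data; the package reproduces the analytic
  quantities exactly and the effect *directions* and recovery behavior
  under simulation.
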