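# Methods

## Data model and aggregation

Spot-level RPPA data are long tables: one row per printed spot with antibody,
sample, treatment arm (AP-treated or untreated lysate), dilution fraction,
replicate, RFI, local background and an `ok`/`poor` image-analysis flag.
Datasets are validated on construction: finite non-negative intensities,
dilution fractions in (0, 1], every spot's antibody annotated, and the paired
design (every AP group has an untreated partner).

A dilution series is reduced to one representative signal (RNFI) by
background-subtracting each ok spot, clamping at zero, rescaling to the 100%
dilution equivalent (dividing by the dilution fraction), and averaging. This
assumes the series sits in the linear response range — the same assumption the
dilution-linearity factor tests — and deliberately avoids nonparametric
dose-response fitting (SuperCurve-style quantification), which this workflow
does not use. Poor spots are excluded, never imputed; groups whose spots are
all poor surface as explicit missing values. The published definition of RNFI
leaves the normalization convention open; an optional per-sample loading
divisor (e.g. SyproRuby total protein) is exposed but off by default, since
per-sample scaling cancels in the paired logFC anyway.

## Quality factors

- **Spot-quality fraction** (factor 1): share of the antibody's summed RFI on
  ok spots, both treatment arms pooled. Pooling both arms was an open choice;
  the factor is a property of the antibody/array combination, not of the
  treatment, so all its spots count.
- **Signal-to-noise** (factor 2): mean over ok spots of raw RFI / local
  background. Using raw rather than background-corrected signal adds a
  constant +1 offset; since classing is rank-based, the tertiles are
  unaffected, and the factor stays independent of the aggregation rule. A
  configurable background floor guards division by zero.
- **Dilution linearity** (factor 3): per untreated sample, Pearson *r* between
  background-subtracted ok-spot RFI and the printed dilution fraction, pooling
  replicate spots (the 4-concentration × 2-replicate series gives 8 points);
  the factor is the mean over samples. Only untreated arms are used — the AP
  arm's signal is deliberately suppressed — and the signed *r* (not *r*²)
  penalizes inverted series. Samples need ≥ 3 distinct dilution points;
  zero-variance samples are excluded with a logged warning.
- **AP log fold change** (factor 4): per sample, log₂ of the ratio of
  aggregated AP to untreated signal, averaged over samples where both arms
  are positive. Base 2 throughout. Samples with a zero arm are excluded and
  logged rather than floored (an optional pseudo-intensity is available but
  off by default: flooring biases strong reducers towards zero). Computing
  the ratio on per-sample aggregated signal (rather than per spot) is the
  implemented reading; with balanced series the two differ only at second
  order in the noise.

## Scoring

Factors 1–4 are each partitioned into panel tertiles — equal-frequency
thirds cut at the empirical 1/3 and 2/3 quantiles — scored 3 (best) to 1
(worst). Fixed absolute bins were the alternative; panel quantiles need no
calibration data and keep the score comparable across batches of differing
dynamic range, at the cost of making each antibody's class depend on its
panel. Directions: factors 1–3 higher-is-better; factor 4 lower-is-better
(a larger AP-induced reduction indicates phospho-specific binding). Ties at
a class boundary resolve by stable input order toward the lower class —
conservative and reproducible. The composite score is
`(c1+c2+c3+c4)·b5·b6` with the two Boolean visual-QC gates, so its image is
{0, 4…12} and one failed gate annihilates the score. Good means
`score ≥ cutoff` with the inclusive default 8 (the inclusive reading keeps
score-8 antibodies Good, matching the published 67/46 Good/Bad split of a
113-antibody panel).

## Predictor evaluation

The ROC treats lower logFC as indicating Good; the curve sweeps all distinct
thresholds (no intermediate dropping) and AUC is the trapezoid rule, which
equals tie-corrected pairwise concordance. The operating point is Youden's
J = tpr − fpr, ties resolved to the most negative threshold (the strictest
filter); the rule is emitted alongside the value so a reproduced cutoff is a
check, not an assumption. The selection filter `logFC ≤ cutoff` is inclusive.
The 2×2 association (filter × label) uses Pearson chi-square with 1 df,
Yates continuity correction off by default (panel sizes ~100) and available
by flag. The AUC sweep re-derives labels at each candidate score cutoff
(default 5–8) and marks single-class cutoffs as undefined rather than failing.

## Expression-analysis conventions

Median centering subtracts each antibody row's median across samples
(idempotent; missing entries untouched). Hierarchical clustering defaults to
1 − Pearson distance with average linkage — the source workflow states only
"unsupervised hierarchical clustering", so both are config-exposed and
recorded in output metadata; zero-variance rows are rejected by name.
PCA treats samples as observations on row-centered data without unit-variance
scaling (consistent with prior median centering); component signs follow a
largest-loading-positive convention so repeated runs are byte-identical.
Group comparisons wrap the standard paired/unpaired t, one-way ANOVA and
Mann–Whitney tests, two-sided; paired tests with zero-variance differences
are rejected explicitly. Western-blot intensities are binned zero/low/high:
exact zeros form their own category (a literal zero category exists in the
comparison this mirrors) and nonzero values split at their median, making
the rule scale-invariant. No multiple-testing adjustment is applied by
default; a Benjamini–Hochberg-style correction is deliberately not wired in
because the conventions mirrored here report unadjusted thresholds.

## Generative model

A spot's RFI is `L_s · A · d · m · ε + B · η₁` and its recorded local
background `B · η₂`, with per-sample loading `L_s` (lognormal, CV 0.2),
antibody amplitude `A`, dilution `d`, `m = 1` untreated and `m = 1 − φρ`
under AP (φ the phospho signal fraction, ρ the AP removal efficiency —
AP acts as a deterministic bulk reaction because lysates are treated before
printing), mean-1 lognormal spot noise ε (CV = `noise_cv`), and a mean-1
lognormal background process (level B = 20, CV 0.1 — local backgrounds are
estimated from many pixels and vary little; the recorded background is an
independent draw, so background subtraction carries realistic, small error).
Intensities are positive and right-skewed, hence multiplicative lognormal
noise. Poor flags are Bernoulli per spot; the b₅/b₆ gates are Bernoulli once
per antibody, independent of continuous quality, so gate annihilation is
exercised. Defaults mirror the study design: 8 samples, dilution series
1.00/0.75/0.50/0.25, duplicate spots.

The closed form `E[logFC] = log₂(1 − φρ)` (0 for total-protein antibodies)
is the recovery oracle; with 8 spots per arm and noise CV 0.1 the per-antibody
estimate has standard error ≈ 0.03 logFC units, so the ±0.1 recovery band is
a ~3–4 σ check.

### Benchmark presets

- **overlap** (default; 106 phospho + 7 total antibodies): a latent antibody
  quality q ~ U(0,1) drives the AP effect (φρ = clip(0.15 + 0.8q + N(0,0.15),
  0.01, 0.97) with ρ ~ U(0.85, 0.99)), the amplitude (300–2000 a.u.,
  noisily increasing in q) and the poor-spot rate (0.02–0.22, decreasing in
  q); gates fail independently with probability 0.08 each. The generating
  label is Good iff q ≥ 0.5 and both gates hold, so label and logFC are
  strongly but imperfectly related — the regime in which a single-factor
  predictor is worth evaluating. The design AUC of true logFC against true
  labels is computable by Monte Carlo from this latent model and the test
  suite checks the pipeline against it, oracle and pipeline sharing no code.
- **clean**: fully separated Good (φρ ∈ [0.7, 0.9]) and Bad (φρ ∈ [0.05,
  0.35]) effects, all gates intact — AUC 1 against the generating labels by
  construction.
- **separation**: every phospho antibody has φρ ∈ [0.6, 0.95] — the strong-
  effect regime in which the AP and untreated arms of the expression matrix
  cluster apart at the top level.

## What the simulations do and do not show

The generator reproduces the features the pipeline's statistics depend on —
paired design, dilution structure, multiplicative noise, background, poor
spots, gate defects, and a mixed-quality panel with overlapping logFC
distributions. It does not simulate spatial array artifacts, scanner
saturation, antibody cross-reactivity to other proteins, or tissue-specific
preanalytical degradation; passing tests therefore demonstrate correctness
and calibration of the computations, not the field performance of any real
antibody panel. Published tissue-cohort results (inter-method R², subtype
marker patterns) depend on undeposited clinical data and are out of scope;
the profiling stage is exercised on synthetic matrices only.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at its native size
(113 antibodies × 8 samples × 2 arms × 4 dilutions × 2 replicates ≈ 14.5k
spots, ~20 ms to generate): recovery uses 50 replicate draws in the suite and
10 in the acceptance script; clustering separation uses 100 seeded runs of a
47-antibody strong-effect panel in the suite and 50 in the script. All
randomness flows from one integer seed per run. Ratio metrics exclude (and
log) zero arms; background subtraction clamps at zero; expression matrices
use canonically sorted axes so results are invariant to input row order;
CSV outputs embed a config hash + seed comment line for byte-level
reproducibility checks.
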