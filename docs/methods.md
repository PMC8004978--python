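# Methods

This note documents the models implemented in `chronofood`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Text normalization and vocabulary consolidation

Annotations are processed in a fixed order: split on commas → strip digits,
stop-terms (units, semi-quantitative words; packaged list covers English,
French, German) and extra whitespace, with case folding and accent
stripping (configurable off) → count unique entries → merge typo variants →
exclude items seen fewer than `min_count = 2` times from annotation.
Exclusion never removes an event: timestamps always count for the eating
window.

The merge rule operates on Levenshtein distance exactly 1. Because the
source rule ("prefer the entry with more counts") does not determine what
happens to chains (a→b→c), consolidation runs as a **single pass in
descending count order** (ties broken lexicographically): each entry either
joins an already-frozen canonical entry at distance 1 — the highest-count
such canonical, which absorbs its count — or becomes canonical itself, and
canonical entries are never remapped. This prevents chain collapse and makes
the output deterministic and order-independent. Count mass is conserved by
construction. Edit distances are computed with edlib; the test suite checks
them against an independent dynamic-programming oracle on 10,000 random
pairs plus the metric axioms.

## Extended-NOVA annotation

Entries are labelled by exact lookup in a TSV lexicon (entry → NOVA1–4,
drink flags ⊆ {A, C, S, D}, or a special marker water / medication /
uninformative). Lexicon misses are uninformative. Reviewer consensus keeps a
category iff ≥ `min_agree` (default 3) reviewers assigned it; ties between
two qualifying NOVA categories stay unresolved. A multi-item text takes the
maximum NOVA category of its informative components and the union of their
flags; consensus is applied per entry before the composite rule, since the
converse order is not determined by the source procedure.

Category **proportions** (used for compliance) exclude water, medication
and uninformative events from the denominator. Category **counts** (used as
regression covariates) are raw per-participant event counts over the
observation phase — both are exposed because they answer different
questions (behaviour change vs exposure).

## Eating window

All event clock times of a phase are pooled (not averaged per day), anchored
at 04:00 — the overnight nadir of ingestion — and the window start/end taken
as the 2.5th/97.5th percentiles with **linear interpolation between order
statistics** (numpy's default). The percentile convention is configurable
because alternatives shift durations by minutes. The midpoint is the median.
Durations are invariant to the anchor whenever all events fall within one
anchor-to-anchor cycle; events are interpreted in the participant's local
timezone (timezone-naive timestamps are rejected unless a default zone is
supplied). TRE eligibility is `duration > 14 h` (strict) and ≥ 1
metabolic-syndrome component.

## Metabolic-syndrome components

IDF-based cut-offs, inclusive exactly as printed: central obesity = BMI ≥ 30
kg/m² or waist ≥ 80 cm (women) / ≥ 94 cm (men); hypertension = SBP ≥ 130
or DBP ≥ 85 mmHg; impaired fasting glucose ≥ 5.6 mmol/L; triglycerides ≥
1.7 mmol/L; low HDL < 1.29 / < 1.03 mmol/L (women/men). The full diagnosis
requires central obesity plus ≥ 2 other components. The hypertension rule is
implemented as a logical OR and deliberately omits treated-hypertension
clauses. Units are SI; a mg/dL converter exists but is never applied
implicitly. Missing measurements yield a missing flag and a count over the
evaluable components, never a guess.

## Bayesian regression

Model, per outcome d: y_id ~ Normal(x_i·β_d, σ_d²) with β_dk ~ Normal(0,
0.1) and σ_d ~ HalfNormal(1); prior scales are **standard deviations** (a
variance reading would change shrinkage ten-fold), and the σ prior is
truncated to positive support because a scale parameter needs it. Outcomes
are log-transformed, IPAQ (MET-min/week) square-root-transformed, then
everything is z-scored; the constants are stored so transforms invert
exactly. Missing covariates are handled complete-case per outcome, with no
imputation. Sex is coded female = 1.

**Exact sampling instead of MCMC.** Conditional on σ the posterior of β is
Gaussian in closed form, and p(y|σ) is analytic, so the joint posterior
factorises as p(σ|y)·p(β|σ,y). σ is integrated over a 300-point log-spaced
quadrature grid spanning three decades below the residual scale up to three
prior standard deviations; draws are exact and independent (σ from the
gridded marginal, β from the conditional Gaussian). This is preferable to
gradient-based MCMC for this model class: no convergence risk, no
autocorrelation, and deterministic posterior means. The test suite verifies
the engine against the closed-form ridge estimator and against an
independent affine-invariant ensemble MCMC run on the identical log density.
Split-R̂ diagnostics are still reported (trivially ≈ 1) for interface
uniformity, and divergences are identically zero.

**Variable selection**: a covariate is selected when ≥ 95% of its posterior
draws share a sign — equivalent to the central 95% credible interval
excluding zero. Under the null this rule admits a covariate with
probability ≈ 5–10% (shrinkage-dependent), so with ~13 inert covariates one
expects roughly one false selection per outcome; this is a property of the
rule itself, not of the sampler.

**LOO-CV R²**: every fold refits the model without the held-out participant
(full refit, no approximation) and predicts with the exact
posterior-predictive mean; R² = 1 − Σe²/Σb² pools held-out errors against
a baseline predictor, the training-fold mean by default (global mean
optional). The reference comparison is age+sex versus all selected
variables.

## Weight trajectories

Per participant: y(t) = a + bt + ct² + ε, t in months, with both baseline
weights entered as separate t = 0 observations (this measurably tightens the
intercept posterior). Priors: b, c ~ Normal(0, 10) (kg/month, kg/month²),
σ_ε ~ HalfNormal(10 kg), and — since the source model leaves it open —
a ~ Normal(first observed weight, 10 kg), weakly informative and
scale-matched. The same exact-sampling engine is used. The 6-month change is
computed per draw as 100·(6b + 36c)/a (% of starting weight; kg-scale
variant available); a participant is a significant responder when the
5th–95th percentile interval excludes zero, matching the whiskers of the
standard box-plot presentation. Fitting happens on the kg scale; the %
scale is derived.

**Calibration behaviour.** With five visits and three mean parameters there
are only two residual degrees of freedom, so σ_ε is weakly identified. When
every parameter is drawn from the model's own priors, 90% change intervals
cover the truth at the nominal rate (measured 90.7% over 400 replicates —
the posterior is exactly calibrated). When the measurement noise is instead
fixed far below the prior scale (0.5 kg vs HalfNormal(10)), the σ_ε
posterior's heavy right tail makes intervals conservative: coverage rises to
≈ 98%. Users analysing low-noise series who need tighter intervals should
supply a sharper σ_ε prior; the default reproduces the reference procedure.

## Trial statistics

Paired two-sided t-tests on change scores (percent-of-initial for weight,
raw differences otherwise); unpaired Student t (pooled variance; Welch
optional) for the TRE − SDA difference with a t-based CI. Zero-variance
inputs are reported as degenerate rather than silently producing
infinities. Compliance: SDA compliant iff ΔNOVA4 < 0 and ΔNOVA1 > 0 (strict
inequalities); TRE compliant iff intervention eating duration ≤ 12 h (the
assigned window; configurable via `--tre-threshold`). A Mann–Whitney
alternative is provided for the weight comparison. Exploratory weight-loss
predictors use Pearson correlations, with sex handled as a two-sample
comparison. No multiple-testing correction anywhere, by design.

## Synthetic-data generator

The generator's defaults encode the study conditions the analysis assumes:
28-day observation phase; ~7 ingestion events per day (Poisson); eating
windows starting ~N(08:00, 1 h) with duration ~N(14, 1.5) h, so the cohort
mean sits just under the 14 h eligibility bar; 2% of event times are
uniform-on-the-clock outliers to exercise percentile trimming; free texts
drawn from a Zipf-weighted lexicon with single-character typos at rate 0.1
and 4% water/medication entries; a 71% female cohort aged ~N(40, 13);
weight series at visits t = 0, 0, 2, 4, 6 months with a ~N(80, 12) kg,
b ~N(−0.1, 0.25) kg/month, c ~N(0, 0.02) kg/month², σ_ε = 0.5 kg. Outcomes
are generated on the standardized scale as y = Xβ_true + ε from the
realized covariates (including the actual per-participant NOVA counts and
eating durations of the generated logs) and mapped to measurement units by
inverting the log/z transform; the default β_true plants the directions a
European adult cohort would show (unprocessed food and activity protective,
age adverse, female sex lowering waist/BP/triglycerides/glucose). One
master seed fans out to per-participant substreams, so cohorts are
reproducible and byte-identical across runs. An optional trial simulation
adds an intervention phase in which ~80% of TRE participants narrow their
window toward ~11.5 h and ~80% of SDA participants shift their item mix
toward NOVA1, plus closeout outcomes consistent with each weight trajectory.

What the generator does **not** emulate: within-day meal-time clustering
(event times are uniform inside the window — real logs cluster at meals);
multilingual annotation workflows; nutrition content beyond processing
category; dropout and missing-visit patterns; seasonal or weekday effects.
Tests passing on synthetic cohorts therefore certify the statistical
machinery and its calibration under the stated generating process, not
robustness to those real-data features.

## Numerical notes and degenerate inputs

- σ quadrature: 300 log-spaced points; trapezoid weights; lower bound
  10⁻³ × residual scale so noiseless series concentrate correctly.
- Percentiles: linear interpolation throughout (windows, posterior
  summaries); posterior percentile summaries are monotone by construction.
- Zero-variance columns are rejected at standardization with the column
  named; non-positive outcomes are rejected before the log with participant
  and variable named.
- Consolidation tie-breaks are lexicographic; event timestamps are
  generated at distinct integer seconds so per-day ordering is strict.
- Windows need ≥ 2 events; trajectory fits need ≥ 3 observations;
  compliance with missing phase data is undetermined (None), not false.

## Known limitations

- The selection rule's per-covariate null admission rate (~5–10%) means a
  16-covariate screen will usually select about one spurious covariate per
  outcome; interpret single-outcome selections accordingly.
- Per-individual trajectory intervals are conservative for low-noise series
  (see calibration above).
- The starter lexicon is illustrative (~55 entries); real studies need a
  curated lexicon, and the consensus machinery assumes one label set per
  reviewer per entry.
- Exact sampling relies on the fixed Gaussian/half-normal prior structure;
  hierarchical extensions would require a real MCMC backend.
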