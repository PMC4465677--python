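# Methods

This note records the models implemented in `occucam`, the assumptions
behind them, and the design choices made where the underlying study
procedures were open to interpretation.

## Detection histories

A *detection history* is a site × weekly-occasion matrix of observation
codes with a parallel matrix of sampling effort (active camera days,
0–7 per week). Weeks run in 7-day blocks from each season's first day,
shared by all sites; a trailing block shorter than 7 days is kept with
its true effort rather than discarded. Only weeks with zero effort are
missing (`-1`); weeks with partial effort (1–6 days) are retained as
observations, with effort available to the detection model as a
covariate ("Number"). This matches how the effort term is used in every
candidate model, and avoids throwing away information from partially
active weeks.

The image-independence rule drops any image within 5 minutes of the
previously *retained* image of the same (site, species) stream.
Individual animals cannot be distinguished from the data, so the stream
is the finest unit the rule can be applied to; anchoring the window to
the last retained image (rather than the last image) makes the filter
deterministic and idempotent. Within a week, an adult-male image gives
multistate code 2 regardless of other images (the states are nested:
males present implies the species present).

## Occupancy models

All probabilities use logit links, and covariates enter through linear
predictors exactly as in logistic regression; the hierarchical
structure corrects the coefficients for imperfect detection.

**Multiseason (implicit dynamics).** Each season's occupancy state is
drawn independently per site — no colonisation/extinction parameters.
The season factor has two levels (winter/summer) shared across years;
year effects are deliberately not modelled. The site-season likelihood
is `ψ Π_w p^y (1−p)^(1−y) + (1−ψ)·1{all y=0}` over surveyed weeks.

**Multistate.** States per site-season: (1) species absent, (2) present
without adult males, (3) adult males present. Parameters: ψ (state 2 or
3), R (state 3 | occupied), weekly detection p1 (state 2) and p2
(state 3), and δ, the probability that a detection at a state-3 site
includes a male. δ is defined per detection-week, which allows males to
go undetected at sites they occupy while hinds are photographed. The
candidate grid is conditional occupancy {constant, Season} × detection
{Season, State+Season, State×Season} × conditional detection
{constant, Season} — 12 models, none carrying an effort term (the
parameter counts of the reference analyses are only consistent with
effort-free multistate detection designs).

**Two-species.** Four latent states (both, A only, B only, neither)
with probabilities from ψ_A, ψ_B and a log-scale co-occurrence factor
η: ψ_AB = ψ_A·ψ_B·e^η, clipped to the feasible simplex with a quadratic
penalty under extreme values. η is fixed at 0 (independence) by
default — the reference candidate sets show only species-factor
occupancy terms and their parameter counts leave no room for an
estimated interaction — but can be freed via
`ModelSpec(co_occurrence=True)`. Detection is conditionally independent
across species and weeks given the state, with a species factor and
shared or species-specific covariate slopes.

**Model structure conventions.** Exactly one habitat covariate per
model, entering occupancy and detection either additively (same slope
in both factor levels) or with a factor interaction (level-specific
slopes). Solar radiation covariates are square-root transformed (zeros
occur at fully shaded sites, so a log with arbitrary offset is
avoided); soil C:N, pH and available P are log transformed; NMDS Axis 1
enters untransformed. Effort enters the detection predictor linearly on
the logit scale, in raw days (unstandardised): the raw scale keeps the
coefficient interpretable as the log-odds change per active day.

**Fitting.** Each model is maximised from one "naive" start (logits of
the raw naive occupancy and detection frequency) plus `n_starts` random
N(0,1) starts, by BFGS with gradient tolerance 1e-8; the lowest −2LL
wins, ties broken by start index. The covariance of the estimates is
the inverse of a central-finite-difference Hessian of the negative
log-likelihood (step 1e-4·(1+|θ|)); a singular Hessian is flagged and a
pseudo-inverse reported. Occupancy estimates within 0.001 of 0 or 1 are
flagged as boundary estimates but not penalised. Predictions use the
delta method on the logit scale, with confidence intervals back-
transformed from `η̂ ± z·SE(η̂)`; covariate values outside the fitted
range are flagged as extrapolation.

## Model selection and averaging

AIC = −2LL + 2K throughout (no AICc/BIC). Candidate sets: per covariate
group, the factor-only null model plus 8 models per covariate (the
3 × 3 grid of {absent, additive, interaction} on occupancy × detection
minus the doubly-absent cell) — 25 solar, 25 soil, 9 plant models. The
null model belongs to each group's separately ranked set, so the total
count (59) counts it once per group; Akaike weights are normalised over
whichever set is actually ranked.

Model averaging operates on predicted probabilities, not coefficients:
`p̄(x) = Σ w_m p̂_m(x)`, with unconditional variance
`Σ w_m [var_m(x) + (p̂_m(x) − p̄(x))²]`. Models built on a different
covariate hold it at its observed median — except that a Total-solar
model evaluated against a Direct or Diffuse grid uses
Total = grid + median(other component), preserving the physical
identity Total = Direct + Diffuse. Confidence intervals are computed on
the probability scale by default (normal approximation, clipped to
[0, 1]); a logit-scale variant is available.

## Plant-composition pipeline

Cover-abundance classes map to midpoints of their percentage ranges
(class 1 "<1%" → 0.5; then 3, 15.5, 38, 63, 88), summed over the seven
height tiers to an importance value. Rows are standardised to site
totals (proportions) *before* the fourth-root transform. Bray–Curtis
similarity is `1 − Σ|x−y|/Σ(x+y)`; a pair of empty sites is undefined
and rejected.

NMDS minimises Kruskal stress-1 on dissimilarities `1 − S` by
alternating isotonic regression (ties in the dissimilarities ordered by
current distance — primary tie treatment) with Guttman majorisation
steps, from 10 random Gaussian starts by default (iteration cap 500,
tolerance 1e-6); the best restart wins, ties by restart index. The
returned configuration is centred, rotated to principal axes (Axis 1 =
largest variance) with a deterministic sign convention. Clustering is
UPGMA (group-average linkage) on the same dissimilarities, cut at a
caller-chosen number of groups — the number of communities is a
property of a given dataset, not a rule. SIMPER decomposes each group
pair's average Bray–Curtis dissimilarity into per-species terms
`mean |x_ik − x_jk| / Σ_m (x_im + x_jm)` over cross pairs, which sum
exactly to the pair's average dissimilarity.

## Synthetic data generator

The generator emulates the target study design: a 25-site grid, two
winters and two summers of 13 weekly occasions (week one anchored
mid-June / mid-December), covariates drawn from truncated normal
distributions whose truncated means match the published means within
the published ranges (e.g. winter direct solar 0.0–5.0 with mean 0.7
total mols m⁻² day⁻¹; C:N 11–24, mean 14.9; available P 3–41 μg g⁻¹,
mean 13.5), with total solar = direct + diffuse by construction and an
NMDS Axis 1 score generated correlated (~0.6) with √(direct solar).
Effort is 7 minus a zero-inflated binomial outage count (whole-week
outage probability 0.01, per-day outage 0.005), putting seasonal
camera-day totals near 2 240 — inside the published 2 200–2 760
envelope.

Default true parameters are set once so the fixture's summaries are of
the same order as the published seasonal data: rusa ψ 0.80 (winter) /
0.90 (summer) with weekly p ≈ 0.20–0.22 and a positive direct-solar
effect on detection (slope 0.8 per unit √solar on the logit scale);
male blocks R 0.70/0.40 and δ 0.50/0.25 (winter/summer, reflecting the
winter rut); red deer ψ 0.04/0.55 — near-absent in winter — with lower
detection. The multistate history is simulated first and the binary
history is its collapse, so all rusa views of the fixture are mutually
consistent; the two-species history pairs the final summer's slices.

What the generator does *not* emulate: year effects (the fixture's two
winters share parameters, while real seasonal summaries differ between
years), spatial autocorrelation between neighbouring cameras,
behavioural movement, and any misclassification of species or age/sex.
Passing tests therefore demonstrate correctness of the estimators under
the models' own assumptions, not robustness to their violation.

## Sizes used in checks

Enumeration oracles use complete outcome spaces up to 4 weeks (2⁴, 3³
and 4³ histories). The grid-search oracle uses a 0.001-step grid over
(ψ, p) on a 3-site toy. The parameter-recovery experiment in the test
suite uses 200 simulated datasets of 500 sites × 13 weeks at ψ = 0.7,
p = 0.4 (the acceptance script runs a 60 × 400 replication of the same
experiment); with 25-model candidate sets on the 25-site fixture, a
full ranking takes a few seconds. The NMDS cross-check compares
Kruskal stress-1 on 6-site toys against an independently optimised
configuration (scikit-learn's nonmetric MDS) to 1e-3.

## Known limitations

- The implicit-dynamics model cannot separate true seasonal turnover
  from sampling noise; it estimates per-season occupancy only.
- With a single occasion, ψ and p are confounded (only their product is
  identified); the fitter does not guard against this beyond the
  boundary flag.
- Wald intervals degrade near boundary estimates (ψ̂ → 1), as expected
  for naive occupancies above 0.9.
- The PAO dialect is a documented subset, not a byte-level clone of
  every PRESENCE file variant; files with survey covariates other than
  effort are out of scope.
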