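# Methods

## Generative model of the task

Horizontal screen position is normalized to [0, 1] screen widths; the
screen's vertical extent plays no role. On a trial of condition
(σs, σl) the hidden target is s ~ N(μ, σs²) with μ = 0.5, the splash is
X = {x₁…x₄}, xᵢ ~ N(s, σl²) i.i.d., and the net starts at a uniform random
position. The default design is two prior widths (σs = .03, .1), three
likelihood widths (σl = .025, .1, .25), splashes of n = 4 dots, and 4 blocks
of 120 trials: prior width constant within a block and alternating across
blocks (starting side chosen at random per subject), the three likelihood
widths balanced (40 each) and shuffled within a block, so each of the six
conditions contributes 80 trials. Neither targets nor splash dots are
truncated or resampled at the screen edges: with the design's SDs around
μ = 0.5 the off-screen mass is negligible, and the analysis is unaffected by
out-of-range dots.

A catch is |response − target| ≤ h with net half-width h = 0.01. The
original apparatus's net width is not part of the published design; h = 0.01
is fixed by the task's stated ~2% chance level, since a uniformly placed net
much narrower than the screen catches a centrally-distributed target with
probability ≈ 2h. Both h and every design constant above are configurable.

## Ideal observer

The splash centroid c is sufficient for the likelihood location, with
c | s ~ N(s, σl²/n). Conjugate updating gives the posterior
N(w·c + (1−w)·μ, (1/σs² + n/σl²)⁻¹) with

    w* = σs² / (σs² + σl²/n),

the optimal reliance on the likelihood. For the default grid, w* is
{0.852, 0.265, 0.054} under the narrow prior and {0.985, 0.800, 0.390}
under the wide prior (likelihood narrow → wide). The noise-free estimate
error w(c−s) − (1−w)(s−μ) has variance w²σl²/n + (1−w)²σs², minimized
exactly at w*, which is why catch rate peaks at the optimal weight.

## Synthetic observers

A simulated subject responds

    ŝ = w(condition)·c + (1 − w(condition))·μ + ε,  ε ~ N(0, σ_motor²),

with a lapse probability per trial. Two lapse modes exist because both
failure modes occur in pediatric testing: "timeout" (no response within the
window; recorded as missing) and "net_init" (the default: the net is never
moved from its random starting position — a response uncorrelated with the
stimulus that *stays in the data*). Weights are either the ideal-observer
value per condition, optionally shrunk by a group-level factor toward the
prior (the default cohort: TD scale 1.0, CP scale 0.75), or a constant
(a heuristic, non-Bayesian observer); subject heterogeneity enters through
i.i.d. per-condition weight jitter (SD 0.08), jittered motor noise
(0.03 ± 0.005) and lapse rate (0.05 ± 0.02), and ages drawn from
N(8.22, 1.80²) years clipped to 5–12 — the default sizes (9 + 9 subjects)
and parameters emulate a small age-matched pediatric cohort. Per-subject
generators are seeded by `SeedSequence(master, spawn_key=(group, subject,
stream))`, so extending a cohort never changes existing subjects.

What the generator does *not* emulate: learning of the prior across early
trials (weights are stationary), response-time structure, sequential
effects, or motor error that scales with movement distance. Passing
recovery and calibration tests therefore shows the *analysis chain* is
sound under the assumed stationary linear-weighting model, not that real
children satisfy that model.

## Estimation slope

For one subject × condition, with responses centered at the true prior mean
(subjects are assumed to have learned μ; a free-intercept fit is available
via `fit_intercept=True`),

    slope = Σ(cᵢ−μ)(ŝᵢ−μ) / Σ(cᵢ−μ)²,

over non-missing trials, pooled across the two blocks sharing the prior.
No outlier or off-screen filtering is applied by default. Degenerate inputs
raise: fewer than two usable trials, or all centroids at μ. The 95% CI is a
trial-level percentile bootstrap (default 1000 resamples; resamples with a
degenerate regressor are dropped — probability ~0 for continuous data).
The percentile method is used rather than BCa: at 80 trials/condition its
coverage is measured at ≈ 0.95 (the coverage experiment reports it), and it
keeps the CI a pure function of the resampled slope distribution.

p(correct) is the per-subject proportion of caught trials; timeouts count
as misses in the denominator (excluding them would reward non-response).

## Group statistics

*Wilcoxon signed-rank.* Ranks of |differences| use average ranks for ties;
zeros are dropped. For m ≤ 20 the p-value is exact: the null distribution
of the negative-rank sum is built by convolving the two-point distributions
{0, rᵢ} over the observed (doubled, hence integer) ranks — identical to
enumerating all 2^m sign assignments, conditional on the ranks. Larger m
uses a normal approximation with tie-adjusted variance Σrᵢ²/4 and a 0.5
continuity correction (agrees with the exact tail to < 0.01 at m = 20).
The reported W is the tail-relevant rank sum (min(T⁺, T⁻) two-sided).
Per-group comparisons against chance are Bonferroni-corrected across
groups. The between-group performance test is a paired signed-rank over
age-matched pairs by default; an unpaired Mann–Whitney U is available
(`paired=False`) — published small-cohort reports are sometimes only
consistent with the unpaired statistic, so both conventions are exposed.

*Scheirer–Ray–Hare.* All N observations are ranked jointly; an ordinary
crossed ANOVA decomposes the rank sums of squares (computed via a
statsmodels OLS, type II — equal to type I/III on balanced layouts); each
effect is tested with H = SS_effect / (SS_total/(N−1)) against χ² with the
effect's df. Using the realized rank variance as divisor absorbs ties
without a separate correction, and the one-factor case equals the
tie-corrected Kruskal–Wallis statistic exactly. The classical test is
two-way; the three-way layout (group × prior × likelihood, 18 subjects × 6
conditions = 108 slope observations) uses the same recipe. The test treats
the 108 rows as exchangeable, ignoring the repetition of subjects across
conditions — the convention its degrees of freedom imply; a simulation
check (200 null cohorts with a condition-independent shared weight
distribution) puts the group effect's type-I rate at ≈ 0.05–0.06. Note the
divisor includes *all* effects' SS, so when prior/likelihood effects are
huge (as in near-optimal cohorts) the group test becomes conservative —
a known property of this statistic, visible in the calibration experiment
if run with condition-dependent null weights.

## Numerical experiments and problem sizes

`candycatch.experiments` packages the standard validation studies, all
driven by one seed each:

- **Recovery** — one 18-subject cohort at the study conditions (motor noise
  0.03, lapse 0.05, 480 trials each); median |fitted − generating weight|
  over the 108 fits. Run with *timeout* lapses: those trials are excluded
  by the fit, so the slope estimates the weight (median error ≈ 0.02).
  With net-init lapses the lapse trials remain in the regression and shift
  the estimand itself away from the weight — mostly in the narrow-prior /
  narrow-likelihood cell, whose regressor variance σs² + σl²/4 ≈ 0.001 is
  by far the smallest; that variant is reported separately (≈ 0.06) as a
  measure of contamination, not of estimator error.
- **Coverage** — 500 subjects, one condition each (grid cycled), known
  weight ~ U(0.1, 0.9), 80 trials, noise 0.03, no lapses; fraction of 95%
  bootstrap CIs containing the weight.
- **Calibration** — 200 null cohorts (both groups drawn from one shared,
  condition-independent weight distribution); SRH group-effect rejection
  rate at α = 0.05.
- **Power** — groups with constant weights 0.4 vs 0.6, noise 0.05, 9+9
  subjects; SRH group-effect rejection rate (≈ 1 at these settings).

These sizes keep the full validation run near a minute on one CPU while
holding Monte-Carlo standard errors near or below the widths of the bands
being checked (e.g. SE ≈ 0.015 for the calibration rate at 200 cohorts).

## Known limitations

- The linear-weighting observer is the only behavioral family simulated; no
  decision noise on the weight, model mismatch, or prior mislearning.
- The SRH statistic ignores within-subject correlation; a mixed-effects or
  permutation alternative is out of scope by design.
- Exact Wilcoxon enumeration is limited to m ≤ 25 differences (the normal
  approximation takes over well before accuracy suffers).
- The trial CSV reader assumes one header row and per-trial rows; it adapts
  column *names* via `column_map` but not unit conventions — positions must
  already be in screen-width units.
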