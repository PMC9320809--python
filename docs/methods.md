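# Methods

This note documents the statistical procedures, the synthetic data
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Ethogram model

A courtship bout is a sequence of states on a fixed grid (default 10 s, 30
min cap → ≤ 180 scored timepoints), one of eight behaviours per timepoint;
`copulating` is absorbing and ends the trial.  Event-logged exports with
off-grid onset times are snapped with the rule *state at grid point t = last
recorded state with time ≤ t* over half-open intervals [t, t+10); a state
recorded after a grid point never snaps backwards.  Snapping is idempotent,
so already-gridded logs pass through unchanged.

**Courtship initiation** is scored two ways: `first` (first non-`separate`
timepoint) and `consecutive3` (first element of the earliest run of ≥3
consecutive non-`separate` timepoints; the default, because a single stray
"engaging" score followed by a long gap is not courtship).  The package
reports the mean/max discrepancy between the two rules as a data-quality
diagnostic.  **Copulation latency** is (copulation index − initiation
index) × interval.  **Time budgets** are fractions of timepoints per
behaviour from initiation up to (excluding) copulation; post-initiation
`separate` timepoints count in the denominator (the scored span, not only
active courtship), which is why budget fractions plus the separate fraction
sum to 1.  Trials without copulation are right-censored; their budget
window is set to the mean successful latency of the same strain pair
(rounded to the grid) when at least one success exists, otherwise the full
recording is used.  Bouts that copulate before a `consecutive3` run can
form (fewer than three pre-copulation timepoints) carry no initiation and
are excluded from budget-based responses; they are rare at realistic
latencies.

**Mating index** (used as an alternative fitness proxy that includes
never-mating combinations): censored latencies are replaced by the maximum
observed time, the mean is divided by the proportion of trials that mated
(larger = worse; zero successes → infinite index, mapped to zero relative
fitness).  The source literature for this index does not fix the weighting
direction; this form was chosen because it extends monotonically from the
all-mated case and is exposed as a configurable convention rather than
hard-coded.

**Progeny-latency assay.**  Days to first progeny over a 16-day window,
right-censored at day 16, are compared between male strains by
Kaplan–Meier curves and pairwise log-rank tests against a reference strain
(via `lifelines`).  The log-rank test is this package's choice of
comparison; with heavily crossing survival curves its power is limited and
a qualitative reading of the curves is advised.

## ART factorial ANOVA (plasticity)

Responses (budgets, CHC abundances, per-trial transition frequencies) are
analysed in a male-strain × female-strain factorial.  For each effect the
response is aligned — estimated effects other than the target are
subtracted using unweighted means of cell means — then midranked, and a
two-factor linear ANOVA with Type-III sums of squares (sum-to-zero coding)
is fitted to the ranks; only the target effect's F and p are reported.
Unbalanced cells are expected (not every strain mates with every female)
and are handled by the Type-III fit; *empty* cells make the alignment
undefined and raise an error naming the cells, so the pipeline first drops
strains not observed in all contexts.

One deliberate refinement: `art_anova` midrank-transforms the response
*before* aligning (`prerank=True`).  Classic ART aligns the raw response,
which makes the result depend on the response's scale: a nonlinear
monotone transform (log, exp) changes cell means and hence the aligned
ranks.  Aligning the initial midranks instead makes the whole procedure a
function of the response ordering only — exactly invariant under strictly
monotone transformations — while leaving null calibration intact (ranks of
exchangeable data are exchangeable) and coinciding with classic ART on
rank-scaled input.  Measured null rejection rates (2×12 design, 5/cell,
1000 replicates) are 0.043–0.057 per effect at α = 0.05, and power for a
1.5 SD context shift at 10/cell exceeds 0.99.  Degenerate fits are defined
explicitly: target sum of squares ≈ 0 → F = 0, p = 1; zero residual sum of
squares with nonzero effect → F = ∞, p = 0.

Trials whose male never courted (no `consecutive3` initiation) are excluded
from plasticity responses; exclusion happens upstream where summaries carry
no initiation.

## Markov-chain homogeneity (sequence plasticity)

One-step transitions are summed over all trials of a (male strain × female
strain) combination; transitions never cross trial boundaries;
self-transitions and transitions into `copulating` are counted (the 10-s
grid makes dwell-time self-loops meaningful).  For a male strain observed
in ≥2 female contexts the test compares per-context count matrices row by
row with the pooled rows:

* Pearson X² = Σ_g Σ_ij (n_gij − n_gi·p̂_ij)²/(n_gi·p̂_ij)   (default)
* G² = 2 Σ_g Σ_ij n_gij log[(n_gij/n_gi·)/(n_+ij/n_+i·)]    (`statistic="lrt"`)

with df = Σ_i (G_i − 1)(k_i − 1) over rows with pooled support, where G_i
counts groups visiting row i and k_i the columns with pooled support —
rows/columns never observed contribute no degrees of freedom, which keeps
the df honest for sparse 8-state matrices.  Pearson is the default because
at the transition counts a 30-min bout design actually yields (a few
hundred per group) the likelihood-ratio form rejects a true null roughly
twice too often (measured ≈ 0.11 at 300 transitions/group), while Pearson
holds ≈ 0.05; both are available and agree asymptotically.  Matrix
estimation adds optional pseudo-counts (α = 0 for inference; α = 0.5 only
for reporting/simulation) and falls back to a uniform row, with a warning,
for rows never visited.

## Selection gradients

Unit of analysis: male-strain means per female context (CHC profiles are
measured on separate virgin males, so strain means are the only level at
which behaviour and chemistry can be joined).  Traits are z-standardized
(n−1 SD); relative fitness has mean 1.  Three conventions:

* `inverse_latency` (default): w = (1/t̄)/mean(1/t̄).  Chosen so that a
  trait that shortens latency gets a positive gradient — positive
  coefficients mean positive selection.  The literal textbook form
  w = t̄/mean(t̄) is available as `latency` but reverses every sign.
* `mating_index`: w = (1/index)/mean(1/index); never-mating strains get
  w = 0 and stay in the regression.

The gradient is the LAD (τ = 0.5 quantile) slope.  The point fit is exact:
all candidate lines through two data points are enumerated for n ≤ 60
(some L1 optimum is always such a basic solution), and an LP (HiGHS)
solves larger problems; the two routes agree to 1e-6 on random instances
and ties between optima are broken by the first minimal-loss candidate.
The 95% CI is a case-resampling bootstrap (paired (z, w) resampling, 2000
replicates by default, percentile interval, fixed seed stored with the
result).  A rank-inversion CI would be the main alternative; at n ≈ 13
strains it is unstable, and the bootstrap was fixed here once as the
package's convention.  Strains with zero successful matings (or no
measurable latency) are excluded from latency-based gradient regressions
but retained in the binomial regressions and under the mating-index path.

Mating success is fitted as logit(p_i) = a + b·z_i by IRLS on the binomial
likelihood (via `statsmodels` GLM) with Wald 95% CIs; complete separation
is detected (diverging estimates/standard errors) and flagged rather than
reported as a finite coefficient.  Against a grid-search maximum-likelihood
oracle the IRLS estimates agree to < 1e-3.

**Variable reduction** mirrors the two-stage importance-screening idea of
VSURF-style procedures, scaled to strain-mean panels: (1) *thresholding* —
over 50 seeded random-forest fits, each trained on a random half of the
rows with permutation importance measured on the held-out half, traits are
ranked by mean importance and dropped if they do not exceed the mean
importance-SD of the lower half of the ranking (the noise floor);
(2) *interpretation* — surviving traits are forward-added in importance
order and kept only if they reduce out-of-bag MSE by more than one SD of
the current error estimate.  Deterministic given a seed.  The union of
traits selected across the two female contexts is analysed for gradients.

**PCA** of combined strain-mean traits is an eigendecomposition of the
correlation matrix; the largest-magnitude loading of each component is made
positive so outputs are reproducible.

## Synthetic panels

`default_config` encodes the study conditions the package assumes: 12 male
strains × 2 female contexts, 5 bouts per pair, 10-s grid, 30-min cap.  A
baseline courting chain (structured support: separate ⇄ engaging → singing
→ {singing2, scissoring, circling, attempted-copulation}, with dwell-time
self-loops) is tilted per pair: the singing column by exp(0.30·z_strain ±
0.35 context), the attempted-copulation column by exp(±0.30 context) —
more singing with M-like females, more escalation with Z-like, matching
the qualitative plasticity pattern the analysis is meant to detect.
Copulation latency is drawn per trial from a log-normal (median 300 s,
σ_log = 0.35) whose log-mean is linear in the strain's latent traits with
context-specific gradients (cVA: −0.3 Z-like/+0.3 M-like — the one
divergent trait; 7-C25: +0.3 Z-like only); the chain is coupled to the
drawn latency by a uniform per-step absorption hazard 1/latency once
courtship has initiated, so sequence structure and fitness structure stay
independently controllable.  Mating success is Bernoulli with logit(p) =
1.0 + Σb·z (b = ±0.8 on the same traits).  CHC abundances are log-normal
with strain effects 0.40·z and individual noise 0.15 (3 males per strain),
normalized against a constant internal-standard area on write-out.  One
strain never courts Z-like females (all-separate chain with 0.02 escape)
and one courts but never mates with M-like females, exercising the
exclusion rules.  All randomness flows from one master seed through
counter-based substreams (one per trial, one per strain's CHC draw), so
panels are byte-identical across runs.

What the generator does **not** emulate: within-strain male heterogeneity
in courtship vigour beyond the trial-level noise, block/recording-session
effects, time-of-day structure, semi-Markov dwell times, female behaviour,
and CHC measurement artefacts (co-eluting peaks, batch drift).  Passing
tests therefore certify the estimators under the model's assumptions — not
robustness to those real-data complications.

## Verification sizes and numerical tolerances

The acceptance suite and `scripts/acceptance.py` use: 200 random instances
(n ≤ 12) for the LAD-vs-enumeration check; 50 instances for the IRLS-vs-
grid check (tolerance 1e-3); 1000 replicates at 300 transitions/group for
homogeneity calibration; 1000 replicates of a null 2×12 factorial (5/cell)
for ART calibration; 500 replicates for the 1.5 SD plasticity power check;
20 seeds (10 in the faster script) of 50-strain panels with 1000 bootstrap
replicates for gradient recovery; 10⁵ steps for the transition-matrix
round trip (tolerance 0.02 per entry).  These sizes keep the full battery
within a few minutes on one CPU while leaving the binomial error of each
calibration estimate well inside its acceptance band.  Row-stochasticity
is enforced to 1e-12; standardized columns and relative fitness are exact
to 1e-9.

## Known limitations

* Gradients are simple (single-trait) regressions after variable
  reduction, not a multivariate selection-gradient vector; correlated
  traits share credit.
* The homogeneity test localizes nothing; per-transition plasticity is
  delegated to ART on per-trial transition frequencies.
* Bootstrap percentile CIs at n = 13 strains are approximate; coverage of
  the neutral-trait CIs measured at n = 50 is ≈ 0.95, and small panels
  should be read with that in mind.
* The ART pre-ranking choice trades exact agreement with raw-response ART
  implementations for exact monotone invariance; on continuous tie-free
  data the two give very similar, not identical, F statistics.
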