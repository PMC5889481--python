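# Methods

## Task model

The elicitation task offers, on each trial, a choice between a sure amount
and a fixed two-outcome gamble (x with probability p, else y; p ∈
{1/6 … 5/6}, amounts ±€300–1200 from a fixed 10-gamble menu per domain).
Each gamble is played as a series of six bisection trials: the first sure
offer is the gamble's expected value; a bracket [y, x] (signed
[−x, −y] for losses) is maintained, the bound on the side of the chosen
option moves to the current offer, and the next offer is the bracket
midpoint. The certainty equivalent (CE) is the midpoint of the terminal
bracket. Because the first offer is the EV rather than the bracket
midpoint, the terminal bracket width is (x−y)·max(p, 1−p)/2⁵, which keeps
the CE estimate within (x−y)/2⁶ of any monotone deterministic agent's true
indifference point; this bound is asserted in the test suite over the full
menu and a 36-point parameter grid.

Staircase arithmetic runs on signed money, where "higher sure offer" is
always "more attractive"; a single bound-update rule therefore covers
gains and losses, and the loss domain is otherwise a reflection (model
math on magnitudes, sign applied at the task/IO boundary).

Each series ends with two control trials at CE·(1 ± ε), ε = 0.05 by
default. A control response is ruled inconsistent only when it contradicts
the terminal bracket (an offer at or above the bracket must be taken sure;
at or below it, gambled). Offers strictly inside the bracket are not
judged: the six staircase responses localize the indifference point only
to the bracket, so no response to an interior offer can be called an
error. This rule means a deterministic monotone agent never fails a
control trial — a simulated noiseless session always contains exactly
160 trials — while genuinely inconsistent (noisy or non-monotone)
responders are caught. Failed series are repeated from scratch up to
`max_repeats` (default 3) and then flagged rather than discarded.

## Synthetic cohorts

Cohorts default to 21 controls and 16 gamblers with per-cell parameter
medians taken from the published group estimates. Parameters are drawn
log-normally around the cell medians: they are strictly positive, the
summary statistic being matched is a median, and the log-normal preserves
medians under the location shift. The default log-scale SD of 0.5
reproduces interquartile ranges of roughly 0.7x the median, the typical
ratio in the published parameter table. A shared per-participant random
effect on the log scale induces the placebo–sulpiride correlation
(default 0.5 — "moderate" test–retest reliability; true between-session
reliability is unknown, so this is an explicit knob, not a calibrated
value).

Choices are generated by a softmax (logistic) rule on the prospect-theory
utility difference — the standard econometric choice kernel — with
temperature in utility units (€^α scale). Temperature 0 is the
deterministic argmax with ties broken toward the sure option. The default
temperature of 10 was chosen as mild trembling-hand noise: it yields
CE-scale residuals with an SE of ~5 € after estimation and a nonzero
control-trial failure rate. What the generator does *not* emulate:
sequential dependencies between trials, lapses or attention drift,
stake-dependent noise, or any systematic deviation from the generating
model family — so passing recovery tests demonstrate estimator
correctness under the assumed model, not robustness to misspecification
in real data.

## Estimation

Step 1 fits (α, w(2/6)) to the six p = 2/6 CEs by bounded nonlinear least
squares in CE (euro) units; step 2 inverts the four zero-floor CEs into
nonparametric weights; the Lattimore or Prelec form is then fitted to the
five (p, w) points. Numerical choices:

* bounds α, δ, γ ∈ [1e-6, 5], w(2/6) ∈ [1e-6, 1−1e-6], matching the
  random-restart ranges (unbounded fits can diverge on degenerate CE
  patterns; published estimates all lie inside these bounds);
* trust-region reflective least squares with ftol = xtol = gtol = 1e-12,
  tight enough that noiseless self-consistency holds to ~1e-8 and the
  grid-identifiability test to 1e-4;
* 200 restarts by default, drawn uniformly from the stated ranges with
  one seeded generator per participant x drug x domain cell (estimates
  are individually reproducible); the neutral start (α = 1, w26 = 1/3,
  δ = γ = 1) is always tried first, which pins the zero-noise recovery
  fixed point bit-stably; ties in resnorm keep the first solution found;
* the per-run pairing of step-1 and step-2 starting values is
  inconsequential because step 2 depends on step 1 only through its best
  fit, so the implementation selects the best step-1 fit across restarts
  first and then the best weighting fit across restarts.

Exclusion rules: a participant is dropped from inference (not from
estimation) when |CE| for the p = 1/6, x = 1200 gamble exceeds |CE| for
the p = 5/6, x = 1200 gamble in any drug x domain condition (violating
probability monotonicity), or when an estimated α lies more than 3 SD from
the across-participant mean of its condition (computed over both groups;
whether the original screen pooled groups is unknown, so this is a
documented default with `k` exposed). With zero dispersion or fewer than
three participants the outlier screen flags nothing.

The linear-value sensitivity variant (α pinned to 1) is exposed as
`fix_alpha`; the Prelec refit as `form="prelec"` (note its inverted
elevation convention: larger δ lowers the curve).

## Parameter recovery

Synthetic CEs are generated from each cell's fitted semi-parametric
parameters (α and w(2/6) for the six p = 2/6 gambles, the nonparametric
weights for the rest), noise is added as i.i.d. Gaussian with SE equal to
the median over all cells of the per-cell RMSE between observed and
model-implied CEs (RMSE per cell over the 10 gambles first, then the
median — the pooled alternative is a one-line change), and every noisy
dataset is re-estimated. Noisy magnitudes are clipped to [0, x] because
the step-2 inversion is undefined beyond x; this mirrors the bounded
response scale of the task. Per-participant medians over simulations are
correlated with the originals (Pearson as the headline, Spearman
alongside), per parameter and condition. Default 200 simulations; the
test suite and acceptance script use 20 simulations with 8 restarts per
re-estimation, which bounds runtime at desk scale while leaving the
correlation criterion (> 0.95 everywhere) intact.

## Statistics

Drug main effects use the Wilcoxon signed-rank test (zeros dropped before
ranking, no continuity correction, no tie correction in the variance —
conventions chosen to match the reported statistics; both are exposed as
toggles), group main effects use Mann–Whitney U on drug-averaged values
with tie-corrected variance, and interactions (drug x group, drug x drug
order) compare sulpiride − placebo differences between arms. All p-values
are two-sided; exact small-sample p-values by enumeration of the null
(sign patterns, or rank assignments) are available and are verified
against independent brute-force enumeration and scipy. Effect sizes are
common-language effect sizes: U/(n₁n₂) for Mann–Whitney and the share of
positive differences (zeros in the denominator) for Wilcoxon. Bonferroni
correction multiplies by 6 (two main effects and the interaction, times
two domains) and caps at 1. Medians and IQRs (Q3 − Q1, linear
interpolation) summarize each group x drug x domain cell.

## Problem sizes and defaults used in checks

The test suite and acceptance script run the pipeline at: full cohort
n = 37 (21 + 16), staircase accuracy over 36 agents x 20 gambles x 2
domains, identifiability over the same 36-point grid with 50 restarts,
recovery with 20 simulations, and effect-detection closure over 5
replicate cohorts with 10 restarts — sizes chosen so each check isolates
one property at a few minutes of compute. The 2 x 2 x 5 repeated-measures
ANOVA on the probability weights is intentionally not reimplemented; it
is off-the-shelf and orthogonal to the bespoke core.

## Known limitations

* The figshare adapter is written against plausible layouts (schema CSVs,
  participant x gamble `.mat` arrays) but has not been validated against
  the actual archive, which must be downloaded manually.
* Recovery correlations are computed across participants; with very low
  between-participant dispersion they become unstable (degenerate spread),
  which the synthetic defaults avoid.
* The choice-noise temperature is not estimable from CE data within this
  design and is a generator-side knob only.
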