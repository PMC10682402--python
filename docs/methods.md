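# Methods

## The model

A yeast mother cell's replicative lifespan (RLS) is the number of mitotic
divisions it completes between birth and death. `yeastrls` models the
survival of a cohort of mother cells with the Weibull survival function

    S(g) / S0 = exp(-(r g)^alpha)

where `g` is the generation index, `S0` the number of cells entering the
experiment, `r` a scale parameter in 1/generations, and `alpha` a
dimensionless shape. `alpha > 1` means the per-generation hazard rises with
age, i.e. the population ages; `alpha = 1` is the memoryless (exponential)
limit. The mean and standard deviation of the full lifespan distribution
follow in closed form,

    mean = Gamma(1 + 1/alpha) / r
    sd   = sqrt(Gamma(1 + 2/alpha) - Gamma(1 + 1/alpha)^2) / r

and the SEM is `sd / sqrt(n)` for `n` analyzed cells. The gamma function is
evaluated through `log-gamma` so shapes as small as `alpha = 0.1` stay
finite; the variance is factored as
`exp(lg2) * (1 - exp(2*lg1 - lg2))` before the square root to avoid
catastrophic overflow of the intermediate `Gamma(1 + 2/alpha)`.

The practical point of the parametric form is truncation: a fixed-duration
(e.g. 3-day) tracking experiment observes only part of the survival curve —
long-lived cells are still dividing when it ends — yet fitting `(r, alpha)`
to the observed part predicts the *full* distribution's mean and SD. The
reported statistics are always the continuous closed forms above. The
expectation of the discretized (integer) lifespan, `sum_{g>=1} S(g)`, sits
about half a generation lower; it is exposed only as a numerical
cross-check (`yeastrls.weibull.discrete_mean`), never reported.

## Survival-curve estimation under right-censoring

Input is one record per mother cell: a division count and an end state,
dead or alive-at-experiment-end (right-censored). The package uses a
discrete product-limit (Kaplan–Meier) estimate. A dead cell with `L`
divisions attempted and failed division `L+1`; a censored cell with `C`
divisions is known alive through generation `C` and leaves the risk set
afterwards (deaths are processed before censorings at a tie). For division
attempt `j >= 1`,

    n_j = #{dead, L >= j-1} + #{censored, C >= j}
    d_j = #{dead, L == j-1}
    s_hat(g) = prod_{j<=g} (1 - d_j / n_j)

With no censoring this is exactly the naive fraction `#{L >= g} / n`. The
product-limit choice is a design decision: the upstream description of the
procedure only states that generation counts and end states feed a
least-squares fit, and product-limit is the standard unbiased estimator
under independent right-censoring. A `naive` mode (curve truncated at the
smallest censored count) is available behind a flag for sensitivity
analysis.

## Least-squares Weibull fitting

The fit minimizes the unweighted residual sum of squares on the survival
scale, `sum_g (s_hat(g) - exp(-(r g)^alpha))^2`, over generations `g >= 1`
whose risk set holds at least 5 cells — tail points estimated from fewer
cells are noise-dominated. Optimization uses bounded nonlinear least
squares (trust-region reflective), `r` in `[1e-6, 10]`, `alpha` in
`[0.1, 50]` (bracketing the ranges seen in real deletion screens,
r ≈ 0.025–0.195 and alpha ≈ 1.6–7.3, with wide margins), objective
tolerance 1e-10, at most 1000 function evaluations, initialized from the
log-log linearization `ln(-ln s_hat) = alpha ln g + alpha ln r`, which is
exact on noiseless data. If the linearization has fewer than two usable
points the start falls back to `alpha = 2` with `r` matched to the
restricted mean. Degenerate inputs — no deaths, deaths at fewer than two
distinct generations, fewer than three usable fit points — raise a typed
`DegenerateDataError` rather than returning a spurious fit; batch drivers
record such strains as unconverged and continue.

Replicates are pooled *before* curve construction (the standard design pools
200 cells from two biological replicates), so fitting the pooled curve and
fitting the concatenated records are identical by construction.

## Comparison statistics

Two lifespan summaries `(x1, s1, n1)` and `(x2, s2, n2)` are compared with
the two-sample Z statistic

    Z = (x1 - x2) / sqrt(s1^2/n1 + s2^2/n2)

with the hypothesized population difference set to zero. Replicate
concordance uses the two-sided p-value `2 Phi(-|Z|)`; the screen question
"does the deletion strain live longer than wild-type?" uses the right-sided
`1 - Phi(Z)`. `Phi` is computed through the complementary error function,
keeping p-values accurate at `|Z| ~ 13` (p ~ 1e-39), which real screens
reach. The default screen calls significance at raw `p < 0.05` with no
multiple-testing correction — matching the convention the 44%-significant
headline count of the motivating screen was computed under — with
Benjamini–Hochberg adjustment available as an option.

Enrichment of a hit list against flat gene-set annotations (GMT) uses the
hypergeometric upper tail `P(X >= k)` for `k` of `n` hits falling in a term
annotating `K` of `N` universe genes; the enrichment score is `-log10(p)`,
and BH FDR is computed across terms (significant at `p < 0.05`, flagged
strong at `FDR < 0.05`). The universe defaults to the union of annotation
genes; pass an explicit gene list to reproduce a whole-genome universe. The
BH step-up and the Pearson correlation are implemented directly (and
cross-checked against statsmodels and scipy in the tests).

Dose–response (mean RLS versus relative protein level) is fitted to the
three-parameter decaying exponential `y = a exp(-b x) + c` with `b >= 0`
and a free asymptote `c` (overexpressing strains still divide, so a
positive floor is biologically sensible); the exact functional form used
upstream is shown only graphically, so this choice is the package's own.
Five fixed initializations are tried and the best residual sum of squares
wins, making the fit deterministic. Goodness of fit is
`R^2 = 1 - SSres/SStot`.

`population_age_fraction(a) = 2^-a` is the symmetric-budding approximation
to the geometric age distribution of an exponentially growing population
(half the cells are newborn, each age class halves). It is a documentation
utility, not a fitted model.

## The synthetic experiment generator

`yeastrls.simulate` emulates a fixed-duration microfluidic aging
experiment:

- integer lifespans `L = floor(w)` with `w` continuous Weibull, which makes
  `P(L >= g)` equal the survival law exactly at every integer generation
  (the fitted object is the curve at integer generations, so exactness
  there is what matters);
- per-cycle durations `T_i = base_cycle * f_age(i) * eps_i` with
  `base_cycle = 90` minutes, lognormal noise `eps` of unit median and
  CV 0.2, and a senescent-elongation ramp
  `f_age(i) = 1 + lambda * max(0, (i - (L-k))/k)` over the final `k = 5`
  cycles (`lambda = 1`, i.e. the last cycle is ~twice as long) — a minimal
  mechanism that makes short-duration censoring bite the way real late-life
  cycle slow-down does;
- death during the failed attempt at division `L+1`; any cell whose death
  falls past the experiment duration (72 h by default) is censored at the
  divisions completed in time;
- all cells enter as newborns at time zero (the platform loads newborn
  cells at the start; staggered entry is out of scope);
- optional snapping of division times up to the next imaging frame
  (default off: generation counting, not timing, drives the analysis);
- 200 cells split evenly across 2 replicate labels. Each cell's random
  stream is keyed by `(seed, cell index)` only, so datasets are
  reproducible byte-for-byte and replicate labelling cannot perturb the
  draws; screens derive per-strain seeds deterministically from the master
  seed and the strain id.

What the generator does *not* emulate: trap-loss and technical dropout,
mother–daughter misclassification, inter-replicate batch effects,
measurement error in division counting, or non-Weibull lifespan laws.
Passing tests therefore demonstrate that the pipeline recovers truth when
its distributional assumptions hold — they do not certify robustness to
model misspecification in real data.

## Monte-Carlo problem sizes and observed behavior

The validation studies use the following sizes, chosen to make binomial
noise small relative to the bands being checked: 100 replicate experiments
for parameter recovery (median relative error of fitted `r` is ~1–2%, and
the true mean falls within predicted mean ± 2 SEM in ~94% of runs); 50
strains with true means spanning 15–36 generations for the
experiment-duration validation (72-h predictions are statistically
indistinguishable from the 120-h benchmark for >90% of strains, while 48-h
predictions carry roughly 3–4× the RMSE of 120-h ones); and 2000 simulated
null strain pairs for the screen's type-I error (empirical rejection rate
~0.05 at nominal 0.05). The unit suite runs scaled-down versions of the
same checks; `scripts/acceptance.py` runs the full sizes.

## Known limitations

- The least-squares fit is not maximum likelihood; censoring enters through
  the product-limit curve, not the likelihood. This mirrors the upstream
  procedure but forfeits some efficiency.
- Unweighted residuals give tail generations (few cells at risk) the same
  weight as early ones; the `n_risk >= 5` floor is a blunt guard.
- The SEM attached to a predicted mean is `sd/sqrt(n)`, the SEM an
  uncensored sample of size `n` would have; it ignores fit uncertainty in
  `(r, alpha)`. The type-I simulations show the resulting Z test is close
  to nominal at the standard design, but this is a calibration property of
  that design, not a theorem.
- Alternative survival families (Gompertz, log-logistic) and GO term
  hierarchy handling are out of scope.
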