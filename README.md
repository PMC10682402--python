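# yeastrls

Censored Weibull survival analysis for yeast replicative-lifespan (RLS)
screens.

Microfluidic platforms track individual yeast mother cells and count their
divisions, but a practical experiment ends after a fixed duration (typically
3 days) while long-lived cells are still dividing — the data are
right-censored. `yeastrls` is for researchers analyzing such
division-tracking data: it builds censoring-aware survival curves, fits the
Weibull survival law by least squares, predicts each strain's *full*
lifespan distribution from the truncated observation, and screens deletion
strains against the wild-type with two-sample Z statistics. A synthetic
experiment generator with the same statistical structure (Weibull lifespans,
~90-minute age-dependent cell cycles, fixed-duration censoring, two pooled
replicates per strain) makes every stage testable without raw data.

## Model

Survival to generation `g` follows

    S(g)/S0 = exp(-(r g)^alpha)

with scale `r` (1/generations) and shape `alpha` (`alpha > 1` ⇒ aging).
From fitted parameters the full distribution's statistics are

    mean = Γ(1 + 1/α) / r
    sd   = sqrt(Γ(1 + 2/α) − Γ(1 + 1/α)²) / r,      SEM = sd / √n

Two strains with summaries `(x̄1, σ1, n1)` and `(x̄2, σ2, n2)` are compared
with

    Z = (x̄1 − x̄2) / sqrt(σ1²/n1 + σ2²/n2)

right-sided for "lives longer than wild-type" calls, two-sided for
replicate concordance, significant at p < 0.05. Downstream analyses
include hypergeometric gene-set enrichment with Benjamini–Hochberg FDR and
a decaying-exponential dose–response fit (`y = a·e^{−bx} + c`) with R².
See `docs/methods.md` for estimator conventions and design choices.

## Worked example

Simulate a miniature screen — a wild-type, a strongly long-lived deletion,
and a no-effect deletion — then fit and screen it:

```yaml
# screen.yaml
seed: 42
strains:
  - {id: WT,     r: 0.043, alpha: 4.2}   # wild-type-like, mean ~21
  - {id: sis2d,  r: 0.025, alpha: 4.5}   # long-lived deletion, mean ~36
  - {id: vhs3d,  r: 0.043, alpha: 4.0}   # no effect
sim: {n_cells: 200, n_replicates: 2, duration_h: 72}
```

```sh
yeastrls simulate --config screen.yaml --out cells.tsv --truth truth.tsv
yeastrls fit --cells cells.tsv --out fits.tsv
yeastrls screen --fits fits.tsv --wildtype WT --out screen.tsv
```

The fit step prints one row per strain (values abridged):

```
strain  n_cells  n_censored  r        alpha  mean_rls  sd_rls  sem
WT      200      0           0.04366  4.160  20.81     5.63    0.398
sis2d   200      57          0.02484  4.043  36.51     10.14   0.717
vhs3d   200      0           0.04308  4.132  21.08     5.74    0.406
```

Note `sis2d`: 57 of its 200 cells were still alive at 72 h, yet the fitted
`(r, α)` recover the generating law (true r = 0.025) and predict the full
mean of 36.5 generations from the censored data. The screen step reports

```
1 of 2 tested strains live significantly longer than WT (p < 0.05, none correction)
```

with per-strain columns in `screen.tsv`:

```
strain  fold_change_vs_wt  z_vs_wt  p_right    significant
WT      1.000              0.00     0.5        False
sis2d   1.755              19.14    5.8e-82    True
vhs3d   1.013              0.47     0.32       False
```

The fold change (1.76×) and Z statistic are the quantities a screen
scatterplot shows; `vhs3d`, simulated with wild-type parameters, is
correctly not called. The same operations are available as library
functions (`simulate_experiment`, `empirical_survival`, `fit_weibull`,
`predict_full_stats`, `classify_screen`, ...). Other subcommands:
`benchmark` (prediction agreement across 48/72/120-hour designs),
`correlate` (Pearson correlation of two table columns), `enrich`
(GMT-based hypergeometric enrichment), `dose-response`.

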