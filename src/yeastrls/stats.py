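"""Screen statistics: two-sample Z tests, Pearson correlation, hypergeometric
enrichment with Benjamini-Hochberg FDR, dose-response fitting.

The screening question is whether a deletion strain's predicted mean
replicative lifespan exceeds the wild-type's.  With full-distribution mean
x1, SD s1 over n1 cells against (x2, s2, n2), the two-sample Z statistic is

    Z = (x1 - x2) / sqrt(s1^2/n1 + s2^2/n2)

(the hypothesized population difference is zero).  Two-sided p = 2*Phi(-|Z|)
for replicate concordance; right-sided p = 1 - Phi(Z) for "lives longer than
wild-type" calls, each significant at p < 0.05.  Phi is evaluated through the
complementary error function so that |Z| ~ 13 (p ~ 1e-39) keeps full tail
accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc
from scipy.stats import hypergeom

from .fit import LifespanSummary
from .weibull import MomentSummary

__all__ = [
    "StrainComparison",
    "CorrelationResult",
    "EnrichmentResult",
    "DoseResponseFit",
    "two_sample_z",
    "classify_screen",
    "pearson",
    "hypergeom_enrichment",
    "bh_fdr",
    "fit_exp_decay",
    "population_age_fraction",
]


def _phi(z: float) -> float:
    """Standard normal CDF via erfc for accurate extreme tails."""
    return 0.5 * erfc(-z / math.sqrt(2.0))


@dataclass(frozen=True)
class StrainComparison:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    z: float
    p_two_sided: float
    p_one_sided_right: float
    significant: bool
    sided: str
    alpha: float


@dataclass(frozen=True)
class CorrelationResult:
    pcc: float
    n: int


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # hits annotated to the term
    K: int  # universe genes annotated to the term
    n: int  # hit-list size
    N: int  # universe size
    p: float
    enrichment_score: float  # -log10(p)
    fdr: float
    significant: bool  # p < 0.05
    strong: bool  # FDR < 0.05


@dataclass(frozen=True)
class DoseResponseFit:
    a: float
    b: float
    c: float
    r_squared: float
    converged: bool

    def predict(self, x):
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float)) + self.c


def two_sample_z(
    s1: MomentSummary,
    s2: MomentSummary,
    sided: str = "two",
    alpha: float = 0.05,
) -> StrainComparison:
    """Two-sample Z test between two lifespan summaries."""
    if sided not in ("two", "right"):
        raise ValueError(f"sided must be 'two' or 'right', got {sided!r}")
    if s1.n < 2 or s2.n < 2:
        raise ValueError("each sample needs n >= 2")
    se = math.sqrt(s1.sd**2 / s1.n + s2.sd**2 / s2.n)
    if se == 0.0:
        raise ZeroDivisionError(
            "both SDs are zero: the Z statistic is undefined for degenerate samples"
        )
    z = (s1.mean - s2.mean) / se
    p_two = erfc(abs(z) / math.sqrt(2.0))  # = 2 * Phi(-|z|)
    p_right = 0.5 * erfc(z / math.sqrt(2.0))  # = 1 - Phi(z)
    p_sel = p_two if sided == "two" else p_right
    return StrainComparison(
        mean1=s1.mean, sd1=s1.sd, n1=s1.n,
        mean2=s2.mean, sd2=s2.sd, n2=s2.n,
        z=z, p_two_sided=p_two, p_one_sided_right=p_right,
        significant=bool(p_sel < alpha), sided=sided, alpha=alpha,
    )


def classify_screen(
    summaries: Sequence[LifespanSummary],
    wildtype_id: str,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Right-sided Z screen of every strain against the wild-type.

    Per strain: fold change of predicted mean RLS over the wild-type mean,
    the Z statistic, its right-sided p-value, and a significance flag at raw
    p < alpha (the default) or at BH-adjusted p < alpha with
    ``correction="BH"``.  The wild-type row carries fold change 1 and is
    never significant.
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"correction must be 'none' or 'BH', got {correction!r}")
    by_id = {s.strain_id: s for s in summaries}
    if wildtype_id not in by_id:
        raise KeyError(f"wild-type strain {wildtype_id!r} not among summaries")
    wt = by_id[wildtype_id]

    rows = []
    pvals = []
    for s in summaries:
        row = {
            "strain": s.strain_id,
            "n_cells": s.moments.n,
            "n_censored": s.fit.n_censored,
            "r": s.fit.params.r,
            "alpha": s.fit.params.alpha,
            "mean_rls": s.moments.mean,
            "sd_rls": s.moments.sd,
            "sem": s.moments.sem,
            "converged": s.fit.converged,
            "fold_change_vs_wt": s.moments.mean / wt.moments.mean,
        }
        if s.strain_id == wildtype_id:
            row.update({"z_vs_wt": 0.0, "p_right": 0.5, "abs_z": 0.0})
        else:
            cmp = two_sample_z(s.moments, wt.moments, sided="right", alpha=alpha)
            row.update({"z_vs_wt": cmp.z, "p_right": cmp.p_one_sided_right, "abs_z": abs(cmp.z)})
        rows.append(row)
        pvals.append(row["p_right"])

    table = pd.DataFrame(rows)
    non_wt = table.strain != wildtype_id
    if correction == "BH":
        adj = np.full(len(table), np.nan)
        adj[non_wt.to_numpy()] = bh_fdr(table.loc[non_wt, "p_right"].to_numpy())
        table["p_adjusted"] = adj
        table["significant"] = non_wt & (table.p_adjusted < alpha)
    else:
        table["significant"] = non_wt & (table.p_right < alpha)
    return table


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson's correlation coefficient of two paired vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = xa.size
    if n < 2:
        raise ValueError("need at least 2 paired points")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return CorrelationResult(pcc=float(dx @ dy) / (sx * sy), n=n)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("all p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_enrichment(
    hits: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per annotation term.

    For a term annotating K of the N universe genes, with k of the n hit
    genes annotated, p = P(X >= k) under Hypergeometric(N, K, n); the
    enrichment score is -log10(p).  BH FDR is computed across all terms.
    Terms are returned sorted by ascending p.
    """
    universe_set = set(universe)
    hit_set = set(hits)
    if not hit_set:
        raise ValueError("empty hit list")
    offenders = sorted(hit_set - universe_set)
    if offenders:
        raise ValueError(f"hit genes absent from the universe: {offenders}")
    N = len(universe_set)
    n = len(hit_set)

    results = []
    for term, genes in annotations.items():
        term_genes = set(genes) & universe_set
        K = len(term_genes)
        k = len(hit_set & term_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        results.append((term, k, K, p))

    fdrs = bh_fdr([p for _, _, _, p in results])
    out = [
        EnrichmentResult(
            term=term, k=k, K=K, n=n, N=N, p=p,
            enrichment_score=-math.log10(p), fdr=float(fdr),
            significant=p < 0.05, strong=fdr < 0.05,
        )
        for (term, k, K, p), fdr in zip(results, fdrs)
    ]
    out.sort(key=lambda e: (e.p, e.term))
    return out


# Fixed multi-start initial decay rates for the dose-response fit.
_DECAY_STARTS = (0.1, 0.5, 1.0, 2.0, 5.0)


def fit_exp_decay(levels: Sequence[float], means: Sequence[float]) -> DoseResponseFit:
    """Fit mean RLS versus relative protein level to y = a*exp(-b*x) + c.

    The decay rate is constrained nonnegative (the relationship is inverse:
    more protein, shorter lifespan) and the asymptote c is free, since
    heavily overexpressing strains still divide.  Deterministic: five fixed
    initializations, best residual sum of squares wins, ties to the first.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(means, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and means must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    if np.any(x < 0):
        raise ValueError("protein levels must be nonnegative")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant response: R-squared undefined (zero total variance)")

    span = max(float(y.max() - y.min()), 1e-12)
    best = None
    for b0 in _DECAY_STARTS:
        theta0 = np.array([span, b0, float(y.min())])

        def resid(theta: np.ndarray) -> np.ndarray:
            a, b, c = theta
            return a * np.exp(-b * x) + c - y

        res = least_squares(
            resid,
            x0=theta0,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            method="trf",
            ftol=1e-12,
            xtol=1e-12,
            max_nfev=2000,
        )
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
    rss, res = best
    a, b, c = (float(v) for v in res.x)
    return DoseResponseFit(
        a=a, b=b, c=c,
        r_squared=1.0 - rss / ss_tot,
        converged=bool(res.success),
    )


def population_age_fraction(a: int) -> float:
    """Fraction of cells aged >= a generations in an exponentially growing
    budding population, under the symmetric-budding geometric-age model:
    half the population is newborn and each age class halves, so the
    fraction is 2**(-a)."""
    if a < 0:
        raise ValueError("age must be a nonnegative integer")
    return 2.0 ** (-a)
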