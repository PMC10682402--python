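"""Screen statistics: Z tests, screen classification, Pearson correlation,
hypergeometric enrichment, BH FDR, dose-response fitting."""

import dataclasses
import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from yeastrls import (
    FitResult,
    LifespanSummary,
    MomentSummary,
    WeibullParams,
    bh_fdr,
    classify_screen,
    fit_exp_decay,
    full_summary,
    hypergeom_enrichment,
    pearson,
    population_age_fraction,
    two_sample_z,
)


def _summary(mean, sd, n):
    return MomentSummary(mean=mean, sd=sd, sem=sd / math.sqrt(n), n=n)


def _lifespan_summary(strain, mean, sd, n):
    """LifespanSummary with moments set directly (params chosen to match the
    mean so the screen's fold-change bookkeeping stays consistent)."""
    r = 1.0 / mean  # exponential law has mean 1/r
    fit = FitResult(
        params=WeibullParams(r, 1.0), init_params=WeibullParams(r, 1.0),
        rss=0.0, n_points_fit=10, converged=True, n_total=n, n_censored=0,
    )
    return LifespanSummary(strain_id=strain, scope="pooled", fit=fit,
                           moments=_summary(mean, sd, n))


class TestTwoSampleZ:
    def test_identical_summaries(self):
        s = _summary(23.0, 6.0, 200)
        cmp = two_sample_z(s, s)
        assert cmp.z == 0.0
        assert cmp.p_two_sided == pytest.approx(1.0)
        assert cmp.p_one_sided_right == pytest.approx(0.5)
        assert not cmp.significant

    def test_hand_worked_example(self):
        """(36, 8, 200) vs (23, 6, 200): z = 13 / sqrt(0.5)."""
        cmp = two_sample_z(_summary(36, 8, 200), _summary(23, 6, 200), sided="right")
        assert cmp.z == pytest.approx(13 / math.sqrt(0.5), rel=1e-10)
        assert cmp.z == pytest.approx(18.3848, abs=1e-4)
        assert cmp.p_one_sided_right < 1e-70
        assert cmp.significant

    def test_swap_negates_z_and_preserves_two_sided_p(self):
        a, b = _summary(30, 7, 150), _summary(25, 5, 150)
        fwd, rev = two_sample_z(a, b), two_sample_z(b, a)
        assert rev.z == pytest.approx(-fwd.z)
        assert rev.p_two_sided == pytest.approx(fwd.p_two_sided)

    def test_deep_tail_accuracy(self):
        """p ~ 1e-39 scale values (|z| ~ 13) survive without underflow."""
        cmp = two_sample_z(_summary(30, 5, 300), _summary(24.5, 5.2, 300), sided="right")
        assert 0 < cmp.p_one_sided_right < 1e-30
        assert cmp.p_one_sided_right == pytest.approx(
            scipy.stats.norm.sf(cmp.z), rel=1e-10
        )

    def test_both_sds_zero_is_typed_error(self):
        with pytest.raises(ZeroDivisionError):
            two_sample_z(_summary(20, 0.0, 10), _summary(20, 0.0, 10))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        m1=st.floats(5, 40), m2=st.floats(5, 40),
        sd1=st.floats(0.5, 15), sd2=st.floats(0.5, 15),
    )
    def test_sided_p_consistency(self, m1, m2, sd1, sd2):
        cmp = two_sample_z(_summary(m1, sd1, 200), _summary(m2, sd2, 200))
        pr = cmp.p_one_sided_right
        assert cmp.p_two_sided == pytest.approx(2 * min(pr, 1 - pr), abs=1e-12)


class TestClassifyScreen:
    def test_wildtype_row_is_reference(self):
        wt = _lifespan_summary("WT", 23.0, 6.0, 200)
        table = classify_screen([wt], "WT")
        row = table.iloc[0]
        assert row.fold_change_vs_wt == 1.0 and not row.significant

    def test_hand_computed_significance(self):
        """Three synthetic strains with hand-set (mean, sd, n): z vs the wild
        type (23, 6, 200) is 18.38 (sig), 1.58 (not), and negative (not)."""
        summaries = [
            _lifespan_summary("WT", 23.0, 6.0, 200),
            _lifespan_summary("long", 36.0, 8.0, 200),
            _lifespan_summary("slight", 24.0, 6.6, 200),
            _lifespan_summary("short", 18.0, 5.0, 200),
        ]
        table = classify_screen(summaries, "WT").set_index("strain")
        assert table.loc["long", "significant"]
        assert not table.loc["slight", "significant"]
        assert not table.loc["short", "significant"]
        assert table.loc["long", "z_vs_wt"] == pytest.approx(18.3848, abs=1e-4)
        assert table.loc["long", "fold_change_vs_wt"] == pytest.approx(36 / 23)

    def test_bh_correction_never_adds_significance(self):
        rng = np.random.default_rng(5)
        summaries = [_lifespan_summary("WT", 23.0, 6.0, 200)] + [
            _lifespan_summary(f"s{i}", rng.uniform(20, 30), rng.uniform(4, 9), 200)
            for i in range(30)
        ]
        raw = classify_screen(summaries, "WT")
        bh = classify_screen(summaries, "WT", correction="BH")
        raw_set = set(raw[raw.significant].strain)
        bh_set = set(bh[bh.significant].strain)
        assert bh_set <= raw_set

    def test_missing_wildtype_errors(self):
        with pytest.raises(KeyError):
            classify_screen([_lifespan_summary("a", 20, 5, 200)], "WT")


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
            ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert pearson(x, y).pcc == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30)
            ours = pearson(x, y).pcc
            ref = scipy.stats.pearsonr(x, y).statistic
            assert ours == pytest.approx(ref, abs=1e-12)
            assert abs(ours) <= 1

    def test_self_correlation_is_one(self):
        x = np.random.default_rng(3).normal(size=50)
        assert pearson(x, x).pcc == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])


def _brute_force_upper_tail(N, K, n, k):
    """P(X >= k) by enumerating all C(N, n) draws from a universe where the
    first K elements are annotated."""
    annotated = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestHypergeomEnrichment:
    def _run_single(self, N, K, n, k_hits):
        universe = [f"g{i}" for i in range(N)]
        annotations = {"T": set(universe[:K])}
        hits = universe[:k_hits] + universe[K : K + (n - k_hits)]
        return hypergeom_enrichment(hits, annotations, universe)[0]

    def test_toy_worked_example(self):
        """N=10, K=5, n=4, k=4: p = C(5,4)/C(10,4) = 5/210."""
        res = self._run_single(10, 5, 4, 4)
        assert res.p == pytest.approx(5 / 210, rel=1e-12)
        assert res.enrichment_score == pytest.approx(-math.log10(5 / 210), rel=1e-12)

    def test_fully_annotated_universe_gives_p_one(self):
        res = self._run_single(8, 8, 3, 3)
        assert res.p == pytest.approx(1.0)

    def test_enrichment_score_definition(self):
        assert -math.log10(0.01) == pytest.approx(2.0)
        res = self._run_single(10, 5, 4, 4)
        assert res.enrichment_score == pytest.approx(-math.log10(res.p))

    def test_hits_outside_universe_listed(self):
        with pytest.raises(ValueError, match="gX"):
            hypergeom_enrichment(["gX"], {"T": {"g0"}}, ["g0", "g1"])

    def test_exhaustive_enumeration_oracle(self):
        """Upper-tail p equals brute-force enumeration over all C(N, n)
        draws for every configuration with N <= 9 (the acceptance suite
        extends the sweep to N <= 12)."""
        for N in range(1, 10):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(K, n) + 1):
                        expected = _brute_force_upper_tail(N, K, n, k)
                        observed = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
                        assert observed == pytest.approx(expected, abs=1e-12), (N, K, n, k)


class TestBhFdr:
    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_reference_implementation(self):
        """Adjusted values equal statsmodels' BH step-up on 100 random
        p-vectors, stay sorted-monotone, and never exceed 1."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = rng.integers(1, 40)
            p = rng.random(m)
            ours = bh_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(ref, abs=1e-12)
            order = np.argsort(p)
            assert np.all(np.diff(ours[order]) >= -1e-15)
            assert np.all(ours <= 1.0)


class TestDoseResponse:
    def test_noiseless_recovery(self):
        x = np.arange(0, 2.25, 0.25)
        y = 30 * np.exp(-1.5 * x) + 6
        fit = fit_exp_decay(x, y)
        assert (fit.a, fit.b, fit.c) == pytest.approx((30, 1.5, 6), abs=1e-5)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_shift_moves_only_asymptote(self):
        x = np.arange(0, 2.25, 0.25)
        y = 30 * np.exp(-1.5 * x) + 6
        base = fit_exp_decay(x, y)
        shifted = fit_exp_decay(x, y + 5)
        assert shifted.a == pytest.approx(base.a, abs=1e-4)
        assert shifted.b == pytest.approx(base.b, abs=1e-4)
        assert shifted.c == pytest.approx(base.c + 5, abs=1e-4)

    def test_noisy_dose_series(self):
        """Six-point dose series emulating a promoter-strength titration:
        fitted curve decreasing, R^2 > 0.9."""
        levels = np.array([0.0, 0.4, 1.0, 2.0, 5.0, 9.0])
        rng = np.random.default_rng(8)
        means = 14 * np.exp(-0.9 * levels) + 22 + rng.normal(0, 0.4, 6)
        fit = fit_exp_decay(levels, means)
        assert fit.b > 0
        preds = fit.predict(np.linspace(0, 9, 50))
        assert np.all(np.diff(preds) < 0)
        assert fit.r_squared > 0.9

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            fit_exp_decay([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exp_decay([0, 1, 2], [3, 2, 1])


class TestPopulationAgeFraction:
    @pytest.mark.parametrize("a,expected", [(0, 1.0), (1, 0.5), (5, 0.03125)])
    def test_geometric_halving(self, a, expected):
        assert population_age_fraction(a) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            population_age_fraction(-1)


class TestScreenTypeIError:
    def test_null_rejection_rate_near_nominal(self, default_sim, reseed):
        """Right-sided screen of identical strains rejects at ~5%: 300 null
        pairs here as a smoke check (acceptance runs the full 2000)."""
        from yeastrls import fit_records, simulate_experiment

        rej = 0
        n_pairs = 300
        for i in range(n_pairs):
            a = fit_records(simulate_experiment(reseed(default_sim, 40_000 + 2 * i), "a"))
            b = fit_records(simulate_experiment(reseed(default_sim, 40_001 + 2 * i), "b"))
            rej += two_sample_z(a.moments, b.moments, sided="right").significant
        assert 0.02 <= rej / n_pairs <= 0.09

    def test_power_against_strong_effect(self, default_sim, reseed):
        """A strain with true mean 1.5x the wild-type's is flagged in every
        one of 40 replicate screens (power > 0.99 at n=200)."""
        from yeastrls import fit_records, simulate_experiment

        wt_params = default_sim.true_params
        long_params = WeibullParams(wt_params.r / 1.5, wt_params.alpha)
        flags = 0
        for i in range(40):
            wt = fit_records(
                simulate_experiment(reseed(default_sim, 60_000 + 2 * i), "wt"))
            mut_sim = dataclasses.replace(
                reseed(default_sim, 60_001 + 2 * i), true_params=long_params)
            mut = fit_records(simulate_experiment(mut_sim, "mut"))
            flags += two_sample_z(mut.moments, wt.moments, sided="right").significant
        assert flags == 40
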