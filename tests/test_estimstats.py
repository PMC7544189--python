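"""Normality gate, BCa bootstrap effect sizes, and the 2x2 comparison suite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protrudyn.errors import GateError, StructuralError
from protrudyn.estimstats import (
    PLANNED_COMPARISONS,
    bootstrap_mean_diff,
    compare_all,
    shapiro_gate,
)


def _design_frame(rng, shift=None, n=15):
    rows = []
    for g in ("WT", "KO"):
        for p in ("EGFP", "PANX1-EGFP"):
            vals = rng.normal(10.0, 2.0, size=n)
            if shift and (g, p) == shift[0]:
                vals += shift[1]
            for v in vals:
                rows.append({"genotype": g, "plasmid": p, "turnover_pct": v})
    return pd.DataFrame(rows)


class TestShapiroGate:
    def test_normal_groups_route_parametric_at_expected_rate(self):
        # operating characteristic: the gate rejects whenever any of the
        # four groups fails Shapiro-Wilk at alpha = 0.05, so with genuinely
        # normal samples it picks the parametric branch with probability
        # 0.95**4 ~ 81.5 %; check within 3 binomial SE over 100 datasets
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, 1, 30) for _ in range(4)]
            hits += shapiro_gate(groups) == "parametric"
        expected = 0.95**4
        se = np.sqrt(expected * (1 - expected) / 100)
        assert abs(hits / 100 - expected) <= 3 * se

    def test_skewed_group_routes_nonparametric(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, 1, 30) for _ in range(3)]
            groups.append(rng.exponential(1.0, 30) ** 2)
            hits += shapiro_gate(groups) == "nonparametric"
        assert hits >= 90

    def test_constant_group_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            route = shapiro_gate([np.zeros(10), np.random.default_rng(0).normal(size=10)])
        assert route == "nonparametric"

    def test_tiny_group_rejected(self):
        with pytest.raises(GateError):
            shapiro_gate([np.array([1.0, 2.0])])


class TestBootstrapMeanDiff:
    def test_identical_groups_centered_on_zero(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(5, 1, 20)
        res = bootstrap_mean_diff(vals, vals.copy(), n_boot=2000, seed=1)
        assert res.effect_size == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_degenerate_means_exact(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = bootstrap_mean_diff(
                np.array([0.0, 0.0]), np.array([1.0, 1.0]), seed=2
            )
        assert res.effect_size == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        r1 = bootstrap_mean_diff(a, b, n_boot=1000, seed=7)
        r2 = bootstrap_mean_diff(a, b, n_boot=1000, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_agrees_with_scipy_bca(self):
        rng = np.random.default_rng(16)
        control = rng.normal(10, 2, 20)
        test = rng.normal(12, 2, 20)
        ours = bootstrap_mean_diff(control, test, n_boot=9999, seed=3)

        def statistic(c, t):
            return t.mean() - c.mean()

        ref = stats.bootstrap(
            (control, test),
            lambda c, t, axis: t.mean(axis=axis) - c.mean(axis=axis),
            n_resamples=9999,
            method="BCa",
            vectorized=True,
            random_state=np.random.default_rng(99),
        )
        width = ref.confidence_interval.high - ref.confidence_interval.low
        assert ours.ci_low == pytest.approx(
            ref.confidence_interval.low, abs=0.15 * width
        )
        assert ours.ci_high == pytest.approx(
            ref.confidence_interval.high, abs=0.15 * width
        )

    def test_bca_reduces_to_percentile_for_symmetric_fixture(self):
        # symmetric groups make the jackknife acceleration exactly 0 and the
        # bias correction ~0, so BCa must coincide with the percentile bounds
        control = np.tile([-1.0, 1.0], 10) + 5.0
        test = np.tile([-1.0, 1.0], 10) + 7.0
        bca = bootstrap_mean_diff(control, test, n_boot=4000, seed=4, method="bca")
        pct = bootstrap_mean_diff(
            control, test, n_boot=4000, seed=4, method="percentile"
        )
        width = pct.ci_high - pct.ci_low
        assert bca.ci_low == pytest.approx(pct.ci_low, abs=0.05 * width)
        assert bca.ci_high == pytest.approx(pct.ci_high, abs=0.05 * width)

    def test_convergence_with_resample_count(self):
        # doubling n_boot moves each bound by < 5 % of the CI width (median
        # over 20 seeds)
        rng = np.random.default_rng(17)
        control = rng.normal(10, 2, 15)
        test = rng.normal(12, 2, 15)
        shifts = []
        for seed in range(20):
            r1 = bootstrap_mean_diff(control, test, n_boot=2000, seed=seed)
            r2 = bootstrap_mean_diff(control, test, n_boot=4000, seed=seed)
            width = r1.ci_high - r1.ci_low
            shifts.append(
                max(abs(r1.ci_low - r2.ci_low), abs(r1.ci_high - r2.ci_high))
                / width
            )
        assert np.median(shifts) < 0.05


class TestCompareAll:
    def test_missing_group_is_structural_error(self):
        rng = np.random.default_rng(18)
        df = _design_frame(rng)
        df = df[~((df.genotype == "KO") & (df.plasmid == "EGFP"))]
        with pytest.raises(StructuralError, match="KO-EGFP"):
            compare_all(df, "turnover_pct")

    def test_four_planned_estimates_emitted(self):
        rng = np.random.default_rng(19)
        tests, estimates = compare_all(
            _design_frame(rng), "turnover_pct", n_boot=200, seed=5
        )
        assert [e.comparison for e in estimates] == [
            f"{a} vs {b}" for a, b in PLANNED_COMPARISONS
        ]
        pairwise = [t for t in tests if " vs " in t.comparison]
        assert len(pairwise) == 4

    def test_bonferroni_never_decreases_p(self):
        rng = np.random.default_rng(20)
        tests, _ = compare_all(_design_frame(rng), "turnover_pct", n_boot=200, seed=6)
        for t in tests:
            assert t.p_adjusted >= t.p_raw - 1e-12
            assert t.p_adjusted <= 1.0

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(21)
        df = _design_frame(rng)
        t1, e1 = compare_all(df, "turnover_pct", n_boot=500, seed=11)
        t2, e2 = compare_all(df, "turnover_pct", n_boot=500, seed=11)
        assert [(x.statistic, x.p_adjusted) for x in t1] == [
            (x.statistic, x.p_adjusted) for x in t2
        ]
        assert [(x.ci_low, x.ci_high) for x in e1] == [
            (x.ci_low, x.ci_high) for x in e2
        ]

    def test_injected_effect_detected_in_right_comparisons(self):
        # a 2-SD shift in the KO/PANX1-EGFP group should make that group's
        # two planned comparisons carry the smallest adjusted p values in
        # most datasets
        wins = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            df = _design_frame(rng, shift=(("KO", "PANX1-EGFP"), 4.0))
            tests, _ = compare_all(df, "turnover_pct", n_boot=50, seed=seed)
            pairwise = {t.comparison: t.p_adjusted for t in tests if " vs " in t.comparison}
            smallest = min(pairwise, key=pairwise.get)
            wins += "KO-PANX1-EGFP" in smallest
        assert wins >= 0.8 * n_rep

    def test_nonparametric_route_on_skewed_data(self):
        rng = np.random.default_rng(22)
        df = _design_frame(rng)
        df.loc[df.genotype == "WT", "turnover_pct"] = (
            rng.exponential(1.0, size=(df.genotype == "WT").sum()) ** 2
        )
        tests, _ = compare_all(df, "turnover_pct", n_boot=100, seed=8)
        assert tests[0].test == "Kruskal-Wallis"
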