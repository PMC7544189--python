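"""Estimation statistics for 2×2 group comparisons of dynamics metrics.

The workflow mirrors common practice for this kind of cell-level data:

1. A Shapiro–Wilk normality gate over all groups routes the analysis to a
   parametric branch (two-way ANOVA with Bonferroni-corrected pairwise
   t tests) or a nonparametric branch (Kruskal–Wallis omnibus with
   Bonferroni-corrected pairwise rank-sum comparisons).
2. Independently of the null-hypothesis tests, each planned comparison gets
   an estimation-statistics summary: the difference of group means with a
   bias-corrected-and-accelerated (BCa) bootstrap 95 % confidence interval
   (5000 resamples by default, acceleration from a leave-one-out jackknife).

The design has two factors — genotype ∈ {WT, KO} and plasmid ∈
{EGFP, PANX1-EGFP} — and four planned comparisons, all against or within the
EGFP/KO axes (every group vs WT-EGFP, plus KO-EGFP vs KO-PANX1-EGFP), so the
Bonferroni multiplier is 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from protrudyn.errors import GateError, StructuralError

__all__ = [
    "EstimationResult",
    "TestResult",
    "PLANNED_COMPARISONS",
    "shapiro_gate",
    "bootstrap_mean_diff",
    "compare_all",
]

GENOTYPES = ("WT", "KO")
PLASMIDS = ("EGFP", "PANX1-EGFP")

#: The four planned comparisons, as (control group, test group) labels.
PLANNED_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("WT-EGFP", "KO-EGFP"),
    ("WT-EGFP", "WT-PANX1-EGFP"),
    ("WT-EGFP", "KO-PANX1-EGFP"),
    ("KO-EGFP", "KO-PANX1-EGFP"),
)
BONFERRONI_M = len(PLANNED_COMPARISONS)


@dataclass
class EstimationResult:
    """Mean-difference effect size with bootstrap confidence interval."""

    comparison: str
    effect_size: float  # mean(test) - mean(control), metric units
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    method: str = "bca"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.effect_size <= self.ci_high):
            warnings.warn(
                f"{self.comparison}: BCa interval "
                f"[{self.ci_low:.4g}, {self.ci_high:.4g}] excludes the point "
                f"estimate {self.effect_size:.4g} (pathological resample "
                "distribution)",
                stacklevel=2,
            )


@dataclass
class TestResult:
    """One null-hypothesis test (omnibus or pairwise)."""

    test: str
    comparison: str
    statistic: float
    df: float | tuple[float, float] | None
    p_raw: float
    p_adjusted: float  # min(1, p_raw * m); equals p_raw for omnibus rows


def shapiro_gate(groups: list[np.ndarray], alpha: float = 0.05) -> str:
    """Route to ``"parametric"`` or ``"nonparametric"``.

    The route is nonparametric as soon as any group rejects Shapiro–Wilk
    normality at ``alpha``. Constant (zero-variance) groups are degenerate and
    routed nonparametric with a warning. Groups smaller than 3 cannot be
    tested and raise :class:`GateError`.
    """
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            raise GateError(f"group {i} has n={g.size} < 3; cannot test normality")
        if np.ptp(g) == 0:
            warnings.warn(
                f"group {i} is constant; normality undefined, routing "
                "nonparametric",
                stacklevel=2,
            )
            return "nonparametric"
        if stats.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def bootstrap_mean_diff(
    control: np.ndarray,
    test: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
    ci: float = 0.95,
    method: str = "bca",
    comparison: str = "test vs control",
) -> EstimationResult:
    """Difference of means with a bias-corrected bootstrap interval.

    The effect size is ``mean(test) − mean(control)``. Both groups are
    resampled independently ``n_boot`` times. ``method="bca"`` (default)
    applies bias correction plus jackknife-estimated acceleration;
    ``method="bc"`` applies bias correction only; ``method="percentile"``
    returns the plain percentile interval. Deterministic for a fixed seed.
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if control.size < 2 or test.size < 2:
        raise GateError("both groups need n >= 2 for the bootstrap")
    effect = float(test.mean() - control.mean())
    if np.ptp(control) == 0 and np.ptp(test) == 0:
        warnings.warn(
            "zero variance in both groups; interval collapses to the point "
            "estimate",
            stacklevel=2,
        )
        return EstimationResult(comparison, effect, effect, effect, n_boot, seed, method)
    rng = np.random.default_rng(seed)
    idx_c = rng.integers(0, control.size, size=(n_boot, control.size))
    idx_t = rng.integers(0, test.size, size=(n_boot, test.size))
    boots = test[idx_t].mean(axis=1) - control[idx_c].mean(axis=1)
    alpha = 1.0 - ci
    if method == "percentile":
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        return EstimationResult(comparison, effect, float(lo), float(hi), n_boot, seed, method)
    # bias correction: z0 from the fraction of resamples below the estimate
    prop = (np.sum(boots < effect) + 0.5 * np.sum(boots == effect)) / n_boot
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1 - 1.0 / (2 * n_boot))
    z0 = stats.norm.ppf(prop)
    if method == "bca":
        accel = _jackknife_acceleration(control, test)
    elif method == "bc":
        accel = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    z_lo, z_hi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    q_lo = stats.norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo)))
    q_hi = stats.norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi)))
    lo, hi = np.quantile(boots, [q_lo, q_hi])
    return EstimationResult(comparison, effect, float(lo), float(hi), n_boot, seed, method)


def _jackknife_acceleration(control: np.ndarray, test: np.ndarray) -> float:
    """Acceleration from leave-one-out estimates across both groups."""
    mc, mt = control.mean(), test.mean()
    loo_c = mt - (control.sum() - control) / (control.size - 1)
    loo_t = (test.sum() - test) / (test.size - 1) - mc
    theta = np.concatenate([loo_c, loo_t])
    d = theta.mean() - theta
    denom = np.sum(d**2) ** 1.5
    if denom == 0:
        return 0.0
    return float(np.sum(d**3) / (6.0 * denom))


def compare_all(
    per_cell: pd.DataFrame,
    metric: str,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    genotype_col: str = "genotype",
    plasmid_col: str = "plasmid",
) -> tuple[list[TestResult], list[EstimationResult]]:
    """Full statistical workflow for one metric over the 2×2 design.

    Runs the normality gate, then either a two-way ANOVA (genotype, plasmid,
    interaction) with Bonferroni-corrected pairwise t tests, or a
    Kruskal–Wallis omnibus with Bonferroni-corrected pairwise rank-sum
    comparisons. The four planned bootstrap effect sizes are always emitted,
    each with a seed derived deterministically from ``seed``.
    """
    for col in (genotype_col, plasmid_col, metric):
        if col not in per_cell.columns:
            raise StructuralError(f"missing column {col!r}")
    labels = per_cell[genotype_col].astype(str) + "-" + per_cell[plasmid_col].astype(str)
    expected = [f"{g}-{p}" for g in GENOTYPES for p in PLASMIDS]
    missing = [g for g in expected if g not in set(labels)]
    if missing:
        raise StructuralError(f"design incomplete; absent groups: {missing}")
    values = {g: per_cell.loc[labels == g, metric].to_numpy(dtype=float) for g in expected}

    route = shapiro_gate([values[g] for g in expected], alpha=alpha)
    tests: list[TestResult] = []
    if route == "parametric":
        df = per_cell[[genotype_col, plasmid_col, metric]].rename(
            columns={genotype_col: "genotype", plasmid_col: "plasmid", metric: "value"}
        )
        model = ols("value ~ C(genotype) * C(plasmid)", data=df).fit()
        table = anova_lm(model, typ=2)
        for term, row_name in (
            ("genotype", "C(genotype)"),
            ("plasmid", "C(plasmid)"),
            ("interaction", "C(genotype):C(plasmid)"),
        ):
            row = table.loc[row_name]
            tests.append(
                TestResult(
                    test="two-way ANOVA",
                    comparison=term,
                    statistic=float(row["F"]),
                    df=(float(row["df"]), float(table.loc["Residual", "df"])),
                    p_raw=float(row["PR(>F)"]),
                    p_adjusted=float(row["PR(>F)"]),
                )
            )
        for a, b in PLANNED_COMPARISONS:
            res = stats.ttest_ind(values[b], values[a])
            tests.append(
                TestResult(
                    test="pairwise t (Bonferroni)",
                    comparison=f"{a} vs {b}",
                    statistic=float(res.statistic),
                    df=float(values[a].size + values[b].size - 2),
                    p_raw=float(res.pvalue),
                    p_adjusted=min(1.0, float(res.pvalue) * BONFERRONI_M),
                )
            )
    else:
        h, p = stats.kruskal(*(values[g] for g in expected))
        tests.append(
            TestResult(
                test="Kruskal-Wallis",
                comparison="omnibus",
                statistic=float(h),
                df=float(len(expected) - 1),
                p_raw=float(p),
                p_adjusted=float(p),
            )
        )
        for a, b in PLANNED_COMPARISONS:
            res = stats.mannwhitneyu(values[b], values[a], alternative="two-sided")
            tests.append(
                TestResult(
                    test="pairwise rank-sum (Bonferroni)",
                    comparison=f"{a} vs {b}",
                    statistic=float(res.statistic),
                    df=None,
                    p_raw=float(res.pvalue),
                    p_adjusted=min(1.0, float(res.pvalue) * BONFERRONI_M),
                )
            )
    estimates = [
        bootstrap_mean_diff(
            values[a],
            values[b],
            n_boot=n_boot,
            seed=_derive_seed(seed, i),
            comparison=f"{a} vs {b}",
        )
        for i, (a, b) in enumerate(PLANNED_COMPARISONS)
    ]
    return tests, estimates


def _derive_seed(seed: int, stream: int) -> int:
    """Distinct deterministic sub-seed per comparison, below 2**31."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))
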