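"""Statistics for the functional-validation assays.

Covers the effect measures and hypothesis tests used to quantify knockdown
phenotypes: percent change versus control, scratch-wound closure, the
chi-square goodness-of-fit test of tip-competition counts against a 50:50
null, and the group-comparison tests (unpaired t-test for two groups,
one-way ANOVA with Tukey HSD post-hoc for three or more).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompetitionCounts",
    "TestResult",
    "percent_change",
    "wound_closure",
    "competition_chisq",
    "pooled_competition_chisq",
    "group_comparison",
    "assay_table_comparison",
]


@dataclass(frozen=True)
class CompetitionCounts:
    """Tip-occupancy counts from mosaic spheroids: k silenced-led tips of n total."""

    k_silenced_at_tip: int
    n_tips_total: int
    p0: float = 0.5

    def __post_init__(self) -> None:
        if self.n_tips_total < 1:
            raise ValueError("need at least one tip")
        if not (0 <= self.k_silenced_at_tip <= self.n_tips_total):
            raise ValueError("k must lie in [0, n]")
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie in (0, 1)")


@dataclass
class TestResult:
    """One test's outcome: named statistic, degrees of freedom, p, effect summary."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "effect": self.effect,
            "flags": self.flags,
        }


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Percent reduction of the treated mean relative to control.

    Positive values are reductions; an increase comes back negative.
    """
    if control_mean <= 0:
        raise ValueError(f"control_mean must be positive, got {control_mean}")
    return (1.0 - treated_mean / control_mean) * 100.0


def wound_closure(gap_t0: float, gap_t18: float) -> float:
    """Scratch-wound closure: (gap at T0 - gap at T18) as % of the T0 gap.

    Negative closure (the gap widened) is allowed and simply comes back
    negative.
    """
    if gap_t0 <= 0:
        raise ValueError(f"gap_t0 must be positive, got {gap_t0}")
    if gap_t18 < 0:
        raise ValueError(f"gap_t18 must be non-negative, got {gap_t18}")
    return (gap_t0 - gap_t18) / gap_t0 * 100.0


def competition_chisq(counts: CompetitionCounts) -> TestResult:
    """Chi-square goodness-of-fit of tip counts against the expected split.

    Two cells (silenced-led, control-led tips), expected n*p0 and n*(1-p0),
    df = 1, upper-tail p.  No continuity correction is applied — the plain
    two-cell Pearson statistic.  Expected counts below 5 raise a
    small-sample flag rather than an error.
    """
    k, n, p0 = counts.k_silenced_at_tip, counts.n_tips_total, counts.p0
    e1, e2 = n * p0, n * (1 - p0)
    chi2 = (k - e1) ** 2 / e1 + ((n - k) - e2) ** 2 / e2
    p = float(stats.chi2.sf(chi2, df=1))
    flags = []
    if min(e1, e2) < 5:
        flags.append("expected count < 5: chi-square approximation unreliable")
    return TestResult(
        name="chi2_gof",
        statistic=float(chi2),
        df=1.0,
        p_value=p,
        effect={"observed_fraction": k / n, "expected_fraction": p0},
        flags=flags,
    )


def pooled_competition_chisq(per_replicate: list[CompetitionCounts]) -> TestResult:
    """Chi-square on counts pooled across replicates (all must share p0)."""
    if not per_replicate:
        raise ValueError("no replicates")
    p0s = {c.p0 for c in per_replicate}
    if len(p0s) != 1:
        raise ValueError("replicates disagree on p0")
    k = sum(c.k_silenced_at_tip for c in per_replicate)
    n = sum(c.n_tips_total for c in per_replicate)
    return competition_chisq(CompetitionCounts(k, n, p0=p0s.pop()))


def _validate_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has {arr.size} replicates (< 2)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        clean[name] = arr
    return clean


def group_comparison(
    groups: dict[str, np.ndarray],
    design: str = "auto",
    welch: bool = False,
) -> list[TestResult]:
    """Two-group t-test or one-way ANOVA with Tukey HSD, per the study design.

    ``design`` is ``two_group_t``, ``oneway_anova_tukey``, or ``auto`` (pick
    by group count: 2 -> t-test, >= 3 -> ANOVA + Tukey).  The t-test is the
    equal-variance Student test by default, matching the unpaired two-tailed
    convention; ``welch=True`` drops the equal-variance assumption.  Tukey
    adjusted p-values come from the studentized-range distribution.
    """
    clean = _validate_groups(groups)
    names = list(clean)
    k = len(names)
    if design == "auto":
        design = "two_group_t" if k == 2 else "oneway_anova_tukey"
    if design == "two_group_t":
        if k != 2:
            raise ValueError(f"two_group_t needs exactly 2 groups, got {k}")
        a, b = clean[names[0]], clean[names[1]]
        flags: list[str] = []
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            # degenerate case: no within-group variability
            if a.mean() == b.mean():
                statistic, dfree, p = 0.0, float(a.size + b.size - 2), 1.0
            else:
                statistic = np.inf if a.mean() > b.mean() else -np.inf
                dfree, p = float(a.size + b.size - 2), float(np.finfo(float).tiny)
                flags.append("zero pooled variance with unequal means")
        else:
            res = stats.ttest_ind(a, b, equal_var=not welch)
            statistic, dfree, p = float(res.statistic), float(res.df), float(res.pvalue)
        reduction = percent_change(a.mean(), b.mean()) if a.mean() > 0 else np.nan
        return [
            TestResult(
                name="welch_t" if welch else "student_t",
                statistic=statistic,
                df=dfree,
                p_value=p,
                effect={
                    "mean_" + names[0]: float(a.mean()),
                    "mean_" + names[1]: float(b.mean()),
                    "percent_change_vs_" + names[0]: float(reduction),
                },
                flags=flags,
            )
        ]
    if design == "oneway_anova_tukey":
        if k < 3:
            raise ValueError(f"oneway_anova_tukey needs >= 3 groups, got {k}")
        arrays = [clean[n] for n in names]
        f_res = stats.f_oneway(*arrays)
        n_total = sum(a.size for a in arrays)
        results = [
            TestResult(
                name="anova_f",
                statistic=float(f_res.statistic),
                df=(float(k - 1), float(n_total - k)),
                p_value=float(f_res.pvalue),
                effect={f"mean_{n}": float(clean[n].mean()) for n in names},
            )
        ]
        tukey = stats.tukey_hsd(*arrays)
        for i in range(k):
            for j in range(i + 1, k):
                results.append(
                    TestResult(
                        name=f"tukey_{names[i]}_vs_{names[j]}",
                        statistic=float(tukey.statistic[i, j]),
                        df=(float(k), float(n_total - k)),
                        p_value=float(tukey.pvalue[i, j]),
                        effect={
                            "mean_difference": float(
                                clean[names[i]].mean() - clean[names[j]].mean()
                            )
                        },
                    )
                )
        return results
    raise ValueError(f"unknown design {design!r}")


def assay_table_comparison(table: pd.DataFrame, welch: bool = False) -> list[TestResult]:
    """Run the appropriate group comparison on a tidy assay table.

    Expects columns ``group`` and ``value`` (one row per replicate).
    """
    for col in ("group", "value"):
        if col not in table.columns:
            raise ValueError(f"assay table lacks column {col!r}")
    groups = {
        str(name): sub["value"].to_numpy() for name, sub in table.groupby("group", sort=False)
    }
    return group_comparison(groups, design="auto", welch=welch)
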