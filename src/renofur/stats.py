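"""Longitudinal group statistics for FUR studies.

Implements the normality-gated testing scheme standard in small-animal
nephrotoxicity studies: Shapiro-Wilk on each sample; if both pass at 0.05 a
two-sided t test (paired, or unpaired with Welch correction), otherwise a
two-sided Mann-Whitney U test (exact null distribution for small untied
samples).  Group summaries are mean ± SEM with raw p-values flagged at the
0.05 and 0.01 levels; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "GroupComparison",
    "LongitudinalSummary",
    "test_normality",
    "compare_groups",
    "summarize_study",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Outcome of one two-group contrast, with its normality gate recorded."""

    group_a: str
    group_b: str
    day: int | None
    n_a: int
    n_b: int
    test: str  # t_paired | t_unpaired | mann_whitney
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float
    paired: bool
    significant_05: bool
    significant_01: bool


@dataclass
class LongitudinalSummary:
    """Per-(group, day) mean ± SEM table plus vs-baseline comparisons."""

    summary: pd.DataFrame  # group, day, n, mean, sem
    comparisons: list[GroupComparison] = field(default_factory=list)
    flagged_cells: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Summary joined with the vs-baseline test results."""
        rows = {
            (c.group_a, c.day): c
            for c in self.comparisons
            if c.day is not None
        }
        out = self.summary.copy()
        out["test"] = [
            rows[(g, d)].test if (g, d) in rows else ""
            for g, d in zip(out["group"], out["day"])
        ]
        out["p"] = [
            rows[(g, d)].p_value if (g, d) in rows else np.nan
            for g, d in zip(out["group"], out["day"])
        ]
        out["sig05"] = out["p"] < 0.05
        out["sig01"] = out["p"] < 0.01
        return out


def test_normality(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 50)."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= x.size <= 50):
        raise StatsError(f"Shapiro-Wilk supported for 3 <= n <= 50, got n={x.size}")
    if np.ptp(x) == 0:
        raise StatsError("zero-variance sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool = False,
    name_a: str = "a",
    name_b: str = "b",
    day: int | None = None,
    force_test: str | None = None,
) -> GroupComparison:
    """Two-sided comparison of two samples with a Shapiro-Wilk gate.

    Both samples normal at the 0.05 level -> t test (paired or Welch
    unpaired); either fails -> Mann-Whitney U (exact distribution when the
    combined n <= 20 and there are no ties, otherwise normal approximation
    with tie correction).  ``force_test`` overrides the gate
    ('t' or 'mann_whitney').
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise StatsError("each sample needs n >= 3")
    if paired and a.size != b.size:
        raise StatsError("paired comparison requires equal sample sizes")

    _, p_norm_a = test_normality(a)
    _, p_norm_b = test_normality(b)
    normal = p_norm_a >= ALPHA and p_norm_b >= ALPHA
    if force_test == "t":
        normal = True
    elif force_test == "mann_whitney":
        normal = False
    elif force_test is not None:
        raise StatsError("force_test must be 't', 'mann_whitney' or None")

    if normal:
        if paired:
            stat, p = sps.ttest_rel(a, b)
            test = "t_paired"
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
            test = "t_unpaired"
    else:
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann_whitney"
    return GroupComparison(
        group_a=name_a,
        group_b=name_b,
        day=day,
        n_a=int(a.size),
        n_b=int(b.size),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        shapiro_p_a=p_norm_a,
        shapiro_p_b=p_norm_b,
        paired=paired,
        significant_05=bool(p < 0.05),
        significant_01=bool(p < 0.01),
    )


def summarize_study(
    results: pd.DataFrame,
    baseline_group: str = "baseline",
    baseline_day: int = 0,
    fur_column: str = "fur",
    paired: bool = False,
) -> LongitudinalSummary:
    """Mean ± SEM per (group, day) and vs-baseline tests per follow-up day.

    ``results`` needs columns ``group``, ``day`` and the FUR column.  Every
    non-baseline group at every day > baseline_day is compared against the
    baseline group's baseline-day sample (unpaired by default).  Cells with
    zero variance (or too few mice) cannot be gated/tested and are flagged
    rather than fatal.
    """
    for col in ("group", "day", fur_column):
        if col not in results.columns:
            raise StatsError(f"results table lacks column {col!r}")
    base = results[
        (results["group"] == baseline_group) & (results["day"] == baseline_day)
    ][fur_column].to_numpy()
    if base.size == 0:
        raise StatsError(
            f"no baseline cell ({baseline_group!r}, day {baseline_day})"
        )

    rows = []
    comparisons: list[GroupComparison] = []
    flagged: list[str] = []
    grouped = results.groupby(["day", "group"], sort=True)
    for (day, group), cell in grouped:
        x = cell[fur_column].to_numpy()
        n = x.size
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "group": group,
                "day": int(day),
                "n": n,
                "mean": float(np.mean(x)),
                "sem": sd / np.sqrt(n) if n > 0 else np.nan,
            }
        )
        if group == baseline_group and day == baseline_day:
            continue
        try:
            comparisons.append(
                compare_groups(
                    x,
                    base,
                    paired=paired,
                    name_a=group,
                    name_b=baseline_group,
                    day=int(day),
                )
            )
        except StatsError as exc:
            flagged.append(f"{group}/day{day}: {exc}")
    summary = pd.DataFrame(rows).sort_values(["day", "group"]).reset_index(drop=True)
    return LongitudinalSummary(
        summary=summary, comparisons=comparisons, flagged_cells=flagged
    )
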