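"""Group comparison tables: Welch t-tests and the significance-star convention.

Group means are compared with the two-sided unequal-variance Student's
t-test (Welch's test, Satterthwaite degrees of freedom), the convention in
the microscopy literature this pipeline serves.  Raw p-values are reported
without multiplicity adjustment and annotated with the standard star legend
(* p <= 0.05, ** p <= 0.01, *** p <= 0.001, **** p <= 0.0001).  Standard
deviations use the n-1 (sample) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_LEVELS: tuple[tuple[float, str], ...] = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """(t, dof, p) for the two-sided unequal-variance t-test."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def stars(p: float) -> str:
    """Significance label; thresholds are inclusive (p = 0.05 earns '*')."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    for threshold, label in STAR_LEVELS:
        if p <= threshold:
            return label
    return "ns"


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    dof: float
    p_value: float
    stars: str


@dataclass
class ComparisonTable:
    """Per-group summaries plus all requested pairwise Welch tests."""

    summary: pd.DataFrame  # columns: group keys, mean, sd, n
    comparisons: list[ComparisonResult]
    smallest_value: Optional[float] = None  # e.g. smallest FWHM = resolution proxy
    value_name: str = "value"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "mean_a": c.mean_a,
                "sd_a": c.sd_a,
                "n_a": c.n_a,
                "mean_b": c.mean_b,
                "sd_b": c.sd_b,
                "n_b": c.n_b,
                "t": c.t_stat,
                "dof": c.dof,
                "p": c.p_value,
                "stars": c.stars,
            }
            for c in self.comparisons
        ]
        return pd.DataFrame(rows)

    def render(self) -> str:
        lines = [f"Group summaries ({self.value_name}):"]
        for _, row in self.summary.iterrows():
            label = " / ".join(str(row[c]) for c in self.summary.columns[:-3])
            lines.append(
                f"  {label}: {row['mean']:.4g} ± {row['sd']:.4g} (n = {int(row['n'])})"
            )
        if self.smallest_value is not None:
            lines.append(f"Smallest measured {self.value_name}: {self.smallest_value:.4g}")
        if self.comparisons:
            lines.append("Pairwise Welch tests (two-sided, unequal variances):")
            for c in self.comparisons:
                lines.append(
                    f"  {c.group_a} vs {c.group_b}: "
                    f"{c.mean_a:.4g} ± {c.sd_a:.4g} (n={c.n_a}) vs "
                    f"{c.mean_b:.4g} ± {c.sd_b:.4g} (n={c.n_b}); "
                    f"t = {c.t_stat:.3f}, dof = {c.dof:.1f}, p = {c.p_value:.3g} [{c.stars}]"
                )
        return "\n".join(lines)


def compare_groups(
    label_a: str, values_a: Sequence[float], label_b: str, values_b: Sequence[float]
) -> ComparisonResult:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    t, dof, p = welch_t_test(a, b)
    return ComparisonResult(
        group_a=label_a,
        group_b=label_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=a.size,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=b.size,
        t_stat=t,
        dof=dof,
        p_value=p,
        stars=stars(p),
    )


def build_table(
    records: pd.DataFrame,
    value: str,
    compare: str,
    by: Optional[list[str]] = None,
    report_smallest: bool = True,
) -> ComparisonTable:
    """Summarize ``value`` per group and Welch-test all level pairs of ``compare``.

    ``compare`` names the column whose levels are tested against each other
    (e.g. modality: confocal vs STED); ``by`` optionally stratifies the test
    within each combination of further columns (e.g. channel).  Empty groups
    are dropped with a warning in the table log, not an error.
    """
    import itertools
    import warnings

    by = by or []
    keys = by + [compare]
    grouped = records.groupby(keys, dropna=False)[value]
    summary = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    empty = summary[summary["n"] == 0]
    if len(empty):
        warnings.warn(f"omitting {len(empty)} empty group(s)", stacklevel=2)
        summary = summary[summary["n"] > 0]

    comparisons: list[ComparisonResult] = []
    strata = records.groupby(by, dropna=False) if by else [((), records)]
    for stratum_key, sub in strata:
        if not isinstance(stratum_key, tuple):
            stratum_key = (stratum_key,)
        prefix = "".join(f"{k}/" for k in stratum_key)
        levels = [lvl for lvl, g in sub.groupby(compare, dropna=False) if g[value].count() >= 2]
        for la, lb in itertools.combinations(levels, 2):
            va = sub.loc[sub[compare] == la, value].dropna()
            vb = sub.loc[sub[compare] == lb, value].dropna()
            try:
                comparisons.append(compare_groups(f"{prefix}{la}", va, f"{prefix}{lb}", vb))
            except ValueError as exc:
                warnings.warn(f"skipping {prefix}{la} vs {prefix}{lb}: {exc}", stacklevel=2)

    smallest = float(records[value].min()) if report_smallest and len(records) else None
    return ComparisonTable(
        summary=summary, comparisons=comparisons, smallest_value=smallest, value_name=value
    )
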