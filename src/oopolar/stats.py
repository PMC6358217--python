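"""Group summaries and nonparametric comparisons of per-oocyte metrics.

Per-oocyte metrics (asymmetry ratio, posterior exclusion ratio, cytoplasmic
fraction...) are pooled by genotype/condition and stage, summarized as
mean +/- SEM with Tukey box-plot statistics, and compared pairwise with the
two-sided Mann-Whitney U test.  p-values map to the conventional star
labels (NS, *, **, ***, ****).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

#: combined sample size at or below which the exact null distribution is used
EXACT_LIMIT = 16


@dataclass
class TestResult:
    u_statistic: float
    p_value: float
    method: str            # "exact" or "normal-approximation"
    stars: str
    n1: int
    n2: int


@dataclass
class GroupSummary:
    """Mean +/- SEM plus Tukey box-plot statistics for one group."""

    n: int
    mean: float
    sem: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    sem_degenerate: bool = False   # n == 1; SEM reported as 0 by convention


def stars_for(p: float) -> str:
    """Significance label for a p-value (NS, *, **, ***, ****)."""
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError("p-value must be in [0, 1]")
    for cut, label in STAR_THRESHOLDS:
        if p < cut:
            return label
    return "NS"


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is used when the combined sample size is at
    most :data:`EXACT_LIMIT` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  The method actually
    used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size) <= EXACT_LIMIT and not has_ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return TestResult(u_statistic=float(res.statistic), p_value=p,
                      method="exact" if exact else "normal-approximation",
                      stars=stars_for(p), n1=int(x.size), n2=int(y.size))


def summarize(values) -> GroupSummary:
    """Mean, SEM (SD with n-1 denominator) and Tukey box-plot statistics.

    Whiskers extend to the most extreme data points within 1.5 IQR of the
    quartile hinges.  Quartiles use linear interpolation.  With n = 1 the
    SEM is reported as 0 and flagged.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("cannot summarize an empty sample")
    n = values.size
    mean = float(values.mean())
    degenerate = n == 1
    sem = 0.0 if degenerate else float(values.std(ddof=1) / np.sqrt(n))
    q1, median, q3 = (float(q) for q in np.percentile(values, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return GroupSummary(n=n, mean=mean, sem=sem, median=median, q1=q1, q3=q3,
                        whisker_low=float(inside.min()),
                        whisker_high=float(inside.max()),
                        sem_degenerate=degenerate)


def pairwise_tests(table: pd.DataFrame, metric: str, group: str,
                   stage: str | int | None = None,
                   stage_column: str = "stage") -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons of ``metric`` between groups."""
    if metric not in table or group not in table:
        raise InvalidInputError(f"table must contain {metric!r} and {group!r}")
    if stage is not None:
        table = table[table[stage_column].astype(str) == str(stage)]
    groups = {name: sub[metric].dropna().to_numpy()
              for name, sub in table.groupby(group, sort=True)}
    rows = []
    for (na, a), (nb, b) in itertools.combinations(groups.items(), 2):
        r = mann_whitney(a, b)
        rows.append({"group1": na, "group2": nb, "n1": r.n1, "n2": r.n2,
                     "u_statistic": r.u_statistic, "p_value": r.p_value,
                     "method": r.method, "stars": r.stars})
    return pd.DataFrame(rows)


def group_summaries(table: pd.DataFrame, metric: str, group: str
                    ) -> pd.DataFrame:
    """One :func:`summarize` row per group, as a tidy table."""
    rows = []
    for name, sub in table.groupby(group, sort=True):
        s = summarize(sub[metric].dropna().to_numpy())
        rows.append({"group": name, "n": s.n, "mean": s.mean, "sem": s.sem,
                     "median": s.median, "q1": s.q1, "q3": s.q3,
                     "whisker_low": s.whisker_low,
                     "whisker_high": s.whisker_high})
    return pd.DataFrame(rows)


def tukey_boxplot(table: pd.DataFrame, metric: str, group: str, ax=None):
    """Tukey box plot (1.5 IQR whiskers) of a metric by group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups = {name: sub[metric].dropna().to_numpy()
              for name, sub in table.groupby(group, sort=True)}
    ax.boxplot(list(groups.values()), tick_labels=[str(k) for k in groups],
               whis=1.5)
    ax.set_ylabel(metric)
    ax.set_xlabel(group)
    return ax
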