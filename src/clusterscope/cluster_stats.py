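"""Per-condition cluster statistics: counts per cell, boxplot summaries,
bootstrap standard errors and nonparametric group comparisons.

Conditions are compared with a Kruskal-Wallis omnibus test followed by
two-sided pairwise Mann-Whitney U tests (midranks for ties); error bars on
histogram fractions and summary statistics come from 1000-repeat bootstrap
resampling over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSample",
    "clusters_per_cell",
    "summarize_metric",
    "compare_groups",
    "bootstrap_sem",
]


@dataclass
class GroupSample:
    """Values of one metric for one condition (all replicates combined)."""

    condition: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


def clusters_per_cell(spots, cells, n_boot: int = 1000, seed: int = 0):
    """Count filtered spots per cell and histogram the counts.

    ``spots`` is a list of SpotFit with ``cell_label`` set (only kept fits
    should be passed); ``cells`` a LabelMask (or 2D label array).  Every cell
    label participates, including cells with zero spots.  Returns
    ``(counts_by_cell, histogram_dataframe)`` where the histogram fractions
    sum to 1 and the per-bin SEM comes from ``n_boot`` bootstrap resamples of
    cells.
    """
    labels = cells.labels if hasattr(cells, "labels") else np.asarray(cells)
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        raise ValueError("no cells in mask")
    counts = {int(i): 0 for i in ids}
    for s in spots:
        if s.cell_label in counts:
            counts[s.cell_label] += 1
    vals = np.array(list(counts.values()))
    kmax = int(vals.max())
    bins = np.arange(kmax + 2)
    hist = np.bincount(vals, minlength=kmax + 1) / vals.size

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, kmax + 1))
    for i in range(n_boot):
        sample = vals[rng.integers(0, vals.size, vals.size)]
        boot[i] = np.bincount(sample, minlength=kmax + 1)[:kmax + 1] / vals.size
    sem = boot.std(axis=0, ddof=0)
    df = pd.DataFrame(dict(n_clusters=bins[:-1], fraction=hist, sem=sem))
    return counts, df


def summarize_metric(sample: GroupSample) -> dict:
    """Boxplot summary: quartiles (linear interpolation) and whiskers at the
    most extreme data within 1.5x IQR of the box edges."""
    v = sample.values
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return dict(condition=sample.condition, n=int(v.size), q1=float(q1),
                median=float(med), q3=float(q3),
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()))


def _mwu(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration for small tie-free samples (both n <= 20), otherwise
    the normal approximation with tie and continuity corrections.
    """
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    small = len(a) <= 20 and len(b) <= 20
    no_ties = np.unique(np.concatenate([a, b])).size == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def compare_groups(samples: list[GroupSample]):
    """Kruskal-Wallis omnibus test plus pairwise two-sided Mann-Whitney U.

    Returns ``(kw_pvalue, pairwise_dataframe)`` with the symmetric p-value
    matrix indexed by condition.  All-identical data across every group is
    degenerate: p = 1 everywhere.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.values.size == 0 for s in samples):
        raise ValueError("every group needs at least one value")
    names = [s.condition for s in samples]
    allv = np.concatenate([s.values for s in samples])
    if np.ptp(allv) == 0:
        kw_p = 1.0
        mat = pd.DataFrame(np.ones((len(samples), len(samples))),
                           index=names, columns=names)
        return kw_p, mat
    kw_p = float(stats.kruskal(*[s.values for s in samples]).pvalue)
    mat = pd.DataFrame(np.ones((len(samples), len(samples))),
                       index=names, columns=names)
    for i, j in combinations(range(len(samples)), 2):
        p = _mwu(samples[i].values, samples[j].values)
        mat.iloc[i, j] = mat.iloc[j, i] = p
    return kw_p, mat


def holm_correct(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (optional; raw p-values are the default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def bootstrap_sem(values, statistic=np.mean, n_rep: int = 1000,
                  seed: int = 0) -> float:
    """SD of ``statistic`` over ``n_rep`` resamples with replacement."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, (n_rep, v.size))
    reps = np.array([statistic(v[row]) for row in idx])
    return float(reps.std(ddof=0))
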