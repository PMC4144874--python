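"""Two-group comparison of network features and onset-age correlation.

Nodal and global features are compared with two-sample two-tailed t-tests,
pooled-variance Student form by default (df = n1 + n2 - 2), with Welch's
unequal-variance form available as an option. P-values are reported
uncorrected by default; Benjamini-Hochberg adjusted values can be added as
an extra column. The t statistic is oriented as group1 minus group2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import NODAL_METRIC_COLUMNS

__all__ = [
    "TTestResult",
    "two_tailed_p",
    "two_sample_ttest",
    "compare_nodal_metrics",
    "compare_global_metrics",
    "correlate_onset",
]

GLOBAL_FEATURES = (
    "clustering",
    "path_length",
    "global_efficiency",
    "local_efficiency",
    "eloc_ratio",
    "eglob_ratio",
)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float


def two_tailed_p(t: float, df: float) -> float:
    """Two-sided tail probability of Student's t at |t| with df degrees of
    freedom."""
    return float(2.0 * sps.t.sf(abs(t), df))


def two_sample_ttest(x: Sequence[float], y: Sequence[float], welch: bool = False) -> TTestResult:
    """Two-sample two-tailed t-test, x versus y (statistic oriented x - y).

    Pooled-variance Student form by default; ``welch=True`` switches to the
    unequal-variance Welch form with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(f"need at least 2 values per sample, got {x.size} and {y.size}")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df))


def _safe_row_ttest(x: np.ndarray, y: np.ndarray, welch: bool) -> tuple[float, float, float]:
    """t-test tolerating degenerate rows (e.g. a metric that is constant in
    both groups, as betweenness often is at peripheral nodes)."""
    df = x.size + y.size - 2
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        diff = x.mean() - y.mean()
        if diff == 0:
            return 0.0, 1.0, df
        return float(np.sign(diff) * np.inf), 0.0, df
    with warnings.catch_warnings():
        # nearly identical samples (common for betweenness at peripheral
        # nodes) trigger a scipy precision warning; the test is still valid
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue), float(res.df)


def _resolve_groups(
    groups: Mapping[str, str], group_order: Sequence[str] | None
) -> tuple[str, str]:
    labels = list(dict.fromkeys(groups.values()))
    if group_order is not None:
        labels = list(group_order)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    return labels[0], labels[1]


def _bh_column(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["p_fdr"] = sps.false_discovery_control(table["p"].to_numpy(), method="bh")
    return table


def compare_nodal_metrics(
    tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    group_order: Sequence[str] | None = None,
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests for every (metric, node) pair.

    ``tables`` maps subject id to its nodal metric table (as produced by
    :func:`tractnet.metrics.nodal_metrics`); ``groups`` maps subject id to
    group label. Returns one row per metric x node with columns feature,
    node, mean_g1, mean_g2, T, df, p (uncorrected; ``fdr=True`` appends a
    Benjamini-Hochberg column).
    """
    missing = [s for s in groups if s not in tables]
    if missing:
        raise ValueError(f"missing metric table for subjects: {missing}")
    g1, g2 = _resolve_groups(groups, group_order)
    subjects = list(groups)
    ref_labels = list(tables[subjects[0]]["label"])
    for s in subjects:
        if list(tables[s]["label"]) != ref_labels:
            raise ValueError(f"node labels of subject {s} differ from the rest")
    members = {g: [s for s in subjects if groups[s] == g] for g in (g1, g2)}
    for g, mem in members.items():
        if len(mem) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    rows = []
    for metric in NODAL_METRIC_COLUMNS:
        stacked = {
            g: np.vstack([tables[s][metric].to_numpy(dtype=float) for s in members[g]])
            for g in (g1, g2)
        }
        for node_idx, node in enumerate(ref_labels):
            x = stacked[g1][:, node_idx]
            y = stacked[g2][:, node_idx]
            t, p, df = _safe_row_ttest(x, y, welch)
            rows.append((metric, node, float(x.mean()), float(y.mean()), t, df, p))
    table = pd.DataFrame(
        rows, columns=["feature", "node", "mean_g1", "mean_g2", "T", "df", "p"]
    )
    return _bh_column(table) if fdr else table


def compare_global_metrics(
    values: Mapping[str, Mapping[str, float]],
    groups: Mapping[str, str],
    group_order: Sequence[str] | None = None,
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests for whole-network features.

    ``values`` maps subject id to a mapping of global feature name to
    value; features compared are those in :data:`GLOBAL_FEATURES` that are
    present for every subject, in that fixed order.
    """
    missing = [s for s in groups if s not in values]
    if missing:
        raise ValueError(f"missing global metrics for subjects: {missing}")
    g1, g2 = _resolve_groups(groups, group_order)
    members = {g: [s for s in groups if groups[s] == g] for g in (g1, g2)}
    for g, mem in members.items():
        if len(mem) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    features = [
        f for f in GLOBAL_FEATURES if all(f in values[s] for s in groups)
    ]
    rows = []
    for feat in features:
        x = np.array([values[s][feat] for s in members[g1]], dtype=float)
        y = np.array([values[s][feat] for s in members[g2]], dtype=float)
        t, p, df = _safe_row_ttest(x, y, welch)
        rows.append((feat, "", float(x.mean()), float(y.mean()), t, df, p))
    table = pd.DataFrame(
        rows, columns=["feature", "node", "mean_g1", "mean_g2", "T", "df", "p"]
    )
    return _bh_column(table) if fdr else table


@dataclass(frozen=True)
class OnsetCorrelation:
    r: float
    pvalue: float
    n: int


def correlate_onset(feature: Sequence[float], onset_age: Sequence[float]) -> OnsetCorrelation:
    """Pearson correlation (with two-sided p) between a per-subject network
    feature and the age at which training began."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(onset_age, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature and onset_age must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired values, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return OnsetCorrelation(float(res.statistic), float(res.pvalue), int(x.size))
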