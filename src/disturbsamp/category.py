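"""Frequency-table tests on heard-only detections and rank correlation of
group-size measures.

Heard-only groups are binned into three coarse distance categories (close
< 100 m, far 100-500 m, very far > 500 m); differences in that distribution
between passages are tested with Pearson chi-squared statistics (no
continuity correction) on pairwise passage tables, with either the
asymptotic chi-squared p-value or a Monte Carlo p-value from tables
resampled with both margins fixed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey import HEARD_CATEGORIES, SurveyDataset

logger = logging.getLogger("disturbsamp")


@dataclasses.dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    method: str


def heard_distance_table(ds: SurveyDataset, passages: Sequence[int]) -> pd.DataFrame:
    """Counts of heard-only records by passage (rows) x distance category."""
    if len(list(passages)) == 0:
        raise ValueError("passages must be non-empty")
    h = ds.heard[ds.heard.passage.isin(list(passages))]
    if len(h) == 0:
        logger.warning("no heard-only records in passages %s", list(passages))
    table = pd.DataFrame(0, index=[f"P{p}" for p in passages], columns=list(HEARD_CATEGORIES))
    for p in passages:
        hp = h[h.passage == p]
        for cat in HEARD_CATEGORIES:
            table.loc[f"P{p}", cat] = int((hp.category == cat).sum())
    return table


def _resample_chi2(table: np.ndarray, B: int, seed) -> np.ndarray:
    """Chi-squared statistics of B tables drawn with both margins fixed.

    Realised by assigning the column label multiset to the row label
    multiset in random order (equivalent to permutation of the underlying
    record-level categories), which preserves both margins exactly.
    """
    rng = np.random.default_rng(seed)
    rows, cols = table.shape
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    n = int(table.sum())
    row_labels = np.repeat(np.arange(rows), row_tot.astype(int))
    col_labels = np.repeat(np.arange(cols), col_tot.astype(int))
    expected = np.outer(row_tot, col_tot) / n
    out = np.empty(B)
    for b in range(B):
        perm = rng.permutation(col_labels)
        t = np.zeros((rows, cols))
        np.add.at(t, (row_labels, perm), 1.0)
        out[b] = float(np.sum((t - expected) ** 2 / expected))
    return out


def pearson_chi2(table, p_method: str = "asymptotic", B: int = 2000,
                 seed: int | None = None) -> Chi2Result:
    """Pearson chi-squared test of independence on a contingency table.

    No continuity correction is applied.  Rows/columns with a zero marginal
    are dropped with a warning before testing.  ``p_method='monte_carlo'``
    draws ``B`` tables with fixed margins and reports
    p = (1 + #{T_b >= T}) / (B + 1).
    """
    t = np.asarray(table, dtype=float)
    if t.sum() <= 0:
        raise ValueError("contingency table has no counts")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping %d zero row(s) and %d zero column(s) before testing",
                       int((~keep_r).sum()), int((~keep_c).sum()))
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table with positive marginals")
    res = stats.chi2_contingency(t, correction=False)
    if p_method == "asymptotic":
        return Chi2Result(float(res.statistic), int(res.dof), float(res.pvalue), "asymptotic")
    if p_method == "monte_carlo":
        sims = _resample_chi2(t, B, seed)
        p = (1.0 + float(np.sum(sims >= res.statistic - 1e-12))) / (B + 1.0)
        return Chi2Result(float(res.statistic), int(res.dof), p, f"monte_carlo(B={B})")
    raise ValueError(f"unknown p_method {p_method!r}")


def far_proportion(ds_or_counts, passage: int | None = None) -> float:
    """Percentage of heard-only groups in the 'far' (100-500 m) category.

    Accepts either a SurveyDataset plus a passage, or a length-3 count
    vector (close, far, very far).  Returns the exact percentage; round for
    reporting.  Undefined (NaN) when there are no heard records.
    """
    if isinstance(ds_or_counts, SurveyDataset):
        h = ds_or_counts.heard[ds_or_counts.heard.passage == passage]
        counts = [int((h.category == c).sum()) for c in HEARD_CATEGORIES]
    else:
        counts = list(ds_or_counts)
    total = sum(counts)
    if total == 0:
        logger.warning("no heard-only records; far proportion undefined")
        return float("nan")
    return 100.0 * counts[1] / total


def spearman_rho(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p).

    Returns (nan, nan) with a warning for constant inputs, where the rank
    correlation is undefined.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman correlation undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
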