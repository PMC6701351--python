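"""Differential expression at fixed fold-change and FDR thresholds.

Counts are normalized to log2 counts-per-million (CPM) with a pseudocount,
each feature is tested with Welch's t between the two groups, and p-values
are Benjamini-Hochberg corrected across all features tested. A feature is
called up-regulated when ``log2FC > lfc_threshold`` and ``FDR < alpha``
(both strict), down-regulated symmetrically, otherwise non-significant.
The location test is deliberately pluggable: ``test_differential`` accepts
any callable mapping two value arrays to a p-value, so a negative-binomial
exact test can be substituted without touching the filtering rule.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

DEFAULT_LFC = 1.5
DEFAULT_ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 0.5


@dataclasses.dataclass
class DEResult:
    feature: str
    log2fc: float
    p_value: float
    fdr: float
    direction: str  # "up" | "down" | "ns"


def normalize_counts(
    matrix: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    quantile: bool = False,
) -> ExpressionMatrix:
    """log2(CPM + pseudocount) normalization (optionally quantile).

    With ``quantile=True``, columns are quantile-normalized after the CPM
    transform: every sample receives the mean sorted profile, assigned back
    in its own rank order (ties by stable order).
    """
    counts = matrix.values.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        bad = matrix.samples[np.where(totals == 0)[0]].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    cpm = counts / totals[None, :] * 1e6
    out = np.log2(cpm + pseudocount)
    if quantile:
        order = np.argsort(out, axis=0, kind="stable")
        ranked = np.take_along_axis(out, order, axis=0)
        mean_profile = ranked.mean(axis=1)
        qn = np.empty_like(out)
        np.put_along_axis(qn, order, mean_profile[:, None], axis=0)
        out = qn
    values = pd.DataFrame(out, index=matrix.features, columns=matrix.samples)
    return ExpressionMatrix(values, matrix.feature_class)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def test_differential(
    matrix: ExpressionMatrix,
    groups: pd.Series | Sequence[str],
    group_a: str = "tumor",
    group_b: str = "normal",
    lfc_threshold: float = DEFAULT_LFC,
    alpha: float = DEFAULT_ALPHA,
    already_normalized: bool = False,
    test: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> list[DEResult]:
    """Per-feature DE calls for ``group_a`` over ``group_b``.

    ``log2fc`` is the difference of group means on the log2-CPM scale; the
    p-value comes from Welch's t (or the supplied ``test``); FDR is BH over
    all features in the matrix.
    """
    groups = pd.Series(np.asarray(groups, dtype=object), index=matrix.samples)
    mask_a = (groups == group_a).to_numpy()
    mask_b = (groups == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {group_a}: {int(mask_a.sum())}, "
            f"{group_b}: {int(mask_b.sum())})"
        )
    norm = matrix if already_normalized else normalize_counts(matrix)
    values = norm.values.to_numpy()
    test = test or _welch_p

    a_vals, b_vals = values[:, mask_a], values[:, mask_b]
    log2fc = a_vals.mean(axis=1) - b_vals.mean(axis=1)
    pvals = np.array([test(a_vals[i], b_vals[i]) for i in range(values.shape[0])])
    fdr = multipletests(pvals, method="fdr_bh")[1]

    results = []
    for i, feat in enumerate(matrix.features):
        if log2fc[i] > lfc_threshold and fdr[i] < alpha:
            direction = "up"
        elif log2fc[i] < -lfc_threshold and fdr[i] < alpha:
            direction = "down"
        else:
            direction = "ns"
        results.append(DEResult(str(feat), float(log2fc[i]), float(pvals[i]),
                                float(fdr[i]), direction))
    return results


def select_deg_sets(results: Sequence[DEResult]) -> tuple[set[str], set[str]]:
    """Partition DE calls into (up, down) feature-id sets; ns excluded."""
    up = {r.feature for r in results if r.direction == "up"}
    down = {r.feature for r in results if r.direction == "down"}
    return up, down


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    """Fixed-column-order table (feature, log2fc, p, fdr, direction)."""
    return pd.DataFrame(
        [(r.feature, r.log2fc, r.p_value, r.fdr, r.direction) for r in results],
        columns=["feature", "log2fc", "p", "fdr", "direction"],
    )
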