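"""Stage-progression screening with pairwise Kolmogorov-Smirnov tests.

Every feature is compared between each pair of available tumor stages
(II/III, II/IV, III/IV) with the two-sample KS test; the per-feature
combined p-value is the Bonferroni-scaled minimum over the pairs, and
Benjamini-Hochberg is applied across features. Stages with fewer than two
samples are dropped with a warning (tiny stage-IV arms are common).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

STAGE_ORDER = ("II", "III", "IV")


@dataclasses.dataclass
class StageTestResult:
    feature: str
    pairwise: dict[tuple[str, str], tuple[float, float]]  # pair -> (D, p)
    combined_p: float
    fdr: float
    significant: bool


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic D = sup|ECDF_a - ECDF_b| with asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >=2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def stage_screen(
    matrix: ExpressionMatrix,
    stages: pd.Series | Sequence[str],
    alpha: float = 0.01,
) -> list[StageTestResult]:
    """Pairwise KS across stages for every feature; BH across features.

    ``significant`` uses a strict ``fdr < alpha`` comparison.
    """
    stages = pd.Series(np.asarray(stages, dtype=object), index=matrix.samples)
    usable = []
    for s in STAGE_ORDER:
        n_s = int((stages == s).sum())
        if n_s >= 2:
            usable.append(s)
        elif n_s:
            logger.warning("stage %s has %d sample(s) — dropped from screen", s, n_s)
    pairs = list(itertools.combinations(usable, 2))
    if not pairs:
        raise ValueError("need at least two stages with >=2 samples")

    values = matrix.values
    masks = {s: (stages == s).to_numpy() for s in usable}
    records = []
    for feat in matrix.features:
        row = values.loc[feat].to_numpy(dtype=float)
        pw = {}
        for s1, s2 in pairs:
            if np.ptp(row[masks[s1]]) == 0 and np.ptp(row[masks[s2]]) == 0 and \
                    row[masks[s1]][0] == row[masks[s2]][0]:
                pw[(s1, s2)] = (0.0, 1.0)
            else:
                pw[(s1, s2)] = ks_two_sample(row[masks[s1]], row[masks[s2]])
        combined = min(1.0, min(p for _, p in pw.values()) * len(pairs))
        records.append((str(feat), pw, combined))

    fdrs = multipletests([r[2] for r in records], method="fdr_bh")[1]
    return [
        StageTestResult(feat, pw, combined, float(fdr), bool(fdr < alpha))
        for (feat, pw, combined), fdr in zip(records, fdrs)
    ]


def results_to_frame(results: Sequence[StageTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict[str, object] = {"feature": r.feature}
        for (s1, s2), (d, p) in r.pairwise.items():
            row[f"D_{s1}_{s2}"] = d
            row[f"p_{s1}_{s2}"] = p
        row["combined_p"] = r.combined_p
        row["fdr"] = r.fdr
        row["significant"] = r.significant
        rows.append(row)
    return pd.DataFrame(rows)
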