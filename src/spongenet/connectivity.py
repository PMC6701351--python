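"""Connectivity-map style drug repositioning screen.

A query signature (disjoint up- and down-regulated gene sets) is located
within each drug's induced gene ranking with a Kolmogorov-Smirnov running
statistic. For a set of size ``t`` whose members sit at ascending ranks
``V(1..t)`` of an ``n``-gene list,

    a = max_j ( j/t - V(j)/n ),   b = max_j ( V(j)/n - (j-1)/t )

and the enrichment score is ``a`` if ``a > b`` else ``-b`` — positive when
the set crowds the top of the ranking. The combined connectivity score is 0
when ES_up and ES_down share a sign, otherwise ``(ES_up - ES_down) / 2``;
a negative score marks a drug that reverses the query signature (it drives
the query's up genes down and vice versa).

Significance uses random query sets of the same sizes. Because the
same-sign rule puts a point mass at zero, p-values are computed one-sided
on the raw combined statistic ``(ES_up - ES_down)/2`` (no zero rule), which
is continuous under the null: p = (1 + #{null <= observed}) / (B + 1),
small p = strongly reversing.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class QuerySignature:
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        self.up, self.down = set(self.up), set(self.down)
        if not self.up or not self.down:
            raise ValueError("both up and down sets must be nonempty")
        if self.up & self.down:
            raise ValueError(f"up/down overlap: {sorted(self.up & self.down)}")


@dataclasses.dataclass
class ConnectivityResult:
    drug: str
    enrichment_score: float
    mean_score: float
    p_value: float
    n_instances: int


def ks_enrichment(members: Sequence[str] | np.ndarray, ranked: Sequence[str]) -> float:
    """KS enrichment of a gene set within a ranked list (1 = top)."""
    index = {g: i + 1 for i, g in enumerate(ranked)}
    missing = [g for g in members if g not in index]
    if missing:
        raise KeyError(f"set members absent from ranked list: {missing[:5]}")
    n = len(ranked)
    v = np.sort(np.array([index[g] for g in members], dtype=float))
    return _ks_from_ranks(v, n)


def _ks_from_ranks(sorted_ranks: np.ndarray, n: int) -> float:
    t = sorted_ranks.size
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - sorted_ranks / n))
    b = float(np.max(sorted_ranks / n - (j - 1) / t))
    return a if a > b else -b


def _raw_combined(es_up: float, es_down: float) -> float:
    return float(np.clip((es_up - es_down) / 2.0, -1.0, 1.0))


def combine_scores(es_up: float, es_down: float) -> float:
    """Same-sign scores cancel to 0; otherwise (ES_up - ES_down)/2 in [-1,1]."""
    if es_up * es_down > 0:
        return 0.0
    return _raw_combined(es_up, es_down)


def connectivity_score(
    signature: QuerySignature, ranking: Sequence[str]
) -> tuple[float, float, float]:
    """Return (combined score, ES_up, ES_down) for one drug ranking."""
    es_up = ks_enrichment(sorted(signature.up), ranking)
    es_down = ks_enrichment(sorted(signature.down), ranking)
    return combine_scores(es_up, es_down), es_up, es_down


def _ranking_from_row(row: pd.Series) -> list[str]:
    return list(row.sort_values(kind="stable").index)


def screen_drugs(
    signature: QuerySignature,
    rank_matrix: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    pool_instances: bool = True,
) -> list[ConnectivityResult]:
    """Score every drug in a drugs(-instances) x genes integer rank matrix.

    Rows sharing an index value are replicate instances of one drug:
    ``mean_score`` averages their per-instance combined scores and
    ``enrichment_score`` is computed on the instance-pooled profile (gene
    ranks averaged across instances and re-ranked) — or, with
    ``pool_instances=False``, taken from the largest-magnitude instance.
    Signature genes missing from the matrix are dropped (error if more than
    half of a set is missing). Results are sorted ascending: the most
    signature-reversing drug comes first.
    """
    if rank_matrix.empty:
        return []
    genes = list(rank_matrix.columns)
    gene_set = set(genes)

    def _present(s: set[str], name: str) -> set[str]:
        kept = s & gene_set
        dropped = len(s) - len(kept)
        if dropped:
            logger.info("%s set: %d gene(s) absent from rank matrix — dropped",
                        name, dropped)
        if len(kept) * 2 < len(s) or not kept:
            raise ValueError(f"more than half of the {name} set is missing")
        return kept

    sig = QuerySignature(_present(signature.up, "up"), _present(signature.down, "down"))
    up = sorted(sig.up)
    down = sorted(sig.down)
    n = len(genes)
    rng = np.random.default_rng(seed)

    # null raw statistics from random gene-set draws of the same sizes
    null_raw = np.empty(n_permutations)
    for i in range(n_permutations):
        picks = rng.choice(n, size=len(up) + len(down), replace=False)
        vu = np.sort(picks[: len(up)] + 1.0)
        vd = np.sort(picks[len(up):] + 1.0)
        null_raw[i] = _raw_combined(_ks_from_ranks(vu, n), _ks_from_ranks(vd, n))

    results = []
    for drug in rank_matrix.index.unique():
        block = rank_matrix.loc[[drug]]
        per_instance = []
        per_instance_raw = []
        for _, row in block.iterrows():
            ranking = _ranking_from_row(row)
            score, es_up, es_down = connectivity_score(sig, ranking)
            per_instance.append(score)
            per_instance_raw.append(_raw_combined(es_up, es_down))
        if pool_instances and len(block) > 1:
            pooled = block.mean(axis=0).rank(method="first")
            ranking = _ranking_from_row(pooled)
            enrichment, es_up, es_down = connectivity_score(sig, ranking)
            raw = _raw_combined(es_up, es_down)
        else:
            best = int(np.argmax(np.abs(per_instance)))
            enrichment = per_instance[best]
            raw = per_instance_raw[best]
        p = (1.0 + int((null_raw <= raw).sum())) / (n_permutations + 1.0)
        results.append(
            ConnectivityResult(str(drug), float(enrichment),
                               float(np.mean(per_instance)), float(p), len(block))
        )
    results.sort(key=lambda r: (r.enrichment_score, r.drug))
    return results


def results_to_frame(results: Sequence[ConnectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.drug, r.enrichment_score, r.mean_score, r.p_value, r.n_instances)
         for r in results],
        columns=["drug", "enrichment_score", "mean_score", "p", "n_instances"],
    )


def signature_from_gmt(sets: dict[str, list[str]], prefix: str) -> QuerySignature:
    """Build a signature from GMT entries ``<prefix>_UP`` / ``<prefix>_DOWN``."""
    try:
        return QuerySignature(set(sets[f"{prefix}_UP"]), set(sets[f"{prefix}_DOWN"]))
    except KeyError as err:
        raise KeyError(f"GMT is missing {prefix}_UP / {prefix}_DOWN") from err
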