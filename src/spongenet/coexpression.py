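"""Soft-thresholded coexpression modules, eigengenes, kME and hub genes.

A WGCNA-style analysis reduced to its deterministic core: the adjacency is
``|pearson|**beta`` (unsigned network, beta = 12 by default), modules come
from average-linkage hierarchical clustering of ``1 - adjacency`` with a
static tree cut, the module eigengene is the first principal component of
the module's standardized expression (sign-oriented so mean kME >= 0), kME
is the correlation of each gene with its module eigengene, and a gene's
degree counts adjacency entries at or above a hard cutoff (0.8 by default).
Hub genes are those with degree strictly greater than ``min_degree``.

Note that cutoff 0.8 at beta = 12 requires |cor| >= 0.8**(1/12) ~ 0.98154
for an edge — on noisy count data few pairs qualify; the cutoff is exposed
so desk-scale analyses can relax it deliberately.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_BETA = 12.0
DEFAULT_CUTOFF = 0.8
DEFAULT_MIN_DEGREE = 10
DEFAULT_CUT_HEIGHT = 0.995
UNASSIGNED = "unassigned"


@dataclasses.dataclass
class CoexpressionModule:
    label: str
    members: list[str]
    eigengene: np.ndarray        # per-sample, unit norm
    kme: pd.Series               # member -> correlation with eigengene
    degree: pd.Series            # member -> thresholded-adjacency degree


def soft_adjacency(values: pd.DataFrame, beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Unsigned soft adjacency a_ij = |pearson(x_i, x_j)|**beta, zero diagonal.

    ``values`` is features x samples. Constant features get zero rows with a
    warning (their correlation is undefined).
    """
    if values.shape[1] < 3:
        raise ValueError("need >=3 samples for a meaningful correlation")
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant feature(s): adjacency rows zeroed",
                       int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    adj = np.abs(corr) ** beta
    adj[constant, :] = 0.0
    adj[:, constant] = 0.0
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=values.index, columns=values.index)


def _eigengene(block: np.ndarray) -> np.ndarray:
    """First principal component (unit norm) of standardized features x samples."""
    sd = block.std(axis=1)
    sd[sd == 0] = 1.0
    Z = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
    # right singular vector of the feature x sample matrix = PC1 score vector
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    return vt[0]


def detect_modules(
    adjacency: pd.DataFrame,
    expression: pd.DataFrame,
    min_size: int = 5,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[CoexpressionModule]:
    """Average-linkage clustering of 1 - adjacency with a static tree cut.

    Clusters smaller than ``min_size`` fall into an "unassigned" bucket
    (returned last, without eigengene semantics). Labels are assigned by
    decreasing size: module_1 is the largest (the turquoise/blue convention).
    """
    features = list(adjacency.index)
    A = adjacency.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    if len(features) < 2:
        raise ValueError("need at least two features")
    dist = 1.0 - A
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")

    groups: dict[int, list[str]] = {}
    for f, g in zip(features, raw):
        groups.setdefault(int(g), []).append(f)
    big = sorted(
        (members for members in groups.values() if len(members) >= min_size),
        key=lambda m: (-len(m), m[0]),
    )
    unassigned = sorted(
        f for members in groups.values() if len(members) < min_size for f in members
    )

    degree_all = degree_series(adjacency, cutoff)
    modules = []
    for i, members in enumerate(big, start=1):
        block = expression.loc[members].to_numpy(dtype=float)
        eig = _eigengene(block)
        kme = pd.Series(
            [float(np.corrcoef(expression.loc[f].to_numpy(dtype=float), eig)[0, 1])
             if expression.loc[f].to_numpy().std() > 0 else 0.0
             for f in members],
            index=members,
        )
        if kme.mean() < 0:
            eig = -eig
            kme = -kme
        modules.append(
            CoexpressionModule(f"module_{i}", members, eig, kme, degree_all[members])
        )
    if unassigned:
        modules.append(
            CoexpressionModule(
                UNASSIGNED, unassigned,
                np.zeros(expression.shape[1]),
                pd.Series(0.0, index=unassigned),
                degree_all[unassigned],
            )
        )
    return modules


def degree_series(adjacency: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.Series:
    """Per-feature degree on the thresholded adjacency (a_ij >= cutoff)."""
    A = adjacency.to_numpy(dtype=float)
    return pd.Series((A >= cutoff).sum(axis=1), index=adjacency.index)


def hub_genes(
    modules: Sequence[CoexpressionModule],
    adjacency: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    min_degree: int = DEFAULT_MIN_DEGREE,
) -> pd.DataFrame:
    """Features with thresholded degree strictly greater than ``min_degree``.

    Returns a table (feature, module, kME, degree) over assigned modules.
    """
    deg = degree_series(adjacency, cutoff)
    rows = []
    for mod in modules:
        if mod.label == UNASSIGNED:
            continue
        for f in mod.members:
            if deg[f] > min_degree:
                rows.append((f, mod.label, float(mod.kme[f]), int(deg[f])))
    return pd.DataFrame(rows, columns=["feature", "module", "kME", "degree"])


def modules_to_frame(modules: Sequence[CoexpressionModule]) -> pd.DataFrame:
    rows = []
    for mod in modules:
        for f in mod.members:
            rows.append((f, mod.label, float(mod.kme[f]), int(mod.degree[f])))
    return pd.DataFrame(rows, columns=["feature", "module", "kME", "degree"])


def eigengenes_to_frame(modules: Sequence[CoexpressionModule], samples: Sequence[str]) -> pd.DataFrame:
    rows = {m.label: m.eigengene for m in modules if m.label != UNASSIGNED}
    return pd.DataFrame(rows, index=list(samples)).T
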