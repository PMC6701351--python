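"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity from its definition
(explicit sums over contingency cells, ECDF sweeps, step-up scans) so the
package implementations are checked against a second, independent route.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import spongenet as sn


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def mi_oracle(x, y) -> float:
    """Plug-in MI as an explicit sum over joint cells (bits)."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    total = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            nxy = np.sum((x == xv) & (y == yv))
            if nxy == 0:
                continue
            pxy = nxy / n
            px = np.sum(x == xv) / n
            py = np.sum(y == yv) / n
            total += pxy * np.log2(pxy / (px * py))
    return total


def cmi_oracle(x, y, z) -> float:
    """Plug-in CMI as an explicit sum over (x, y, z) cells (bits)."""
    x, y, z = np.asarray(x), np.asarray(y), np.asarray(z)
    n = len(x)
    total = 0.0
    for xv, yv, zv in itertools.product(np.unique(x), np.unique(y), np.unique(z)):
        nxyz = np.sum((x == xv) & (y == yv) & (z == zv))
        if nxyz == 0:
            continue
        pxyz = nxyz / n
        pz = np.sum(z == zv) / n
        pxz = np.sum((x == xv) & (z == zv)) / n
        pyz = np.sum((y == yv) & (z == zv)) / n
        total += pxyz * np.log2(pz * pxyz / (pxz * pyz))
    return total


def ks_d_oracle(a, b) -> float:
    """sup |ECDF_a - ECDF_b| by sweeping every observed breakpoint."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for t in np.concatenate([a, b]):
        best = max(best, abs(np.mean(a <= t) - np.mean(b <= t)))
    return best


def bh_oracle(pvals) -> np.ndarray:
    """BH adjusted p-values as the minimum over the step-up tail."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def ks_enrichment_oracle(ranks, n) -> float:
    """Direct max over j of the two running KS deviations."""
    v = sorted(ranks)
    t = len(v)
    a = max((j + 1) / t - v[j] / n for j in range(t))
    b = max(v[j] / n - j / t for j in range(t))
    return a if a > b else -b


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SMALL_SPEC = dict(
    n_tumor=120, n_normal=40, n_mrna=150, n_lncrna=30, n_mirna=15,
    n_sponge_triplets=3, module_sizes=(20, 20), seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    spec = sn.CohortSpec(**SMALL_SPEC)
    matrix, meta, truth = sn.generate_cohort(spec)
    return spec, matrix, meta, truth


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    _, matrix, meta, truth = small_cohort
    return sn.normalize_counts(matrix), meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_matrix(values: np.ndarray, classes: list[str] | None = None,
               prefix: str = "g") -> sn.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    feats = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    cls = pd.Series(classes or ["mRNA"] * len(feats), index=feats)
    return sn.ExpressionMatrix(pd.DataFrame(values, index=feats, columns=cols), cls)
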