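"""Coexpression: soft adjacency, module detection, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from spongenet.coexpression import (
    detect_modules,
    degree_series,
    hub_genes,
    soft_adjacency,
    UNASSIGNED,
)


def frame(vals, prefix="g"):
    feats = [f"{prefix}{i}" for i in range(vals.shape[0])]
    return pd.DataFrame(vals, index=feats,
                        columns=[f"s{j}" for j in range(vals.shape[1])])


def two_block_data(n_per=20, n_samples=100, rho=0.9, n_noise=20, seed=0):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for b in range(2):
        f = rng.normal(size=n_samples)
        eps = rng.normal(size=(n_per, n_samples))
        blocks.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * eps)
        labels += [f"block{b}"] * n_per
    blocks.append(rng.normal(size=(n_noise, n_samples)))
    labels += ["noise"] * n_noise
    return frame(np.vstack(blocks)), np.array(labels)


class TestSoftAdjacency:
    def test_powered_correlation(self, rng):
        base = rng.normal(size=100)
        x = base + rng.normal(scale=0.48, size=100)   # cor around 0.9
        vals = frame(np.vstack([base, x]))
        adj = soft_adjacency(vals, beta=12)
        r = abs(np.corrcoef(base, x)[0, 1])
        assert adj.iloc[0, 1] == pytest.approx(r ** 12, abs=1e-12)
        assert adj.iloc[0, 0] == 0.0

    def test_perfect_pair_unit_adjacency(self):
        v = np.arange(10.0)
        adj = soft_adjacency(frame(np.vstack([v, 2 * v + 3])), beta=12)
        assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_feature_zeroed_with_warning(self, caplog, rng):
        vals = frame(np.vstack([np.full(30, 4.0), rng.normal(size=(2, 30))]))
        with caplog.at_level("WARNING"):
            adj = soft_adjacency(vals)
        assert "constant" in caplog.text
        assert (adj.iloc[0] == 0).all()

    def test_edge_condition_inverts_power_analytically(self, rng):
        """adjacency >= 0.8 at beta = 12 is exactly |cor| >= 0.8**(1/12)."""
        threshold = 0.8 ** (1 / 12)
        assert threshold == pytest.approx(0.9816, abs=1e-4)
        base = rng.normal(size=400)
        rows = [base] + [base + rng.normal(scale=s, size=400)
                         for s in np.linspace(0.05, 0.4, 12)]
        vals = frame(np.vstack(rows))
        adj = soft_adjacency(vals, beta=12)
        corr = np.abs(np.corrcoef(vals.to_numpy()))
        got = adj.to_numpy() >= 0.8
        expected = (corr >= threshold) & ~np.eye(len(rows), dtype=bool)
        assert (got == expected).all()

    def test_values_in_unit_interval_symmetric(self, rng):
        adj = soft_adjacency(frame(rng.normal(size=(10, 40))))
        A = adj.to_numpy()
        assert ((A >= 0) & (A <= 1)).all()
        np.testing.assert_allclose(A, A.T)
        assert np.diag(A).sum() == 0


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        vals, labels = two_block_data(seed=3)
        adj = soft_adjacency(vals)
        modules = detect_modules(adj, vals, min_size=5)
        detected = {f: m.label for m in modules for f in m.members}
        block_mask = labels != "noise"
        truth = labels[block_mask]
        pred = [detected[f] for f in vals.index[block_mask]]
        assert sum(m.label != UNASSIGNED for m in modules) == 2
        assert rand_score(truth, pred) >= 0.95

    def test_uncorrelated_features_all_unassigned(self, rng):
        vals = frame(rng.normal(size=(20, 60)))
        modules = detect_modules(soft_adjacency(vals), vals, min_size=5)
        assert len(modules) == 1 and modules[0].label == UNASSIGNED

    def test_duplicated_features_land_in_same_module(self):
        vals, _ = two_block_data(n_per=10, n_noise=5, seed=4)
        dup = vals.iloc[[0]].rename(index={"g0": "g_dup"})
        vals2 = pd.concat([vals, dup])
        modules = detect_modules(soft_adjacency(vals2), vals2, min_size=5)
        detected = {f: m.label for m in modules for f in m.members}
        assert detected["g_dup"] == detected["g0"]

    def test_eigengene_is_leading_pc(self):
        vals, _ = two_block_data(n_per=15, n_noise=0, seed=5)
        adj = soft_adjacency(vals)
        modules = [m for m in detect_modules(adj, vals, min_size=5)
                   if m.label != UNASSIGNED]
        for mod in modules:
            block = vals.loc[mod.members].to_numpy()
            Z = (block - block.mean(1, keepdims=True)) / block.std(1, keepdims=True)
            # eigengene variance share must match the top squared singular value
            _, s, vt = np.linalg.svd(Z, full_matrices=False)
            share = (Z @ mod.eigengene) ** 2
            assert share.sum() == pytest.approx(s[0] ** 2, rel=1e-9)
            assert mod.kme.mean() >= 0

    def test_hub_kme_coherence(self):
        vals, _ = two_block_data(n_per=15, n_noise=10, seed=6)
        adj = soft_adjacency(vals)
        modules = [m for m in detect_modules(adj, vals, min_size=5, cutoff=0.25)
                   if m.label != UNASSIGNED]
        for mod in modules:
            top = mod.degree[mod.degree == mod.degree.max()].index
            assert mod.kme[top].max() >= mod.kme.median() - 1e-9


class TestHubGenes:
    def _block_adjacency(self, n, a=0.95):
        A = np.full((n, n), a)
        np.fill_diagonal(A, 0.0)
        feats = [f"g{i}" for i in range(n)]
        return pd.DataFrame(A, index=feats, columns=feats)

    def test_isolated_feature_degree_zero_excluded(self, rng):
        vals = frame(rng.normal(size=(6, 30)))
        adj = soft_adjacency(vals)
        hubs = hub_genes(
            detect_modules(adj, vals, min_size=2, cut_height=1.1),
            adj, cutoff=0.8, min_degree=0,
        )
        assert hubs.empty or (hubs["degree"] > 0).all()

    def test_degree_exactly_ten_excluded_strict(self):
        adj = self._block_adjacency(11)          # every gene has degree 10
        assert (degree_series(adj, 0.8) == 10).all()
        vals = frame(np.tile(np.arange(30.0), (11, 1)) +
                     np.random.default_rng(0).normal(scale=0.01, size=(11, 30)))
        modules = detect_modules(adj, vals, min_size=5)
        hubs = hub_genes(modules, adj, cutoff=0.8, min_degree=10)
        assert hubs.empty

    def test_fifteen_gene_block_at_0995_all_hubs(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=200)
        vals = frame(np.vstack(
            [base + rng.normal(scale=0.055, size=200) for _ in range(15)]
        ))
        corr = np.corrcoef(vals.to_numpy())
        assert (corr[~np.eye(15, dtype=bool)] >= 0.99).all()
        adj = soft_adjacency(vals, beta=12)
        modules = detect_modules(adj, vals, min_size=5)
        hubs = hub_genes(modules, adj, cutoff=0.8, min_degree=10)
        assert len(hubs) == 15
        assert (hubs["degree"] == 14).all()
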