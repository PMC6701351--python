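"""Connectivity-map scoring: KS enrichment, combination rule, drug screen."""

import numpy as np
import pandas as pd
import pytest

from spongenet.connectivity import (
    QuerySignature,
    combine_scores,
    connectivity_score,
    ks_enrichment,
    screen_drugs,
    signature_from_gmt,
)

from conftest import ks_enrichment_oracle


GENES = [f"G{i}" for i in range(100)]


class TestKsEnrichment:
    def test_top_ranks_extreme(self):
        # the running-statistic maximum for ranks 1..t is exactly 1 - t/n,
        # reaching 1 - 1/n in the single-member extreme
        assert ks_enrichment(GENES[:1], GENES) == pytest.approx(1 - 1 / 100)
        assert ks_enrichment(GENES[:5], GENES) == pytest.approx(1 - 5 / 100)

    def test_bottom_ranks_mirror(self):
        # b is penalized by (j-1)/t rather than V(j)/n: bottom t ranks
        # give -max_j(V(j)/n - (j-1)/t) = -(1 - (t-1)/t - ...) = -(0.96)
        assert ks_enrichment(GENES[-5:], GENES) == pytest.approx(-0.96)
        assert ks_enrichment(GENES[-1:], GENES) == pytest.approx(-1.0)

    def test_scattered_set_matches_brute_force(self):
        members = [GENES[1], GENES[49], GENES[97]]   # ranks 2, 50, 98
        got = ks_enrichment(members, GENES)
        assert got == pytest.approx(ks_enrichment_oracle([2, 50, 98], 100), abs=1e-12)

    def test_random_sets_match_oracle(self, rng):
        for _ in range(20):
            t = rng.integers(1, 12)
            picks = rng.choice(100, size=t, replace=False)
            got = ks_enrichment([GENES[i] for i in picks], GENES)
            assert got == pytest.approx(
                ks_enrichment_oracle(sorted(picks + 1), 100), abs=1e-12
            )

    def test_missing_member_errors(self):
        with pytest.raises(KeyError):
            ks_enrichment(["nope"], GENES)

    def test_rank_reversal_antisymmetry(self, rng):
        # reversal maps (a, b) -> (b - 1/n, a + 1/n), so the score flips
        # sign up to the 1/n discretization of the running statistic
        for _ in range(20):
            picks = rng.choice(100, size=6, replace=False)
            members = [GENES[i] for i in picks]
            v = sorted(picks + 1)
            t, n = len(v), 100
            a = max((j + 1) / t - v[j] / n for j in range(t))
            b = max(v[j] / n - j / t for j in range(t))
            if abs(a - b) < 1e-12:
                continue          # exact a == b ties flip the max branch
            fwd = ks_enrichment(members, GENES)
            rev = ks_enrichment(members, GENES[::-1])
            assert fwd == pytest.approx(-rev, abs=1 / 100 + 1e-12)


class TestCombination:
    def test_same_sign_zero(self):
        assert combine_scores(0.4, 0.7) == 0.0
        assert combine_scores(-0.2, -0.9) == 0.0

    def test_opposite_signs_average(self):
        assert combine_scores(0.8, -0.6) == pytest.approx(0.7)
        assert combine_scores(-0.9, 0.9) == pytest.approx(-0.9)

    def test_signature_validation(self):
        with pytest.raises(ValueError):
            QuerySignature({"a"}, {"a", "b"})
        with pytest.raises(ValueError):
            QuerySignature(set(), {"b"})

    def test_reversing_profile_scores_near_minus_one(self):
        sig = QuerySignature(set(GENES[:5]), set(GENES[-5:]))
        score_fwd, *_ = connectivity_score(sig, GENES)
        sig_rev = QuerySignature(set(GENES[-5:]), set(GENES[:5]))
        score_rev, *_ = connectivity_score(sig_rev, GENES)
        # ES_up = 0.95 (top), ES_down = -0.96 (bottom): (0.95 + 0.96)/2
        assert score_fwd == pytest.approx(0.955)
        assert score_rev == pytest.approx(-0.955)

    def test_relabeling_outside_query_sets_is_irrelevant(self, rng):
        sig = QuerySignature(set(GENES[10:14]), set(GENES[60:64]))
        ranking = list(rng.permutation(GENES))
        renamed = [g if g in sig.up | sig.down else f"X_{g}" for g in ranking]
        s1, *_ = connectivity_score(sig, ranking)
        s2, *_ = connectivity_score(sig, renamed)
        assert s1 == pytest.approx(s2, abs=1e-12)


def rank_row(order):
    ranks = np.empty(len(order), dtype=int)
    for pos, g in enumerate(order):
        ranks[GENES.index(g)] = pos + 1
    return ranks


class TestScreen:
    def test_empty_matrix_empty_result(self):
        sig = QuerySignature({"G1"}, {"G2"})
        assert screen_drugs(sig, pd.DataFrame()) == []

    def test_planted_reversing_drug_ranks_first(self, rng):
        sig = QuerySignature(set(GENES[:10]), set(GENES[10:20]))
        rows, index = [], []
        reversing_order = GENES[10:20] + GENES[20:] + GENES[:10]
        rows.append(rank_row(reversing_order))
        index.append("reverser")
        for d in range(10):
            rows.append(rank_row(list(rng.permutation(GENES))))
            index.append(f"drug_{d}")
        matrix = pd.DataFrame(rows, index=index, columns=GENES)
        results = screen_drugs(sig, matrix, n_permutations=200, seed=0)
        assert results[0].drug == "reverser"
        assert results[0].enrichment_score < -0.9
        assert results[0].p_value <= 1 / 201 + 1e-12

    def test_null_mean_score_near_zero(self, rng):
        sig = QuerySignature(set(GENES[:8]), set(GENES[8:16]))
        scores = []
        for _ in range(400):
            ranking = list(rng.permutation(GENES))
            s, *_ = connectivity_score(sig, ranking)
            scores.append(s)
        assert abs(np.mean(scores)) < 0.02

    def test_instances_averaged_into_mean_score(self, rng):
        sig = QuerySignature(set(GENES[:5]), set(GENES[5:10]))
        rows = [rank_row(list(rng.permutation(GENES))) for _ in range(3)]
        matrix = pd.DataFrame(rows, index=["d", "d", "d"], columns=GENES)
        res = screen_drugs(sig, matrix, n_permutations=50, seed=1)
        assert res[0].n_instances == 3
        per = []
        for _, row in matrix.iterrows():
            ranking = list(row.sort_values(kind="stable").index)
            per.append(connectivity_score(sig, ranking)[0])
        assert res[0].mean_score == pytest.approx(np.mean(per))

    def test_mostly_missing_signature_errors(self):
        sig = QuerySignature({"A1", "A2", "G1"}, {"G2", "B1"})
        matrix = pd.DataFrame([np.arange(1, 101)], index=["d"], columns=GENES)
        with pytest.raises(ValueError):
            screen_drugs(sig, matrix)


def test_signature_gmt_round_trip(tmp_path):
    from spongenet.io import read_gmt, write_gmt

    path = tmp_path / "sig.gmt"
    write_gmt({"Q_UP": ["a", "b"], "Q_DOWN": ["c"]}, path)
    sets = read_gmt(path)
    sig = signature_from_gmt(sets, "Q")
    assert sig.up == {"a", "b"} and sig.down == {"c"}
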