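"""Signal2Noise ranking and the weighted running-sum enrichment score."""

import numpy as np
import pandas as pd
import pytest

from ntsig.gsea import (
    enrichment_score,
    gsea_many,
    gsea_permutation,
    network_list_frequency,
    rank_signal2noise,
)
from ntsig.matrix import ExpressionMatrix


def _matrix(rows, samples=None):
    df = pd.DataFrame(rows).T.astype(float)
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, id_level="gene")


def _brute_force_es(genes, scores, gene_set, p=1.0):
    """Independent running-sum implementation (plain loop)."""
    nh = sum(g in gene_set for g in genes)
    nr = sum(abs(s) ** p for g, s in zip(genes, scores) if g in gene_set)
    miss = 1.0 / (len(genes) - nh)
    best, running = 0.0, 0.0
    path = []
    for g, s in zip(genes, scores):
        running += abs(s) ** p / nr if g in gene_set else -miss
        path.append(running)
    pos, neg = max(path), min(path)
    return pos if abs(pos) >= abs(neg) else neg


class TestSignal2Noise:
    def test_floored_sd_hand_example(self):
        m = _matrix({"g": [4.0, 4.0, 2.0, 2.0]})
        scores = rank_signal2noise(m, ["s0", "s1"], ["s2", "s3"])
        # sigma floors: 0.2*4 = 0.8 and 0.2*2 = 0.4 -> 2 / 1.2
        assert scores["g"] == pytest.approx(2.0 / 1.2)

    def test_identical_groups_zero(self):
        m = _matrix({"g": [3.0, 5.0, 3.0, 5.0]})
        scores = rank_signal2noise(m, ["s0", "s1"], ["s2", "s3"])
        assert scores["g"] == 0.0

    def test_swapping_groups_negates(self, random_matrix):
        a, b = random_matrix.sample_ids[:6], random_matrix.sample_ids[6:]
        fwd = rank_signal2noise(random_matrix, a, b)
        rev = rank_signal2noise(random_matrix, b, a)
        np.testing.assert_allclose(fwd.sort_index().to_numpy(), -rev.sort_index().to_numpy())

    def test_descending_with_symbol_tie_break(self):
        m = _matrix({"b_gene": [4.0, 4.0, 2.0, 2.0], "a_gene": [4.0, 4.0, 2.0, 2.0]})
        scores = rank_signal2noise(m, ["s0", "s1"], ["s2", "s3"])
        assert list(scores.index) == ["a_gene", "b_gene"]

    def test_abs_sorting_mode(self):
        m = _matrix({"up": [6.0, 6.1, 2.0, 2.1], "down": [1.0, 1.1, 9.0, 9.2], "flat": [5.0, 5.1, 5.0, 5.2]})
        scores = rank_signal2noise(m, ["s0", "s1"], ["s2", "s3"], sort_abs=True)
        assert list(scores.index)[-1] == "flat"

    def test_small_group_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            rank_signal2noise(random_matrix, random_matrix.sample_ids[:1], random_matrix.sample_ids[1:])


class TestEnrichmentScore:
    def _ranked(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(scores, index=[f"g{i:02d}" for i in range(n)])

    def test_all_hits_on_top_give_one(self):
        ranked = self._ranked()
        es, _ = enrichment_score(ranked, set(ranked.index[:8]))
        assert es == pytest.approx(1.0)

    def test_hits_at_bottom_match_brute_force_negative(self):
        ranked = self._ranked()
        gene_set = set(ranked.index[-8:])
        es, _ = enrichment_score(ranked, gene_set)
        oracle = _brute_force_es(list(ranked.index), ranked.to_numpy(), gene_set)
        assert es == pytest.approx(oracle)
        assert es < 0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_sets_match_brute_force(self, seed):
        ranked = self._ranked(seed=seed)
        rng = np.random.default_rng(seed + 100)
        gene_set = set(rng.choice(ranked.index, size=8, replace=False))
        es, running = enrichment_score(ranked, gene_set)
        assert es == pytest.approx(_brute_force_es(list(ranked.index), ranked.to_numpy(), gene_set))
        assert len(running) == len(ranked)

    def test_scale_invariance_of_weighted_es(self):
        ranked = self._ranked()
        gene_set = set(ranked.index[10:18])
        es1, _ = enrichment_score(ranked, gene_set)
        es2, _ = enrichment_score(ranked * 7.3, gene_set)
        assert es1 == pytest.approx(es2)

    def test_p_zero_reduces_to_ks_statistic(self):
        ranked = self._ranked()
        gene_set = set(ranked.index[5:13])
        es, _ = enrichment_score(ranked, gene_set, p=0.0)
        # unweighted KS-style oracle: +1/Nh on hits, -1/(N-Nh) on misses
        nh, n = 8, len(ranked)
        running, path = 0.0, []
        for g in ranked.index:
            running += 1.0 / nh if g in gene_set else -1.0 / (n - nh)
            path.append(running)
        oracle = max(path) if abs(max(path)) >= abs(min(path)) else min(path)
        assert es == pytest.approx(oracle)

    def test_degenerate_sets_rejected(self):
        ranked = self._ranked()
        with pytest.raises(ValueError):
            enrichment_score(ranked, set())
        with pytest.raises(ValueError):
            enrichment_score(ranked, set(ranked.index))


class TestPermutation:
    def test_nominal_p_uniform_on_null_ranking(self):
        rng = np.random.default_rng(0)
        ranked = pd.Series(
            np.sort(rng.normal(size=200))[::-1], index=[f"g{i:03d}" for i in range(200)]
        )
        hits = 0
        for rep in range(200):
            gene_set = set(rng.choice(ranked.index, size=15, replace=False))
            res = gsea_permutation(ranked, gene_set, n_perm=200, seed=rep)
            hits += res.p_nominal < 0.05
        frac = hits / 200
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200) + 0.01

    def test_set_size_bounds_skip(self):
        ranked = pd.Series(np.linspace(2, -2, 50), index=[f"g{i}" for i in range(50)])
        assert gsea_permutation(ranked, {"g1", "g2"}, min_size=10) is None

    def test_zero_permutations_rejected(self):
        ranked = pd.Series(np.linspace(2, -2, 50), index=[f"g{i}" for i in range(50)])
        with pytest.raises(ValueError):
            gsea_permutation(ranked, set(ranked.index[:12]), n_perm=0)

    def test_seed_stability_within_binomial_error(self):
        rng = np.random.default_rng(3)
        ranked = pd.Series(
            np.sort(rng.normal(size=100))[::-1] + np.linspace(1, 0, 100),
            index=[f"g{i:03d}" for i in range(100)],
        )
        gene_set = set(ranked.index[:12])
        ps = [gsea_permutation(ranked, gene_set, n_perm=1000, seed=s).p_nominal for s in (1, 2)]
        se = np.sqrt(max(ps[0], 1e-3) * (1 - ps[0]) / 1000)
        assert abs(ps[0] - ps[1]) < 4 * se + 2e-3

    def test_gsea_many_reports_and_bounds(self):
        rng = np.random.default_rng(4)
        ranked = pd.Series(
            np.sort(rng.normal(size=120))[::-1], index=[f"g{i:03d}" for i in range(120)]
        )
        sets = {
            "top": list(ranked.index[:15]),
            "bottom": list(ranked.index[-15:]),
            "random": list(rng.choice(ranked.index, 15, replace=False)),
            "tiny": list(ranked.index[:3]),
        }
        out = gsea_many(ranked, sets, n_perm=200, seed=0)
        assert set(out["NAME"]) == {"top", "bottom", "random"}  # "tiny" skipped
        assert out["ES"].abs().le(1.0 + 1e-9).all()
        assert out["NOM p-val"].between(0, 1).all()
        assert out.loc[out["NAME"] == "top", "ES"].iloc[0] > 0
        assert out.loc[out["NAME"] == "bottom", "ES"].iloc[0] < 0


class TestNetworkListFrequency:
    def test_partner_overlap_percentage(self):
        members = [f"m{i}" for i in range(38)]
        gene_list = members[:17] + ["other"]
        assert network_list_frequency(members, gene_list) == pytest.approx(44.7, abs=0.05)

    def test_disjoint_and_superset(self):
        members = ["a", "b"]
        assert network_list_frequency(members, ["c"]) == 0.0
        assert network_list_frequency(members, ["a", "b", "c"]) == 100.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_list_frequency([], ["a"])
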