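"""GC3 ranking, the running-sum enrichment statistic against brute-force
enumeration, BH FDR, group derivation and the perturbation-robustness
protocol."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from codonshift.enrichment import (
    GeneSetCollection,
    RankedGeneList,
    bh_fdr,
    derive_groups,
    enrichment_score,
    perturbation_robustness,
    preranked_enrichment,
    rank_by_gc3,
)
from codonshift.synthetic import make_gene_sets


class TestRanking:
    def test_equal_values_rank_zero(self):
        ranked = rank_by_gc3(pd.Series({"a": 58.30, "b": 58.30}))
        assert ranked.scores == pytest.approx([0.0, 0.0])

    def test_log2_ratio_to_mean_and_order(self):
        ranked = rank_by_gc3(pd.Series({"a": 80.0, "b": 40.0, "c": 60.0}))
        assert ranked.gene_ids == ("a", "c", "b")
        assert ranked.scores == pytest.approx(
            [np.log2(80 / 60), 0.0, np.log2(40 / 60)]
        )

    def test_scale_invariance(self):
        g = pd.Series({"a": 20.0, "b": 35.0, "c": 50.0})
        assert np.allclose(rank_by_gc3(g).scores, rank_by_gc3(2 * g).scores)

    def test_zero_gc3_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            ranked = rank_by_gc3(pd.Series({"a": 50.0, "b": 0.0, "c": 60.0}))
        assert "b" not in ranked.gene_ids

    def test_ties_broken_lexicographically(self):
        ranked = rank_by_gc3(pd.Series({"z": 50.0, "a": 50.0, "m": 70.0}))
        assert ranked.gene_ids == ("m", "a", "z")


def _ranked(scores: dict[str, float]) -> RankedGeneList:
    order = sorted(scores.items(), key=lambda t: (-t[1], t[0]))
    mean = float(np.mean(list(scores.values())))
    return RankedGeneList(entries=tuple(order), mean_gc3_pct=mean)


def _es_bruteforce(scores: np.ndarray, hit_idx: set[int], weight: float = 1.0):
    """Literal running-sum evaluation, position by position."""
    n = len(scores)
    k = len(hit_idx)
    w = np.abs(scores) ** weight
    denom = sum(w[i] for i in hit_idx) or float(k)
    running, best = 0.0, 0.0
    for i in range(n):
        running += (w[i] / denom) if i in hit_idx else -1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def test_top_block_with_equal_scores_has_maximal_es(self):
        ranked = _ranked({f"g{i}": 1.0 for i in range(10)})
        genes = ranked.gene_ids
        es, leading = enrichment_score(ranked, genes[:3])
        assert es == pytest.approx(1.0)
        assert set(leading) == set(genes[:3])

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(8)
        scores = {f"g{i:02d}": float(s) for i, s in
                  enumerate(rng.normal(size=20))}
        ranked = _ranked(scores)
        for _ in range(20):
            members = rng.choice(ranked.gene_ids, size=5, replace=False)
            hit_idx = {ranked.gene_ids.index(m) for m in members}
            es, _ = enrichment_score(ranked, members)
            assert es == pytest.approx(
                _es_bruteforce(ranked.scores, hit_idx), abs=1e-10
            )

    def test_reversing_the_list_negates_es(self):
        rng = np.random.default_rng(9)
        scores = {f"g{i:02d}": float(s) for i, s in
                  enumerate(rng.normal(size=15))}
        ranked = _ranked(scores)
        members = ranked.gene_ids[2:6]
        es_fwd, _ = enrichment_score(ranked, members)
        es_rev, _ = enrichment_score(ranked.reversed(), members)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        ranked = _ranked({f"g{i}": 1.0 for i in range(10)})
        sets = GeneSetCollection(
            sets={"top3": ("top", tuple(ranked.gene_ids[:3]))}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = preranked_enrichment(ranked, sets, n_perm=5000, seed=0,
                                       min_size=3)[0]
        null = []
        for combo in itertools.combinations(range(10), 3):
            null.append(_es_bruteforce(ranked.scores, set(combo)))
        p_exact = np.mean(np.abs(null) >= abs(res.es) - 1e-12)
        assert res.es == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(p_exact, abs=0.01)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(10)
        n_lists, hits = 1000, 0
        for i in range(n_lists):
            scores = {f"g{j:03d}": float(s) for j, s in
                      enumerate(rng.normal(size=60))}
            ranked = _ranked(scores)
            members = rng.choice(ranked.gene_ids, size=8, replace=False)
            sets = GeneSetCollection(sets={"s": ("s", tuple(members))})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = preranked_enrichment(ranked, sets, n_perm=199,
                                           seed=i)[0]
            hits += res.p_perm < 0.05
        assert hits / n_lists == pytest.approx(0.05, abs=0.02)


def _bh_oracle(p):
    """Hand step-up: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBHFDR:
    def test_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_matches_stepup_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        assert q.max() <= 1.0
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestGroupDerivation:
    def test_single_negative_set_defines_gp1(self):
        from codonshift.enrichment import EnrichmentResult

        res = [EnrichmentResult("s1", "s1", 2, -0.8, -2.0, 0.001, 0.001, -1,
                                ("a", "b"))]
        gp1, gp2 = derive_groups(res)
        assert gp1 == {"a", "b"} and gp2 == set()

    def test_impossible_cut_gives_empty_groups(self):
        from codonshift.enrichment import EnrichmentResult

        res = [EnrichmentResult("s1", "s1", 2, -0.8, -2.0, 0.001, 0.0001, -1,
                                ("a",))]
        with pytest.warns(UserWarning, match="no significant sets"):
            gp1, gp2 = derive_groups(res, fdr_cut=0.0)
        assert gp1 == set() and gp2 == set()

    def test_planted_groups_recovered(self, default_comp, default_genome):
        _, truth = default_genome
        sets = make_gene_sets(truth, seed=3)
        ranked = rank_by_gc3(default_comp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = preranked_enrichment(ranked, sets, n_perm=1000, seed=4)
        # full membership: recovery of the planted structure
        gp1, gp2 = derive_groups(res, use_leading_edge=False, sets=sets)
        j1 = len(gp1 & set(truth.gp1)) / len(gp1 | set(truth.gp1))
        j2 = len(gp2 & set(truth.gp2)) / len(gp2 | set(truth.gp2))
        assert j1 >= 0.8 and j2 >= 0.8
        # leading edge (the default) recovers the majority of each group
        le1, le2 = derive_groups(res)
        assert len(le1 & set(truth.gp1)) / len(truth.gp1) > 0.5
        assert len(le2 & set(truth.gp2)) / len(truth.gp2) > 0.5
        assert not le1 & le2


class TestPerturbationRobustness:
    @pytest.fixture(scope="class")
    def robustness_inputs(self, default_comp, default_genome):
        _, truth = default_genome
        return default_comp["gc3_pct"], make_gene_sets(truth, seed=3), truth

    def test_zero_delta_equals_unperturbed_count(self, robustness_inputs):
        gc3, sets, _ = robustness_inputs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = perturbation_robustness(gc3, sets, [0.0], n_reps=5,
                                            n_perm=500, seed=5)
            ranked = rank_by_gc3(gc3)
            res = preranked_enrichment(ranked, sets, n_perm=500, seed=99)
        unperturbed = sum(1 for r in res if r.fdr_bh < 0.01)
        assert table.loc[0, "surviving_count"] == unperturbed
        assert unperturbed >= 2  # both planted sets are far from borderline

    def test_counts_decay_to_zero_beyond_the_planted_gap(self, robustness_inputs):
        gc3, sets, _ = robustness_inputs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = perturbation_robustness(
                gc3, sets, [0.0, 5.0, 15.0, 40.0], n_reps=5, n_perm=500,
                seed=6,
            )
        counts = table["surviving_count"].to_numpy()
        assert np.all(np.diff(counts) <= 0)
        assert counts[-1] == 0

    def test_negative_delta_is_error(self, robustness_inputs):
        gc3, sets, _ = robustness_inputs
        with pytest.raises(ValueError):
            perturbation_robustness(gc3, sets, [-1.0], n_reps=5, seed=0)
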