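import numpy as np
import pandas as pd
import pytest

import oracles
from pairedlfq.enrichment import (
    GeneSetCollection,
    RankedList,
    enrichment_score,
    overrepresentation,
    permutation_null,
    preranked,
)


def ranked(n=10, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"g{i}" for i in range(n)]
    return RankedList.from_scores(ids, rng.normal(0, 2, n))


class TestRankedList:
    def test_stable_descending_sort_with_ties(self):
        rl = RankedList.from_scores(["a", "b", "c", "d"], [1.0, 3.0, 1.0, 2.0])
        assert rl.ids == ["b", "d", "a", "c"]  # ties keep input order

    def test_rejects_duplicates_and_unsorted_scores(self):
        with pytest.raises(ValueError, match="unique"):
            RankedList(["a", "a"], [2.0, 1.0])
        with pytest.raises(ValueError, match="nonincreasing"):
            RankedList(["a", "b"], [1.0, 2.0])


class TestEnrichmentScore:
    def test_unweighted_top_singleton_hits_es_one(self):
        rl = RankedList([f"g{i}" for i in range(4)], [4.0, 3.0, 2.0, 1.0])
        es, _, edge = enrichment_score(rl, {"g0"}, weight=0.0)
        assert es == pytest.approx(1.0)
        assert edge == ["g0"]

    def test_five_gene_instance_matches_brute_force_walk(self):
        rl = RankedList(list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0])
        es, running, _ = enrichment_score(rl, {"a", "c"}, weight=1.0)
        b_es, b_running = oracles.brute_enrichment_score(
            list("abcde"), [5.0, 4.0, 3.0, 2.0, 1.0], {"a", "c"}, 1.0
        )
        assert es == pytest.approx(b_es, abs=1e-12)
        np.testing.assert_allclose(running, b_running, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_brute_force(self, seed):
        rl = ranked(40, seed)
        rng = np.random.default_rng(100 + seed)
        members = set(rng.choice(rl.ids, 8, replace=False))
        es, running, _ = enrichment_score(rl, members)
        b_es, b_running = oracles.brute_enrichment_score(
            rl.ids, list(rl.scores), members, 1.0
        )
        assert es == pytest.approx(b_es, abs=1e-12)
        np.testing.assert_allclose(running, b_running, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_sign_and_order_reversal_negates_es(self, seed):
        rl = ranked(30, seed)
        rng = np.random.default_rng(200 + seed)
        members = set(rng.choice(rl.ids, 6, replace=False))
        es, _, _ = enrichment_score(rl, members)
        flipped = RankedList(rl.ids[::-1], -rl.scores[::-1])
        es_f, _, _ = enrichment_score(flipped, members)
        assert es_f == pytest.approx(-es, abs=1e-12)

    def test_running_sum_returns_to_zero(self):
        rl = ranked(50, 9)
        members = set(rl.ids[3:9])
        for w in (0.0, 1.0):
            _, running, _ = enrichment_score(rl, members, weight=w)
            assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_weight_zero_es_invariant_to_monotone_rescaling(self):
        rl = ranked(30, 3)
        members = set(rl.ids[2:7])
        es, _, _ = enrichment_score(rl, members, weight=0.0)
        rescaled = RankedList(rl.ids, np.exp(rl.scores))  # monotone, positive
        es2, _, _ = enrichment_score(rescaled, members, weight=0.0)
        assert es2 == pytest.approx(es, abs=1e-12)

    def test_no_overlap_and_full_cover_are_errors(self):
        rl = ranked(5)
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(rl, {"zzz"})
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(rl, set(rl.ids))

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_gseapy_prerank(self, seed):
        gseapy = pytest.importorskip("gseapy")
        rl = ranked(30, 50 + seed)
        rng = np.random.default_rng(300 + seed)
        members = set(rng.choice(rl.ids, 6, replace=False))
        es, _, _ = enrichment_score(rl, members, weight=1.0)
        rnk = pd.DataFrame({"gene": rl.ids, "score": rl.scores})
        res = gseapy.prerank(
            rnk=rnk, gene_sets={"S": sorted(members)}, permutation_num=10,
            min_size=1, max_size=1000, seed=0, outdir=None, no_plot=True,
        )
        assert es == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-9)


class TestPermutationNull:
    def test_fixed_seed_is_bit_reproducible(self):
        rl = ranked(60, 4)
        members = set(rl.ids[:8])
        a = permutation_null(rl, members, n_perm=200, seed=11)
        b = permutation_null(rl, members, n_perm=200, seed=11)
        assert a == b

    def test_strong_enrichment_gets_an_add_one_bounded_small_p(self):
        # no same-sign null can beat a top-block set, so p sits at the
        # add-one floor over the same-sign null count (> 0, never 0)
        rl = RankedList([f"g{i}" for i in range(200)],
                        np.linspace(10, 0.1, 200))
        nes, p, _ = permutation_null(rl, set(rl.ids[:10]), n_perm=200, seed=1)
        assert 1.0 / 201.0 <= p < 0.02
        assert nes > 1

    def test_null_p_values_are_calibrated(self):
        # random sets on regenerated data: P(p < 0.05) should be near 0.05
        hits = 0
        reps = 200
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            rl = RankedList.from_scores(
                [f"g{i}" for i in range(50)], rng.normal(0, 1, 50)
            )
            members = set(rng.choice(rl.ids, 8, replace=False))
            _, p, _ = permutation_null(rl, members, n_perm=100, seed=r)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_n_perm_floor_is_enforced(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(ranked(10), {"g1"}, n_perm=10, seed=0)


class TestOverrepresentation:
    def test_exact_hypergeometric_tail(self):
        # universe 10, set 5, hits 4, overlap 4 -> C(5,4)C(5,0)/C(10,4)
        universe = {f"u{i}" for i in range(10)}
        members = set(list(universe)[:5])
        hits = set(list(members)[:4])
        gsc = GeneSetCollection({"S": members})
        res = overrepresentation(hits, universe, gsc)
        assert res["p_value"].item() == pytest.approx(5 / 210)
        assert res["overlap_count"].item() == 4

    def test_zero_overlap_gives_p_one(self):
        universe = {f"u{i}" for i in range(10)}
        gsc = GeneSetCollection({"S": set(list(universe)[:5])})
        hits = set(list(universe)[5:8])
        res = overrepresentation(hits, universe, gsc)
        assert res["p_value"].item() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_one_sided_fisher_exact(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(20, 100))
        n = int(rng.integers(2, M - 1))
        N = int(rng.integers(2, M - 1))
        universe = {f"u{i}" for i in range(M)}
        members = set(rng.choice(sorted(universe), n, replace=False))
        hits = set(rng.choice(sorted(universe), N, replace=False))
        res = overrepresentation(hits, universe, GeneSetCollection({"S": members}))
        k = len(members & hits)
        assert res["p_value"].item() == pytest.approx(
            oracles.fisher_upper_tail(k, M, n, N), rel=1e-9
        )

    def test_p_monotone_in_overlap_at_fixed_margins(self):
        from scipy.stats import hypergeom

        ps = [float(hypergeom.sf(k - 1, 50, 10, 12)) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_hits_outside_universe_are_rejected(self):
        gsc = GeneSetCollection({"S": {"a"}})
        with pytest.raises(ValueError, match="outside"):
            overrepresentation({"zzz"}, {"a", "b"}, gsc)


def test_preranked_collection_reports_bh_adjusted_p():
    rl = ranked(80, 8)
    rng = np.random.default_rng(77)
    sets = {
        f"S{i}": set(rng.choice(rl.ids, 10, replace=False)) for i in range(4)
    }
    out = preranked(rl, GeneSetCollection(sets), n_perm=100, seed=5)
    assert set(out["set_name"]) == set(sets)
    assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()
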