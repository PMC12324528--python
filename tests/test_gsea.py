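import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somamod.gmt import GeneSet, GeneSetCollection
from somamod.gsea import (GseaParams, RankedList, build_ranked_list, enrichment_score,
                          gsea_collection, gsea_preranked, normalize_and_test,
                          permutation_null, step_variable)

from _oracles import brute_force_es


def ranked(ids, scores):
    return build_ranked_list(dict(zip(ids, scores)))


def uniform_ranked(n):
    return ranked([f"g{i:03d}" for i in range(n)], list(np.linspace(3, -3, n)))


class TestRankedList:
    def test_sorted_by_score_descending(self):
        rl = ranked(["a", "b", "c"], [2.0, -1.0, 3.0])
        assert rl.identifiers == ["c", "a", "b"]

    def test_ties_ordered_by_identifier(self):
        rl = ranked(["b", "a"], [1.0, 1.0])
        assert rl.identifiers == ["a", "b"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_ranked_list({})

    def test_duplicate_identifier_rejected(self):
        with pytest.raises(ValueError):
            RankedList(identifiers=["a", "a"], scores=np.array([2.0, 1.0]))

    def test_rnk_file_round_trip(self, tmp_path):
        p = tmp_path / "x.rnk"
        p.write_text("# comment\nb\t1.5\na\t-0.5\nc\t2.0\n")
        rl = RankedList.from_file(p)
        assert rl.identifiers == ["c", "b", "a"]

    def test_rnk_sanitize_option(self, tmp_path):
        p = tmp_path / "x.rnk"
        p.write_text("10346-5\t1.0\n10354-57\t0.5\n")
        rl = RankedList.from_file(p, sanitize=True)
        assert rl.identifiers == ["10346_5", "10354_57"]


class TestStepVariable:
    def test_unweighted_alternating_steps(self):
        rl = ranked(["a", "b", "c", "d"], [4.0, 3.0, 2.0, 1.0])
        prof = step_variable(rl, ["a", "c"], weight=0)
        assert np.allclose(prof.steps, [0.5, -0.5, 0.5, -0.5])

    def test_weighted_steps_direct_evaluation(self):
        # scores (3, 1, -2), member at the top, p=1:
        # member step = |3|/|3| = 1; the two non-members each get -1/2
        rl = ranked(["a", "b", "c"], [3.0, 1.0, -2.0])
        prof = step_variable(rl, ["a"], weight=1)
        assert np.allclose(prof.steps, [1.0, -0.5, -0.5])

    def test_steps_sum_to_zero_and_running_ends_at_zero(self):
        rl = uniform_ranked(30)
        prof = step_variable(rl, ["g002", "g011", "g025"], weight=1.5)
        assert abs(prof.steps.sum()) < 1e-9
        assert abs(prof.running[-1]) < 1e-9

    def test_members_outside_universe_ignored(self):
        rl = uniform_ranked(10)
        prof = step_variable(rl, ["g001", "NOT_THERE"], weight=0)
        assert prof.steps[1] == pytest.approx(1.0)

    def test_full_universe_set_rejected(self):
        rl = uniform_ranked(5)
        with pytest.raises(ValueError):
            step_variable(rl, [f"g{i:03d}" for i in range(5)], weight=0)

    def test_empty_intersection_rejected(self):
        rl = uniform_ranked(5)
        with pytest.raises(ValueError):
            step_variable(rl, ["zzz"], weight=0)

    def test_all_zero_member_scores_fall_back_to_uniform(self, caplog):
        rl = ranked(["a", "b", "c", "d"], [1.0, 0.0, 0.0, -1.0])
        with caplog.at_level("WARNING"):
            prof = step_variable(rl, ["b", "c"], weight=2)
        assert np.allclose(prof.steps, [-0.5, 0.5, 0.5, -0.5])


class TestEnrichmentScore:
    def test_top_prefix_gives_plus_one(self):
        rl = uniform_ranked(20)
        prof = step_variable(rl, [f"g{i:03d}" for i in range(5)], weight=0)
        assert enrichment_score(prof) == pytest.approx(1.0)

    def test_bottom_suffix_gives_minus_one(self):
        rl = uniform_ranked(20)
        prof = step_variable(rl, [f"g{i:03d}" for i in range(15, 20)], weight=0)
        assert enrichment_score(prof) == pytest.approx(-1.0)

    def test_alternating_four_element_case(self):
        rl = ranked(["a", "b", "c", "d"], [4.0, 3.0, 2.0, 1.0])
        prof = step_variable(rl, ["a", "c"], weight=0)
        assert np.allclose(prof.running[1:], [0.5, 0.0, 0.5, 0.0])
        assert enrichment_score(prof) == pytest.approx(0.5)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_es_bounded_and_profile_closes(self, data):
        n = data.draw(st.integers(5, 40))
        m = data.draw(st.integers(1, n - 1))
        weight = data.draw(st.sampled_from([0.0, 1.0, 1.5, 2.0]))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        rl = ranked([f"g{i:03d}" for i in range(n)],
                    sorted(rng.standard_normal(n), reverse=True))
        members = [f"g{i:03d}" for i in rng.choice(n, size=m, replace=False)]
        prof = step_variable(rl, members, weight)
        assert abs(prof.es) <= 1 + 1e-12
        assert abs(prof.running[-1]) < 1e-9

    def test_unweighted_es_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(4)
        scores = sorted(rng.standard_normal(30), reverse=True)
        ids = [f"g{i:03d}" for i in range(30)]
        members = ["g003", "g007", "g019", "g022"]
        es_raw = step_variable(ranked(ids, scores), members, 0).es
        warped = [np.tanh(s) * 5 + 0.1 * s for s in scores]  # strictly monotone
        es_warped = step_variable(ranked(ids, warped), members, 0).es
        assert es_raw == pytest.approx(es_warped)


class TestOracleEquivalence:
    @pytest.mark.parametrize("weight", [0.0, 1.0, 1.5, 2.0])
    def test_matches_brute_force_on_random_instances(self, weight):
        rng = np.random.default_rng(17)
        for _ in range(50):  # 50 per weight = 200 instances
            n = int(rng.integers(5, 51))
            m = int(rng.integers(1, n))
            scores = np.sort(rng.standard_normal(n))[::-1]
            ids = [f"g{i:03d}" for i in range(n)]
            members = [ids[i] for i in rng.choice(n, size=m, replace=False)]
            rl = ranked(ids, list(scores))
            prof = step_variable(rl, members, weight)
            flags = [i in set(members) for i in rl.identifiers]
            es_bf, running_bf = brute_force_es(rl.scores, flags, weight)
            assert prof.es == es_bf
            assert np.allclose(prof.running[1:], running_bf, atol=1e-12)
            assert abs(sum(prof.steps)) < 1e-9


class TestPermutationNull:
    def test_same_seed_identical(self):
        rl = uniform_ranked(100)
        params = GseaParams(n_permutations=50, seed=5)
        a = permutation_null(rl, 10, params)
        b = permutation_null(rl, 10, params)
        assert np.array_equal(a, b)

    def test_null_values_bounded(self):
        rl = uniform_ranked(100)
        null = permutation_null(rl, 8, GseaParams(n_permutations=200, seed=1))
        assert np.all(np.abs(null) <= 1 + 1e-12)

    def test_unweighted_null_mean_near_zero(self):
        rl = uniform_ranked(200)
        null = permutation_null(rl, 20, GseaParams(n_permutations=4000, seed=3))
        # ES is a max-deviation statistic; its *signed* null is near-symmetric
        assert abs(null.mean()) < 3 * null.std() / np.sqrt(len(null))

    def test_set_size_bounds_enforced(self):
        rl = uniform_ranked(10)
        with pytest.raises(ValueError):
            permutation_null(rl, 10, GseaParams())

    def test_matches_scalar_path(self):
        # vectorized permutation ES agrees with the scalar profile code on
        # the same drawn sets
        rl = uniform_ranked(60)
        params = GseaParams(weight=1.0, n_permutations=20, seed=8)
        rng = np.random.default_rng(params.seed)
        pos = np.argsort(rng.random((params.n_permutations, rl.n)), axis=1)[:, :7]
        null = permutation_null(rl, 7, params)
        for row, es in zip(pos, null):
            members = [rl.identifiers[i] for i in row]
            assert step_variable(rl, members, params.weight).es == pytest.approx(es, abs=1e-12)


class TestNormalizeAndTest:
    def test_nes_definition(self):
        nes, _ = normalize_and_test(0.8, np.array([0.4, 0.4, 0.4, -0.2]))
        assert nes == pytest.approx(2.0)

    def test_extreme_es_p_is_pseudocounted(self):
        null = np.abs(np.random.default_rng(0).normal(0.2, 0.05, 1000))
        _, p = normalize_and_test(0.99, null)
        assert p == pytest.approx(1 / 1001)

    def test_sign_stratification(self):
        null = np.array([-0.5, -0.4, 0.3, 0.2])
        nes_pos, _ = normalize_and_test(0.5, null)
        nes_neg, _ = normalize_and_test(-0.5, null)
        assert nes_pos == pytest.approx(0.5 / 0.25)
        assert nes_neg == pytest.approx(-0.5 / 0.45)

    def test_no_same_sign_null_reported_undefined(self):
        nes, p = normalize_and_test(-0.5, np.array([0.1, 0.2]))
        assert nes is None and p is None


class TestCollectionRuns:
    def test_fully_top_set(self):
        rl = uniform_ranked(50)
        coll = GeneSetCollection(prefix="T", sets=[
            GeneSet(set_id="TOP", name="TOP", members=[f"g{i:03d}" for i in range(6)])],
            id_space="symbol")
        res = gsea_collection(rl, coll, GseaParams(n_permutations=200, seed=2))
        assert res[0].es == pytest.approx(1.0)
        assert res[0].nominal_p <= 1 / 100

    def test_identical_seed_identical_results(self):
        rl = uniform_ranked(80)
        coll = GeneSetCollection(prefix="T", sets=[
            GeneSet(set_id="A", name="A", members=[f"g{i:03d}" for i in range(4, 14)]),
            GeneSet(set_id="B", name="B", members=[f"g{i:03d}" for i in range(40, 48)])],
            id_space="symbol")
        params = GseaParams(n_permutations=100, seed=42)
        r1 = gsea_collection(rl, coll, params)
        r2 = gsea_collection(rl, coll, params)
        assert [(r.set_id, r.es, r.nes, r.nominal_p) for r in r1] == \
               [(r.set_id, r.es, r.nes, r.nominal_p) for r in r2]

    def test_per_set_nulls_independent_of_other_sets(self):
        rl = uniform_ranked(80)
        a = GeneSet(set_id="A", name="A", members=[f"g{i:03d}" for i in range(4, 14)])
        b = GeneSet(set_id="B", name="B", members=[f"g{i:03d}" for i in range(40, 48)])
        params = GseaParams(n_permutations=100, seed=42)
        alone = gsea_collection(rl, GeneSetCollection(prefix="T", sets=[a],
                                                      id_space="symbol"), params)
        together = gsea_collection(rl, GeneSetCollection(prefix="T", sets=[b, a],
                                                         id_space="symbol"), params)
        res_a = next(r for r in together if r.set_id == "A")
        assert (alone[0].es, alone[0].nes, alone[0].nominal_p) == \
               (res_a.es, res_a.nes, res_a.nominal_p)

    def test_disjoint_set_skipped_with_warning(self, caplog):
        rl = uniform_ranked(20)
        coll = GeneSetCollection(prefix="T", sets=[
            GeneSet(set_id="GONE", name="GONE", members=["zz1", "zz2"]),
            GeneSet(set_id="OK", name="OK", members=["g001", "g002"])], id_space="symbol")
        with caplog.at_level("WARNING"):
            res = gsea_collection(rl, coll, GseaParams(n_permutations=20, seed=0))
        assert [r.set_id for r in res] == ["OK"]

    def test_planted_enriched_set_detected(self):
        from somamod.ranking import build_scores
        from somamod.synthetic import simulate_ranked_stats
        universe = [f"f{i:04d}" for i in range(1000)]
        enriched = universe[100:130]
        stats = simulate_ranked_stats(universe, enriched, shift=1.5, seed=21)
        rl = build_scores(stats)
        gs = GeneSet(set_id="PLANT", name="PLANT", members=list(enriched))
        res = gsea_preranked(rl, gs, GseaParams(n_permutations=500, seed=21))
        assert res.es > 0
        assert res.nominal_p < 0.05
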