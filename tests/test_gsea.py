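"""Ranking metric, enrichment score, permutation null."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom

import motifmeta as mm
from motifmeta.gsea import _snr, rank_genes
from motifmeta.preprocess import Label

from conftest import brute_force_es, random_ranked_instance


def make_cohort(values, tn_mask, name="toy", genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    labels = [Label.TN if t else Label.ERPOS for t in tn_mask]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return mm.ExpressionCohort(
        name=name, genes=genes, sample_ids=samples, values=values, labels=labels
    )


class TestSignalToNoise:
    def test_floor_engages_for_constant_arms(self):
        # TN (2,2) vs ER (1,1): both sd are 0, floored at 0.2*|mu| -> 0.6
        cohort = make_cohort([[2.0, 2.0, 1.0, 1.0]], [True, True, False, False])
        score = mm.signal_to_noise(cohort)
        assert score[0] == pytest.approx(1.0 / 0.6, rel=1e-12)

    def test_absolute_floor_for_zero_mean_arms(self):
        cohort = make_cohort([[0.0, 0.0, 0.0, 0.0]], [True, True, False, False])
        assert mm.signal_to_noise(cohort)[0] == 0.0

    def test_identical_distributions_score_zero(self):
        cohort = make_cohort(
            [[3.0, 5.0, 3.0, 5.0]], [True, True, False, False]
        )
        assert mm.signal_to_noise(cohort)[0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flips_when_labels_swap(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(10, 8))
        mask = np.array([True] * 4 + [False] * 4)
        a = _snr(values, mask)
        b = _snr(values, ~mask)
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_arm_smaller_than_two_rejected(self):
        cohort_values = np.zeros((2, 4))
        with pytest.raises(ValueError, match="2 samples per arm"):
            _snr(cohort_values, np.array([True, False, False, False]))


class TestEnrichmentScore:
    def ranked(self, metric, genes=None):
        metric = np.asarray(metric, dtype=float)
        genes = genes or [f"G{i:03d}" for i in range(len(metric))]
        return mm.RankedList(genes=tuple(genes), metric=metric)

    def test_single_hit_at_top_scores_one(self):
        ranked = self.ranked([3.0, 2.0, 1.0, 0.5])
        es, rs, edge = mm.enrichment_score(ranked, ["G000"], weight_exponent=1)
        assert es == pytest.approx(1.0)
        assert edge == ("G000",)

    def test_unweighted_bottom_hit_scores_minus_one(self):
        ranked = self.ranked([3.0, 2.0, 1.0, -4.0])
        es, rs, edge = mm.enrichment_score(ranked, ["G003"], weight_exponent=0)
        np.testing.assert_allclose(rs, [-1 / 3, -2 / 3, -1.0, 0.0], atol=1e-12)
        assert es == pytest.approx(-1.0)
        assert edge == ("G003",)

    def test_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ranked, members, w = random_ranked_instance(rng)
            _, rs, _ = mm.enrichment_score(ranked, members, w)
            assert abs(rs[-1]) < 1e-9

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ranked, members, w = random_ranked_instance(rng)
            es, rs, _ = mm.enrichment_score(ranked, members, w)
            es_ref, rs_ref = brute_force_es(
                ranked.metric,
                np.array([g in set(members) for g in ranked.genes]),
                w,
            )
            assert es == pytest.approx(es_ref, abs=1e-12)
            np.testing.assert_allclose(rs, rs_ref, atol=1e-12)

    def test_es_invariant_under_positive_metric_scaling(self):
        rng = np.random.default_rng(5)
        ranked, members, _ = random_ranked_instance(rng)
        es1, _, _ = mm.enrichment_score(ranked, members, 1.0)
        scaled = mm.RankedList(genes=ranked.genes, metric=ranked.metric * 37.5)
        es2, _, _ = mm.enrichment_score(scaled, members, 1.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            ranked, members, w = random_ranked_instance(rng)
            es, _, _ = mm.enrichment_score(ranked, members, w)
            assert -1.0 <= es <= 1.0

    def test_no_overlap_is_an_error(self):
        ranked = self.ranked([2.0, 1.0])
        with pytest.raises(ValueError, match="no overlap"):
            mm.enrichment_score(ranked, ["ABSENT"])

    def test_full_coverage_is_degenerate(self):
        ranked = self.ranked([2.0, 1.0])
        with pytest.raises(ValueError, match="degenerate|whole"):
            mm.enrichment_score(ranked, ["G000", "G001"])

    def test_leading_edge_subset_of_hits_and_nonempty_for_nonzero_es(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            ranked, members, w = random_ranked_instance(rng)
            es, _, edge = mm.enrichment_score(ranked, members, w)
            assert set(edge) <= set(members)
            if es != 0:
                assert edge

    def test_rank_ties_broken_by_gene_symbol(self):
        cohort = make_cohort(
            np.array([[1.0, 1.0, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0]]),
            [True, True, False, False],
            genes=["ZZZ", "AAA"],
        )
        ranked = rank_genes(cohort)
        assert ranked.genes == ("AAA", "ZZZ")


@pytest.fixture(scope="module")
def planted_cohort():
    rng = np.random.default_rng(21)
    values = rng.normal(size=(60, 40))
    values[:10, :20] += 2.0  # strong TN module in genes 0..9
    return make_cohort(values, [True] * 20 + [False] * 20)


class TestPermutationNull:

    def test_planted_module_hits_the_p_floor(self, planted_cohort):
        geneset = mm.GeneSet(name="PLANTED", genes=tuple(f"G{i:03d}" for i in range(10)))
        p, nes = mm.permutation_null(planted_cohort, geneset, n_perm=200, seed=4)
        # all same-sign permutations are weaker than the observed ES
        assert p <= 1.0 / (100 + 1) * 2  # floor given ~half same-sign perms
        assert nes > 1.5

    def test_determinism_under_fixed_seed(self, planted_cohort):
        geneset = mm.GeneSet(name="S", genes=tuple(f"G{i:03d}" for i in range(5, 25)))
        a = mm.permutation_null(planted_cohort, geneset, n_perm=50, seed=123)
        b = mm.permutation_null(planted_cohort, geneset, n_perm=50, seed=123)
        assert a == b

    def test_single_permutation_p_support(self):
        # with n_perm=1 the add-one estimate can only be 1/2 or 1
        rng = np.random.default_rng(8)
        values = rng.normal(size=(30, 12))
        cohort = make_cohort(values, [True] * 6 + [False] * 6)
        geneset = mm.GeneSet(name="S", genes=tuple(f"G{i:03d}" for i in range(8)))
        ps = {
            mm.permutation_null(cohort, geneset, n_perm=1, seed=s)[0]
            for s in range(10)
        }
        assert ps <= {0.5, 1.0}

    def test_null_p_values_are_calibrated(self):
        """Exchangeable data: P(p <= 0.05) within the binomial 99% band."""
        rng = np.random.default_rng(17)
        hits = 0
        n_runs = 200
        for i in range(n_runs):
            values = rng.normal(size=(40, 16))
            cohort = make_cohort(values, [True] * 8 + [False] * 8)
            geneset = mm.GeneSet(
                name="S", genes=tuple(f"G{i:03d}" for i in range(12))
            )
            p, _ = mm.permutation_null(cohort, geneset, n_perm=99, seed=1000 + i)
            hits += p <= 0.05
        lo = binom.ppf(0.005, n_runs, 0.05)
        hi = binom.ppf(0.995, n_runs, 0.05)
        assert lo <= hits <= hi


class TestRunGsea:
    def test_small_sets_filtered_by_min_size(self, small_cohorts, small_study):
        tiny = mm.GeneSetCollection(
            sets=(
                mm.GeneSet(name="TINY", genes=tuple(f"GENE{i:04d}" for i in range(1, 11))),
            ),
            kind="motif",
        )
        res = mm.run_gsea(
            small_cohorts[0], tiny, mm.GseaParams(min_size=15, n_perm=10)
        )
        assert res == []

    def test_planted_set_beats_disjoint_decoy(self, small_cohorts, small_study):
        planted_name = next(iter(small_study.truth.shifted_genes))
        planted = small_study.motif_sets[planted_name]
        taken = {
            g for s in small_study.motif_sets if s.name.startswith("V$PLANTED")
            for g in s.genes
        }
        free = [g for g in small_cohorts[0].genes if g not in taken]
        decoy = mm.GeneSet(name="DISJOINT_DECOY", genes=tuple(free[: len(planted)]))
        coll = mm.GeneSetCollection(sets=(planted, decoy), kind="motif")
        res = {
            r.set_name: r
            for r in mm.run_gsea(
                small_cohorts[0], coll, mm.GseaParams(min_size=10, n_perm=100), seed=2
            )
        }
        assert (res[planted_name].p_nominal, -res[planted_name].es) < (
            res["DISJOINT_DECOY"].p_nominal,
            -res["DISJOINT_DECOY"].es,
        )

    def test_same_seed_gives_identical_results(self, small_cohorts, small_study):
        params = mm.GseaParams(min_size=10, n_perm=30)
        a = mm.run_gsea(small_cohorts[1], small_study.motif_sets, params, seed=5)
        b = mm.run_gsea(small_cohorts[1], small_study.motif_sets, params, seed=5)
        assert a == b

    def test_empty_collection_gives_empty_result(self, small_cohorts):
        coll = mm.GeneSetCollection(sets=(), kind="motif")
        assert mm.run_gsea(small_cohorts[0], coll) == []

    def test_p_nominal_respects_add_one_floor(self, small_cohorts, small_study):
        res = mm.run_gsea(
            small_cohorts[0],
            small_study.motif_sets,
            mm.GseaParams(min_size=10, n_perm=50),
            seed=0,
        )
        for r in res:
            assert r.p_nominal >= 1.0 / (r.n_perm + 1)
            assert set(r.leading_edge) <= set(
                small_study.motif_sets[r.set_name].genes
            )
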