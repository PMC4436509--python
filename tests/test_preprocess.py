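"""Probe collapse and IHC phenotype classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import motifmeta as mm
from motifmeta.io import WITHDRAWN
from motifmeta.preprocess import Label


def make_map(rows):
    return mm.ProbeMap(
        table=pd.DataFrame(rows, columns=["probe_id", "accession", "symbol"])
    )


class TestCollapseProbes:
    def test_single_probe_gene_is_identity(self):
        raw = mm.RawExpression(["p1"], ["s1", "s2"], np.array([[3.0, 4.0]]))
        genes, matrix = mm.collapse_probes(raw, make_map([("p1", "A", "GENE1")]))
        assert genes == ["GENE1"]
        np.testing.assert_allclose(matrix, [[3.0, 4.0]])

    def test_per_sample_maximum_is_taken_independently_per_sample(self):
        # p1 wins in sample 1, p2 in sample 2: the collapsed profile is
        # chimeric across probes by design.
        raw = mm.RawExpression(
            ["p1", "p2"], ["s1", "s2"], np.array([[5.0, 1.0], [2.0, 4.0]])
        )
        pmap = make_map([("p1", "A", "GENE1"), ("p2", "A", "GENE1")])
        genes, matrix = mm.collapse_probes(raw, pmap)
        np.testing.assert_allclose(matrix, [[5.0, 4.0]])

    def test_withdrawn_probe_absent_from_output(self):
        raw = mm.RawExpression(
            ["p1", "p2"], ["s1", "s2"], np.array([[1.0, 1.0], [9.0, 9.0]])
        )
        pmap = make_map([("p1", "A", "GENE1"), ("p2", "W", WITHDRAWN)])
        genes, matrix = mm.collapse_probes(raw, pmap)
        assert genes == ["GENE1"]
        np.testing.assert_allclose(matrix, [[1.0, 1.0]])

    def test_unmapped_probe_is_an_error_listing_probes(self):
        raw = mm.RawExpression(["p9"], ["s1", "s2"], np.zeros((1, 2)))
        with pytest.raises(ValueError, match="p9"):
            mm.collapse_probes(raw, make_map([("p1", "A", "GENE1")]))

    def test_all_probes_withdrawn_is_an_error(self):
        raw = mm.RawExpression(["p1"], ["s1", "s2"], np.zeros((1, 2)))
        with pytest.raises(ValueError, match="withdrawn"):
            mm.collapse_probes(raw, make_map([("p1", "W", WITHDRAWN)]))

    def test_collapse_is_idempotent_on_one_probe_per_gene(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(4, 3))
        raw = mm.RawExpression(
            [f"p{i}" for i in range(4)], ["s1", "s2", "s3"], values
        )
        pmap = make_map([(f"p{i}", "A", f"GENE{i}") for i in range(4)])
        genes, matrix = mm.collapse_probes(raw, pmap)
        raw2 = mm.RawExpression(genes, ["s1", "s2", "s3"], matrix)
        pmap2 = make_map([(g, "A", g) for g in genes])
        genes2, matrix2 = mm.collapse_probes(raw2, pmap2)
        assert genes2 == genes
        np.testing.assert_allclose(matrix2, matrix)

    def test_global_max_mean_keeps_a_single_probe_profile(self):
        raw = mm.RawExpression(
            ["p1", "p2"], ["s1", "s2"], np.array([[5.0, 1.0], [2.0, 5.0]])
        )
        pmap = make_map([("p1", "A", "GENE1"), ("p2", "A", "GENE1")])
        genes, matrix = mm.collapse_probes(raw, pmap, method="global_max_mean")
        # p2 has the higher mean (3.5 vs 3): its whole profile is kept
        np.testing.assert_allclose(matrix, [[2.0, 5.0]])

    def test_gene_count_never_exceeds_unique_mapped_symbols(self, small_study):
        c = small_study.cohorts[0]
        genes, _ = mm.collapse_probes(c.raw, c.probe_map)
        mapped = {
            s for s in c.probe_map.symbols.values() if s != WITHDRAWN
        }
        assert len(genes) <= len(mapped)
        assert set(genes) == mapped


class TestClassifySamples:
    @pytest.mark.parametrize(
        "code,tn,er,expected",
        [
            ("NNN", "NNN", "PXN", Label.TN),
            ("PPN", "NNN", "PXN", Label.ERPOS),  # X matches P
            ("PNN", "NNN", "PXN", Label.ERPOS),
            ("Nn1", "Nn1", "PX1", Label.TN),  # METABRIC dialect
            ("PP1", "Nn1", "PX1", Label.ERPOS),
            ("NN1", "NNN", "PXN", Label.EXCLUDED),  # wrong dialect
            ("NNP", "NNN", "PXN", Label.EXCLUDED),  # HER2+
            ("nnn", "NNN", "PXN", Label.EXCLUDED),  # case-sensitive
            (None, "NNN", "PXN", Label.EXCLUDED),  # absent metadata
        ],
    )
    def test_pattern_matching(self, code, tn, er, expected):
        pheno = mm.PhenotypeTable(codes={"s": code})
        labels = mm.classify_samples(
            pheno, mm.PhenotypePattern(tn=tn, er=er)
        )
        assert labels["s"] is expected

    def test_pattern_length_enforced(self):
        with pytest.raises(ValueError, match="length 3"):
            mm.PhenotypePattern(tn="NN", er="PXN")


class TestBuildCohort:
    @pytest.fixture()
    def six_sample_inputs(self):
        rng = np.random.default_rng(1)
        raw = mm.RawExpression(
            probe_ids=["p1", "p2"],
            sample_ids=[f"s{i}" for i in range(6)],
            values=rng.normal(size=(2, 6)),
        )
        pmap = make_map([("p1", "A", "GENE1"), ("p2", "A", "GENE2")])
        pheno = mm.PhenotypeTable(
            codes={
                "s0": "NNN",
                "s1": "NNN",
                "s2": "NNN",
                "s3": "PPN",
                "s4": "PNN",
                "s5": None,
            }
        )
        return raw, pmap, pheno

    def test_excluded_samples_dropped_and_arms_counted(self, six_sample_inputs):
        raw, pmap, pheno = six_sample_inputs
        cohort = mm.build_cohort("toy", raw, pmap, pheno, mm.PhenotypePattern())
        assert cohort.n == 5
        assert (cohort.n_tn, cohort.n_er) == (3, 2)
        assert "s5" not in cohort.sample_ids
        assert cohort.n_tn + cohort.n_er == cohort.n

    def test_all_excluded_is_an_error(self, six_sample_inputs):
        raw, pmap, _ = six_sample_inputs
        pheno = mm.PhenotypeTable(codes={f"s{i}": None for i in range(6)})
        with pytest.raises(ValueError, match="empty arm"):
            mm.build_cohort("toy", raw, pmap, pheno, mm.PhenotypePattern())

    def test_simulated_cohorts_classify_back_to_configured_arms(
        self, small_study, small_cohorts
    ):
        for inputs, cohort, (n_tn, n_er) in zip(
            small_study.cohorts, small_cohorts, small_study.config.cohort_arms
        ):
            assert (cohort.n_tn, cohort.n_er) == (n_tn, n_er)
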