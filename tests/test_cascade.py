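"""Database novelty cascade and recessive candidate-gene models."""

import numpy as np
import pytest

from mendelseek.cascade import (CascadeConfig, compound_het_model,
                                run_cascade, shared_homozygote_model,
                                shared_variants, stage_filter)
from mendelseek.qc import QCThresholds
from mendelseek.simulate import SimConfig, sequenced_affected, simulate_family
from mendelseek.variants import DatabaseCatalog, VariantConfigError
from .conftest import make_table


def _catalog(keys, name="cat"):
    return DatabaseCatalog(name=name, sites=frozenset(keys))


class TestStageFilter:
    def test_two_of_five_removed(self):
        rows = [{"chrom": "1", "pos": 100 * i, "ref": "A", "alt": "G"}
                for i in range(1, 6)]
        t = make_table(rows, [[1, 1]] * 5, ["S1", "S2"])
        cat = _catalog([("1", 100, "G"), ("1", 300, "G")])
        assert len(stage_filter(t, cat)) == 3

    def test_empty_catalog_is_identity(self, toy_table):
        out = stage_filter(toy_table, _catalog([]))
        assert list(out.records["pos"]) == list(toy_table.records["pos"])

    def test_matches_set_difference_oracle(self):
        rng = np.random.default_rng(5)
        rows = [{"chrom": str(rng.integers(1, 4)),
                 "pos": int(rng.integers(1, 50)) * 10,
                 "ref": "A", "alt": "G"} for _ in range(60)]
        t = make_table(rows, [[1, 1]] * 60, ["S1", "S2"])
        cat_keys = {(str(rng.integers(1, 4)),
                     int(rng.integers(1, 50)) * 10, "G")
                    for _ in range(40)}
        out = stage_filter(t, _catalog(cat_keys))
        # naive double loop
        expect = [i for i, k in enumerate(t.keys())
                  if not any(k == c for c in cat_keys)]
        assert list(out.records.index) == list(range(len(expect)))
        assert len(out) == len(expect)
        assert out.keys() == [t.keys()[i] for i in expect]


class TestSharedVariants:
    def test_missing_in_one_affected_excluded(self):
        rows = [{"chrom": "1", "pos": 100, "ref": "A", "alt": "G"}]
        t = make_table(rows, [[1, -1]], ["II2", "II3"])
        assert len(shared_variants(t, ["II2", "II3"])) == 0

    def test_hom_alt_in_both_included(self):
        rows = [{"chrom": "1", "pos": 100, "ref": "A", "alt": "G"}]
        t = make_table(rows, [[2, 2]], ["II2", "II3"])
        assert len(shared_variants(t, ["II2", "II3"])) == 1

    def test_matches_bruteforce_predicate(self):
        rng = np.random.default_rng(9)
        n = 80
        rows = [{"chrom": "1", "pos": 10 * (i + 1), "ref": "A", "alt": "G",
                 "vclass": str(rng.choice(["NS", "SS", "Indel", "other"]))}
                for i in range(n)]
        g = rng.integers(-1, 3, size=(n, 3)).astype(np.int8)
        t = make_table(rows, g, ["A1", "A2", "U1"])
        out = shared_variants(t, ["A1", "A2"])
        expect = [i for i in range(n)
                  if rows[i]["vclass"] in ("NS", "SS", "Indel")
                  and g[i, 0] >= 1 and g[i, 1] >= 1]
        assert len(out) == len(expect)

    def test_unknown_sample_is_config_error(self, toy_table):
        with pytest.raises(VariantConfigError):
            shared_variants(toy_table, ["NOPE"])


class TestInheritanceModels:
    def test_shared_homozygote(self):
        rows = [
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "G", "gene": "X"},
            {"chrom": "1", "pos": 200, "ref": "A", "alt": "G", "gene": "Y"},
        ]
        t = make_table(rows, [[2, 2], [2, 1]], ["II2", "II3"])
        assert shared_homozygote_model(t, ["II2", "II3"]) == ["X"]

    def test_compound_het_trans_confirmed(self, fam1_ped):
        # father carries only A, mother only B -> trans possible
        rows = [
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "T", "gene": "G"},
            {"chrom": "1", "pos": 200, "ref": "G", "alt": "T", "gene": "G"},
        ]
        # samples: affected II1, II2; parents I1, I2 in the table
        t = make_table(rows, [[1, 1, 1, 0], [1, 1, 0, 1]],
                       ["II1", "II2", "I1", "I2"])
        cands, phase_unknown = compound_het_model(
            t, ["II1", "II2"], pedigree=fam1_ped)
        assert cands == ["G"] and phase_unknown == []

    def test_single_het_variant_not_candidate(self):
        rows = [{"chrom": "1", "pos": 100, "ref": "A", "alt": "T",
                 "gene": "G"}]
        t = make_table(rows, [[1, 1]], ["II1", "II2"])
        assert compound_het_model(t, ["II1", "II2"])[0] == []

    def test_cis_configuration_excluded_with_pedigree(self, fam1_ped):
        """One parent carrying both variants: no trans assignment."""
        rows = [
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "T", "gene": "G"},
            {"chrom": "1", "pos": 200, "ref": "G", "alt": "T", "gene": "G"},
        ]
        t = make_table(rows, [[1, 1, 1, 0], [1, 1, 1, 0]],
                       ["II1", "II2", "I1", "I2"])
        cands, _ = compound_het_model(t, ["II1", "II2"], pedigree=fam1_ped)
        assert cands == []
        # enumeration oracle: father has both on his two haplotypes at
        # most, mother has neither -> affected children cannot be het
        # at both with one from each parent
        cands_no_ped, unknown = compound_het_model(t, ["II1", "II2"])
        assert cands_no_ped == ["G"] and unknown == ["G"]


@pytest.fixture(scope="module")
def sim():
    return simulate_family(SimConfig(seed=7, n_background_variants=500))


class TestRunCascade:

    def test_planted_gene_is_unique_candidate(self, sim):
        aff = sequenced_affected(sim)
        rep = run_cascade(sim.table, QCThresholds(),
                          CascadeConfig(stages=sim.catalogs,
                                        affected_samples=aff),
                          pedigree=sim.pedigree)
        assert rep.candidate_genes["shared_homozygote"] == [sim.planted_gene]

    def test_matrix_shape_and_monotonicity(self, sim):
        aff = sequenced_affected(sim)
        rep = run_cascade(sim.table, QCThresholds(),
                          CascadeConfig(stages=sim.catalogs,
                                        affected_samples=aff))
        assert rep.matrix.shape == (5, 7)  # input + 4 stages x 7 counts
        for col in rep.matrix.columns:
            v = rep.matrix[col].to_numpy()
            assert (np.diff(v) <= 0).all()
        shared = rep.matrix["shared"].to_numpy()
        per_sample = rep.matrix[list(aff)].to_numpy().min(axis=1)
        assert (shared <= per_sample).all()

    def test_zero_stages(self, sim):
        aff = sequenced_affected(sim)
        rep = run_cascade(sim.table, QCThresholds(),
                          CascadeConfig(stages=[], affected_samples=aff))
        assert list(rep.matrix.index) == ["input"]
        assert sim.planted_gene in rep.candidate_genes["shared_homozygote"]

    def test_stage_order_insensitive_final_sensitive_counts(self, sim):
        """Set subtraction commutes, so final survivors (and candidate
        lists) ignore catalog order; per-stage counts do not."""
        aff = sequenced_affected(sim)
        fwd = run_cascade(sim.table, None,
                          CascadeConfig(stages=sim.catalogs,
                                        affected_samples=aff))
        rev = run_cascade(sim.table, None,
                          CascadeConfig(stages=sim.catalogs[::-1],
                                        affected_samples=aff))
        assert fwd.candidate_genes == rev.candidate_genes
        assert fwd.matrix.iloc[-1].tolist() == rev.matrix.iloc[-1].tolist()
        interior_equal = (
            fwd.matrix.iloc[1:-1].to_numpy()
            == rev.matrix.iloc[1:-1].to_numpy()).all()
        assert not interior_equal  # order shows up mid-cascade
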