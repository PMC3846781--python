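"""Synthetic family generator: study-condition structure and
reproducibility."""

import json

import numpy as np
import pytest
from scipy import stats

from mendelseek.linkage import haldane_theta
from mendelseek.pedigree import Genotype, mendelian_check
from mendelseek.simulate import (SimConfig, SimConfigError,
                                 sequenced_affected, simulate_family,
                                 simulate_transmission_bits,
                                 write_fixture_bundle)


class TestTemplates:
    def test_family1_shape_seed7(self):
        res = simulate_family(SimConfig(seed=7, n_background_variants=50))
        assert len(res.pedigree) == 7
        assert len(res.pedigree.affected) == 4
        # planted variant hom-alt in exactly the affecteds
        i = res.table.keys().index(
            (res.planted_keys[0][0], res.planted_keys[0][1],
             res.planted_keys[0][2]))
        affected = {m.id for m in res.pedigree.affected}
        for j, s in enumerate(res.table.samples):
            g = Genotype(int(res.table.genotypes[i, j]))
            assert (g is Genotype.HOM_ALT) == (s in affected)

    def test_no_background_leaves_only_planted(self):
        res = simulate_family(SimConfig(seed=1, n_background_variants=0))
        assert len(res.table) == 1
        assert set(res.table.records["gene"]) == {res.planted_gene}

    def test_compound_het_planting(self):
        res = simulate_family(SimConfig(
            seed=3, n_background_variants=0,
            planted_model="compound_heterozygote"))
        assert len(res.table) == 2
        affected = {m.id for m in res.pedigree.affected}
        for j, s in enumerate(res.table.samples):
            g = [Genotype(int(res.table.genotypes[i, j])) for i in (0, 1)]
            if s in affected:
                assert g == [Genotype.HET, Genotype.HET]
            else:
                assert Genotype.HOM_ALT not in g
                assert g.count(Genotype.HET) <= 1
        # each parent carries exactly one of the two variants
        for parent in ("I1", "I2"):
            j = res.table.samples.index(parent)
            carried = sum(res.table.genotypes[i, j] >= 1 for i in (0, 1))
            assert carried == 1

    def test_impossible_template_rejected(self):
        with pytest.raises(SimConfigError, match="more affected"):
            SimConfig(template="nuclear", n_children=2, n_affected=3)

    def test_sequenced_affected_defaults_to_two(self):
        res = simulate_family(SimConfig(seed=0, n_background_variants=0))
        assert sequenced_affected(res) == ["II1", "II2"]


class TestMendelianCleanliness:
    @pytest.mark.parametrize("seed", range(5))
    def test_no_violations_without_genotyping_error(self, seed):
        res = simulate_family(SimConfig(seed=seed,
                                        n_background_variants=20))
        assert mendelian_check(res.pedigree, res.disease_genotypes) == []
        # planted variant rows transmit Mendelian-consistently too
        for i in range(len(res.table)):
            if res.table.records["gene"][i] != res.planted_gene:
                continue
            site = {s: Genotype(int(res.table.genotypes[i, j]))
                    for j, s in enumerate(res.table.samples)}
            assert mendelian_check(res.pedigree, site) == []
        # marker genotypes: every child allele pair is splittable into
        # one paternal and one maternal allele
        for g in res.marker_genotypes:
            for m in res.pedigree.nonfounders:
                a, b = g[m.id]
                fa, mo = set(g[m.father_id]), set(g[m.mother_id])
                assert (a in fa and b in mo) or (b in fa and a in mo)


class TestPenetranceAndRecombination:
    def test_affection_frequency_matches_penetrance(self):
        """Unascertained children of carrier x carrier parents are
        affected with probability 0.25 * 0.95."""
        res = simulate_family(SimConfig(
            seed=12, template="nuclear", n_children=10_000,
            n_background_variants=0, n_markers=2))
        n_aff = len(res.pedigree.affected)
        p = 0.25 * 0.95
        test = stats.binomtest(n_aff, 10_000, p)
        assert test.pvalue > 0.001

    def test_recombination_fraction_matches_haldane(self):
        """10,000 meioses at two loci 10 cM apart: observed switch rate
        within 3 SE of theta = (1 - e^-0.2)/2."""
        rng = np.random.default_rng(99)
        bits = simulate_transmission_bits(rng, np.array([0.0, 10.0]),
                                          n_meioses=10_000)
        obs = float((bits[:, 0] != bits[:, 1]).mean())
        theta = haldane_theta(10.0)
        se = np.sqrt(theta * (1 - theta) / 10_000)
        assert abs(obs - theta) < 3 * se


class TestFixtureBundle:
    def test_same_seed_byte_identical(self, tmp_path):
        m1 = write_fixture_bundle(tmp_path / "a",
                                  SimConfig(seed=5, n_background_variants=40))
        m2 = write_fixture_bundle(tmp_path / "b",
                                  SimConfig(seed=5, n_background_variants=40))
        assert m1["files"] == m2["files"]

    def test_different_seeds_differ(self, tmp_path):
        m1 = write_fixture_bundle(tmp_path / "a",
                                  SimConfig(seed=5, n_background_variants=40))
        m2 = write_fixture_bundle(tmp_path / "b",
                                  SimConfig(seed=6, n_background_variants=40))
        assert m1["planted_keys"] != m2["planted_keys"]

    def test_manifest_lists_every_file(self, tmp_path):
        out = tmp_path / "a"
        write_fixture_bundle(out, SimConfig(seed=5,
                                            n_background_variants=40))
        manifest = json.loads((out / "manifest.json").read_text())
        emitted = {p.name for p in out.iterdir()} - {"manifest.json"}
        assert set(manifest["files"]) == emitted


class TestQCNoise:
    def test_qc_noise_plants_failures(self):
        from mendelseek.qc import apply_qc

        res = simulate_family(SimConfig(seed=4, n_background_variants=400,
                                        qc_noise=0.3))
        _, rep = apply_qc(res.table)
        assert rep.removed > 0
        assert sum(rep.per_criterion.values()) >= rep.removed

    def test_default_metrics_pass_qc(self):
        from mendelseek.qc import apply_qc

        res = simulate_family(SimConfig(seed=4, n_background_variants=400))
        _, rep = apply_qc(res.table)
        assert rep.removed == 0
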