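"""Exact pedigree likelihoods, two-point and multipoint LOD scores.

The closed-form expectation for the discovery-family shape was derived
by hand before the engine was written: with carrier x carrier parents,
four affected homozygous children, one unaffected heterozygous child
and a fully informative co-segregating marker, summing the per-child
log10 likelihood-ratio terms (and the phase-sum prefactor, which
cancels one log10 4) gives

    LOD(theta=0) = 3*log10(4) + log10(4 / 3.05)  ~= 1.9240

under homozygote penetrance 0.95.  Parental disease genotypes other
than carrier x carrier contribute at relative order of the disease
allele frequency (1e-4), hence the 1e-3 comparison tolerance.
"""

import math

import numpy as np
import pytest

from mendelseek.bruteforce import (pedigree_likelihood_enum,
                                   pedigree_log_likelihood_enum)
from mendelseek.linkage import (DEFAULT_THETA_GRID, DiseaseModel,
                                FounderFrequencyError, LanderGreenEngine,
                                LODResult, Marker, MarkerMap,
                                MeiosisBoundError,
                                MendelianInconsistencyError,
                                candidate_region, disease_locus,
                                estimate_founder_freqs, haldane_cM,
                                haldane_theta, marker_locus, multipoint_lod,
                                twopoint_lod)
from mendelseek.pedigree import Affection, Individual, Pedigree, Sex

CLOSED_FORM_FAM1_LOD0 = 3 * math.log10(4) + math.log10(4 / 3.05)


def nuclear(n_children, affected_idx=(), family="F"):
    members = [
        Individual("P1", family, None, None, Sex.MALE, Affection.UNAFFECTED),
        Individual("P2", family, None, None, Sex.FEMALE,
                   Affection.UNAFFECTED),
    ]
    for i in range(n_children):
        aff = (Affection.AFFECTED if i in affected_idx
               else Affection.UNAFFECTED)
        members.append(Individual(f"C{i}", family, "P1", "P2",
                                  Sex.MALE if i % 2 else Sex.FEMALE, aff))
    return Pedigree(family, members)


def fam1_shape():
    """Parents + 5 children, children 0-2 and 4 affected."""
    return nuclear(5, affected_idx=(0, 1, 2, 4))


def fam1_informative_marker():
    """Fully informative co-segregating marker: affected children carry
    the disease-coupled allele from each parent; the unaffected child
    is an obligate paternal carrier."""
    g = {"P1": (0, 1), "P2": (2, 3),
         "C0": (0, 2), "C1": (0, 2), "C2": (0, 2),
         "C3": (0, 3), "C4": (0, 2)}
    return marker_locus([0.25] * 4, g)


class TestFounderFreqs:
    def test_all_alleles_seen_plain_counts(self):
        ped = nuclear(1)
        freqs = estimate_founder_freqs(
            ped, {"P1": (0, 1), "P2": (0, 0)}, n_alleles=2)
        assert np.allclose(freqs, [0.75, 0.25])

    def test_unseen_allele_pseudocounted(self):
        ped = nuclear(1)
        freqs = estimate_founder_freqs(ped, {"P1": (0, 0)}, n_alleles=2)
        # 2 observed + one pseudocount per declared allele = 3/4, 1/4
        assert np.allclose(freqs, [0.75, 0.25])

    def test_no_genotyped_founder_errors(self):
        ped = nuclear(1)
        with pytest.raises(FounderFrequencyError):
            estimate_founder_freqs(ped, {"C0": (0, 1)}, n_alleles=2)


class TestTwopoint:
    def test_grid_and_zero_at_half(self):
        res = twopoint_lod(fam1_shape(), DiseaseModel(),
                           fam1_informative_marker())
        assert len(res.lods) == 8
        assert res.lods[list(res.positions).index(0.5)] == 0.0

    def test_cosegregating_marker_peaks_at_theta_zero(self):
        res = twopoint_lod(fam1_shape(), DiseaseModel(),
                           fam1_informative_marker())
        assert res.argmax_position == 0.0
        assert res.max_lod > 1.5

    def test_family1_closed_form(self):
        res = twopoint_lod(fam1_shape(), DiseaseModel(),
                           fam1_informative_marker(), theta_grid=[0.0])
        assert res.lods[0] == pytest.approx(CLOSED_FORM_FAM1_LOD0, abs=1e-3)

    def test_mendelian_violation_raises(self):
        ped = nuclear(1)
        # child carries an allele neither parent has
        g = {"P1": (0, 0), "P2": (0, 0), "C0": (1, 1)}
        with pytest.raises(MendelianInconsistencyError):
            twopoint_lod(ped, DiseaseModel(), marker_locus([0.5, 0.5], g))

    def test_uninformative_marker_flat_zero(self):
        """Penetrance (0,0,1), single affected child, marker with every
        individual homozygous for the same allele: LOD 0 at all theta."""
        ped = nuclear(1, affected_idx=(0,))
        model = DiseaseModel(penetrance=(0, 0, 1.0))
        g = {"P1": (0, 0), "P2": (0, 0), "C0": (0, 0)}
        res = twopoint_lod(ped, model, marker_locus([0.99, 0.01], g))
        assert np.allclose(res.lods, 0.0, atol=1e-12)

    def test_obligate_recombinant_gives_minus_inf_at_zero(self):
        """Full penetrance: an affected child sharing neither parental
        disease-coupled haplotype makes theta=0 impossible."""
        ped = nuclear(2, affected_idx=(0, 1))
        model = DiseaseModel(penetrance=(0, 0, 1.0))
        # C0 and C1 affected but carry opposite parental haplotypes
        g = {"P1": (0, 1), "P2": (2, 3),
             "C0": (0, 2), "C1": (1, 3)}
        res = twopoint_lod(ped, model, marker_locus([0.25] * 4, g),
                           theta_grid=[0.0, 0.5])
        assert res.lods[0] == -math.inf
        assert res.lods[1] == 0.0


class TestEngineAgainstEnumeration:
    def _random_instance(self, rng):
        n_children = int(rng.integers(1, 4))  # <= 6 meioses
        ped = nuclear(n_children,
                      affected_idx=tuple(
                          i for i in range(n_children)
                          if rng.random() < 0.5))
        n_loci = int(rng.integers(1, 4))      # <= 3 markers
        loci, ids = [], [m.id for m in ped.members]
        for _ in range(n_loci):
            k = int(rng.integers(2, 4))
            freqs = rng.dirichlet(np.ones(k))
            g = {}
            hap = {f: rng.integers(0, k, size=2) for f in ("P1", "P2")}
            for iid in ids:
                if rng.random() < 0.8:
                    if iid in hap:
                        g[iid] = tuple(int(x) for x in hap[iid])
                    else:
                        g[iid] = (int(hap["P1"][rng.integers(2)]),
                                  int(hap["P2"][rng.integers(2)]))
            loci.append(marker_locus(freqs, g))
        thetas = [float(rng.uniform(0, 0.5)) for _ in range(n_loci - 1)]
        return ped, loci, thetas

    def test_hmm_equals_bruteforce(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(8):
            ped, loci, thetas = self._random_instance(rng)
            # include the latent disease locus half the time
            if rng.random() < 0.5:
                loci = [disease_locus(DiseaseModel(), ped)] + loci
                thetas = ([float(rng.uniform(0, 0.5))] if thetas or loci
                          else []) + thetas
                thetas = thetas[:len(loci) - 1]
            engine = LanderGreenEngine(ped)
            a = engine.log_likelihood(loci, thetas)
            b = pedigree_log_likelihood_enum(ped, loci, thetas)
            if math.isinf(a):
                assert math.isinf(b)
            else:
                assert a == pytest.approx(b, rel=1e-9)
                checked += 1
        assert checked >= 4  # most instances must be non-degenerate

    def test_likelihood_is_polynomial_in_theta(self):
        """With m meioses the two-locus likelihood is a polynomial of
        degree <= m in theta: values at m+1 nodes predict the rest."""
        ped = nuclear(2, affected_idx=(0, 1))
        m = ped.n_meioses
        loc = marker_locus([0.25] * 4, {"P1": (0, 1), "P2": (2, 3),
                                        "C0": (0, 2), "C1": (0, 2)})
        dloc = disease_locus(DiseaseModel(), ped)
        engine = LanderGreenEngine(ped)
        lik = lambda t: 10.0 ** engine.log_likelihood([dloc, loc], [t])
        nodes = np.linspace(0.0, 0.5, m + 1)
        coeffs = np.polynomial.polynomial.polyfit(
            nodes, [lik(t) for t in nodes], deg=m)
        for t in np.linspace(0.03, 0.47, 7):
            assert np.polynomial.polynomial.polyval(t, coeffs) == (
                pytest.approx(lik(t), rel=1e-8))

    def test_allele_relabeling_invariance(self):
        ped = nuclear(2, affected_idx=(0,))
        g = {"P1": (0, 1), "P2": (1, 2), "C0": (0, 1), "C1": (1, 1)}
        freqs = [0.5, 0.3, 0.2]
        perm = [2, 0, 1]  # relabel alleles, permute frequencies to match
        g2 = {iid: (perm[a], perm[b]) for iid, (a, b) in g.items()}
        freqs2 = [0.0] * 3
        for old, new in enumerate(perm):
            freqs2[new] = freqs[old]
        engine = LanderGreenEngine(ped)
        dloc = disease_locus(DiseaseModel(), ped)
        a = engine.log_likelihood([dloc, marker_locus(freqs, g)], [0.1])
        b = engine.log_likelihood([dloc, marker_locus(freqs2, g2)], [0.1])
        assert a == pytest.approx(b, rel=1e-12)

    def test_meiosis_bound_enforced(self):
        ped = nuclear(8)  # 16 meioses
        with pytest.raises(MeiosisBoundError):
            LanderGreenEngine(ped)
        with pytest.raises(MeiosisBoundError):
            pedigree_likelihood_enum(
                ped, [disease_locus(DiseaseModel(), ped)], [])


class TestMultipoint:
    def test_single_marker_map_equals_twopoint(self):
        ped = fam1_shape()
        loc = fam1_informative_marker()
        mm = MarkerMap([Marker("m1", "16", 5.0, (0.25,) * 4)])
        r = multipoint_lod(ped, DiseaseModel(), mm,
                           [dict(loc_genotypes())],
                           eval_positions=[5.0])
        tp = twopoint_lod(ped, DiseaseModel(), loc, theta_grid=[0.0])
        assert r.lods[0] == pytest.approx(tp.lods[0], rel=1e-12)

    def test_multipoint_matches_enumeration(self):
        ped = nuclear(2, affected_idx=(0, 1))
        mm = MarkerMap([Marker("a", "1", 0.0, (0.5, 0.5)),
                        Marker("b", "1", 10.0, (0.5, 0.5))])
        gts = [{"P1": (0, 1), "P2": (0, 1), "C0": (0, 0), "C1": (0, 1)},
               {"P1": (0, 1), "P2": (1, 1), "C0": (1, 1), "C1": (0, 1)}]
        r_hmm = multipoint_lod(ped, DiseaseModel(), mm, gts,
                               eval_positions=[0.0, 3.0, 5.0, 10.0])
        r_enum = multipoint_lod(ped, DiseaseModel(), mm, gts,
                                eval_positions=[0.0, 3.0, 5.0, 10.0],
                                method="enum")
        assert np.allclose(r_hmm.lods, r_enum.lods, rtol=1e-9)


def loc_genotypes():
    return {"P1": (0, 1), "P2": (2, 3),
            "C0": (0, 2), "C1": (0, 2), "C2": (0, 2),
            "C3": (0, 3), "C4": (0, 2)}


class TestCandidateRegion:
    def _mm(self):
        return MarkerMap([Marker(f"m{i}", "16", float(2 * i), (0.5, 0.5))
                          for i in range(6)])

    def test_flat_curve_returns_whole_map(self):
        mm = self._mm()
        lod = LODResult(positions=mm.positions, lods=np.zeros(6),
                        kind="multipoint")
        left, right, width = candidate_region(lod, mm)
        assert (left.name, right.name) == ("m0", "m5")
        assert width == pytest.approx(10.0)

    def test_single_peak_returns_planted_interval(self):
        mm = self._mm()
        lods = np.array([0.0, 0.5, 1.9, 1.9, 0.5, 0.0])
        lod = LODResult(positions=mm.positions, lods=lods,
                        kind="multipoint")
        left, right, width = candidate_region(lod, mm)
        assert (left.name, right.name) == ("m2", "m3")
        assert width == pytest.approx(2.0)

    def test_empty_result_is_error(self):
        with pytest.raises(ValueError):
            LODResult(positions=np.array([]), lods=np.array([]),
                      kind="multipoint")


def test_haldane_roundtrip():
    for d in (0.5, 2.0, 10.0, 40.0):
        assert haldane_cM(haldane_theta(d)) == pytest.approx(d, rel=1e-12)
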