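"""Exact pedigree linkage: two-point and multipoint LOD scores.

The production engine is a Lander–Green hidden Markov model over
inheritance vectors (one bit per meiosis recording which grandparental
haplotype was transmitted).  A loop-free pedigree with m meioses (two
per non-founder) has 2^m inheritance vectors; the meiosis bound
(default 14, i.e. 16384 states) keeps the computation exact and fast
for the small two-generation families this kind of study uses.

* Emission at a marker: P(observed genotypes | inheritance vector),
  summing founder-allele assignments weighted by allele frequencies.
* Emission at the disease locus: P(affection statuses | vector), the
  same sum with penetrance terms P(affected | genotype) under the
  recessive disease model in place of genotype observations.
* Transitions between adjacent loci flip each meiosis bit
  independently with the interval's recombination fraction; map
  distances convert through the Haldane function
  theta = (1 - exp(-2 d / 100)) / 2 for d in cM (sex-averaged).

LOD(theta) = log10 L(theta) - log10 L(1/2); multipoint LOD at map
position x compares the likelihood with the disease locus inserted at x
against the unlinked baseline P(markers) * P(phenotypes).  Likelihoods
are accumulated with per-locus rescaling; an impossible configuration
yields -inf LOD rather than an exception.

An independent brute-force enumeration (:mod:`mendelseek.bruteforce`)
computes the same likelihoods by exhaustive summation and serves as the
oracle the HMM is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pedigree import Individual, Pedigree, PedigreeError

DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


class MendelianInconsistencyError(PedigreeError):
    """Marker genotypes impossible under any transmission pattern."""


class MeiosisBoundError(ValueError):
    """Pedigree exceeds the exact-computation meiosis bound."""


class FounderFrequencyError(ValueError):
    """No genotyped founder to estimate marker allele frequencies from."""


def haldane_theta(d_cM: float) -> float:
    """Map distance (cM) to recombination fraction."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def haldane_cM(theta: float) -> float:
    """Inverse Haldane map function."""
    if not 0 <= theta < 0.5:
        raise ValueError(f"theta must be in [0, 0.5): {theta}")
    return -50.0 * math.log(1.0 - 2.0 * theta)


@dataclass(frozen=True)
class DiseaseModel:
    """Single-locus disease parameterization.

    ``penetrance`` gives P(affected | 0, 1, 2 copies of the disease
    allele); the recessive default has no phenocopies and 95%
    penetrance of the homozygote.
    """

    disease_allele_freq: float = 0.0001
    penetrance: tuple[float, float, float] = (0.0, 0.0, 0.95)
    inheritance: str = "autosomal_recessive"

    def __post_init__(self):
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease allele frequency must be in (0,1)")
        if any(not 0.0 <= f <= 1.0 for f in self.penetrance):
            raise ValueError("penetrances must be in [0,1]")
        if self.inheritance != "autosomal_recessive":
            raise ValueError(f"unsupported inheritance {self.inheritance!r}")


@dataclass(frozen=True)
class Marker:
    name: str
    chrom: str
    position_cM: float
    freqs: tuple[float, ...]

    def __post_init__(self):
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError(
                f"marker {self.name}: allele frequencies sum to "
                f"{sum(self.freqs)}, not 1")


@dataclass
class MarkerMap:
    markers: list[Marker]

    def __post_init__(self):
        by_chrom: dict[str, float] = {}
        for m in self.markers:
            if m.chrom in by_chrom and m.position_cM <= by_chrom[m.chrom]:
                raise ValueError(
                    f"marker positions must strictly increase per "
                    f"chromosome (at {m.name})")
            by_chrom[m.chrom] = m.position_cM

    def __len__(self):
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position_cM for m in self.markers])


@dataclass
class LODResult:
    """LOD curve: ``positions`` are theta values (two-point) or map
    positions in cM (multipoint)."""

    positions: np.ndarray
    lods: np.ndarray
    kind: str  # "twopoint" | "multipoint"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.lods = np.asarray(self.lods, dtype=float)
        if len(self.positions) == 0:
            raise ValueError("empty LOD result")

    @property
    def max_lod(self) -> float:
        return float(np.max(self.lods))

    @property
    def argmax_position(self) -> float:
        return float(self.positions[int(np.argmax(self.lods))])


# ---------------------------------------------------------------------
# Loci: allele frequencies + per-individual observation weights
# ---------------------------------------------------------------------

@dataclass
class Locus:
    """One locus in a likelihood computation.

    ``weights[iid]`` is a K x K matrix giving the probability of the
    individual's observed data given ordered genotype (paternal,
    maternal allele); individuals absent from the mapping are
    unobserved (weight 1 everywhere).
    """

    freqs: np.ndarray
    weights: dict[str, np.ndarray]

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("locus allele frequencies must sum to 1")

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)

    def weight_of(self, iid: str) -> np.ndarray:
        w = self.weights.get(iid)
        if w is None:
            k = self.n_alleles
            return np.ones((k, k))
        return w


def marker_locus(freqs: Sequence[float],
                 genotypes: Mapping[str, tuple[int, int]]) -> Locus:
    """Locus for a genotyped marker; alleles are 0-based indices and
    genotypes unordered pairs."""
    freqs = np.asarray(freqs, dtype=float)
    k = len(freqs)
    weights = {}
    for iid, (a, b) in genotypes.items():
        if not (0 <= a < k and 0 <= b < k):
            raise ValueError(f"{iid}: allele outside declared set 0..{k-1}")
        w = np.zeros((k, k))
        w[a, b] = 1.0
        w[b, a] = 1.0
        weights[iid] = w
    return Locus(freqs=freqs, weights=weights)


def disease_locus(model: DiseaseModel, pedigree: Pedigree) -> Locus:
    """Latent disease locus: emission is the affection status.

    Allele 0 = wild type, allele 1 = disease; the weight of an affected
    individual with g disease alleles is penetrance[g], of an unaffected
    one 1 - penetrance[g]; unknown status is uninformative.
    """
    from .pedigree import Affection

    p = model.disease_allele_freq
    freqs = np.array([1.0 - p, p])
    pen = np.asarray(model.penetrance)
    copies = np.add.outer(np.arange(2), np.arange(2))
    weights = {}
    for m in pedigree.members:
        if m.affection is Affection.AFFECTED:
            weights[m.id] = pen[copies]
        elif m.affection is Affection.UNAFFECTED:
            weights[m.id] = 1.0 - pen[copies]
    return Locus(freqs=freqs, weights=weights)


# ---------------------------------------------------------------------
# Lander-Green engine
# ---------------------------------------------------------------------

class LanderGreenEngine:
    """Exact inheritance-vector HMM for one loop-free pedigree.

    One meiosis bit per parent-child transmission: bit 2j selects the
    paternal grandparental haplotype of the j-th non-founder (in
    topological order), bit 2j+1 the maternal one.  Founder haplotypes
    occupy slots 2i, 2i+1 in founder order.
    """

    def __init__(self, pedigree: Pedigree, max_meioses: int = 14):
        self.pedigree = pedigree
        if pedigree.n_meioses > max_meioses:
            raise MeiosisBoundError(
                f"{pedigree.n_meioses} meioses exceed the exact bound "
                f"{max_meioses}")
        self.n_bits = pedigree.n_meioses
        self.n_states = 1 << self.n_bits
        self._order = pedigree.topological_order()
        founders = [m for m in self._order if m.is_founder]
        self.founder_ids = [m.id for m in founders]
        self.n_slots = 2 * len(founders)
        self._build_slots()

    def _build_slots(self) -> None:
        states = np.arange(self.n_states)
        slots: dict[str, np.ndarray] = {}
        for i, fid in enumerate(self.founder_ids):
            s = np.empty((self.n_states, 2), dtype=np.int64)
            s[:, 0] = 2 * i
            s[:, 1] = 2 * i + 1
            slots[fid] = s
        j = 0
        for m in self._order:
            if m.is_founder:
                continue
            pat_bit = (states >> (2 * j)) & 1
            mat_bit = (states >> (2 * j + 1)) & 1
            s = np.empty((self.n_states, 2), dtype=np.int64)
            s[:, 0] = slots[m.father_id][states, pat_bit]
            s[:, 1] = slots[m.mother_id][states, mat_bit]
            slots[m.id] = s
            j += 1
        self.slots = slots  # iid -> (n_states, 2) founder-slot indices

    # -- emission -----------------------------------------------------
    def emission(self, locus: Locus) -> np.ndarray:
        """P(locus observations | inheritance vector), per state."""
        k = locus.n_alleles
        founder_choices = []
        founder_factor = []
        for fid in self.founder_ids:
            w = locus.weight_of(fid)
            pairs, facs = [], []
            for a in range(k):
                for b in range(k):
                    wf = w[a, b] * locus.freqs[a] * locus.freqs[b]
                    if wf > 0.0:
                        pairs.append((a, b))
                        facs.append(wf)
            if not pairs:
                return np.zeros(self.n_states)
            founder_choices.append(pairs)
            founder_factor.append(facs)

        nonfounders = [m for m in self._order if not m.is_founder]
        nf_weights = [locus.weight_of(m.id) for m in nonfounders]
        nf_slots = [self.slots[m.id] for m in nonfounders]

        out = np.zeros(self.n_states)
        slot_alleles = np.empty(self.n_slots, dtype=np.int64)

        def rec(fi: int, factor: float):
            if fi == len(self.founder_ids):
                term = np.full(self.n_states, factor)
                for w, s in zip(nf_weights, nf_slots):
                    a = slot_alleles[s]  # (n_states, 2)
                    term = term * w[a[:, 0], a[:, 1]]
                    if not term.any():
                        return
                out_add(term)
                return
            for (a, b), f in zip(founder_choices[fi], founder_factor[fi]):
                slot_alleles[2 * fi] = a
                slot_alleles[2 * fi + 1] = b
                rec(fi + 1, factor * f)

        def out_add(term):
            np.add(out, term, out=out)

        rec(0, 1.0)
        return out

    # -- transitions --------------------------------------------------
    def transition(self, p: np.ndarray, theta: float) -> np.ndarray:
        """Apply one inter-locus transition (each bit flips w.p. theta)."""
        if self.n_bits == 0 or theta == 0.0:
            return p.copy()
        arr = p.reshape([2] * self.n_bits)
        for axis in range(self.n_bits):
            arr = (1.0 - theta) * arr + theta * np.flip(arr, axis=axis)
        return arr.reshape(-1)

    # -- likelihood ---------------------------------------------------
    def log_likelihood(self, loci: Sequence[Locus],
                       thetas: Sequence[float]) -> float:
        """log10 P(data) for ordered loci with recombination fractions
        ``thetas`` between adjacent loci (len(loci) - 1 of them)."""
        if len(thetas) != len(loci) - 1:
            raise ValueError("need one theta per adjacent locus pair")
        prior = 1.0 / self.n_states
        f = prior * self.emission(loci[0])
        log10 = 0.0
        for locus, theta in zip(loci[1:], thetas):
            s = f.sum()
            if s == 0.0:
                return -math.inf
            f /= s
            log10 += math.log10(s)
            f = self.transition(f, theta) * self.emission(locus)
        s = f.sum()
        if s == 0.0:
            return -math.inf
        return log10 + math.log10(s)


# ---------------------------------------------------------------------
# Founder allele frequencies
# ---------------------------------------------------------------------

def estimate_founder_freqs(
    pedigree: Pedigree,
    genotypes: Mapping[str, tuple[int, int]],
    n_alleles: int,
) -> np.ndarray:
    """Empirical founder allele frequencies.

    Counts alleles over genotyped founders.  If every declared allele
    was observed the plain empirical frequencies are returned;
    otherwise one pseudocount is added to every declared allele so that
    unseen alleles keep positive frequency.
    """
    counts = np.zeros(n_alleles)
    seen = False
    for f in pedigree.founders:
        g = genotypes.get(f.id)
        if g is None:
            continue
        seen = True
        for a in g:
            if not 0 <= a < n_alleles:
                raise ValueError(f"allele {a} outside declared 0..{n_alleles-1}")
            counts[a] += 1
    if not seen:
        raise FounderFrequencyError(
            "no genotyped founder; supply frequencies explicitly")
    if (counts == 0).any():
        counts = counts + 1.0
    return counts / counts.sum()


# ---------------------------------------------------------------------
# LOD computations
# ---------------------------------------------------------------------

def _engine_or_enum(method: str):
    if method == "hmm":
        def fn(pedigree, loci, thetas, max_meioses):
            return LanderGreenEngine(
                pedigree, max_meioses=max_meioses).log_likelihood(loci, thetas)
        return fn
    if method == "enum":
        from .bruteforce import pedigree_log_likelihood_enum
        return pedigree_log_likelihood_enum
    raise ValueError(f"unknown method {method!r}")


def twopoint_lod(
    pedigree: Pedigree,
    model: DiseaseModel,
    marker: Locus,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    method: str = "hmm",
    max_meioses: int = 14,
) -> LODResult:
    """Two-point LOD between the disease and one marker over a theta
    grid.  LOD(1/2) is identically 0.  Raises
    :class:`MendelianInconsistencyError` when the marker genotypes are
    impossible in the pedigree (zero likelihood at every theta).
    """
    if any(not 0.0 <= t <= 0.5 for t in theta_grid):
        raise ValueError("theta grid must lie within [0, 0.5]")
    loglik = _engine_or_enum(method)
    dloc = disease_locus(model, pedigree)
    l_half = loglik(pedigree, [dloc, marker], [0.5], max_meioses)
    if l_half == -math.inf:
        raise MendelianInconsistencyError(
            "marker genotypes have zero likelihood in this pedigree")
    lods = np.array([
        loglik(pedigree, [dloc, marker], [t], max_meioses) - l_half
        for t in theta_grid])
    return LODResult(positions=np.asarray(theta_grid), lods=lods,
                     kind="twopoint")


def multipoint_lod(
    pedigree: Pedigree,
    model: DiseaseModel,
    marker_map: MarkerMap,
    marker_genotypes: Sequence[Mapping[str, tuple[int, int]]],
    eval_positions: Sequence[float] | None = None,
    method: str = "hmm",
    max_meioses: int = 14,
) -> LODResult:
    """Multipoint LOD along a marker map.

    ``marker_genotypes[j]`` maps individual id to the unordered allele
    pair at the j-th marker.  The disease locus is inserted at each
    evaluation position (default: marker positions plus interval
    midpoints) and compared against the unlinked baseline
    P(markers) * P(phenotypes).
    """
    if len(marker_genotypes) != len(marker_map):
        raise ValueError("one genotype mapping per map marker required")
    chroms = {m.chrom for m in marker_map}
    if len(chroms) != 1:
        raise ValueError("multipoint map must lie on a single chromosome")
    loci = [marker_locus(m.freqs, g)
            for m, g in zip(marker_map, marker_genotypes)]
    pos = marker_map.positions
    if eval_positions is None:
        mids = (pos[:-1] + pos[1:]) / 2.0
        eval_positions = np.sort(np.concatenate([pos, mids]))
    eval_positions = np.asarray(eval_positions, dtype=float)

    loglik = _engine_or_enum(method)
    dloc = disease_locus(model, pedigree)
    marker_thetas = [haldane_theta(d) for d in np.diff(pos)]
    log_markers = loglik(pedigree, loci, marker_thetas, max_meioses)
    if log_markers == -math.inf:
        raise MendelianInconsistencyError(
            "marker genotypes have zero likelihood in this pedigree")
    log_pheno = loglik(pedigree, [dloc], [], max_meioses)

    lods = np.empty(len(eval_positions))
    for i, x in enumerate(eval_positions):
        ins = int(np.searchsorted(pos, x))
        merged = loci[:ins] + [dloc] + loci[ins:]
        mpos = np.concatenate([pos[:ins], [x], pos[ins:]])
        thetas = [haldane_theta(d) for d in np.diff(mpos)]
        log_joint = loglik(pedigree, merged, thetas, max_meioses)
        lods[i] = log_joint - log_markers - log_pheno
    return LODResult(positions=eval_positions, lods=lods, kind="multipoint")


def candidate_region(
    lod: LODResult,
    marker_map: MarkerMap,
    tol: float = 1e-6,
) -> tuple[Marker | None, Marker | None, float]:
    """Maximal contiguous run of evaluation positions attaining the
    maximum LOD (within ``tol``), with its flanking markers and width.

    Returns (left flanking marker or None, right flanking marker or
    None, width in cM of the plateau).  Flanking markers are the
    nearest map markers at or outside the plateau boundaries.
    """
    at_max = lod.lods >= lod.max_lod - tol
    best = (0, -1)
    i = 0
    n = len(at_max)
    while i < n:
        if at_max[i]:
            j = i
            while j + 1 < n and at_max[j + 1]:
                j += 1
            if j - i > best[1] - best[0] or best[1] < best[0]:
                best = (i, j)
            i = j + 1
        else:
            i += 1
    lo = float(lod.positions[best[0]])
    hi = float(lod.positions[best[1]])
    left = right = None
    for m in marker_map:
        if m.position_cM <= lo + tol:
            left = m
        if m.position_cM >= hi - tol and right is None:
            right = m
    return left, right, hi - lo


# ---------------------------------------------------------------------
# MAP file I/O
# ---------------------------------------------------------------------

def read_map(path, freqs: Sequence[Sequence[float]] | None = None
             ) -> MarkerMap:
    """Read a linkage MAP file (chrom, marker, cM[, bp]).

    Allele frequencies are not part of the MAP format; pass them per
    marker or attach uniform 2-allele frequencies by default (to be
    replaced by :func:`estimate_founder_freqs`).
    """
    markers = []
    with open(path) as fh:
        rows = [ln.split() for ln in fh if ln.strip()
                and not ln.startswith("#")]
    for i, f in enumerate(rows):
        if len(f) < 3:
            raise ValueError(f"MAP line {i + 1}: expected >=3 columns")
        fr = tuple(freqs[i]) if freqs is not None else (0.5, 0.5)
        markers.append(Marker(name=f[1], chrom=f[0],
                              position_cM=float(f[2]), freqs=fr))
    return MarkerMap(markers=markers)


def write_map(path, marker_map: MarkerMap) -> None:
    with open(path, "w") as fh:
        for m in marker_map:
            fh.write(f"{m.chrom}\t{m.name}\t{m.position_cM:g}\n")
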