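"""Exhaustive pedigree likelihood by direct enumeration.

Independent oracle for the Lander-Green engine: sums over every founder
multilocus ordered diplotype and every per-meiosis transmission pattern
the product of

* founder haplotype priors (linkage equilibrium: product of allele
  frequencies per locus),
* transmission probabilities (1/2 for the first locus, then theta or
  1 - theta per interval depending on whether the transmitted
  grandparental origin switches),
* per-individual observation weights at every locus (genotype match
  indicators for markers, penetrance terms for the disease locus).

Exponential in meioses and loci; genotype-incompatible branches are
pruned, which keeps pedigrees of <= ~12 meioses and <= 4 loci
tractable.  The algorithm shares no code with the HMM beyond the
:class:`~mendelseek.linkage.Locus` container.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Sequence

import numpy as np

from .linkage import Locus, MeiosisBoundError
from .pedigree import Pedigree


def pedigree_likelihood_enum(
    pedigree: Pedigree,
    loci: Sequence[Locus],
    thetas: Sequence[float],
    max_meioses: int = 12,
) -> float:
    """P(data) for ordered loci with recombination fractions between
    adjacent loci.  Loops are rejected by :class:`Pedigree` itself."""
    if len(thetas) != len(loci) - 1:
        raise ValueError("need one theta per adjacent locus pair")
    if pedigree.n_meioses > max_meioses:
        raise MeiosisBoundError(
            f"{pedigree.n_meioses} meioses exceed enumeration bound "
            f"{max_meioses}")
    L = len(loci)
    order = pedigree.topological_order()

    # candidate haplotypes: all allele tuples across loci
    haplotypes = list(product(*[range(lc.n_alleles) for lc in loci]))

    def hap_prior(h) -> float:
        p = 1.0
        for lc, a in zip(loci, h):
            p *= lc.freqs[a]
        return p

    def obs_weight(iid: str, h_pat, h_mat) -> float:
        w = 1.0
        for lc, a, b in zip(loci, h_pat, h_mat):
            w *= lc.weight_of(iid)[a, b]
            if w == 0.0:
                return 0.0
        return w

    # per-meiosis transmission: pattern of grandparental origins per locus
    patterns = list(product((0, 1), repeat=L))

    def pattern_prob(pat) -> float:
        p = 0.5
        for k, theta in enumerate(thetas):
            p *= theta if pat[k] != pat[k + 1] else 1.0 - theta
        return p

    def transmitted(diplotype, pat):
        return tuple(diplotype[pat[k]][k] for k in range(L))

    has_children = {m.id: False for m in order}
    for m in order:
        if not m.is_founder:
            has_children[m.father_id] = True
            has_children[m.mother_id] = True

    total = 0.0
    diplo: dict[str, tuple[tuple, tuple]] = {}

    def rec(idx: int, acc: float) -> None:
        nonlocal total
        if acc == 0.0:
            return
        if idx == len(order):
            total += acc
            return
        m = order[idx]
        if m.is_founder:
            for h_pat in haplotypes:
                pp = hap_prior(h_pat)
                if pp == 0.0:
                    continue
                for h_mat in haplotypes:
                    pm = hap_prior(h_mat)
                    if pm == 0.0:
                        continue
                    w = obs_weight(m.id, h_pat, h_mat)
                    if w == 0.0:
                        continue
                    diplo[m.id] = (h_pat, h_mat)
                    rec(idx + 1, acc * pp * pm * w)
            diplo.pop(m.id, None)
        elif not has_children[m.id]:
            # leaf: its transmissions affect no one else, sum locally
            fd, md = diplo[m.father_id], diplo[m.mother_id]
            local = 0.0
            for pat_p in patterns:
                h_pat = transmitted(fd, pat_p)
                ppat = pattern_prob(pat_p)
                for pat_m in patterns:
                    w = obs_weight(m.id, h_pat, transmitted(md, pat_m))
                    if w != 0.0:
                        local += ppat * pattern_prob(pat_m) * w
            rec(idx + 1, acc * local)
        else:
            fd, md = diplo[m.father_id], diplo[m.mother_id]
            for pat_p in patterns:
                h_pat = transmitted(fd, pat_p)
                ppat = pattern_prob(pat_p)
                for pat_m in patterns:
                    h_mat = transmitted(md, pat_m)
                    w = obs_weight(m.id, h_pat, h_mat)
                    if w == 0.0:
                        continue
                    diplo[m.id] = (h_pat, h_mat)
                    rec(idx + 1, acc * ppat * pattern_prob(pat_m) * w)
            diplo.pop(m.id, None)

    rec(0, 1.0)
    return total


def pedigree_log_likelihood_enum(
    pedigree: Pedigree,
    loci: Sequence[Locus],
    thetas: Sequence[float],
    max_meioses: int = 12,
) -> float:
    """log10 of :func:`pedigree_likelihood_enum` (-inf for zero)."""
    lik = pedigree_likelihood_enum(pedigree, loci, thetas, max_meioses)
    return math.log10(lik) if lik > 0.0 else -math.inf
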