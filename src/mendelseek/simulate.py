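"""Seeded generator of pedigrees, genotypes, variant tables and CNV
calls with a planted recessive causal gene.

The generator emulates the statistical structure a recessive-disease
exome/linkage study assumes:

* a two-generation pedigree — either the study family shape (two
  founders, five offspring, four affected) or a generic nuclear family;
* a disease locus under the recessive model (parents are obligate
  carriers; for the ascertained templates the offspring disease
  genotypes are fixed by the template, matching how such families come
  to attention; the unascertained nuclear mode draws affection from
  penetrance instead);
* multiallelic marker genotypes transmitted along a genetic map with
  Haldane-model recombination anchored at the disease locus;
* an exome variant table: the planted causal variant(s) in a designated
  gene, absent from every catalog and genotype-consistent with the
  planted inheritance model, plus background variants with independent
  per-sample genotypes, QC metrics drawn to pass QC (unless qc_noise
  plants failures) and database-catalog membership by the configured
  fractions;
* a CNV table of random non-co-segregating segments.

When the per-catalog fractions sum to 1 every background variant is
assigned to exactly one catalog, so no background variant can survive
the full cascade and the planted gene is the unique final candidate —
the guarantee the cascade recovery tests rely on.

All randomness flows from one ``numpy`` Generator keyed by the seed;
re-running with the same seed reproduces byte-identical fixture files.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cnv import CNVSegment, write_cnv_table
from .linkage import DiseaseModel, Marker, MarkerMap, haldane_theta, write_map
from .pedigree import (Affection, Genotype, Individual, Pedigree, Sex,
                       write_ped)
from .variants import (DatabaseCatalog, VariantTable, write_annotation,
                       write_catalog, write_variants)

CATALOG_NAMES = ("dbsnp_like", "thousand_genomes_like", "hapmap_yh_like",
                 "inhouse_like")

PLANTED_GENE = "GENE0000"


class SimConfigError(ValueError):
    """Impossible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    seed: int = 0
    template: str = "family1"            # family1 | nuclear
    n_children: int = 5                  # nuclear template
    n_affected: int | None = None        # nuclear: None = draw by penetrance
    planted_model: str = "shared_homozygote"
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    n_background_variants: int = 2000
    fraction_catalogued: dict[str, float] = field(
        default_factory=lambda: {n: 0.25 for n in CATALOG_NAMES})
    n_markers: int = 11
    spacing_cM: float = 2.0
    n_marker_alleles: int = 4
    marker_freqs: tuple[float, ...] | None = None  # None = uniform
    fully_informative_markers: bool = False
    disease_chrom: str = "16"
    disease_position_cM: float = 10.0
    genotyping_error_rate: float = 0.0
    sequenced: tuple[str, ...] | None = None  # None = first two affected
    qc_noise: float = 0.0
    n_cnv_segments: int = 3

    def __post_init__(self):
        if self.template not in ("family1", "nuclear"):
            raise SimConfigError(f"unknown template {self.template!r}")
        if self.planted_model not in ("shared_homozygote",
                                      "compound_heterozygote"):
            raise SimConfigError(f"unknown model {self.planted_model!r}")
        if self.n_background_variants < 0:
            raise SimConfigError("n_background_variants must be >= 0")
        for name, p in self.fraction_catalogued.items():
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"fraction for {name} outside [0,1]")
        if not 0.0 <= self.genotyping_error_rate <= 1.0:
            raise SimConfigError("genotyping_error_rate outside [0,1]")
        if (self.template == "nuclear" and self.n_affected is not None
                and self.n_affected > self.n_children):
            raise SimConfigError("more affected than offspring")


@dataclass
class SimResult:
    config: SimConfig
    pedigree: Pedigree
    disease_genotypes: dict[str, Genotype]
    marker_map: MarkerMap
    marker_genotypes: list[dict[str, tuple[int, int]]]
    table: VariantTable
    catalogs: list[DatabaseCatalog]
    cnv_segments: list[CNVSegment]
    planted_gene: str
    planted_keys: list[tuple[str, int, str]]
    gene_positions: pd.DataFrame  # gene, chrom, position_cM


# ---------------------------------------------------------------------
# Pedigree templates and disease genotypes
# ---------------------------------------------------------------------

def _family1_pedigree() -> Pedigree:
    """Two founders, five offspring, four affected (II:4 unaffected)."""
    members = [
        Individual("I1", "FAM1", None, None, Sex.MALE, Affection.UNAFFECTED),
        Individual("I2", "FAM1", None, None, Sex.FEMALE, Affection.UNAFFECTED),
    ]
    for i in range(1, 6):
        aff = Affection.UNAFFECTED if i == 4 else Affection.AFFECTED
        sex = Sex.MALE if i % 2 else Sex.FEMALE
        members.append(Individual(f"II{i}", "FAM1", "I1", "I2", sex, aff))
    return Pedigree("FAM1", members)


def _nuclear_pedigree(n_children: int) -> Pedigree:
    members = [
        Individual("P1", "NUC", None, None, Sex.MALE, Affection.UNAFFECTED),
        Individual("P2", "NUC", None, None, Sex.FEMALE, Affection.UNAFFECTED),
    ]
    for i in range(1, n_children + 1):
        sex = Sex.MALE if i % 2 else Sex.FEMALE
        members.append(Individual(f"C{i}", "NUC", "P1", "P2", sex,
                                  Affection.UNKNOWN))
    return Pedigree("NUC", members)


def _disease_inheritance(config: SimConfig, rng: np.random.Generator
                         ) -> tuple[Pedigree, dict[str, Genotype],
                                    dict[str, tuple[int, int]]]:
    """Pedigree, disease genotypes and per-child disease-locus meiosis
    bits (paternal_bit, maternal_bit).

    Parents are obligate carriers with the disease allele on haplotype
    0 by convention.  Ascertained templates fix offspring genotypes
    (affected hom-alt, unaffected het); the unascertained nuclear mode
    transmits freely and draws affection from penetrance.
    """
    pen = config.disease_model.penetrance
    if config.template == "family1":
        ped = _family1_pedigree()
        bits: dict[str, tuple[int, int]] = {}
        genos: dict[str, Genotype] = {"I1": Genotype.HET, "I2": Genotype.HET}
        for m in ped.nonfounders:
            if m.affection is Affection.AFFECTED:
                bits[m.id] = (0, 0)
                genos[m.id] = Genotype.HOM_ALT
            else:  # the study's unaffected sibling is a carrier
                which = int(rng.integers(2))
                bits[m.id] = (0, 1) if which == 0 else (1, 0)
                genos[m.id] = Genotype.HET
        return ped, genos, bits

    ped = _nuclear_pedigree(config.n_children)
    genos = {"P1": Genotype.HET, "P2": Genotype.HET}
    bits = {}
    if config.n_affected is None:
        members, new_aff = [], {}
        for m in ped.nonfounders:
            bp, bm = int(rng.integers(2)), int(rng.integers(2))
            bits[m.id] = (bp, bm)
            n_alt = (bp == 0) + (bm == 0)
            genos[m.id] = Genotype(n_alt)
            affected = rng.random() < pen[n_alt]
            new_aff[m.id] = (Affection.AFFECTED if affected
                             else Affection.UNAFFECTED)
        for m in ped.members:
            aff = new_aff.get(m.id, m.affection)
            members.append(Individual(m.id, m.family_id, m.father_id,
                                      m.mother_id, m.sex, aff))
        return Pedigree(ped.family_id, members), genos, bits

    members = []
    children = ped.nonfounders
    for k, m in enumerate(children):
        if k < config.n_affected:
            bits[m.id] = (0, 0)
            genos[m.id] = Genotype.HOM_ALT
            aff = Affection.AFFECTED
        else:
            which = int(rng.integers(2))
            bits[m.id] = (0, 1) if which == 0 else (1, 0)
            genos[m.id] = Genotype.HET
            aff = Affection.UNAFFECTED
        members.append(Individual(m.id, m.family_id, m.father_id,
                                  m.mother_id, m.sex, aff))
    ped2 = Pedigree(ped.family_id,
                    [m for m in ped.members if m.is_founder] + members)
    return ped2, genos, bits


# ---------------------------------------------------------------------
# Marker transmission
# ---------------------------------------------------------------------

def simulate_transmission_bits(
    rng: np.random.Generator,
    positions_cM: np.ndarray,
    n_meioses: int,
    anchor_index: int | None = None,
    anchor_bits: np.ndarray | None = None,
) -> np.ndarray:
    """Grandparental-origin bits per meiosis along a map.

    Bits follow the Haldane model: adjacent loci switch origin with
    probability theta(gap).  With an anchor, the chain is conditioned
    on the given bits at ``anchor_index`` and walked outward in both
    directions (valid because the chain is Markov and symmetric);
    otherwise the first locus is uniform.  Returns an
    (n_meioses, n_loci) 0/1 array.
    """
    positions_cM = np.asarray(positions_cM, dtype=float)
    n_loci = len(positions_cM)
    bits = np.zeros((n_meioses, n_loci), dtype=np.int8)
    if anchor_index is None:
        anchor_index = 0
        bits[:, 0] = rng.integers(2, size=n_meioses)
    else:
        bits[:, anchor_index] = anchor_bits
    for j in range(anchor_index + 1, n_loci):
        theta = haldane_theta(positions_cM[j] - positions_cM[j - 1])
        flip = rng.random(n_meioses) < theta
        bits[:, j] = bits[:, j - 1] ^ flip
    for j in range(anchor_index - 1, -1, -1):
        theta = haldane_theta(positions_cM[j + 1] - positions_cM[j])
        flip = rng.random(n_meioses) < theta
        bits[:, j] = bits[:, j + 1] ^ flip
    return bits


def _simulate_markers(config: SimConfig, ped: Pedigree,
                      disease_bits: dict[str, tuple[int, int]],
                      rng: np.random.Generator
                      ) -> tuple[MarkerMap, list[dict[str, tuple[int, int]]]]:
    k = config.n_marker_alleles
    freqs = (tuple(config.marker_freqs) if config.marker_freqs is not None
             else tuple([1.0 / k] * k))
    if abs(sum(freqs) - 1.0) > 1e-9 or len(freqs) != k:
        raise SimConfigError("marker_freqs must be n_marker_alleles "
                             "probabilities summing to 1")
    positions = np.array([config.spacing_cM * j
                          for j in range(config.n_markers)])
    marker_map = MarkerMap([
        Marker(f"M{j+1:03d}", config.disease_chrom, float(p), freqs)
        for j, p in enumerate(positions)])

    # founder haplotypes: iid draws from the allele frequencies, or
    # fixed distinct alleles per founder (fully informative mode, in
    # which every transmission's grandparental origin is observable)
    founders = ped.founders
    if config.fully_informative_markers:
        if k < 2 * len(founders):
            raise SimConfigError(
                "fully informative markers need >= 2 alleles per founder")
        hap = {f.id: np.tile(np.array([[2 * i], [2 * i + 1]]),
                             (1, config.n_markers))
               for i, f in enumerate(founders)}
    else:
        hap = {f.id: rng.choice(k, size=(2, config.n_markers), p=freqs)
               for f in founders}

    # meiosis bits anchored at the disease locus position
    nonf = ped.nonfounders
    x = config.disease_position_cM
    merged = np.sort(np.append(positions, x))
    d_idx = int(np.searchsorted(merged, x))
    anchor = np.array([disease_bits[m.id][p] for m in nonf for p in (0, 1)],
                      dtype=np.int8)
    allbits = simulate_transmission_bits(rng, merged, 2 * len(nonf),
                                         anchor_index=d_idx,
                                         anchor_bits=anchor)
    marker_cols = [j for j, p in enumerate(merged) if j != d_idx]

    genotypes: list[dict[str, tuple[int, int]]] = []
    child_hap: dict[str, np.ndarray] = dict(hap)
    for mi, m in enumerate(nonf):
        pat_bits = allbits[2 * mi][marker_cols]
        mat_bits = allbits[2 * mi + 1][marker_cols]
        fa, mo = child_hap[m.father_id], child_hap[m.mother_id]
        idx = np.arange(config.n_markers)
        child_hap[m.id] = np.stack([fa[pat_bits, idx], mo[mat_bits, idx]])
    for j in range(config.n_markers):
        g: dict[str, tuple[int, int]] = {}
        for m in ped.members:
            a, b = int(child_hap[m.id][0, j]), int(child_hap[m.id][1, j])
            if (config.genotyping_error_rate > 0
                    and rng.random() < config.genotyping_error_rate):
                a, b = int(rng.integers(k)), int(rng.integers(k))
            g[m.id] = (a, b)
        genotypes.append(g)
    return marker_map, genotypes


# ---------------------------------------------------------------------
# Variant table, catalogs, CNVs
# ---------------------------------------------------------------------

_BACKGROUND_CHROMS = tuple(str(c) for c in range(1, 23))


def _planted_records(config: SimConfig, ped: Pedigree,
                     disease_genotypes: dict[str, Genotype],
                     disease_bits: dict[str, tuple[int, int]],
                     samples: list[str], rng: np.random.Generator):
    """Planted causal variant rows + genotype rows, model-consistent."""
    chrom = config.disease_chrom
    base_pos = int(rng.integers(2_000_000, 4_000_000))
    rows, gts = [], []
    if config.planted_model == "shared_homozygote":
        variants = [(base_pos, "C", "T")]
    else:
        variants = [(base_pos, "A", "T"), (base_pos + 5000, "G", "T")]
    for vi, (pos, ref, alt) in enumerate(variants):
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": PLANTED_GENE, "vclass": "NS",
            "consensus_quality": 60.0, "depth": 80,
            "copy_number_estimate": 1.0,
        })
        row = np.zeros(len(samples), dtype=np.int8)
        for si, s in enumerate(samples):
            g = disease_genotypes[s]
            if config.planted_model == "shared_homozygote":
                row[si] = int(g)
            else:
                # compound het: disease haplotype 0 of the father carries
                # variant 0, of the mother variant 1
                m = ped[s]
                if m.is_founder:
                    founder_idx = 0 if m.sex == Sex.MALE else 1
                    carries = (g is not Genotype.HOM_REF
                               and vi == founder_idx)
                    row[si] = int(Genotype.HET if carries else Genotype.HOM_REF)
                else:
                    if g is Genotype.HOM_ALT:
                        row[si] = int(Genotype.HET)  # one from each parent
                    elif g is Genotype.HET:
                        # carries the father's (vi=0) or mother's (vi=1)
                        # variant depending on which meiosis transmitted
                        # the disease haplotype (haplotype 0 by convention)
                        which = 0 if disease_bits[s][0] == 0 else 1
                        row[si] = int(Genotype.HET if vi == which
                                      else Genotype.HOM_REF)
                    else:
                        row[si] = int(Genotype.HOM_REF)
        gts.append(row)
    return rows, gts


def _background_records(config: SimConfig, samples: list[str],
                        rng: np.random.Generator):
    n = config.n_background_variants
    rows, gts = [], []
    genes = [f"GENE{1 + i // 3:04d}" for i in range(n)]
    chroms = rng.choice(len(_BACKGROUND_CHROMS), size=n)
    vclass = rng.choice(["NS", "SS", "Indel"], size=n, p=[0.7, 0.1, 0.2])
    offsets = rng.integers(1, 200_000, size=n)
    pos_by_chrom: dict[str, int] = {}
    quality = rng.uniform(30.0, 90.0, size=n)
    depth = rng.integers(10, 201, size=n)
    cn = rng.uniform(0.8, 1.6, size=n)
    af = rng.uniform(0.05, 0.5, size=n)
    fail_mask = rng.random(n) < config.qc_noise
    fail_kind = rng.integers(4, size=n)
    for i in range(n):
        chrom = _BACKGROUND_CHROMS[chroms[i]]
        pos = pos_by_chrom.get(chrom, 1_000_000) + int(offsets[i])
        pos_by_chrom[chrom] = pos
        ref, alt = ("G", "A") if i % 2 else ("T", "C")
        q, d, c = float(quality[i]), int(depth[i]), float(cn[i])
        if fail_mask[i]:
            kind = int(fail_kind[i])
            if kind == 0:
                q = float(rng.uniform(1.0, 19.0))
            elif kind == 1:
                c = float(rng.uniform(2.0, 4.0))
            elif kind == 2:
                d = int(rng.choice([rng.integers(0, 4),
                                    rng.integers(501, 1000)]))
            else:
                pos = pos_by_chrom[chrom] = pos_by_chrom[chrom] + 2
                # 2 bp from the previous variant on this chromosome
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": genes[i], "vclass": str(vclass[i]),
            "consensus_quality": q, "depth": d, "copy_number_estimate": c,
        })
        gts.append(rng.binomial(2, af[i], size=len(samples)).astype(np.int8))
    return rows, gts


def _catalogs(config: SimConfig, background_keys, rng: np.random.Generator
              ) -> list[DatabaseCatalog]:
    names = list(config.fraction_catalogued)
    fracs = np.array([config.fraction_catalogued[n] for n in names])
    sites: dict[str, set] = {n: set() for n in names}
    categorical = abs(fracs.sum() - 1.0) < 1e-9
    for key in background_keys:
        if categorical:
            pick = names[int(rng.choice(len(names), p=fracs))]
            sites[pick].add(key)
        else:
            for n, f in zip(names, fracs):
                if rng.random() < f:
                    sites[n].add(key)
    return [DatabaseCatalog(name=n, sites=frozenset(sites[n]))
            for n in names]


def _cnv_segments(config: SimConfig, ped: Pedigree,
                  rng: np.random.Generator) -> list[CNVSegment]:
    segs = []
    ids = [m.id for m in ped.members]
    for _ in range(config.n_cnv_segments):
        iid = ids[int(rng.integers(len(ids)))]
        chrom = _BACKGROUND_CHROMS[int(rng.integers(len(_BACKGROUND_CHROMS)))]
        start = int(rng.integers(1_000_000, 50_000_000))
        length = int(rng.integers(10_000, 500_000))
        cnum = int(rng.choice([0, 1, 3]))
        segs.append(CNVSegment(iid, chrom, start, start + length, cnum))
    return segs


# ---------------------------------------------------------------------

def simulate_family(config: SimConfig) -> SimResult:
    """Generate one family's full synthetic data set."""
    rng = np.random.default_rng(config.seed)
    ped, disease_genotypes, disease_bits = _disease_inheritance(config, rng)
    marker_map, marker_genotypes = _simulate_markers(
        config, ped, disease_bits, rng)

    samples = [m.id for m in ped.members]
    planted_rows, planted_gts = _planted_records(
        config, ped, disease_genotypes, disease_bits, samples, rng)
    bg_rows, bg_gts = _background_records(config, samples, rng)
    records = pd.DataFrame(planted_rows + bg_rows)
    gmat = (np.vstack(planted_gts + bg_gts) if len(records)
            else np.empty((0, len(samples)), dtype=np.int8))
    table = VariantTable(samples=samples, records=records, genotypes=gmat)
    table.records["dist_to_nearest_snp"] = _plausible_distances(table)

    planted_keys = [(r["chrom"], r["pos"], r["alt"]) for r in planted_rows]
    bg_keys = [(r["chrom"], r["pos"], r["alt"]) for r in bg_rows]
    catalogs = _catalogs(config, bg_keys, rng)

    gene_rows = [(PLANTED_GENE, config.disease_chrom,
                  config.disease_position_cM)]
    seen = {PLANTED_GENE}
    for r in bg_rows:
        if r["gene"] not in seen:
            seen.add(r["gene"])
            gene_rows.append((r["gene"], r["chrom"],
                              round(float(rng.uniform(0.0, 150.0)), 3)))
    gene_positions = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "position_cM"])

    return SimResult(
        config=config, pedigree=ped, disease_genotypes=disease_genotypes,
        marker_map=marker_map, marker_genotypes=marker_genotypes,
        table=table, catalogs=catalogs,
        cnv_segments=_cnv_segments(config, ped, rng),
        planted_gene=PLANTED_GENE, planted_keys=planted_keys,
        gene_positions=gene_positions)


def _plausible_distances(table: VariantTable) -> np.ndarray:
    """Distances recomputed exactly as the VCF reader would."""
    from .variants import _nearest_snp_distances

    return _nearest_snp_distances(table.records, table.genotypes)


# ---------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------

def write_fixture_bundle(out_dir, config: SimConfig) -> dict:
    """Simulate and write the standard-format fixture files.

    Emits PED (structure + disease genotypes), marker PED/MAP, VCF,
    annotation TSV, one catalog TSV per stage, CNV TSV, a gene→map
    position TSV and a manifest JSON recording the seed and per-file
    SHA-256 checksums.  Same seed, same bytes.
    """
    os.makedirs(out_dir, exist_ok=True)
    res = simulate_family(config)
    files: dict[str, str] = {}

    def path(name):
        files[name] = os.path.join(out_dir, name)
        return files[name]

    dis = {iid: _geno_to_alleles(g)
           for iid, g in res.disease_genotypes.items()}
    write_ped(path("family.ped"), res.pedigree, [dis])
    markers = [{iid: (str(a + 1), str(b + 1)) for iid, (a, b) in g.items()}
               for g in res.marker_genotypes]
    write_ped(path("markers.ped"), res.pedigree, markers)
    write_map(path("markers.map"), res.marker_map)
    write_variants(path("variants.vcf"), res.table)
    write_annotation(path("annotations.tsv"), res.table)
    for cat in res.catalogs:
        write_catalog(path(f"catalog_{cat.name}.tsv"), cat)
    write_cnv_table(path("cnv.tsv"), res.cnv_segments)
    res.gene_positions.to_csv(path("gene_map.tsv"), sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "template": config.template,
        "planted_model": config.planted_model,
        "planted_gene": res.planted_gene,
        "planted_keys": [list(k) for k in res.planted_keys],
        "disease_chrom": config.disease_chrom,
        "disease_position_cM": config.disease_position_cM,
        "sequenced_affected": sequenced_affected(res),
        "files": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def sequenced_affected(res: SimResult) -> list[str]:
    """The samples whose exomes enter the cascade: the configured list,
    or by default the first two affected members (mirroring a study
    that sequences two affected siblings)."""
    if res.config.sequenced is not None:
        return list(res.config.sequenced)
    return [m.id for m in res.pedigree.affected][:2]


def _geno_to_alleles(g: Genotype) -> tuple[str, str]:
    return {Genotype.HOM_REF: ("1", "1"), Genotype.HET: ("1", "2"),
            Genotype.HOM_ALT: ("2", "2"),
            Genotype.MISSING: ("0", "0")}[g]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()
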