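"""Database novelty cascade and recessive candidate-gene models.

After QC, candidate-deleterious variants (classes NS/SS/Indel) pass
through an ordered series of known-site catalogs — by default emulating
dbSNP, 1000 Genomes, "HapMap 8"+YH and an in-house control set — each
stage removing the variants whose (chrom, pos, alt) key the catalog
contains.  After every stage the report records, per affected sample and
for the affected individuals jointly:

* per-sample NS/SS/Indel count;
* per-sample homozygote count;
* shared count (variants alt-carried by every affected sample);
* shared-homozygote count (hom-alt in every affected sample);
* compound-heterozygote count (variants in genes with >=2 distinct
  shared-het variants).

This mirrors the count matrix a recessive exome study tabulates: each
column is non-increasing down the stages.  Candidate genes are taken
from the final stage's survivors under the shared-homozygote and
compound-heterozygote models.  Unaffected relatives are deliberately
not consulted here — segregation against the full pedigree is a
separate downstream check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Genotype, Pedigree
from .qc import QCReport, QCThresholds, apply_qc
from .variants import DatabaseCatalog, VariantConfigError, VariantTable

MODELS = ("shared_all", "shared_homozygote", "compound_heterozygote")


@dataclass
class CascadeConfig:
    stages: list[DatabaseCatalog]
    affected_samples: list[str]
    models: tuple[str, ...] = MODELS

    def __post_init__(self):
        if not self.affected_samples:
            raise VariantConfigError("need >=1 affected sample")
        bad = set(self.models) - set(MODELS)
        if bad:
            raise VariantConfigError(f"unknown models {bad}")


@dataclass
class FilterReport:
    """Stage-by-stage count matrix plus final candidate gene lists.

    ``matrix`` rows: input, then one per stage; columns: per-sample
    counts, per-sample homozygote counts, shared, shared-homozygote,
    compound-heterozygote.
    """

    matrix: pd.DataFrame
    candidate_genes: dict[str, list[str]]
    phase_unknown_genes: list[str]
    qc: QCReport | None = None

    def to_json_dict(self) -> dict:
        return {
            "matrix": self.matrix.to_dict(orient="index"),
            "candidate_genes": self.candidate_genes,
            "phase_unknown_genes": self.phase_unknown_genes,
            "qc": self.qc.as_dict() if self.qc else None,
        }


def deleterious_mask(table: VariantTable) -> np.ndarray:
    """NS/SS/Indel records — the classes the cascade counts."""
    return table.records["vclass"].isin(("NS", "SS", "Indel")).to_numpy()


def stage_filter(table: VariantTable, catalog: DatabaseCatalog
                 ) -> VariantTable:
    """Survivors are exactly the records whose key is not catalogued."""
    keys = table.keys()
    keep = np.array([k not in catalog.sites for k in keys], dtype=bool)
    return table.subset(keep)


def _affected_cols(table: VariantTable, affected: list[str]) -> list[int]:
    return [table.sample_index(s) for s in affected]


def shared_variants(table: VariantTable, affected: list[str]
                    ) -> VariantTable:
    """NS/SS/Indel records where every affected sample carries >=1 alt
    allele (het or hom-alt; missing does not count as carrying)."""
    cols = _affected_cols(table, affected)
    g = table.genotypes[:, cols]
    mask = deleterious_mask(table) & (g >= int(Genotype.HET)).all(axis=1)
    return table.subset(mask)


def shared_homozygote_model(table: VariantTable, affected: list[str]
                            ) -> list[str]:
    """Genes with >=1 record hom-alt in all affected samples."""
    cols = _affected_cols(table, affected)
    g = table.genotypes[:, cols]
    mask = deleterious_mask(table) & (g == int(Genotype.HOM_ALT)).all(axis=1)
    genes = table.records.loc[mask, "gene"]
    return sorted(set(genes) - {""})


def compound_het_model(
    table: VariantTable,
    affected: list[str],
    pedigree: Pedigree | None = None,
    parent_genotypes: dict[str, dict[tuple[str, int, str], Genotype]] | None = None,
) -> tuple[list[str], list[str]]:
    """Genes with >=2 distinct variants each het in all affected samples.

    Returns ``(candidates, phase_unknown)``.  Without parental
    genotypes phase cannot be asserted and every candidate is also
    listed phase-unknown.  With parental genotypes (either parents
    present as table samples, via ``pedigree``, or an explicit
    ``parent_genotypes`` map keyed by parent id then variant key) a gene
    is kept only when a trans configuration is possible: each parent
    carries at least one of the gene's shared-het variants and no
    parent carries all of them.
    """
    cols = _affected_cols(table, affected)
    g = table.genotypes[:, cols]
    het_all = deleterious_mask(table) & (g == int(Genotype.HET)).all(axis=1)
    sub = table.records.loc[het_all]
    all_keys = table.keys()
    keys = [all_keys[i] for i in np.flatnonzero(het_all)]

    by_gene: dict[str, list[tuple[str, int, str]]] = {}
    for gene, key in zip(sub["gene"], keys):
        if gene:
            by_gene.setdefault(gene, []).append(key)

    parents = _parent_lookup(table, affected, pedigree, parent_genotypes)

    candidates, phase_unknown = [], []
    for gene, gene_keys in sorted(by_gene.items()):
        if len(set(gene_keys)) < 2:
            continue
        if parents is None:
            candidates.append(gene)
            phase_unknown.append(gene)
            continue
        carried = []
        for pid, gt_of in parents.items():
            carried.append({k for k in set(gene_keys)
                            if gt_of(k) in (Genotype.HET, Genotype.HOM_ALT)})
        # trans possible: every parent carries >=1, none carries all
        uniq = set(gene_keys)
        if all(c for c in carried) and not any(c == uniq for c in carried):
            candidates.append(gene)
    return candidates, phase_unknown


def _parent_lookup(table, affected, pedigree, parent_genotypes):
    """Genotype accessors for the affecteds' parents, or None if
    parental genotypes are unavailable."""
    if parent_genotypes:
        return {pid: (lambda k, _g=gmap: _g.get(k, Genotype.MISSING))
                for pid, gmap in parent_genotypes.items()}
    if pedigree is None:
        return None
    parent_ids = set()
    for s in affected:
        if s in pedigree and not pedigree[s].is_founder:
            parent_ids.update((pedigree[s].father_id, pedigree[s].mother_id))
    avail = [p for p in sorted(parent_ids) if p in table.samples]
    if not avail:
        return None
    key_to_row = {k: i for i, k in enumerate(table.keys())}

    def make(pid):
        ci = table.sample_index(pid)

        def gt_of(key):
            i = key_to_row.get(key)
            if i is None:
                return Genotype.MISSING
            return Genotype(int(table.genotypes[i, ci]))
        return gt_of

    return {pid: make(pid) for pid in avail}


def run_cascade(
    table: VariantTable,
    qc: QCThresholds | None,
    config: CascadeConfig,
    pedigree: Pedigree | None = None,
) -> FilterReport:
    """QC, then ordered catalog stages, recounting after every stage."""
    qc_report = None
    if qc is not None:
        table, qc_report = apply_qc(table, qc)

    affected = config.affected_samples
    for s in affected:
        table.sample_index(s)  # raises VariantConfigError if absent

    rows = {}

    def count_row(t: VariantTable) -> dict[str, int]:
        out = {}
        delet = deleterious_mask(t)
        for s in affected:
            ci = t.sample_index(s)
            carry = t.genotypes[:, ci] >= int(Genotype.HET)
            hom = t.genotypes[:, ci] == int(Genotype.HOM_ALT)
            out[s] = int((delet & carry).sum())
            out[f"{s}_homozygote"] = int((delet & hom).sum())
        shared = shared_variants(t, affected)
        out["shared"] = len(shared)
        cols = [shared.sample_index(s) for s in affected]
        g = shared.genotypes[:, cols]
        out["shared_homozygote"] = int(
            (g == int(Genotype.HOM_ALT)).all(axis=1).sum())
        het_all = (g == int(Genotype.HET)).all(axis=1)
        gene_counts = shared.records.loc[het_all, "gene"].value_counts()
        ch_genes = set(gene_counts[gene_counts >= 2].index) - {""}
        out["compound_heterozygote"] = int(
            shared.records.loc[het_all, "gene"].isin(ch_genes).sum())
        return out

    rows["input"] = count_row(table)
    current = table
    for k, catalog in enumerate(config.stages, start=1):
        current = stage_filter(current, catalog)
        rows[f"after_stage_{k}_{catalog.name}"] = count_row(current)

    candidates: dict[str, list[str]] = {}
    phase_unknown: list[str] = []
    final_shared = shared_variants(current, affected)
    if "shared_all" in config.models:
        candidates["shared_all"] = sorted(
            set(final_shared.records["gene"]) - {""})
    if "shared_homozygote" in config.models:
        candidates["shared_homozygote"] = shared_homozygote_model(
            current, affected)
    if "compound_heterozygote" in config.models:
        ch, phase_unknown = compound_het_model(current, affected, pedigree)
        candidates["compound_heterozygote"] = ch

    matrix = pd.DataFrame.from_dict(rows, orient="index")
    return FilterReport(matrix=matrix, candidate_genes=candidates,
                        phase_unknown_genes=phase_unknown, qc=qc_report)
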