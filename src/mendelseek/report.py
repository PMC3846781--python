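"""End-to-end run: QC -> cascade -> co-segregation -> linkage -> CNV ->
consequence, with a JSON run report.

The final step intersects the cascade's candidate genes with the
linkage candidate region, which requires a gene -> map position table
(gene, chrom, position_cM) supplied by the user or emitted by the
simulator: positional candidacy is an explicit join, not an implicit
annotation lookup.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__
from .cascade import CascadeConfig, FilterReport, run_cascade
from .cnv import cosegregating_cnvs, read_cnv_table
from .consequence import (annotate_variants, bundled_cds,
                          read_transcript_fasta)
from .linkage import (DiseaseModel, FounderFrequencyError, LODResult,
                      Marker, MarkerMap, candidate_region,
                      estimate_founder_freqs, multipoint_lod, read_map)
from .pedigree import Genotype, Pedigree, cosegregation_check, read_ped
from .qc import QCThresholds
from .variants import read_catalog, read_variants

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    ped_path: str
    vcf_path: str
    annot_path: str
    catalog_paths: list[str]          # ordered: one per cascade stage
    markers_ped_path: str | None = None
    markers_map_path: str | None = None
    cnv_path: str | None = None
    gene_map_path: str | None = None
    cds_fasta_path: str | None = None
    hgvs: list[str] = field(default_factory=list)
    affected_samples: list[str] | None = None  # default: affected members
    qc: QCThresholds = field(default_factory=QCThresholds)
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    overlap_fraction: float = 0.5
    out_dir: str | None = None

    def input_paths(self) -> list[str]:
        paths = [self.ped_path, self.vcf_path, self.annot_path,
                 *self.catalog_paths]
        for p in (self.markers_ped_path, self.markers_map_path,
                  self.cnv_path, self.gene_map_path, self.cds_fasta_path):
            if p is not None:
                paths.append(p)
        return paths


def _marker_genotypes_from_ped(genotype_dicts):
    """PED allele strings (1-based) to 0-based integer pairs, plus the
    per-marker allele count."""
    out, counts = [], []
    for g in genotype_dicts:
        conv = {iid: (int(a) - 1, int(b) - 1) for iid, (a, b) in g.items()}
        n = max((max(p) for p in conv.values()), default=1) + 1
        out.append(conv)
        counts.append(max(n, 2))
    return out, counts


def run_full(config: RunConfig) -> dict:
    """Execute the whole workflow; returns (and optionally writes) the
    run report as a JSON-ready dict."""
    pedigree, ped_genotypes = read_ped(config.ped_path)
    table = read_variants(config.vcf_path, config.annot_path)
    catalogs = [read_catalog(p) for p in config.catalog_paths]

    affected = config.affected_samples
    if affected is None:
        affected = [m.id for m in pedigree.affected if m.id in table.samples]

    cascade_cfg = CascadeConfig(stages=catalogs, affected_samples=affected)
    filt: FilterReport = run_cascade(table, config.qc, cascade_cfg,
                                     pedigree=pedigree)

    # co-segregation of each candidate gene against the full pedigree
    coseg = _cosegregation_verdicts(pedigree, table, filt)

    linkage_out = None
    if config.markers_ped_path and config.markers_map_path:
        linkage_out = _linkage_step(config, pedigree)

    cnv_out = None
    if config.cnv_path:
        segs = read_cnv_table(config.cnv_path)
        hits = cosegregating_cnvs(segs, pedigree,
                                  overlap_fraction=config.overlap_fraction)
        cnv_out = {
            "n_segments": len(segs),
            "cosegregating_loci": [
                {"chrom": h.chrom, "start": h.start, "end": h.end,
                 "direction": h.direction, "carriers": h.carriers}
                for h in hits],
        }

    consequence_out = None
    if config.hgvs:
        tx = (read_transcript_fasta(config.cds_fasta_path)
              if config.cds_fasta_path else bundled_cds())
        consequence_out = [
            {"hgvs_c": str(c.variant), "protein": c.protein_notation,
             "effect": c.effect, "ref_codon": c.ref_codon,
             "alt_codon": c.alt_codon, "truncated_length": c.truncated_length}
            for c in annotate_variants(tx, config.hgvs)]

    final = _intersect_with_region(config, filt, linkage_out)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "pedigree": {"family_id": pedigree.family_id,
                     "n_members": len(pedigree),
                     "n_affected": len(pedigree.affected)},
        "affected_samples": affected,
        "qc": filt.qc.as_dict() if filt.qc else None,
        "filter_matrix": filt.matrix.to_dict(orient="index"),
        "candidate_genes": filt.candidate_genes,
        "phase_unknown_genes": filt.phase_unknown_genes,
        "cosegregation": coseg,
        "linkage": linkage_out,
        "cnv": cnv_out,
        "consequences": consequence_out,
        "final_candidates": final,
    }

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        filt.matrix.to_csv(os.path.join(config.out_dir,
                                        "filter_matrix.tsv"), sep="\t")
        if linkage_out is not None:
            pd.DataFrame({
                "position_cM": linkage_out["positions_cM"],
                "lod": linkage_out["lods"],
            }).to_csv(os.path.join(config.out_dir, "lod.tsv"),
                      sep="\t", index=False)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _cosegregation_verdicts(pedigree: Pedigree, table, filt: FilterReport
                            ) -> dict[str, bool]:
    """Recessive co-segregation verdict per candidate gene, using the
    full pedigree's genotypes from the variant table."""
    verdicts: dict[str, bool] = {}
    genes = set()
    for lst in filt.candidate_genes.values():
        genes.update(lst)
    in_ped = [s for s in table.samples if s in pedigree]
    for gene in sorted(genes):
        idx = np.flatnonzero((table.records["gene"] == gene).to_numpy())
        site_maps = []
        for i in idx:
            site_maps.append({
                s: Genotype(int(table.genotypes[i, table.sample_index(s)]))
                for s in in_ped})
        ok = False
        for g in site_maps:
            if cosegregation_check(pedigree, g):
                ok = True
                break
        if not ok and len(site_maps) >= 2:
            for a in range(len(site_maps)):
                for b in range(a + 1, len(site_maps)):
                    if cosegregation_check(pedigree, site_maps[a],
                                           second_site=site_maps[b]):
                        ok = True
                        break
                if ok:
                    break
        verdicts[gene] = ok
    return verdicts


def _linkage_step(config: RunConfig, pedigree: Pedigree) -> dict:
    mped, mgeno_raw = read_ped(config.markers_ped_path)
    if {m.id for m in mped.members} != {m.id for m in pedigree.members}:
        raise ValueError("marker PED members differ from family PED")
    genotypes, n_alleles = _marker_genotypes_from_ped(mgeno_raw)
    base_map = read_map(config.markers_map_path)
    if len(base_map) != len(genotypes):
        raise ValueError(
            f"MAP has {len(base_map)} markers but PED carries "
            f"{len(genotypes)}")
    markers = []
    for m, g, k in zip(base_map, genotypes, n_alleles):
        try:
            freqs = estimate_founder_freqs(pedigree, g, k)
        except FounderFrequencyError:
            freqs = np.full(k, 1.0 / k)
        markers.append(Marker(m.name, m.chrom, m.position_cM,
                              tuple(freqs)))
    marker_map = MarkerMap(markers)
    lod = multipoint_lod(pedigree, config.disease_model, marker_map,
                         genotypes)
    # plateau tolerance 1e-3: positions whose LOD ties the maximum can
    # differ at the order of the disease allele frequency (second-order
    # founder-genotype terms), far below any meaningful LOD difference
    left, right, width = candidate_region(lod, marker_map, tol=1e-3)
    return {
        "positions_cM": [float(x) for x in lod.positions],
        "lods": [float(x) for x in lod.lods],
        "max_lod": lod.max_lod,
        "argmax_cM": lod.argmax_position,
        "chrom": markers[0].chrom,
        "region": {
            "left_marker": left.name if left else None,
            "left_cM": left.position_cM if left else None,
            "right_marker": right.name if right else None,
            "right_cM": right.position_cM if right else None,
            "width_cM": width,
        },
    }


def _intersect_with_region(config: RunConfig, filt: FilterReport,
                           linkage_out: dict | None) -> dict:
    """Cascade candidates restricted to the linkage candidate region
    (when both linkage results and a gene map are available)."""
    union = sorted({g for lst in filt.candidate_genes.values() for g in lst})
    if linkage_out is None or config.gene_map_path is None:
        return {"genes": union, "restricted_by_region": False}
    gm = pd.read_csv(config.gene_map_path, sep="\t",
                     dtype={"gene": str, "chrom": str})
    region = linkage_out["region"]
    chrom = linkage_out["chrom"]
    lo = region["left_cM"] if region["left_cM"] is not None else -np.inf
    hi = region["right_cM"] if region["right_cM"] is not None else np.inf
    inside = set(gm.loc[(gm["chrom"] == chrom)
                        & (gm["position_cM"] >= lo)
                        & (gm["position_cM"] <= hi), "gene"])
    return {"genes": sorted(set(union) & inside),
            "restricted_by_region": True}
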