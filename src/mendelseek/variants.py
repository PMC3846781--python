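"""Variant table model, VCF/annotation readers and database catalogs.

The pipeline starts from called coding variants: a VCF 4.x file with GT
per sample plus a sidecar annotation TSV keyed by (chrom, pos, ref, alt)
supplying the gene symbol, the deleterious class (NS = non-synonymous,
SS = splice acceptor/donor, Indel) and the caller's regional copy-number
estimate.  Database catalogs (known-site sets emulating dbSNP /
1000 Genomes / HapMap+YH / in-house controls) are plain TSVs of
(chrom, pos, alt) keys.

Coordinates are 1-based inclusive (VCF convention).  Catalog membership
is allele-aware on (chrom, pos, alt); indel alleles are left-aligned and
trimmed to a normal form before lookup so that equivalent spellings
match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Genotype

VCLASSES = ("NS", "SS", "Indel")


class VariantConfigError(ValueError):
    """Sample mismatch or inconsistent table configuration."""


class CatalogParseError(ValueError):
    """Malformed catalog TSV."""


@dataclass(frozen=True)
class DatabaseCatalog:
    """A named set of known (chrom, pos, alt) variant keys.

    One cascade stage removes exactly the records whose normalized key
    is a member.
    """

    name: str
    sites: frozenset[tuple[str, int, str]]

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self.sites

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class VariantTable:
    """Coding-variant calls for a fixed ordered set of samples.

    ``records`` is a DataFrame with one row per variant and columns
    chrom, pos, ref, alt, gene, vclass, consensus_quality, depth,
    copy_number_estimate, dist_to_nearest_snp.  ``genotypes`` is an
    (n_records, n_samples) int8 matrix of :class:`Genotype` codes, so
    every record carries an entry (possibly missing) for every sample.
    """

    samples: list[str]
    records: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self):
        if self.genotypes.shape != (len(self.records), len(self.samples)):
            raise VariantConfigError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.records)} records x {len(self.samples)} samples")
        if len(self.records) and (self.records["pos"] < 1).any():
            raise VariantConfigError("positions must be >= 1")
        if len(self.records) and (self.records["ref"] == self.records["alt"]).any():
            raise VariantConfigError("ref == alt in a record")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise VariantConfigError(
                f"sample {sample!r} not in table {self.samples}") from None

    def keys(self) -> list[tuple[str, int, str]]:
        """Normalized (chrom, pos, alt) catalog keys, one per record."""
        return [
            normalize_key(c, int(p), r, a)
            for c, p, r, a in zip(self.records["chrom"], self.records["pos"],
                                  self.records["ref"], self.records["alt"])
        ]

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            samples=list(self.samples),
            records=self.records.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask],
        )


def normalize_key(chrom: str, pos: int, ref: str, alt: str
                  ) -> tuple[str, int, str]:
    """Left-align/trim an allele pair and return the (chrom,pos,alt) key.

    Shared trailing then leading bases are stripped (keeping one anchor
    base for pure insertions/deletions), moving ``pos`` right past any
    stripped leading bases — standard VCF left normalization restricted
    to what a catalog lookup needs.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, alt)


# ---------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------

_GT_CODE = {
    (0, 0): Genotype.HOM_REF, (0, 1): Genotype.HET, (1, 0): Genotype.HET,
    (1, 1): Genotype.HOM_ALT,
}


def read_variants(vcf_path, annot_path, samples: list[str] | None = None
                  ) -> VariantTable:
    """Read a VCF 4.x + annotation TSV into a :class:`VariantTable`.

    The TSV must have columns chrom, pos, ref, alt, gene, vclass and
    optionally copy_number_estimate.  VCF records absent from the TSV
    get vclass ``other`` (and never enter the cascade).  When
    ``samples`` is given (e.g. from a pedigree) it must match the VCF
    header sample set.  ``dist_to_nearest_snp`` is recomputed from the
    table: for each record, the minimum distance to another record on
    the same chromosome carried by a common sample (a carrier-aware
    adjacency, since QC is defined per sample's call set).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    if samples is not None and set(samples) != set(vcf_samples):
        raise VariantConfigError(
            f"VCF samples {vcf_samples} do not match expected {samples}")
    order = samples or vcf_samples
    col = [vcf_samples.index(s) for s in order]

    annot = pd.read_csv(annot_path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "vclass"}
    missing = required - set(annot.columns)
    if missing:
        raise VariantConfigError(f"annotation TSV missing columns {missing}")
    akey = {}
    for row in annot.itertuples(index=False):
        akey[(str(row.chrom), int(row.pos), row.ref.upper(), row.alt.upper())] = row

    rows, gts = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise VariantConfigError(
                f"multi-allelic record at {v.CHROM}:{v.POS}; split upstream")
        ann = akey.get((v.CHROM, v.POS, v.REF.upper(), v.ALT[0].upper()))
        qual = v.QUAL if v.QUAL is not None else np.nan
        depth = v.INFO.get("DP", -1)
        rows.append({
            "chrom": v.CHROM, "pos": v.POS, "ref": v.REF.upper(),
            "alt": v.ALT[0].upper(),
            "gene": ann.gene if ann is not None else "",
            "vclass": (ann.vclass if ann is not None and ann.vclass in VCLASSES
                       else "other"),
            "consensus_quality": qual,
            "depth": int(depth),
            "copy_number_estimate": (
                float(getattr(ann, "copy_number_estimate", np.nan))
                if ann is not None else np.nan),
        })
        row_gt = np.full(len(order), int(Genotype.MISSING), dtype=np.int8)
        gt_types = v.genotypes  # [allele1, allele2, phased]
        for j, ci in enumerate(col):
            a = tuple(gt_types[ci][:2])
            if a in _GT_CODE:
                row_gt[j] = int(_GT_CODE[a])
        gts.append(row_gt)

    records = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "vclass",
                       "consensus_quality", "depth", "copy_number_estimate"])
    gmat = (np.vstack(gts) if gts
            else np.empty((0, len(order)), dtype=np.int8))
    records["dist_to_nearest_snp"] = _nearest_snp_distances(records, gmat)
    return VariantTable(samples=list(order), records=records, genotypes=gmat)


def _nearest_snp_distances(records: pd.DataFrame, gmat: np.ndarray
                           ) -> np.ndarray:
    """Per-record min distance to another record in a shared carrier's
    call set on the same chromosome; large sentinel when none exists."""
    n = len(records)
    out = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    if n == 0:
        return out
    # a record is in sample s's call set if its genotype there is called
    called = gmat >= int(Genotype.HOM_REF)
    for s in range(gmat.shape[1]):
        in_set = called[:, s]
        for chrom, idx in records.groupby("chrom").indices.items():
            idx = np.asarray(idx)
            idx = idx[in_set[idx]]
            if len(idx) < 2:
                continue
            pos = records["pos"].to_numpy()[idx]
            order = np.argsort(pos, kind="stable")
            sp = pos[order]
            gaps = np.diff(sp)
            d = np.full(len(sp), np.iinfo(np.int64).max, dtype=np.int64)
            d[:-1] = np.minimum(d[:-1], gaps)
            d[1:] = np.minimum(d[1:], gaps)
            np.minimum.at(out, idx[order], d)
    return out


def write_variants(path, table: VariantTable) -> None:
    """Write a minimal VCF 4.2 (GT format, DP info) for the table.

    Restricted to the pipeline's own schema: biallelic records, one GT
    per sample.  Round-trips through :func:`read_variants` preserving
    (chrom, pos, ref, alt, GT) exactly.
    """
    gt_out = {int(Genotype.HOM_REF): "0/0", int(Genotype.HET): "0/1",
              int(Genotype.HOM_ALT): "1/1", int(Genotype.MISSING): "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description='
                 '"Sequencing depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        for chrom in pd.unique(table.records["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i, row in table.records.iterrows():
            qual = row["consensus_quality"]
            qual_s = "." if pd.isna(qual) else f"{qual:g}"
            depth = int(row["depth"])
            info = f"DP={depth}" if depth >= 0 else "."
            gts = "\t".join(gt_out[int(g)] for g in table.genotypes[i])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t{qual_s}\tPASS\t{info}\tGT\t{gts}\n")


def write_annotation(path, table: VariantTable) -> None:
    """Sidecar annotation TSV matching :func:`read_variants`."""
    cols = ["chrom", "pos", "ref", "alt", "gene", "vclass",
            "copy_number_estimate"]
    table.records[cols].to_csv(path, sep="\t", index=False)


def read_catalog(path, name: str | None = None) -> DatabaseCatalog:
    """Read a catalog TSV (columns chrom, pos, alt; ref optional).

    Duplicate rows collapse; keys are normalized like table keys when a
    ref column is present, else taken as-is.
    """
    import os

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for c in ("chrom", "pos", "alt"):
        if c not in df.columns:
            raise CatalogParseError(f"catalog {path}: missing column {c!r}")
    try:
        pos = df["pos"].astype(int)
    except (ValueError, TypeError) as e:
        raise CatalogParseError(f"catalog {path}: non-integer pos ({e})")
    if "ref" in df.columns:
        sites = frozenset(
            normalize_key(c, int(p), r, a)
            for c, p, r, a in zip(df["chrom"], pos, df["ref"], df["alt"]))
    else:
        sites = frozenset(
            (c, int(p), a.upper())
            for c, p, a in zip(df["chrom"], pos, df["alt"]))
    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return DatabaseCatalog(name=name, sites=sites)


def write_catalog(path, catalog: DatabaseCatalog) -> None:
    df = pd.DataFrame(sorted(catalog.sites), columns=["chrom", "pos", "alt"])
    df.to_csv(path, sep="\t", index=False)
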