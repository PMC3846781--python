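"""Co-segregation screen of copy-number variant calls.

CNV calls (non-diploid segments per individual) are clustered across
individuals by reciprocal overlap and copy-number direction (loss
CN < 2 vs gain CN > 2); a cluster co-segregates with a recessive
phenotype when every affected member contributes a segment and no
unaffected genotyped member does.  The study design expects this screen
to come back empty — any hit flags a locus the exome cascade cannot
see.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pedigree import Affection, Pedigree


class CNVParseError(ValueError):
    """Malformed CNV table row."""


@dataclass(frozen=True)
class CNVSegment:
    individual_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    copy_number: int

    def __post_init__(self):
        if self.start > self.end:
            raise CNVParseError(
                f"{self.individual_id} {self.chrom}:{self.start}-{self.end}: "
                "start > end")
        if self.copy_number < 0:
            raise CNVParseError("copy number must be >= 0")
        if self.copy_number == 2:
            raise CNVParseError("diploid segments are not CNV calls")

    @property
    def direction(self) -> str:
        return "loss" if self.copy_number < 2 else "gain"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def reciprocal_overlap(a: CNVSegment, b: CNVSegment) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


@dataclass
class CNVLocus:
    """A cluster of overlapping same-direction segments across
    individuals, reported as its spanning interval."""

    chrom: str
    start: int
    end: int
    direction: str
    carriers: list[str]
    segments: list[CNVSegment]


def cluster_segments(segments: list[CNVSegment],
                     overlap_fraction: float = 0.5) -> list[CNVLocus]:
    """Single-linkage clusters under reciprocal overlap >= threshold
    and matching direction."""
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    n = len(segments)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = segments[i], segments[j]
            if (a.direction == b.direction
                    and reciprocal_overlap(a, b) >= overlap_fraction):
                parent[find(i)] = find(j)

    groups: dict[int, list[CNVSegment]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(segments[i])
    loci = []
    for segs in groups.values():
        loci.append(CNVLocus(
            chrom=segs[0].chrom,
            start=min(s.start for s in segs),
            end=max(s.end for s in segs),
            direction=segs[0].direction,
            carriers=sorted({s.individual_id for s in segs}),
            segments=segs,
        ))
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.direction))
    return loci


def cosegregating_cnvs(
    segments: list[CNVSegment],
    pedigree: Pedigree,
    overlap_fraction: float = 0.5,
    genotyped: set[str] | None = None,
) -> list[CNVLocus]:
    """CNV loci present in all affected and absent from all unaffected
    genotyped members.

    ``genotyped`` limits which members count as screened (default: all
    individuals contributing at least one segment plus all pedigree
    members — i.e. absence of calls is treated as a diploid genome).
    """
    affected = {m.id for m in pedigree.affected}
    if not affected:
        return []
    unaffected = {m.id for m in pedigree.members
                  if m.affection is Affection.UNAFFECTED}
    if genotyped is not None:
        affected &= genotyped
        unaffected &= genotyped
        if not affected:
            return []
    out = []
    for locus in cluster_segments(segments, overlap_fraction):
        carriers = set(locus.carriers)
        if affected <= carriers and not (carriers & unaffected):
            out.append(locus)
    return out


# ---------------------------------------------------------------------
# I/O: BED-like TSV (individual, chrom, start, end, copy_number)
# ---------------------------------------------------------------------

CNV_COLUMNS = ["individual", "chrom", "start", "end", "copy_number"]


def read_cnv_table(path) -> list[CNVSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CNV_COLUMNS) - set(df.columns)
    if missing:
        raise CNVParseError(f"CNV table missing columns {sorted(missing)}")
    segs = []
    for row in df.itertuples(index=False):
        try:
            segs.append(CNVSegment(
                individual_id=str(row.individual), chrom=str(row.chrom),
                start=int(row.start), end=int(row.end),
                copy_number=int(row.copy_number)))
        except (TypeError, ValueError) as e:
            raise CNVParseError(f"bad CNV row {tuple(row)}: {e}") from e
    return segs


def write_cnv_table(path, segments: list[CNVSegment]) -> None:
    pd.DataFrame(
        [(s.individual_id, s.chrom, s.start, s.end, s.copy_number)
         for s in segments],
        columns=CNV_COLUMNS).to_csv(path, sep="\t", index=False)
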