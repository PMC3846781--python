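"""HGVS c.-notation parsing and coding-consequence calls.

Given a transcript CDS and a coding substitution in HGVS notation
(``c.493C>T``, also tolerating the terser journal dialect ``c.493CT``),
compute the affected codon, translate reference and alternate codons
with the standard genetic code, and classify the effect as missense,
nonsense or synonymous.  For a nonsense change the truncated protein
length is the index of the last intact codon (stop codon index - 1).

Codon arithmetic: CDS position ``p`` (1-based) sits in codon
``ceil(p/3)`` at within-codon position ``((p-1) mod 3) + 1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio import SeqIO

_STOPS = set(standard_dna_table.stop_codons)


class HGVSParseError(ValueError):
    """Unparseable or unsupported (non-substitution) HGVS expression."""


class RefMismatchError(ValueError):
    """Transcript base at the stated CDS position differs from the
    variant's reference base."""


class TranscriptError(ValueError):
    """CDS fails structural validation."""


@dataclass(frozen=True)
class CodingTranscript:
    """A transcript identified by accession with its CDS sequence.

    Validation (override with ``validate=False`` via
    :func:`make_transcript`): length divisible by 3, starts ATG, ends
    with a stop codon, no internal in-frame stop.
    """

    id: str
    cds: str

    def __post_init__(self):
        object.__setattr__(self, "cds", self.cds.upper())

    def validate(self) -> None:
        cds = self.cds
        if len(cds) % 3 != 0:
            raise TranscriptError(f"{self.id}: CDS length {len(cds)} not a "
                                  "multiple of 3")
        if not cds.startswith("ATG"):
            raise TranscriptError(f"{self.id}: CDS does not start with ATG")
        if cds[-3:] not in _STOPS:
            raise TranscriptError(f"{self.id}: CDS does not end with a stop")
        for i in range(0, len(cds) - 3, 3):
            if cds[i:i + 3] in _STOPS:
                raise TranscriptError(
                    f"{self.id}: internal stop at codon {i // 3 + 1}")

    def codon(self, codon_index: int) -> str:
        return self.cds[3 * (codon_index - 1): 3 * codon_index]

    @property
    def protein_length(self) -> int:
        """Amino acids encoded, excluding the terminal stop."""
        return len(self.cds) // 3 - 1


def make_transcript(tx_id: str, cds: str, validate: bool = True
                    ) -> CodingTranscript:
    tx = CodingTranscript(id=tx_id, cds=cds)
    if validate:
        tx.validate()
    return tx


def read_transcript_fasta(path, validate: bool = True) -> CodingTranscript:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return make_transcript(rec.id, str(rec.seq), validate=validate)


def bundled_cds() -> CodingTranscript:
    """The package's synthetic CHIP-like CDS fixture.

    A constructed 303-codon CDS (not the real NM_005861 sequence) whose
    codons 130/147/165/207/236 are fixed to AAC/TGG/CTC/TAC/AGC, the
    codons consistent with the five published coding substitutions.
    """
    with resources.files("mendelseek.data").joinpath(
            "chip_like_cds_synthetic.fa").open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return make_transcript(rec.id, str(rec.seq))


# ---------------------------------------------------------------------

_HGVS_RE = re.compile(
    r"^c\.(?P<pos>\d+)\s*(?P<ref>[ACGT])\s*(?:>|γ)?\s*(?P<alt>[ACGT])$")
_UNSUPPORTED_RE = re.compile(r"del|ins|dup|inv", re.IGNORECASE)


@dataclass(frozen=True)
class HGVSc:
    cds_pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.cds_pos < 1:
            raise HGVSParseError(f"CDS position must be >=1: {self.cds_pos}")
        if self.ref_base == self.alt_base:
            raise HGVSParseError("ref and alt base identical")

    def __str__(self) -> str:
        return f"c.{self.cds_pos}{self.ref_base}>{self.alt_base}"


def parse_hgvs_c(text: str) -> HGVSc:
    """Parse a coding substitution, normalizing ``c.493CT``-style input.

    Deletions/insertions/duplications are rejected as unsupported.
    """
    s = text.strip()
    if _UNSUPPORTED_RE.search(s) or "_" in s:
        raise HGVSParseError(f"unsupported (non-substitution) variant: {text!r}")
    m = _HGVS_RE.match(s)
    if not m:
        raise HGVSParseError(f"cannot parse HGVS c. substitution: {text!r}")
    return HGVSc(cds_pos=int(m["pos"]), ref_base=m["ref"], alt_base=m["alt"])


def cds_to_codon(cds_pos: int) -> tuple[int, int]:
    """Map a 1-based CDS position to (codon_index, codon_position).

    Round-trips: ``3*(codon_index-1) + codon_position == cds_pos``.
    """
    if cds_pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {cds_pos}")
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3 + 1


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "*",
}


@dataclass(frozen=True)
class ConsequenceCall:
    variant: HGVSc
    codon_index: int
    codon_position: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str                      # missense | nonsense | synonymous
    truncated_length: int | None     # nonsense only: codon_index - 1

    @property
    def protein_notation(self) -> str:
        alt = "X" if self.alt_aa == "*" else self.alt_aa
        return f"p.{self.ref_aa}{self.codon_index}{alt}"


def call_consequence(tx: CodingTranscript, v: HGVSc) -> ConsequenceCall:
    """Apply the substitution to the CDS and classify its effect."""
    if v.cds_pos > len(tx.cds):
        raise RefMismatchError(
            f"{v}: position beyond CDS of length {len(tx.cds)}")
    found = tx.cds[v.cds_pos - 1]
    if found != v.ref_base:
        raise RefMismatchError(
            f"{v}: transcript {tx.id} has {found!r} at CDS position "
            f"{v.cds_pos}, expected {v.ref_base!r}")
    codon_index, codon_position = cds_to_codon(v.cds_pos)
    ref_codon = tx.codon(codon_index)
    alt_codon = (ref_codon[:codon_position - 1] + v.alt_base
                 + ref_codon[codon_position:])
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        effect, trunc = "nonsense", codon_index - 1
    elif alt_aa == ref_aa:
        effect, trunc = "synonymous", None
    else:
        effect, trunc = "missense", None
    return ConsequenceCall(
        variant=v, codon_index=codon_index, codon_position=codon_position,
        ref_codon=ref_codon, alt_codon=alt_codon, ref_aa=ref_aa,
        alt_aa=alt_aa, effect=effect, truncated_length=trunc)


def annotate_variants(tx: CodingTranscript, hgvs_list: list[str]
                      ) -> list[ConsequenceCall]:
    """Call consequences for a list of HGVS c. strings on one CDS."""
    return [call_consequence(tx, parse_hgvs_c(h)) for h in hgvs_list]


#: the five coding substitutions reported across the three study families
FAMILY_VARIANTS = {
    "family1": ["c.493C>T"],
    "family2": ["c.389A>T", "c.441G>T"],
    "family3": ["c.621C>G", "c.707G>C"],
}


def annotate_family_variants(tx: CodingTranscript | None = None
                             ) -> list[ConsequenceCall]:
    """The five family mutation calls on the bundled (or a supplied) CDS."""
    if tx is None:
        tx = bundled_cds()
    hgvs = [h for fam in sorted(FAMILY_VARIANTS) for h in FAMILY_VARIANTS[fam]]
    return annotate_variants(tx, hgvs)
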