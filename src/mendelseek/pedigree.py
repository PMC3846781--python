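"""Pedigree data model, PED/FAM I/O and segregation checks.

A pedigree is a set of individuals with parent links, sex and affection
status.  Founders have no parents inside the pedigree; everyone else has
both.  Genotypes live alongside the structure as per-site collections of
:class:`GenotypeCall` so the same pedigree can carry disease-locus calls,
marker panels and candidate-variant genotypes.

The module implements the two checks a segregation claim rests on:
Mendelian consistency of a biallelic site, and phenotype co-segregation
under a recessive model (single homozygous variant, or a compound
heterozygous pair).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class PedigreeError(ValueError):
    """Structural problem in a pedigree (missing parent, cycle, loop)."""


class PedParseError(ValueError):
    """Malformed PED/FAM input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UnsupportedSiteError(ValueError):
    """Site is not biallelic / not usable by the requested check."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Genotype(enum.IntEnum):
    """Biallelic genotype code; ``MISSING`` never triggers violations."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2

    @property
    def n_alt(self) -> int:
        if self is Genotype.MISSING:
            raise ValueError("missing genotype has no allele count")
        return int(self)


#: allele-count pairs (n_alt of transmitted gametes) possible per genotype
_GAMETES = {
    Genotype.HOM_REF: (0,),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1,),
}


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id}: either both parents or neither "
                "must be present"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class Pedigree:
    """Validated family structure.

    Members are kept in input order; parents must precede no one in
    particular (order-independent validation), but parentage must be
    acyclic, every referenced parent must exist and at least one member
    must be a founder.  Inbreeding loops (a member with both parents
    sharing an ancestor) are rejected: the exact likelihood engines
    assume loop-free pedigrees.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self):
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError(f"duplicate individual ids in {self.family_id}")
        self._by_id = {m.id: m for m in self.members}
        for m in self.members:
            for pid, role in ((m.father_id, "father"), (m.mother_id, "mother")):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"individual {m.id}: {role} {pid!r} not in pedigree"
                    )
            if m.father_id is not None:
                f, mo = self._by_id[m.father_id], self._by_id[m.mother_id]
                if f.sex is Sex.FEMALE or mo.sex is Sex.MALE:
                    raise PedigreeError(
                        f"individual {m.id}: parental sexes inconsistent"
                    )
        if not any(m.is_founder for m in self.members):
            raise PedigreeError(f"{self.family_id}: no founder")
        self._check_acyclic()
        self._check_no_loops()

    # -- structure ----------------------------------------------------
    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise PedigreeError(f"parentage cycle through {iid}")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            m = self._by_id[iid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 2

        for m in self.members:
            visit(m.id)

    def _ancestors(self, iid: str) -> set[str]:
        out: set[str] = set()
        stack = [iid]
        while stack:
            m = self._by_id[stack.pop()]
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out

    def _check_no_loops(self) -> None:
        for m in self.members:
            if m.is_founder:
                continue
            shared = self._ancestors(m.father_id) & self._ancestors(m.mother_id)
            if shared:
                raise PedigreeError(
                    f"inbreeding loop at {m.id}: parents share ancestor(s) "
                    f"{sorted(shared)}; loops are unsupported"
                )

    # -- convenience --------------------------------------------------
    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    @property
    def n_meioses(self) -> int:
        """Two meioses per non-founder (one per parent)."""
        return 2 * len(self.nonfounders)

    def topological_order(self) -> list[Individual]:
        """Members ordered founders-first, parents before children."""
        done: set[str] = set()
        out: list[Individual] = []
        pending = list(self.members)
        while pending:
            rest = []
            for m in pending:
                if m.is_founder or (m.father_id in done and m.mother_id in done):
                    out.append(m)
                    done.add(m.id)
                else:
                    rest.append(m)
            pending = rest
        return out


# ---------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------

_SEX_CODE = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_AFF_CODE = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED,
             "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}


def read_ped(path) -> tuple[Pedigree, list[dict[str, tuple[str, str]]]]:
    """Read a linkage-format PED/FAM file.

    Standard 6-column dialect (family, id, father, mother, sex,
    affection) with ``0`` for missing parents/alleles and optional
    genotype columns in pairs, one pair per marker.

    Returns the validated :class:`Pedigree` and a list of per-marker
    genotype dicts ``{individual_id: (allele, allele)}``; missing
    genotypes (``0 0``) are omitted from the dicts.  A file holding more
    than one family raises :class:`PedParseError` (split upstream).
    """
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedParseError(
                    f"expected >=6 whitespace-delimited columns, got "
                    f"{len(fields)}", ln)
            if len(fields) % 2 != 0:
                raise PedParseError(
                    "genotype columns must come in pairs", ln)
            rows.append((ln, fields))
    if not rows:
        raise PedParseError("empty PED file")

    n_markers = (len(rows[0][1]) - 6) // 2
    members: list[Individual] = []
    genotypes: list[dict[str, tuple[str, str]]] = [dict() for _ in range(n_markers)]
    fam_ids = set()
    for ln, f in rows:
        if (len(f) - 6) // 2 != n_markers:
            raise PedParseError(
                f"inconsistent marker count ({(len(f) - 6) // 2} vs "
                f"{n_markers})", ln)
        fam, iid, fid, mid = f[0], f[1], f[2], f[3]
        fam_ids.add(fam)
        if f[4] not in _SEX_CODE:
            raise PedParseError(f"bad sex code {f[4]!r}", ln)
        if f[5] not in _AFF_CODE:
            raise PedParseError(f"bad affection code {f[5]!r}", ln)
        members.append(Individual(
            id=iid, family_id=fam,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_SEX_CODE[f[4]], affection=_AFF_CODE[f[5]],
        ))
        for k in range(n_markers):
            a, b = f[6 + 2 * k], f[7 + 2 * k]
            if a != "0" and b != "0":
                genotypes[k][iid] = (a, b)
    if len(fam_ids) > 1:
        raise PedParseError(
            f"multiple families in one file: {sorted(fam_ids)}")
    return Pedigree(family_id=fam_ids.pop(), members=members), genotypes


def write_ped(path, pedigree: Pedigree,
              genotypes: Sequence[Mapping[str, tuple[str, str]]] = ()) -> None:
    """Inverse of :func:`read_ped` (missing genotypes written as ``0 0``)."""
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1",
               Affection.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for m in pedigree.members:
            row = [m.family_id, m.id, m.father_id or "0", m.mother_id or "0",
                   sex_out[m.sex], aff_out[m.affection]]
            for g in genotypes:
                row.extend(g.get(m.id, ("0", "0")))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------
# Checks
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class MendelianViolation:
    individual_id: str
    child_genotype: Genotype
    father_genotype: Genotype
    mother_genotype: Genotype


def mendelian_check(
    pedigree: Pedigree,
    site_genotypes: Mapping[str, Genotype],
) -> list[MendelianViolation]:
    """List children whose biallelic genotype is impossible given parents.

    A violation requires all three genotypes to be non-missing; missing
    genotypes never violate.  An empty list means the site is consistent
    with Mendelian transmission.
    """
    out = []
    for m in pedigree.nonfounders:
        gc = site_genotypes.get(m.id, Genotype.MISSING)
        gf = site_genotypes.get(m.father_id, Genotype.MISSING)
        gm = site_genotypes.get(m.mother_id, Genotype.MISSING)
        if Genotype.MISSING in (gc, gf, gm):
            continue
        possible = {a + b for a in _GAMETES[gf] for b in _GAMETES[gm]}
        if gc.n_alt not in possible:
            out.append(MendelianViolation(m.id, gc, gf, gm))
    return out


def cosegregation_check(
    pedigree: Pedigree,
    site_genotypes: Mapping[str, Genotype],
    second_site: Mapping[str, Genotype] | None = None,
    model: str = "recessive",
) -> bool:
    """Does the variant (or compound-het pair) track the phenotype?

    Single site, recessive: True iff every affected member is hom-alt
    and no unaffected or unknown-status member is hom-alt.  With
    ``second_site`` given, the compound-heterozygous form: every
    affected member het at both sites, and no unaffected member het at
    both.  Missing genotypes are ignored (they neither confirm nor
    refute), so adding a missing genotype can never flip True to False.
    """
    if model != "recessive":
        raise UnsupportedSiteError(f"model {model!r} not supported")

    def geno(gt_map, iid):
        g = gt_map.get(iid, Genotype.MISSING)
        if not isinstance(g, Genotype):
            raise UnsupportedSiteError(
                f"non-biallelic genotype for {iid}: {g!r}")
        return g

    for m in pedigree.members:
        if second_site is None:
            g = geno(site_genotypes, m.id)
            if g is Genotype.MISSING:
                continue
            if m.affection is Affection.AFFECTED:
                if g is not Genotype.HOM_ALT:
                    return False
            elif g is Genotype.HOM_ALT:
                # unaffected or unknown status carrying two copies
                return False
        else:
            g1 = geno(site_genotypes, m.id)
            g2 = geno(second_site, m.id)
            if m.affection is Affection.AFFECTED:
                if Genotype.MISSING in (g1, g2):
                    continue
                if not (g1 is Genotype.HET and g2 is Genotype.HET):
                    return False
            elif m.affection is Affection.UNAFFECTED:
                if g1 is Genotype.HET and g2 is Genotype.HET:
                    return False
    return True
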