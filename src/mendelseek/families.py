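"""Printed-family fixtures: the three ataxia kindreds' pedigrees and
Sanger genotype patterns at their candidate-gene variants.

Family 1 is the discovery family: two founders, five offspring of whom
four are affected; every affected member is homozygous for the
c.493C>T missense variant while both parents and the unaffected
sibling are heterozygous.  Families 2 and 3 each segregate a compound
heterozygous pair (c.389A>T/c.441G>T and c.621C>G/c.707G>C).  Parental
genotypes in families 2 and 3 were not tabulated in the source
figures; each parent is encoded as a carrier of exactly one of the two
variants — the only configuration under which a fully penetrant
recessive compound-het model co-segregates — and this assumption is
what the fixtures document.

Genotypes are keyed by the HGVS c. string of the variant.
"""

from __future__ import annotations

from .pedigree import Affection, Genotype, Individual, Pedigree, Sex

HOM, HET = Genotype.HOM_ALT, Genotype.HET
REF = Genotype.HOM_REF


def family1() -> tuple[Pedigree, dict[str, dict[str, Genotype]]]:
    members = [
        Individual("I1", "FAM1", None, None, Sex.MALE, Affection.UNAFFECTED),
        Individual("I2", "FAM1", None, None, Sex.FEMALE,
                   Affection.UNAFFECTED),
        Individual("II1", "FAM1", "I1", "I2", Sex.MALE, Affection.AFFECTED),
        Individual("II2", "FAM1", "I1", "I2", Sex.FEMALE,
                   Affection.AFFECTED),
        Individual("II3", "FAM1", "I1", "I2", Sex.MALE, Affection.AFFECTED),
        Individual("II4", "FAM1", "I1", "I2", Sex.FEMALE,
                   Affection.UNAFFECTED),
        Individual("II5", "FAM1", "I1", "I2", Sex.MALE, Affection.AFFECTED),
    ]
    genotypes = {
        "c.493C>T": {"I1": HET, "I2": HET, "II1": HOM, "II2": HOM,
                     "II3": HOM, "II4": HET, "II5": HOM},
    }
    return Pedigree("FAM1", members), genotypes


def _compound_het_family(fam: str, var_pat: str, var_mat: str
                         ) -> tuple[Pedigree, dict[str, dict[str, Genotype]]]:
    members = [
        Individual("I1", fam, None, None, Sex.MALE, Affection.UNAFFECTED),
        Individual("I2", fam, None, None, Sex.FEMALE, Affection.UNAFFECTED),
        Individual("II1", fam, "I1", "I2", Sex.FEMALE, Affection.AFFECTED),
    ]
    genotypes = {
        var_pat: {"I1": HET, "I2": REF, "II1": HET},
        var_mat: {"I1": REF, "I2": HET, "II1": HET},
    }
    return Pedigree(fam, members), genotypes


def family2():
    """Compound heterozygous c.389A>T (paternal) / c.441G>T (maternal)."""
    return _compound_het_family("FAM2", "c.389A>T", "c.441G>T")


def family3():
    """Compound heterozygous c.621C>G (paternal) / c.707G>C (maternal)."""
    return _compound_het_family("FAM3", "c.621C>G", "c.707G>C")
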