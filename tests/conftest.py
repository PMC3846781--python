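import numpy as np
import pandas as pd
import pytest

from mendelseek.families import family1
from mendelseek.pedigree import Genotype
from mendelseek.variants import VariantTable


@pytest.fixture
def fam1():
    """Discovery family: 7 members, 4 affected, candidate-site genotypes."""
    return family1()


@pytest.fixture
def fam1_ped(fam1):
    return fam1[0]


def make_table(rows, genotypes, samples):
    """Build a VariantTable from plain dicts/lists (tests' constructor).

    ``rows``: list of dicts with at least chrom/pos/ref/alt; QC metrics
    default to passing values.  ``genotypes``: list of per-sample
    genotype code lists.
    """
    defaults = {"gene": "", "vclass": "NS", "consensus_quality": 60.0,
                "depth": 50, "copy_number_estimate": 1.0,
                "dist_to_nearest_snp": 10_000}
    full = [{**defaults, **r} for r in rows]
    records = pd.DataFrame(full) if full else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", *defaults])
    g = (np.array(genotypes, dtype=np.int8) if len(genotypes)
         else np.empty((0, len(samples)), dtype=np.int8))
    return VariantTable(samples=list(samples), records=records, genotypes=g)


@pytest.fixture
def toy_table():
    rows = [
        {"chrom": "1", "pos": 100, "ref": "A", "alt": "G", "gene": "G1"},
        {"chrom": "1", "pos": 200, "ref": "C", "alt": "T", "gene": "G1"},
        {"chrom": "2", "pos": 100, "ref": "G", "alt": "A", "gene": "G2"},
    ]
    g = [[2, 2], [1, 1], [0, 1]]
    return make_table(rows, g, ["S1", "S2"])
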