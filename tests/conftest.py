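import numpy as np
import pandas as pd
import pytest

from gendiv.genotype_qc import GenotypePanel
from gendiv.pedigree import Pedigree, PedigreeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_panel(calls, positions=None, chroms=None, sample_ids=None):
    """Build a GenotypePanel from a dosage array (missing = -1)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 100_000
    if chroms is None:
        chroms = np.ones(n_snps, dtype=int)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(n_snps)],
            "chrom": np.asarray(chroms, dtype=int),
            "bp": np.asarray(positions, dtype=np.int64),
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypePanel(sample_ids=list(sample_ids), snps=snps, calls=calls)


def pedigree_from_parents(parents, sexes=None, years=None):
    """Pedigree from a {child: (sire, dam)} dict with int or str ids."""
    records = []
    for animal, (sire, dam) in parents.items():
        records.append(
            PedigreeRecord(
                str(animal),
                None if sire is None else str(sire),
                None if dam is None else str(dam),
                sex=(sexes or {}).get(animal, "U"),
                birth_year=(years or {}).get(animal),
            )
        )
    return Pedigree(records)


@pytest.fixture
def fullsib_pedigree():
    # X is the offspring of full sibs; Y of paternal half sibs
    return pedigree_from_parents(
        {
            "S": (None, None),
            "D1": (None, None),
            "D2": (None, None),
            "B": ("S", "D1"),
            "C": ("S", "D1"),
            "C2": ("S", "D2"),
            "X": ("B", "C"),
            "Y": ("B", "C2"),
        }
    )
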