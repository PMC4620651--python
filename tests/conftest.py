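import numpy as np
import pandas as pd
import pytest

from adnapop.io import DiagnosticPanel, GenotypeTable, ReadObservationSet

PANEL_COLUMNS = [
    "chrom", "pos", "endogenous_allele", "contaminant_alleles", "mutation_class",
]


def make_panel(rows):
    return DiagnosticPanel(pd.DataFrame(rows, columns=PANEL_COLUMNS))


def make_reads(observations, lengths=None, mismatches=None):
    obs = pd.DataFrame(observations, columns=["read_id", "locus_id", "allele"])
    ln = (
        pd.DataFrame(lengths, columns=["read_id", "length_bp"])
        if lengths is not None
        else None
    )
    mm = (
        pd.DataFrame(
            mismatches,
            columns=["read_id", "end", "position", "ref_base", "read_base"],
        )
        if mismatches is not None
        else None
    )
    return ReadObservationSet(obs, ln, mm)


def make_genotypes(dosages, ploidy=None, sample_ids=None, chrom="1"):
    """GenotypeTable from an (n_loci, n_samples) array; loci 100 bp apart."""
    dosages = np.asarray(dosages, dtype=float)
    n_loci, n_samples = dosages.shape
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_samples)]
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_loci + 1) * 100,
            "ref_allele": "A",
            "alt_allele": "G",
        }
    )
    return GenotypeTable(list(sample_ids), loci, dosages, ploidy)


@pytest.fixture
def mito_panel():
    """15 diagnostic loci, one transversion — the classic mtDNA setup."""
    rows = [("MT", 1000 + 500 * i, "A", ["G"], "transition") for i in range(14)]
    rows.append(("MT", 14129, "C", ["A"], "transversion"))
    return make_panel(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
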