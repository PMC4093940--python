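import numpy as np
import pandas as pd
import pytest

from mirsnp.core_io import (
    GenotypeMatrix,
    PhenotypeTable,
    SequenceRecord,
    VariantRecord,
)

# GC-rich seed so canonical sites clear the default scorer cutoffs
STRONG_MIRNA = "AGCUGGCCAUGCUAGCUAGCU"
# AU-rich seed: a 6mer site carries weak stacks and fails the energy cutoff
WEAK_MIRNA = "AUUAUAAAGCUAGCUAGCUA"


@pytest.fixture
def strong_mirna() -> SequenceRecord:
    return SequenceRecord(name="mir-strong", kind="mirna", sequence=STRONG_MIRNA)


@pytest.fixture
def weak_mirna() -> SequenceRecord:
    return SequenceRecord(name="mir-weak", kind="mirna", sequence=WEAK_MIRNA)


def make_utr(seq: str, name: str = "TX1", chrom: str = "12", strand: str = "+",
             start: int = 1000, gene: str = "GENE1") -> SequenceRecord:
    return SequenceRecord(
        name=name, kind="utr", sequence=seq, transcript_id=name,
        gene_symbol=gene, chrom=chrom, strand=strand, genomic_start=start,
    )


def make_matrix(dosages, chrom: str = "1", positions=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    variants = [
        VariantRecord(chrom=chrom, pos=positions[j], id=f"v{j}",
                      ref_allele="A", alt_allele="G")
        for j in range(m)
    ]
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)], variants=variants, dosages=dosages
    )


def make_pheno(values, sample_ids=None, trait: str = "trait",
               covariates: dict | None = None) -> PhenotypeTable:
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(len(values))]
    data = pd.DataFrame({trait: values}, index=pd.Index(sample_ids, name="sample_id"))
    for name, col in (covariates or {}).items():
        data[name] = np.asarray(col, dtype=float)
    return PhenotypeTable(
        data=data,
        trait_names=[trait],
        covariate_names=list(covariates or {}),
    )
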