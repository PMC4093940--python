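"""Domain types, file I/O and configuration.

All genomic coordinates are 1-based (VCF convention).  UTR-internal offsets
are 1-based inclusive on the mRNA sense strand.  UTR sequences are stored as
sense-strand mRNA written in DNA alphabet regardless of genomic strand; the
genomic anchor (chrom, strand, start) allows projecting UTR offsets back to
genomic positions.

Missing dosages are kept missing (NaN) at read time and mean-imputed per
variant only at regression time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger("mirsnp")

SNP_ALPHABET = frozenset("ACGT")
MIRNA_ALPHABET = frozenset("ACGU")
MIRNA_MIN_LEN = 18
MIRNA_MAX_LEN = 24


class DataError(ValueError):
    """Raised on malformed or internally inconsistent input data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: chromosome, 1-based position, id and alleles."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise DataError(f"{self.id}: ref and alt alleles are identical")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in SNP_ALPHABET:
                raise DataError(
                    f"{self.id}: allele {allele!r} is not a single A/C/G/T base "
                    "(only biallelic SNPs are supported)"
                )


@dataclass
class GenotypeMatrix:
    """Samples x variants allele-dosage matrix.

    ``dosages[i, j]`` is the expected alternative-allele count of sample *i*
    at variant *j*, in [0, 2]; missing entries are NaN.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise DataError(
                f"dosage matrix shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise DataError("dosages must lie in [0, 2] or be NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(variant_id)

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]


@dataclass
class PhenotypeTable:
    """Per-sample trait values and covariates, indexed by sample id."""

    data: pd.DataFrame
    trait_names: list[str]
    covariate_names: list[str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dups[:5]}")
        for trait in self.trait_names:
            if trait not in self.data.columns:
                raise DataError(f"trait column {trait!r} missing")
            if self.data[trait].notna().sum() < 1:
                raise DataError(f"trait column {trait!r} has no non-missing value")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class SequenceRecord:
    """A mature miRNA (RNA alphabet, 5'->3') or a 3'UTR (DNA alphabet,
    mRNA-sense, 5'->3') with its genomic anchor."""

    name: str
    kind: str  # "mirna" | "utr"
    sequence: str
    transcript_id: str | None = None
    gene_symbol: str | None = None
    chrom: str | None = None
    strand: str | None = None
    genomic_start: int | None = None  # 1-based genomic start of the UTR span

    def __post_init__(self) -> None:
        if self.kind not in ("mirna", "utr"):
            raise DataError(f"{self.name}: unknown sequence kind {self.kind!r}")
        if not self.sequence:
            raise DataError(f"{self.name}: empty sequence")
        alphabet = MIRNA_ALPHABET if self.kind == "mirna" else SNP_ALPHABET
        extra = set(self.sequence) - alphabet
        if extra:
            raise DataError(
                f"{self.name}: characters {sorted(extra)} outside the "
                f"{self.kind} alphabet"
            )
        if self.kind == "mirna" and not (
            MIRNA_MIN_LEN <= len(self.sequence) <= MIRNA_MAX_LEN
        ):
            raise DataError(
                f"{self.name}: miRNA length {len(self.sequence)} outside "
                f"[{MIRNA_MIN_LEN}, {MIRNA_MAX_LEN}]"
            )
        if self.kind == "utr" and self.strand is not None and self.strand not in "+-":
            raise DataError(f"{self.name}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive genomic interval assigned to a gene symbol."""

    gene_symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"{self.gene_symbol}: start {self.start} > end {self.end}"
            )


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

DEFAULT_DOSAGE_PREFERENCE = ("DS", "GP", "GT")


def read_genotypes(
    path: str | Path,
    dosage_field_preference: Sequence[str] = DEFAULT_DOSAGE_PREFERENCE,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Per record, the dosage is taken from the first available FORMAT field in
    ``dosage_field_preference``: ``DS`` (dosage literal), ``GP`` (genotype
    probability triple, as ``0*P(0/0) + 1*P(0/1) + 2*P(1/1)``) or ``GT``
    (hard-call alternative-allele count).  Multiallelic and non-SNP records
    are skipped with a logged warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise DataError(f"{path}: VCF contains no samples")

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            logger.warning(
                "skipping non-biallelic-SNP record %s at %s:%d",
                rec.ID or ".", rec.CHROM, rec.POS,
            )
            continue
        variants.append(
            VariantRecord(
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
            )
        )
        rows.append(_record_dosages(rec, len(sample_ids), dosage_field_preference))
    vcf.close()

    dosages = (
        np.vstack(rows).T if rows else np.empty((len(sample_ids), 0), dtype=float)
    )
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def _record_dosages(
    rec, n_samples: int, preference: Sequence[str]
) -> np.ndarray:
    for field_name in preference:
        if field_name == "GT":
            out = np.full(n_samples, np.nan)
            for i, gt in enumerate(rec.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                if len(alleles) == 2:
                    out[i] = float(sum(alleles))
            return out
        try:
            values = rec.format(field_name)
        except KeyError:
            values = None
        if values is None:
            continue
        values = np.asarray(values, dtype=float)
        if field_name == "GP":
            dosage = values[:, 1] + 2.0 * values[:, 2]
        else:
            dosage = values.reshape(n_samples, -1)[:, 0]
        dosage = np.where(np.isfinite(dosage), dosage, np.nan)
        return dosage
    return np.full(n_samples, np.nan)


def write_genotypes(
    gm: GenotypeMatrix, path: str | Path, hard_calls: bool = True
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2.

    Integer dosages are written as GT hard calls; fractional dosages (or
    ``hard_calls=False``) use a DS FORMAT field with GT set from the rounded
    dosage.
    """
    path = Path(path)
    with np.errstate(invalid="ignore"):
        fractional = np.nanmax(np.abs(gm.dosages - np.round(gm.dosages))) > 1e-9 \
            if gm.dosages.size else False
    use_ds = fractional or not hard_calls
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if use_ds:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,'
                'Description="Alt allele dosage">\n'
            )
        for chrom in sorted({v.chrom for v in gm.variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        order = np.lexsort(
            ([v.pos for v in gm.variants], [v.chrom for v in gm.variants])
        )
        for j in order:
            v = gm.variants[j]
            cells = []
            for d in gm.dosages[:, j]:
                if np.isnan(d):
                    cells.append("./." + (":." if use_ds else ""))
                    continue
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(round(np.clip(d, 0, 2)))]
                cells.append(f"{gt}:{d:.4f}" if use_ds else gt)
            fmt = "GT:DS" if use_ds else "GT"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------
#
# FASTA header dialect:
#   miRNA: >name
#   UTR:   >name|transcript_id|gene_symbol|chrom|strand|genomic_start


def read_sequences(path: str | Path, kind: str) -> list[SequenceRecord]:
    """Read a FASTA file as miRNAs or UTRs (see header dialect above).

    Sequences are upper-cased; for miRNAs, T is transliterated to U.
    Records are returned in file order.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        seq = str(bio.seq).upper()
        if kind == "mirna":
            seq = seq.replace("T", "U")
            records.append(SequenceRecord(name=bio.id, kind="mirna", sequence=seq))
        else:
            parts = bio.id.split("|")
            if len(parts) != 6:
                raise DataError(
                    f"{path}: UTR header {bio.id!r} must have 6 |-separated "
                    "fields: name|transcript|gene|chrom|strand|start"
                )
            name, transcript, gene, chrom, strand, start = parts
            records.append(
                SequenceRecord(
                    name=name,
                    kind="utr",
                    sequence=seq,
                    transcript_id=transcript,
                    gene_symbol=gene,
                    chrom=chrom,
                    strand=strand,
                    genomic_start=int(start),
                )
            )
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bios = []
    for rec in records:
        if rec.kind == "utr":
            header = "|".join(
                [
                    rec.name,
                    rec.transcript_id or ".",
                    rec.gene_symbol or ".",
                    rec.chrom or ".",
                    rec.strand or ".",
                    str(rec.genomic_start or 0),
                ]
            )
        else:
            header = rec.name
        bios.append(BioSeqRecord(Seq(rec.sequence), id=header, description=""))
    SeqIO.write(bios, str(path), "fasta")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "trait", "n", "beta", "se", "p"]


def write_assoc_table(rows: Iterable, path: str | Path) -> None:
    """Write association rows as TSV; P in scientific notation, 6 sig digits."""
    rows = list(rows)
    if not rows:
        logger.warning("write_assoc_table: no rows, writing header only")
    with open(path, "w") as fh:
        fh.write("\t".join(ASSOC_COLUMNS) + "\n")
        for r in rows:
            v = r.variant
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.id,
                        v.ref_allele,
                        v.alt_allele,
                        r.trait,
                        str(r.n),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.p),
                    ]
                )
                + "\n"
            )


def _fmt(x: float) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6e}"


def read_assoc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    missing = set(ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_phenotypes(
    path: str | Path,
    trait_names: Sequence[str],
    covariate_names: Sequence[str] = ("age", "sex", "education"),
) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: phenotype table needs a 'sample_id' column")
    df = df.set_index("sample_id")
    return PhenotypeTable(
        data=df,
        trait_names=list(trait_names),
        covariate_names=list(covariate_names),
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open; .bed suffix) or TSV
    with columns gene_symbol, chrom, start, end (1-based inclusive)."""
    path = Path(path)
    out: list[GeneInterval] = []
    if path.suffix.lower() == ".bed":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            out.append(
                GeneInterval(
                    gene_symbol=name, chrom=chrom, start=int(start) + 1, end=int(end)
                )
            )
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for rec in df.itertuples():
            out.append(
                GeneInterval(
                    gene_symbol=str(rec.gene_symbol),
                    chrom=str(rec.chrom),
                    start=int(rec.start),
                    end=int(rec.end),
                )
            )
    if not out:
        raise DataError(f"{path}: no gene intervals")
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """All pipeline thresholds, overridable from YAML."""

    # association
    p_genomewide: float = 5e-8
    p_suggestive: float = 1e-6
    n_pcs: int = 3
    clump_window_bp: int = 1_000_000
    # LD proxies
    r2_min: float = 0.8
    proxy_window_bp: int = 1_000_000
    # target-site consensus
    k_min: int = 3
    align_min: float = 55.0
    energy_max: float = -8.0
    # enrichment
    enrich_p_assoc: float = 1e-4
    enrich_margin_bp: int = 10_000
    n_permutations: int = 100_000
    # misc
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))
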