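"""Synthetic inputs with the statistical structure each pipeline stage
assumes, plus ground-truth tables for parameter-recovery tests.

Every generator is a pure function of its parameters and seed.  LD is
modeled as a founder-copying block mosaic: within a block each haplotype
copies one of a few founder haplotypes (plus per-site mutation), and the
founder choice re-randomizes between blocks, giving high within-block and
low between-block r-squared.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DataError,
    GenotypeMatrix,
    PhenotypeTable,
    SequenceRecord,
    VariantRecord,
)
from .mirtarget import SITE_CLASSES, _m8_complement, seed_match_6, find_seed_sites
from .reporter import ReporterDataset

_BASES = "ACGT"


@dataclass
class HaplotypePanel:
    """2N phased haplotypes x M variants, 0/1 coded."""

    haplotypes: np.ndarray
    variants: list[VariantRecord]
    block_boundaries: list[int]  # start index of each block

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise DataError("haplotype entries must be 0/1")
        freqs = self.haplotypes.mean(axis=0)
        if ((freqs == 0) | (freqs == 1)).any():
            raise DataError("panel contains a monomorphic variant")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class TruthTable:
    """Planted parameters for parameter-recovery tests."""

    causal_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float | None = None
    sites: list[dict] = field(default_factory=list)
    site_snps: list[dict] = field(default_factory=list)
    eqtl: dict = field(default_factory=dict)
    reporter: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        return cls(**json.loads(Path(path).read_text()))

    def merge(self, other: "TruthTable") -> "TruthTable":
        return TruthTable(
            causal_effects={**self.causal_effects, **other.causal_effects},
            covariate_effects={**self.covariate_effects, **other.covariate_effects},
            noise_sd=other.noise_sd if other.noise_sd is not None else self.noise_sd,
            sites=self.sites + other.sites,
            site_snps=self.site_snps + other.site_snps,
            eqtl={**self.eqtl, **other.eqtl},
            reporter={**self.reporter, **other.reporter},
        )


def _random_variants(
    rng: np.random.Generator,
    n_var: int,
    chrom: str,
    positions: Sequence[int] | None,
    spacing: int,
    id_prefix: str,
) -> list[VariantRecord]:
    if positions is None:
        positions = [1 + j * spacing for j in range(n_var)]
    if len(positions) != n_var:
        raise DataError("positions length must equal n_var")
    out = []
    for j, pos in enumerate(positions):
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        out.append(
            VariantRecord(
                chrom=chrom, pos=int(pos), id=f"{id_prefix}{j:04d}",
                ref_allele=str(ref), alt_allele=str(alt),
            )
        )
    return out


def gen_panel(
    n_hap: int,
    n_var: int,
    block_len: int,
    n_founders_per_block: int,
    mutation_rate: float,
    seed: int,
    chrom: str = "1",
    positions: Sequence[int] | None = None,
    spacing: int = 1000,
    max_retries: int = 100,
) -> HaplotypePanel:
    """Founder-copying block-mosaic haplotype panel.

    Within each block of ``block_len`` variants every haplotype copies one
    of ``n_founders_per_block`` random founder haplotypes, with per-site
    mutation at ``mutation_rate``; blocks with a monomorphic variant are
    resampled (bounded retries).
    """
    if n_hap % 2:
        raise DataError("n_hap must be even")
    if n_founders_per_block < 2:
        raise DataError("n_founders_per_block must be >= 2")
    rng = np.random.default_rng(seed)
    variants = _random_variants(rng, n_var, chrom, positions, spacing, "v")
    haps = np.zeros((n_hap, n_var), dtype=np.int8)
    boundaries = list(range(0, n_var, block_len))
    for s in boundaries:
        e = min(s + block_len, n_var)
        width = e - s
        for attempt in range(max_retries):
            founders = rng.integers(0, 2, size=(n_founders_per_block, width))
            # every variant must distinguish at least two founders; resample
            # constant founder columns individually
            for _ in range(max_retries):
                const = founders.min(axis=0) == founders.max(axis=0)
                if not const.any():
                    break
                founders[:, const] = rng.integers(
                    0, 2, size=(n_founders_per_block, int(const.sum()))
                )
            assign = rng.integers(0, n_founders_per_block, size=n_hap)
            block = founders[assign].astype(np.int8)
            if mutation_rate > 0:
                block ^= (rng.random(block.shape) < mutation_rate).astype(np.int8)
            freqs = block.mean(axis=0)
            if ((freqs > 0) & (freqs < 1)).all():
                haps[:, s:e] = block
                break
        else:
            raise DataError(
                f"could not generate a polymorphic block after {max_retries} tries"
            )
    return HaplotypePanel(haplotypes=haps, variants=variants, block_boundaries=boundaries)


def gen_cohort(panel: HaplotypePanel, n_ind: int, seed: int) -> GenotypeMatrix:
    """Diploid cohort: each individual sums two panel haplotypes drawn with
    replacement."""
    if n_ind < 1:
        raise DataError("n_ind must be >= 1")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, panel.n_haplotypes, size=(n_ind, 2))
    dosages = (
        panel.haplotypes[picks[:, 0]] + panel.haplotypes[picks[:, 1]]
    ).astype(float)
    sample_ids = [f"S{i:05d}" for i in range(n_ind)]
    return GenotypeMatrix(
        sample_ids=sample_ids, variants=list(panel.variants), dosages=dosages
    )


def gen_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """age ~ U(60, 80); sex ~ Bernoulli(0.5); education ~ N(13, 3) truncated
    to [8, 20]."""
    age = rng.uniform(60, 80, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    edu = rng.normal(13, 3, size=n)
    while True:
        bad = (edu < 8) | (edu > 20)
        if not bad.any():
            break
        edu[bad] = rng.normal(13, 3, size=int(bad.sum()))
    return pd.DataFrame({"age": age, "sex": sex, "education": edu})


def gen_phenotype(
    G: GenotypeMatrix,
    effects: Mapping[str, float],
    covar_effects: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    trait_name: str = "trait",
) -> tuple[PhenotypeTable, TruthTable]:
    """Quantitative trait with planted additive SNP effects, covariate
    effects and Gaussian noise."""
    if noise_sd < 0:
        raise DataError("noise_sd must be >= 0")
    covar_effects = dict(covar_effects or {})
    rng = np.random.default_rng(seed)
    n = G.n_samples
    covs = gen_covariates(rng, n)
    y = np.zeros(n)
    for variant_id, beta in effects.items():
        d = G.dosage_vector(variant_id)  # KeyError if absent, per contract
        y = y + beta * np.nan_to_num(d, nan=np.nanmean(d) if np.isnan(d).any() else 0.0)
    for cov, c in covar_effects.items():
        y = y + c * covs[cov].to_numpy()
    y = y + rng.normal(0, noise_sd, size=n)
    data = covs.copy()
    data[trait_name] = y
    data.index = pd.Index(G.sample_ids, name="sample_id")
    pheno = PhenotypeTable(
        data=data,
        trait_names=[trait_name],
        covariate_names=["age", "sex", "education"],
    )
    truth = TruthTable(
        causal_effects=dict(effects),
        covariate_effects=covar_effects,
        noise_sd=noise_sd,
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# targetome
# ---------------------------------------------------------------------------


def _has_any_core(seq: str, cores: Sequence[str]) -> bool:
    return any(core in seq for core in cores)


def _build_site(rng: np.random.Generator, mirna_seq: str, site_class: str) -> str:
    core = seed_match_6(mirna_seq)
    m8 = _m8_complement(mirna_seq)
    not_m8 = [b for b in _BASES if b != m8]
    not_a = [b for b in _BASES if b != "A"]
    if site_class == "8mer":
        return m8 + core + "A"
    if site_class == "7mer-m8":
        return m8 + core + str(rng.choice(not_a))
    if site_class == "7mer-A1":
        return str(rng.choice(not_m8)) + core + "A"
    if site_class == "6mer":
        return str(rng.choice(not_m8)) + core + str(rng.choice(not_a))
    raise DataError(f"unknown site class {site_class!r}")


def gen_targetome(
    mirnas: Sequence[SequenceRecord],
    n_transcripts: int,
    site_rate: float,
    snp_in_site_rate: float,
    utr_len: int,
    seed: int,
    chrom: str = "12",
    utr_spacing: int = 100_000,
    max_retries: int = 200,
) -> tuple[list[SequenceRecord], list[VariantRecord], TruthTable]:
    """Random-background 3'UTRs with planted canonical sites and
    site-disrupting SNPs.

    Backgrounds are rejection-sampled to be free of accidental >=6mer seed
    matches for any supplied miRNA; with probability ``site_rate`` a site of
    a uniformly drawn class for a uniformly drawn miRNA is planted, and with
    probability ``snp_in_site_rate`` a SNP whose alt allele breaks seed
    complementarity is planted inside that site's seed-pairing region.
    """
    if utr_len < 30:
        raise DataError("utr_len must be >= 30")
    rng = np.random.default_rng(seed)
    cores = [seed_match_6(m.sequence) for m in mirnas]
    utrs: list[SequenceRecord] = []
    variants: list[VariantRecord] = []
    truth = TruthTable()

    for t in range(n_transcripts):
        transcript = f"TX{t:04d}"
        gene = f"GENE{t:04d}"
        genomic_start = 1 + t * utr_spacing

        seq = None
        for attempt in range(max_retries):
            cand = "".join(rng.choice(list(_BASES), size=utr_len))
            if not _has_any_core(cand, cores):
                seq = cand
                break
        if seq is None:
            raise DataError(
                "rejection budget exceeded while sampling clean background; "
                "raise utr_len or reduce the miRNA set"
            )

        planted = None
        if rng.random() < site_rate:
            mi = rng.integers(0, len(mirnas))
            mirna = mirnas[mi]
            site_class = str(rng.choice(SITE_CLASSES))
            for attempt in range(max_retries):
                site_seq = _build_site(rng, mirna.sequence, site_class)
                # interior offsets only, so flanks cannot up-class the site
                off0 = int(rng.integers(1, utr_len - len(site_seq)))
                cand = seq[:off0] + site_seq + seq[off0 + len(site_seq):]
                found = {
                    m.name: find_seed_sites(m, SequenceRecord(
                        name="tmp", kind="utr", sequence=cand))
                    for m in mirnas
                }
                ours = found.pop(mirna.name)
                others = [s for lst in found.values() for s in lst]
                # the pairing region starts after the leading flank/m8 base
                pair_start0 = off0 if site_class in ("8mer", "7mer-m8") else off0 + 1
                pair_len = 7 if site_class in ("8mer", "7mer-m8") else 6
                ok = (
                    not others
                    and len(ours) == 1
                    and ours[0].site_class == site_class
                    and ours[0].utr_start == pair_start0 + 1
                )
                if ok:
                    seq = cand
                    planted = {
                        "transcript": transcript,
                        "gene": gene,
                        "mirna": mirna.name,
                        "site_class": site_class,
                        "utr_start": ours[0].utr_start,
                        "utr_end": ours[0].utr_end,
                        "pair_start": pair_start0 + 1,
                        "pair_len": pair_len,
                    }
                    truth.sites.append(planted)
                    break
            else:
                raise DataError(
                    "rejection budget exceeded while planting a site; "
                    "raise utr_len"
                )

        if planted is not None and rng.random() < snp_in_site_rate:
            pair_start = planted["pair_start"]
            snp_off = int(
                rng.integers(pair_start, pair_start + planted["pair_len"])
            )
            ref = seq[snp_off - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            snp = VariantRecord(
                chrom=chrom,
                pos=genomic_start + snp_off - 1,
                id=f"mirsnp{t:04d}",
                ref_allele=ref,
                alt_allele=alt,
            )
            variants.append(snp)
            truth.site_snps.append(
                {
                    "id": snp.id,
                    "transcript": transcript,
                    "gene": gene,
                    "mirna": planted["mirna"],
                    "utr_offset": snp_off,
                    "pos": snp.pos,
                    "ref": ref,
                    "alt": alt,
                }
            )

        utrs.append(
            SequenceRecord(
                name=transcript,
                kind="utr",
                sequence=seq,
                transcript_id=transcript,
                gene_symbol=gene,
                chrom=chrom,
                strand="+",
                genomic_start=genomic_start,
            )
        )
    return utrs, variants, truth


def gen_expression(
    dosages: Sequence[float],
    intercept: float,
    beta_per_allele: float,
    noise_sd: float,
    outlier_frac: float,
    outlier_shift: float,
    seed: int,
) -> tuple[np.ndarray, TruthTable]:
    """Per-sample expression with a linear per-allele effect plus injected
    outliers to exercise the IQR filter."""
    if not 0 <= outlier_frac < 1:
        raise DataError("outlier_frac must be in [0, 1)")
    d = np.asarray(dosages, dtype=float)
    rng = np.random.default_rng(seed)
    expr = intercept + beta_per_allele * d + rng.normal(0, noise_sd, size=d.size)
    n_out = int(round(outlier_frac * d.size))
    idx = rng.choice(d.size, size=n_out, replace=False) if n_out else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_out)
    expr[idx] += signs * outlier_shift
    truth = TruthTable(
        eqtl={
            "intercept": intercept,
            "beta": beta_per_allele,
            "noise_sd": noise_sd,
            "outlier_indices": [int(i) for i in idx],
        }
    )
    return expr, truth


def gen_plate(
    n_experiments: int,
    n_replicates: int,
    baseline_mean: float,
    knockdown_ref: float,
    allele_effect: float,
    cv: float,
    seed: int,
) -> tuple[ReporterDataset, TruthTable]:
    """Reporter plates with a multiplicative allele effect.

    Targeting-miRNA condition means are ``baseline * knockdown_ref`` (ref)
    and ``baseline * (knockdown_ref + allele_effect)`` (alt); the scrambled
    control sits at baseline.  Noise is multiplicative (Gaussian on the log
    scale, sd = cv), with experiment-level baseline jitter (sd = cv / 2).
    """
    if n_replicates < 2:
        raise DataError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    experiments = []
    for _ in range(n_experiments):
        baseline = baseline_mean * float(np.exp(rng.normal(0, cv / 2))) if cv else baseline_mean
        means = {
            ("ref", "scrambled"): baseline,
            ("alt", "scrambled"): baseline,
            ("ref", "targeting"): baseline * knockdown_ref,
            ("alt", "targeting"): baseline * (knockdown_ref + allele_effect),
        }
        conditions = {}
        for key, mu in means.items():
            noise = np.exp(rng.normal(0, cv, size=n_replicates)) if cv else np.ones(n_replicates)
            conditions[key] = mu * noise
        experiments.append(conditions)
    truth = TruthTable(
        reporter={
            "baseline_mean": baseline_mean,
            "knockdown_ref": knockdown_ref,
            "allele_effect": allele_effect,
            "cv": cv,
        }
    )
    return ReporterDataset(experiments=experiments), truth


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

DEFAULT_MIRNAS = (
    # GC-rich seeds so planted canonical sites clear the default scorer cutoffs
    ("mir-sim-1", "AGCUGGCCAUGCUAGCUAGCU"),
    ("mir-sim-2", "UCGGACGCAUAGCUAGGCUAA"),
)


def simulate_scenario(outdir: str | Path, seed: int = 0, n_ind: int = 600) -> dict:
    """Generate one coherent input set for the whole chain and write it as
    standard files (VCF, FASTA, TSV, CSV) plus a truth JSON.

    Returns a dict of the written paths.
    """
    from .core_io import write_genotypes, write_phenotypes, write_sequences
    from .reporter import write_plates

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    mirnas = [
        SequenceRecord(name=n, kind="mirna", sequence=s) for n, s in DEFAULT_MIRNAS
    ]

    # trait cohort with one planted causal variant
    panel = gen_panel(
        n_hap=400, n_var=60, block_len=10, n_founders_per_block=4,
        mutation_rate=0.02, seed=seed,
    )
    cohort = gen_cohort(panel, n_ind=n_ind, seed=seed + 1)
    causal_id = panel.variants[25].id
    pheno, truth_ph = gen_phenotype(
        cohort,
        effects={causal_id: 0.5},
        covar_effects={"age": -0.02, "sex": 0.1, "education": 0.05},
        noise_sd=1.0,
        seed=seed + 2,
    )

    # targetome with planted sites and site SNPs
    utrs, site_variants, truth_tg = gen_targetome(
        mirnas, n_transcripts=30, site_rate=0.8, snp_in_site_rate=0.6,
        utr_len=120, seed=seed + 3,
    )

    # LD panel tying an index SNP to the site SNPs (single block, 2 founders,
    # no mutation -> perfect proxies, mirroring an r2 = 1 proxy cluster)
    index_pos = 2_104_170
    site_pos = [v.pos for v in site_variants]
    ld_positions = [index_pos] + site_pos
    ld_panel = gen_panel(
        n_hap=200, n_var=len(ld_positions), block_len=len(ld_positions),
        n_founders_per_block=2, mutation_rate=0.0, seed=seed + 4,
        chrom="12", positions=ld_positions,
    )
    # rename/realign the LD panel variants to the site SNP identities
    renamed = [
        VariantRecord(chrom="12", pos=index_pos, id="idx0001",
                      ref_allele="G", alt_allele="A")
    ] + list(site_variants)
    order = np.argsort([v.pos for v in renamed], kind="stable")
    ld_panel = HaplotypePanel(
        haplotypes=ld_panel.haplotypes[:, order],
        variants=[renamed[i] for i in order],
        block_boundaries=[0],
    )

    # expression at the index SNP for the eQTL stage
    ld_cohort = gen_cohort(ld_panel, n_ind=300, seed=seed + 5)
    expr, truth_eq = gen_expression(
        ld_cohort.dosage_vector("idx0001"),
        intercept=400.0, beta_per_allele=80.0, noise_sd=120.0,
        outlier_frac=0.05, outlier_shift=800.0, seed=seed + 6,
    )

    # reporter plates
    plates, truth_rp = gen_plate(
        n_experiments=7, n_replicates=6, baseline_mean=1000.0,
        knockdown_ref=0.585, allele_effect=0.118, cv=0.06, seed=seed + 7,
    )

    truth = truth_ph.merge(truth_tg).merge(truth_eq).merge(truth_rp)

    paths = {
        "cohort_vcf": outdir / "cohort.vcf",
        "pheno_tsv": outdir / "phenotypes.tsv",
        "mirna_fasta": outdir / "mirnas.fa",
        "utr_fasta": outdir / "utrs.fa",
        "ld_vcf": outdir / "ld_panel.vcf",
        "expr_tsv": outdir / "expression.tsv",
        "plates_csv": outdir / "plates.csv",
        "genes_tsv": outdir / "genes.tsv",
        "truth_json": outdir / "truth.json",
    }
    write_genotypes(cohort, paths["cohort_vcf"])
    write_phenotypes(pheno, paths["pheno_tsv"])
    write_sequences(mirnas, paths["mirna_fasta"])
    write_sequences(utrs, paths["utr_fasta"])
    write_genotypes(gen_cohort(ld_panel, n_ind=200, seed=seed + 8), paths["ld_vcf"])
    pd.DataFrame(
        {
            "sample_id": ld_cohort.sample_ids,
            "value": expr,
            "sex": np.random.default_rng(seed + 9).integers(0, 2, len(expr)),
            "population": np.random.default_rng(seed + 10).choice(
                ["POP1", "POP2"], len(expr)
            ),
            "dosage": ld_cohort.dosage_vector("idx0001"),
        }
    ).to_csv(paths["expr_tsv"], sep="\t", index=False)
    write_plates(plates, paths["plates_csv"])
    pd.DataFrame(
        {
            "gene_symbol": [u.gene_symbol for u in utrs],
            "chrom": [u.chrom for u in utrs],
            "start": [u.genomic_start for u in utrs],
            "end": [u.genomic_start + len(u.sequence) - 1 for u in utrs],
        }
    ).to_csv(paths["genes_tsv"], sep="\t", index=False)
    truth.to_json(paths["truth_json"])
    return {k: str(v) for k, v in paths.items()}
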