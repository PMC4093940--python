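"""miRNA target-site prediction in 3'UTRs and allele-specific rescoring.

Canonical site classes are defined on the mRNA sense strand, written 5'->3'
as the reverse complement of the miRNA seed (miRNA positions 2-8 counted
from the 5' end), with the t1 A at the site's 3' end:

    8mer     WC match to miRNA 2-8 plus an A opposite position 1
    7mer-m8  WC match to miRNA 2-8
    7mer-A1  WC match to miRNA 2-7 plus an A opposite position 1
    6mer     WC match to miRNA 2-7

The t1 A is required to be an A in the mRNA regardless of the identity of
miRNA position 1.  A longer-class match suppresses the shorter classes it
contains at the same locus.

Three scorers feed a k-of-n consensus: the seed-class caller, a local
complementarity alignment (``align_score``) and a nearest-neighbor duplex
stability estimate (``duplex_energy``).  Their parameters are declared
defaults, not fitted values; downstream logic depends only on their
documented relative behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Config, DataError, SequenceRecord, VariantRecord

logger = logging.getLogger("mirsnp")

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

# weight of each site class in the normalized consensus site score
CLASS_WEIGHT = {"8mer": 1.0, "7mer-m8": 0.75, "7mer-A1": 0.5, "6mer": 0.25}

# RNA base of the miRNA -> complementary DNA base on the mRNA sense strand
_RNA_TO_DNA_COMPLEMENT = {"A": "T", "U": "A", "G": "C", "C": "G"}

# alignment scoring (seed positions are miRNA 2-8, weighted x2)
ALIGN_WC = 5.0
ALIGN_WOBBLE = 2.0
ALIGN_MISMATCH = -3.0
ALIGN_GAP_OPEN = -8.0
ALIGN_GAP_EXTEND = -2.0

# nearest-neighbor stack energies (kcal/mol-like) for a Watson-Crick stack,
# keyed by two consecutive miRNA bases 5'->3'; Turner-style RNA/RNA values.
STACK_ENERGY = {
    ("A", "A"): -0.93, ("A", "U"): -1.10, ("A", "G"): -2.08, ("A", "C"): -2.24,
    ("U", "A"): -1.33, ("U", "U"): -0.93, ("U", "G"): -2.11, ("U", "C"): -2.35,
    ("G", "A"): -2.35, ("G", "U"): -2.24, ("G", "G"): -3.26, ("G", "C"): -3.42,
    ("C", "A"): -2.11, ("C", "U"): -2.08, ("C", "G"): -2.36, ("C", "C"): -3.26,
}
WOBBLE_STACK_PENALTY = 1.0
T1_BONUS = -0.3  # unpaired t1 A contribution for 8mer / 7mer-A1 sites

ALIGN_NORM = 75.0   # score of a fully WC-paired seed+position-1 duplex
ENERGY_NORM = -12.0  # reference stability for score normalization


@dataclass(frozen=True)
class SeedSite:
    """A canonical seed-match site; UTR offsets are 1-based inclusive."""

    mirna_name: str
    transcript_id: str | None
    site_class: str
    utr_start: int
    utr_end: int


@dataclass(frozen=True)
class SiteCall:
    site: SeedSite
    scores: Mapping[str, float]
    n_supporting: int


@dataclass(frozen=True)
class AlleleDelta:
    """Ref-vs-alt consensus score change for a SNP inside a UTR."""

    snp: VariantRecord
    mirna_name: str
    transcript_id: str | None
    score_ref: float
    score_alt: float

    @property
    def delta(self) -> float:
        return self.score_alt - self.score_ref

    @property
    def predicted_expression_direction(self) -> str:
        # weakened binding under the alt allele de-represses the transcript
        if self.delta < 0:
            return "up"
        if self.delta > 0:
            return "down"
        return "none"


def seed_match_6(mirna_seq: str) -> str:
    """Reverse complement of miRNA positions 2-7, as DNA (mRNA sense)."""
    return "".join(_RNA_TO_DNA_COMPLEMENT[b] for b in reversed(mirna_seq[1:7]))


def _m8_complement(mirna_seq: str) -> str:
    return _RNA_TO_DNA_COMPLEMENT[mirna_seq[7]]


def find_seed_sites(
    mirna: SequenceRecord, utr: SequenceRecord
) -> list[SeedSite]:
    """Enumerate all canonical seed-match sites of ``mirna`` in ``utr``.

    Every occurrence is classified into exactly one of the four canonical
    classes, so an 8mer is never additionally reported as the 7mer/6mer it
    contains.  Overlapping occurrences are each reported.
    """
    seq = utr.sequence
    if len(seq) < 8:
        return []
    core = seed_match_6(mirna.sequence)
    m8 = _m8_complement(mirna.sequence)
    sites: list[SeedSite] = []
    start = 0
    while True:
        j = seq.find(core, start)
        if j < 0:
            break
        start = j + 1
        has_m8 = j > 0 and seq[j - 1] == m8
        has_a1 = j + 6 < len(seq) and seq[j + 6] == "A"
        if has_m8 and has_a1:
            cls, s, e = "8mer", j - 1, j + 6
        elif has_m8:
            cls, s, e = "7mer-m8", j - 1, j + 5
        elif has_a1:
            cls, s, e = "7mer-A1", j, j + 6
        else:
            cls, s, e = "6mer", j, j + 5
        sites.append(
            SeedSite(
                mirna_name=mirna.name,
                transcript_id=utr.transcript_id,
                site_class=cls,
                utr_start=s + 1,
                utr_end=e + 1,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# alignment scorer
# ---------------------------------------------------------------------------


def _pair_score(mi_base: str, dna_base: str) -> float:
    if _RNA_TO_DNA_COMPLEMENT[mi_base] == dna_base:
        return ALIGN_WC
    if (mi_base == "G" and dna_base == "T") or (mi_base == "U" and dna_base == "G"):
        return ALIGN_WOBBLE  # G:U wobble on the RNA duplex
    return ALIGN_MISMATCH


def align_score(mirna: SequenceRecord | str, utr_window: str) -> float:
    """Best local antiparallel complementarity alignment score (>= 0).

    Smith-Waterman with affine gaps over the miRNA (5'->3') and the reversed
    UTR window, so index i of the miRNA is considered against the window
    base it would face in the duplex.  Substitution scores at miRNA
    positions 2-8 are doubled.
    """
    mi = mirna.sequence if isinstance(mirna, SequenceRecord) else mirna
    if not 6 <= len(utr_window) <= 40:
        raise DataError(f"window length {len(utr_window)} outside [6, 40]")
    win = utr_window[::-1]  # 3'->5' so both strings run in pairing order
    n, m = len(mi), len(win)
    neg = -np.inf
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in miRNA (consume window)
    F = np.full((n + 1, m + 1), neg)  # gap in window (consume miRNA)
    best = 0.0
    for i in range(1, n + 1):
        weight = 2.0 if 2 <= i <= 8 else 1.0
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + ALIGN_GAP_OPEN, E[i][j - 1] + ALIGN_GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + ALIGN_GAP_OPEN, F[i - 1][j] + ALIGN_GAP_EXTEND)
            diag = H[i - 1][j - 1] + weight * _pair_score(mi[i - 1], win[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return float(best)


# ---------------------------------------------------------------------------
# duplex-energy scorer
# ---------------------------------------------------------------------------


def duplex_energy(mirna: SequenceRecord, utr_window: str, site: SeedSite | None = None) -> float:
    """Nearest-neighbor stability of the seed duplex (more negative = more
    stable).

    Sums stack energies over consecutive Watson-Crick pairs of the seed
    duplex; wobble-containing stacks are penalized by +1.0 each, and the
    unpaired t1 A contributes a fixed -0.3 for 8mer/7mer-A1 sites.
    """
    window_rec = SequenceRecord(name="window", kind="utr", sequence=utr_window)
    if site is None:
        sites = find_seed_sites(mirna, window_rec)
        if not sites:
            raise DataError("duplex_energy: no seed-class site in window")
        site = max(sites, key=lambda s: CLASS_WEIGHT[s.site_class])

    # miRNA seed positions paired by this site class
    n_paired = 7 if site.site_class in ("8mer", "7mer-m8") else 6
    mi = mirna.sequence
    energy = 0.0
    # pairs at miRNA positions 2..(1+n_paired); all WC by construction of the
    # site classes, but re-check so wobble-extended callers are handled
    for k in range(n_paired - 1):
        b1, b2 = mi[1 + k], mi[2 + k]
        stack = STACK_ENERGY[(b1, b2)]
        energy += stack
    if site.site_class in ("8mer", "7mer-A1"):
        energy += T1_BONUS
    return float(energy)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

SCORER_NAMES = ("seed", "align", "energy")


def _site_window(utr_seq: str, site: SeedSite, mirna_len: int, pad: int = 2) -> str:
    """UTR window covering the site plus room for the miRNA 3' end, which
    pairs upstream (5') of the seed match on the mRNA."""
    lo = max(0, site.utr_start - 1 - (mirna_len - 8) - pad)
    hi = min(len(utr_seq), site.utr_end + pad)
    window = utr_seq[lo:hi]
    if len(window) < 6:
        window = utr_seq[max(0, hi - 6):hi]
    return window[-40:]


def call_consensus(
    mirna: SequenceRecord,
    utr: SequenceRecord,
    k_min: int | None = None,
    config: Config | None = None,
) -> list[SiteCall]:
    """Score every seed-match site with all scorers and keep those supported
    by at least ``k_min`` of them (default 3 of 3)."""
    config = config or Config()
    if k_min is None:
        k_min = config.k_min
    if k_min > len(SCORER_NAMES):
        raise DataError(
            f"k_min={k_min} exceeds the {len(SCORER_NAMES)} configured scorers"
        )
    calls: list[SiteCall] = []
    for site in find_seed_sites(mirna, utr):
        window = _site_window(utr.sequence, site, len(mirna.sequence))
        a = align_score(mirna, window)
        e = duplex_energy(mirna, window, site=site)
        n_sup = 1  # the seed-class caller found the site
        n_sup += int(a >= config.align_min)
        n_sup += int(e <= config.energy_max)
        if n_sup >= k_min:
            calls.append(
                SiteCall(
                    site=site,
                    scores={"seed": CLASS_WEIGHT[site.site_class], "align": a, "energy": e},
                    n_supporting=n_sup,
                )
            )
    return calls


def _normalized_site_score(call: SiteCall) -> float:
    w_class = call.scores["seed"]
    w_align = min(max(call.scores["align"] / ALIGN_NORM, 0.0), 1.0)
    w_energy = min(max(call.scores["energy"] / ENERGY_NORM, 0.0), 1.0)
    return w_class + w_align + w_energy


# ---------------------------------------------------------------------------
# allele-specific rescoring
# ---------------------------------------------------------------------------


def allele_delta(
    mirna: SequenceRecord,
    utr: SequenceRecord,
    snp: VariantRecord,
    utr_offset_of_snp: int,
    k_min: int = 1,
    config: Config | None = None,
) -> AlleleDelta:
    """Consensus site score under the ref vs. alt allele of a UTR SNP.

    The score is the sum of normalized scorer scores over called sites
    overlapping the SNP offset, computed once on the reference UTR and once
    on the alt-substituted UTR.  A SNP overlapping no site under either
    allele yields delta 0 / direction "none".
    """
    off = utr_offset_of_snp
    if not 1 <= off <= len(utr.sequence):
        raise DataError(
            f"{snp.id}: UTR offset {off} outside [1, {len(utr.sequence)}]"
        )
    if utr.sequence[off - 1] != snp.ref_allele:
        raise DataError(
            f"{snp.id}: ref allele {snp.ref_allele} does not match UTR base "
            f"{utr.sequence[off - 1]} at offset {off} of {utr.name}"
        )

    def total_score(seq: str) -> float:
        rec = SequenceRecord(
            name=utr.name,
            kind="utr",
            sequence=seq,
            transcript_id=utr.transcript_id,
            gene_symbol=utr.gene_symbol,
            chrom=utr.chrom,
            strand=utr.strand,
            genomic_start=utr.genomic_start,
        )
        calls = call_consensus(mirna, rec, k_min=k_min, config=config)
        return sum(
            _normalized_site_score(c)
            for c in calls
            if c.site.utr_start <= off <= c.site.utr_end
        )

    alt_seq = utr.sequence[: off - 1] + snp.alt_allele + utr.sequence[off:]
    return AlleleDelta(
        snp=snp,
        mirna_name=mirna.name,
        transcript_id=utr.transcript_id,
        score_ref=total_score(utr.sequence),
        score_alt=total_score(alt_seq),
    )


# ---------------------------------------------------------------------------
# genomic projection and the proxy -> site annotation table
# ---------------------------------------------------------------------------


def project_to_utr(utr: SequenceRecord, pos: int) -> int | None:
    """Map a genomic position into a 1-based UTR offset, or None if outside.

    Minus-strand UTRs are stored as sense mRNA, so the offset runs against
    genomic coordinates.
    """
    if utr.genomic_start is None or utr.strand is None:
        return None
    end = utr.genomic_start + len(utr.sequence) - 1
    if not utr.genomic_start <= pos <= end:
        return None
    if utr.strand == "+":
        return pos - utr.genomic_start + 1
    return end - pos + 1


_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def map_snps_to_sites(
    proxy_pairs: Iterable,
    utrs: Sequence[SequenceRecord],
    mirnas: Sequence[SequenceRecord],
    k_min: int = 1,
    config: Config | None = None,
) -> pd.DataFrame:
    """Annotate LD proxies with predicted allele effects on miRNA binding.

    One row per (index SNP, proxy SNP, miRNA, transcript) whose allele delta
    is non-zero; the machine-readable product of the proxy -> site mapping.
    """
    rows = []
    for pair in proxy_pairs:
        snp = pair.proxy
        for utr in utrs:
            if utr.chrom != snp.chrom:
                continue
            off = project_to_utr(utr, snp.pos)
            if off is None:
                continue
            if utr.strand == "-":
                snp_local = VariantRecord(
                    chrom=snp.chrom,
                    pos=snp.pos,
                    id=snp.id,
                    ref_allele=_DNA_COMPLEMENT[snp.ref_allele],
                    alt_allele=_DNA_COMPLEMENT[snp.alt_allele],
                )
            else:
                snp_local = snp
            for mirna in mirnas:
                try:
                    d = allele_delta(
                        mirna, utr, snp_local, off, k_min=k_min, config=config
                    )
                except DataError as exc:
                    logger.warning("projection failure skipped: %s", exc)
                    continue
                if d.delta == 0:
                    continue
                rows.append(
                    {
                        "gwas_snp": pair.index.id,
                        "proxy_snp": snp.id,
                        "chrom": snp.chrom,
                        "pos": snp.pos,
                        "distance_bp": pair.distance_bp,
                        "alleles": f"{snp.ref_allele}/{snp.alt_allele}",
                        "r2": pair.r2,
                        "mirna": mirna.name,
                        "gene": utr.gene_symbol,
                        "transcript": utr.transcript_id,
                        "score_ref": d.score_ref,
                        "score_alt": d.score_alt,
                        "delta": d.delta,
                        "direction": d.predicted_expression_direction,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gwas_snp", "proxy_snp", "chrom", "pos", "distance_bp", "alleles",
            "r2", "mirna", "gene", "transcript", "score_ref", "score_alt",
            "delta", "direction",
        ],
    )
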