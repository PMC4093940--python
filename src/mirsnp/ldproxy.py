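"""Pairwise LD (r-squared) and proxy-SNP search around index variants."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import DataError, GenotypeMatrix, VariantRecord

logger = logging.getLogger("mirsnp")


class MonomorphicError(DataError):
    """r-squared is undefined at a monomorphic site."""


@dataclass(frozen=True)
class ProxyPair:
    index: VariantRecord
    proxy: VariantRecord
    r2: float
    distance_bp: int


def compute_r2(
    a: Sequence[float], b: Sequence[float], mode: str = "haplotype"
) -> float:
    """LD r-squared between two sites.

    haplotype mode: ``a``/``b`` are 0/1 haplotype columns and
    r2 = D^2 / (p_A (1-p_A) p_B (1-p_B)) with D = p_AB - p_A p_B.
    genotype mode: squared Pearson correlation of dosage vectors
    (composite LD, an approximation for unphased data).
    The result is clamped to [0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("r2: input vectors differ in length")
    if mode == "haplotype":
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise DataError("haplotype-mode r2 requires 0/1 vectors")
        p_a, p_b = a.mean(), b.mean()
        if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
            raise MonomorphicError("r2 undefined: monomorphic site")
        d = (a * b).mean() - p_a * p_b
        r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    elif mode == "genotype":
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        if a.std() == 0 or b.std() == 0:
            raise MonomorphicError("r2 undefined: monomorphic site")
        r = np.corrcoef(a, b)[0, 1]
        r2 = r * r
    else:
        raise ValueError(f"unknown r2 mode {mode!r}")
    return float(min(max(r2, 0.0), 1.0))


def find_proxies(
    index_ids: Sequence[str],
    reference,
    r2_min: float = 0.8,
    window_bp: int = 1_000_000,
    mode: str | None = None,
) -> tuple[list[ProxyPair], list[str]]:
    """All variants within +-window_bp of each index SNP with r2 >= r2_min.

    ``reference`` is a :class:`~mirsnp.synthdata.HaplotypePanel` (haplotype
    mode) or a :class:`GenotypeMatrix` (genotype mode); ``mode`` overrides
    the autodetected choice.  The index SNP itself is always emitted
    (r2 = 1, distance 0).  Pairs are sorted by descending r2, then distance.
    Absent index ids produce an error record; the run continues.
    """
    if isinstance(reference, GenotypeMatrix):
        columns = reference.dosages
        detected_mode = "genotype"
    else:  # HaplotypePanel (duck-typed to avoid a circular import)
        columns = np.asarray(reference.haplotypes, dtype=float)
        detected_mode = "haplotype"
    mode = mode or detected_mode
    variants = reference.variants
    by_id = {v.id: j for j, v in enumerate(variants)}

    pairs: list[ProxyPair] = []
    errors: list[str] = []
    for index_id in index_ids:
        if index_id not in by_id:
            msg = f"index SNP {index_id} absent from the reference data"
            logger.warning(msg)
            errors.append(msg)
            continue
        j0 = by_id[index_id]
        index_var = variants[j0]
        found: list[ProxyPair] = []
        for j, v in enumerate(variants):
            if v.chrom != index_var.chrom:
                continue
            dist = abs(v.pos - index_var.pos)
            if dist > window_bp:
                continue
            if j == j0:
                found.append(ProxyPair(index_var, v, 1.0, 0))
                continue
            try:
                r2 = compute_r2(columns[:, j0], columns[:, j], mode=mode)
            except MonomorphicError:
                continue
            if r2 >= r2_min:
                found.append(ProxyPair(index_var, v, r2, dist))
        found.sort(key=lambda p: (-p.r2, p.distance_bp))
        pairs.extend(found)
    return pairs, errors
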