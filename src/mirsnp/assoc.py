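"""Additive-model association scan with covariate/PC adjustment and locus
clumping.

The scan is ordinary least squares of the trait on per-variant dosage plus
covariates, principal components and an intercept; imputed genotypes enter
as expected dosages.  Missing dosages are mean-imputed per variant at
regression time; samples missing the trait or any covariate are dropped
(complete-case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import DataError, GenotypeMatrix, PhenotypeTable, VariantRecord

logger = logging.getLogger("mirsnp")


@dataclass(frozen=True)
class AssocRow:
    variant: VariantRecord
    trait: str
    n: int
    beta: float
    se: float
    t_stat: float
    p: float
    note: str = ""


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int
    end: int
    lead_variant: VariantRecord
    min_p: float
    n_snps: int


def compute_pcs(G: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of the standardized dosage matrix.

    Variants are mean-centered and scaled to unit variance (zero-variance
    variants dropped with a warning); missing dosages are mean-imputed for
    the decomposition.  Sign convention: the largest-magnitude loading of
    each component is positive.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    if G.n_samples < k + 1:
        raise DataError(f"need at least {k + 1} samples for {k} PCs")
    X = G.dosages.copy()
    col_means = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_means, np.where(nan_mask)[1])
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DataError("all variants are zero-variance; PCA undefined")
    if (~keep).any():
        logger.warning("compute_pcs: dropping %d zero-variance variants", (~keep).sum())
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # eigenvectors of the sample covariance via SVD of the centered matrix
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k_eff = min(k, S.size)
    scores = np.empty((G.n_samples, k_eff))
    for c in range(k_eff):
        v = Vt[c]
        sign = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
        scores[:, c] = sign * U[:, c] * S[c]
    return scores


def scan_trait(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    covariate_names: Sequence[str] = ("age", "sex", "education"),
    pcs: np.ndarray | None = None,
) -> list[AssocRow]:
    """Per-variant OLS of ``trait`` on dosage + covariates + PCs + intercept.

    beta/SE/t and the two-sided P come from the t distribution with
    n - p degrees of freedom.  Monomorphic variants emit an NA row with a
    reason.  Zero-variance traits yield beta 0 / p NA for every variant
    (documented policy).
    """
    if trait not in pheno.data.columns:
        raise DataError(f"trait {trait!r} not in phenotype table")
    pheno_df = pheno.data.reindex(G.sample_ids)
    needed = [trait, *covariate_names]
    missing_cols = [c for c in covariate_names if c not in pheno_df.columns]
    if missing_cols:
        raise DataError(f"covariates missing from phenotype table: {missing_cols}")
    complete = pheno_df[needed].notna().all(axis=1).to_numpy()
    idx = np.where(complete)[0]
    n = idx.size

    y = pheno_df[trait].to_numpy(float)[idx]
    C = [np.ones(n)]
    for c in covariate_names:
        C.append(pheno_df[c].to_numpy(float)[idx])
    if pcs is not None:
        for c in range(pcs.shape[1]):
            C.append(np.asarray(pcs)[idx, c])
    C = np.column_stack(C)
    p_model = C.shape[1] + 1  # + dosage term
    if n < p_model + 1:
        raise DataError(
            f"trait {trait!r}: {n} complete samples < {p_model + 1} required"
        )

    # residualize once against the shared covariate block (FWL), then each
    # variant costs one slope fit
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    df = n - p_model
    trait_degenerate = float(np.var(y)) == 0.0

    rows: list[AssocRow] = []
    for j, variant in enumerate(G.variants):
        g = G.dosages[idx, j].copy()
        nan = np.isnan(g)
        if nan.all():
            rows.append(_na_row(variant, trait, n, "all dosages missing"))
            continue
        if nan.any():
            g[nan] = g[~nan].mean()
        if g.std() == 0:
            rows.append(_na_row(variant, trait, n, "monomorphic"))
            continue
        if trait_degenerate:
            rows.append(
                AssocRow(variant, trait, n, 0.0, np.nan, np.nan, np.nan,
                         note="zero-variance trait")
            )
            continue
        g_res = g - Q @ (Q.T @ g)
        gg = float(g_res @ g_res)
        beta = float(g_res @ y_res) / gg
        rss = float(y_res @ y_res) - beta * float(g_res @ y_res)
        sigma2 = max(rss, 0.0) / df
        se = float(np.sqrt(sigma2 / gg))
        if se == 0:
            t = np.inf if beta != 0 else 0.0
            p = 0.0 if beta != 0 else 1.0
        else:
            t = beta / se
            p = float(2 * stats.t.sf(abs(t), df))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(AssocRow(variant, trait, n, beta, se, float(t), p))
    return rows


def _na_row(variant: VariantRecord, trait: str, n: int, reason: str) -> AssocRow:
    return AssocRow(variant, trait, n, np.nan, np.nan, np.nan, np.nan, note=reason)


def clump_loci(
    rows: Sequence[AssocRow],
    p_thresh: float = 1e-6,
    merge_window_bp: int = 1_000_000,
) -> list[Locus]:
    """Greedy merge of significant variants into loci.

    Variants with p <= p_thresh on the same chromosome are merged when
    within ``merge_window_bp`` of the growing locus (gap to the nearest
    member); the lead is the min-p variant, ties broken by smaller position.
    """
    sig = [
        r for r in rows
        if r.p is not None and np.isfinite(r.p) and r.p <= p_thresh
    ]
    sig.sort(key=lambda r: (r.variant.chrom, r.variant.pos))
    loci: list[Locus] = []
    current: list[AssocRow] = []

    def close(group: list[AssocRow]) -> Locus:
        lead = min(group, key=lambda r: (r.p, r.variant.pos))
        return Locus(
            chrom=group[0].variant.chrom,
            start=group[0].variant.pos,
            end=group[-1].variant.pos,
            lead_variant=lead.variant,
            min_p=lead.p,
            n_snps=len(group),
        )

    for r in sig:
        if current and (
            r.variant.chrom != current[-1].variant.chrom
            or r.variant.pos - current[-1].variant.pos > merge_window_bp
        ):
            loci.append(close(current))
            current = []
        current.append(r)
    if current:
        loci.append(close(current))
    return loci
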