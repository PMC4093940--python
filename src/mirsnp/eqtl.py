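"""Expression-QTL stage: IQR outlier filtering, normality check,
covariate-adjusted additive regression, and the homozygote-exclusion
sensitivity analysis.

Quantiles use linear interpolation of order statistics (R type 7), the
default of the statistical environment the convention targets; the fences
at Q1 - 1.5*IQR and Q3 + 1.5*IQR are inclusive, so boundary values are
kept.  The slope is reported per minor allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DataError

logger = logging.getLogger("mirsnp")


@dataclass(frozen=True)
class EqtlResult:
    n_used: int
    n_excluded_outliers: int
    n_missing: int
    beta: float
    se: float
    t_stat: float
    p: float
    covariates: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_used": self.n_used,
            "n_excluded_outliers": self.n_excluded_outliers,
            "n_missing": self.n_missing,
            "beta": self.beta,
            "se": self.se,
            "t": self.t_stat,
            "p": self.p,
            "covariates": list(self.covariates),
        }


def iqr_filter(
    values: Sequence[float], k: float = 1.5, quantile_method: str = "linear"
) -> tuple[np.ndarray, int]:
    """Keep-mask and exclusion count under the 1.5-IQR fence rule.

    NaN values are excluded from the quantile computation and flagged as not
    kept; fences are inclusive.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        raise DataError("iqr_filter needs at least 4 non-missing values")
    q1, q3 = np.quantile(values[finite], [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = finite & (values >= lo) & (values <= hi)
    n_excluded = int((finite & ~keep).sum())
    return keep, n_excluded


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk statistic and P.  Advisory only; never gates the fit."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if not 3 <= values.size <= 5000:
        raise DataError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def load_geuvadis_expression(path: str, mirna_id: str) -> pd.Series:
    """Extract one miRNA's per-sample quantifications from a GEUVADIS-style
    release matrix (tab-separated; features as rows, samples as numeric
    columns, feature ids in the leading non-numeric column(s))."""
    df = pd.read_csv(path, sep="\t")
    id_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if not id_cols:
        raise DataError(f"{path}: no feature-id column found")
    mask = pd.Series(False, index=df.index)
    for c in id_cols:
        mask |= df[c].astype(str).str.contains(mirna_id, regex=False, na=False)
    hits = df[mask]
    if len(hits) != 1:
        raise DataError(
            f"{path}: expected exactly one row matching {mirna_id!r}, "
            f"found {len(hits)}"
        )
    values = hits.iloc[0].drop(labels=id_cols)
    return pd.to_numeric(values, errors="coerce").dropna()


def _minor_allele_dosage(dosages: np.ndarray) -> np.ndarray:
    """Flip coding so the slope is expressed per minor allele."""
    freq = np.nanmean(dosages) / 2.0
    return 2.0 - dosages if freq > 0.5 else dosages


def fit_eqtl(
    expr: Sequence[float],
    dosages: Sequence[float],
    covariates: pd.DataFrame | None = None,
    apply_iqr: bool = True,
    quantile_method: str = "linear",
) -> EqtlResult:
    """OLS of (IQR-filtered) expression on minor-allele count + covariates.

    ``covariates`` may mix numeric columns (used as-is) and categorical ones
    (one-hot encoded with the first level dropped), e.g. sex + population of
    origin.  Two-sided P from the t distribution.
    """
    expr = np.asarray(expr, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    if expr.shape != dosages.shape:
        raise DataError("expression and dosage vectors differ in length")
    n_input = expr.size

    missing = ~(np.isfinite(expr) & np.isfinite(dosages))
    if covariates is not None:
        if len(covariates) != n_input:
            raise DataError("covariate table length mismatch")
        missing |= covariates.isna().any(axis=1).to_numpy()
    n_missing = int(missing.sum())

    work = np.where(missing, np.nan, expr)
    keep, n_excluded = iqr_filter(work, quantile_method=quantile_method) if apply_iqr \
        else (~missing, 0)

    y = expr[keep]
    g = _minor_allele_dosage(dosages)[keep]
    if np.nanstd(g) == 0:
        raise DataError("genotype monomorphic after filtering")

    cols = [np.ones(y.size), g]
    names: list[str] = []
    if covariates is not None:
        sub = covariates.loc[np.asarray(keep)]
        for name in covariates.columns:
            col = sub[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(float))
                names.append(name)
            else:
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                for dcol in dummies.columns:
                    cols.append(dummies[dcol].to_numpy(float))
                    names.append(dcol)
    X = np.column_stack(cols)
    n, p_model = X.shape
    if n <= p_model:
        raise DataError("fewer samples than model parameters")

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - p_model
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    return EqtlResult(
        n_used=n,
        n_excluded_outliers=n_excluded,
        n_missing=n_missing,
        beta=beta,
        se=se,
        t_stat=float(t),
        p=p,
        covariates=tuple(names),
    )


def sensitivity_excluding_genotype(
    expr: Sequence[float],
    dosages: Sequence[float],
    covariates: pd.DataFrame | None = None,
    excluded_genotype: int = 2,
    apply_iqr: bool = True,
    quantile_method: str = "linear",
) -> EqtlResult:
    """Refit after dropping carriers of ``excluded_genotype`` (minor-allele
    count coding); otherwise identical to :func:`fit_eqtl`."""
    expr = np.asarray(expr, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    minor = _minor_allele_dosage(dosages)
    drop = np.round(minor) == excluded_genotype
    keep = ~drop
    logger.info(
        "sensitivity analysis: excluding %d carriers of genotype %d",
        int(drop.sum()), excluded_genotype,
    )
    sub_cov = covariates.loc[keep].reset_index(drop=True) if covariates is not None else None
    return fit_eqtl(
        expr[keep], minor[keep], sub_cov,
        apply_iqr=apply_iqr, quantile_method=quantile_method,
    )
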