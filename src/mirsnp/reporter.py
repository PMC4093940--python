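"""Reporter-assay statistics: outlier rule, scrambled-control normalization,
binding and allele tests, and the percent-point difference between alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DataError

logger = logging.getLogger("mirsnp")

ALLELES = ("ref", "alt")
MIRNA_CONDITIONS = ("targeting", "scrambled")


@dataclass
class ReporterDataset:
    """Replicate luminescence values per experiment and condition.

    ``experiments[e][(allele, mirna)]`` is the replicate vector for construct
    allele in {"ref", "alt"} and co-transfected miRNA in {"targeting",
    "scrambled"}.
    """

    experiments: list[dict[tuple[str, str], np.ndarray]]

    def __post_init__(self) -> None:
        for e, conditions in enumerate(self.experiments):
            for allele in ALLELES:
                for mirna in MIRNA_CONDITIONS:
                    if (allele, mirna) not in conditions:
                        raise DataError(
                            f"experiment {e}: missing condition ({allele}, {mirna})"
                        )
            for key, values in conditions.items():
                conditions[key] = np.asarray(values, dtype=float)
                if conditions[key].size < 2:
                    raise DataError(
                        f"experiment {e}, condition {key}: fewer than 2 replicates"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"experiment": e, "allele": allele, "mirna": mirna,
             "replicate": r, "value": float(v)}
            for e, conditions in enumerate(self.experiments)
            for (allele, mirna), values in conditions.items()
            for r, v in enumerate(values)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReporterDataset":
        experiments = []
        for _, sub in df.groupby("experiment", sort=True):
            conditions = {
                (str(allele), str(mirna)): grp.sort_values("replicate")["value"].to_numpy()
                for (allele, mirna), grp in sub.groupby(["allele", "mirna"])
            }
            experiments.append(conditions)
        return cls(experiments=experiments)


@dataclass
class ReporterResult:
    ratios: dict[str, np.ndarray]          # allele -> per-experiment ratios
    means: dict[str, float]
    sems: dict[str, float]
    binding: dict[str, tuple[float, float]]  # allele -> (t, one-tailed p)
    allele_t: float
    allele_p: float
    percent_point_difference: float

    def to_dict(self) -> dict:
        return {
            "ratios": {a: list(map(float, v)) for a, v in self.ratios.items()},
            "means": self.means,
            "sems": self.sems,
            "binding": {a: {"t": t, "p_one_tailed": p} for a, (t, p) in self.binding.items()},
            "allele_test": {"t": self.allele_t, "p_two_tailed": self.allele_p},
            "percent_point_difference": self.percent_point_difference,
        }


def sd_outlier_filter(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Drop values deviating more than ``k`` standard deviations from the
    condition mean (single pass; mean/sd from all values)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise DataError("sd_outlier_filter needs >= 3 values per condition")
    if not np.isfinite(k):
        return values
    sd = values.std(ddof=1)
    if sd == 0:
        return values
    keep = np.abs(values - values.mean()) <= k * sd
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("sd_outlier_filter removed %d of %d values", n_removed, values.size)
    return values[keep]


def normalize_to_control(
    dataset: ReporterDataset, sd_k: float = 3.0, filter_first: bool = True
) -> dict[str, np.ndarray]:
    """Per-experiment, per-allele ratio of targeting-miRNA mean to the
    scrambled-control mean.  The 3-SD filter is applied per condition before
    normalization by default (configurable order)."""
    ratios: dict[str, list[float]] = {a: [] for a in ALLELES}
    for e, conditions in enumerate(dataset.experiments):
        for allele in ALLELES:
            targeting = conditions[(allele, "targeting")]
            scrambled = conditions[(allele, "scrambled")]
            if filter_first:
                targeting = sd_outlier_filter(targeting, k=sd_k)
                scrambled = sd_outlier_filter(scrambled, k=sd_k)
            control_mean = scrambled.mean()
            if control_mean <= 0:
                raise DataError(
                    f"experiment {e}, allele {allele}: non-positive control mean"
                )
            ratios[allele].append(targeting.mean() / control_mean)
    return {a: np.asarray(v) for a, v in ratios.items()}


def binding_test(ratios_for_one_allele: Sequence[float]) -> tuple[float, float]:
    """One-sample t of the normalized ratios against 1, one-tailed with
    alternative mean < 1 (binding suppresses expression)."""
    ratios = np.asarray(ratios_for_one_allele, dtype=float)
    if ratios.size < 2:
        raise DataError("binding_test needs >= 2 ratios")
    if ratios.std(ddof=1) == 0 and ratios.mean() == 1.0:
        return 0.0, 0.5  # degenerate: every ratio exactly at the null
    t, p = stats.ttest_1samp(ratios, popmean=1.0, alternative="less")
    return float(t), float(p)


def allele_test(
    ratios_ref: Sequence[float],
    ratios_alt: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t (Welch by default), two-sided P."""
    a = np.asarray(ratios_ref, dtype=float)
    b = np.asarray(ratios_alt, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("allele_test needs >= 2 ratios per allele")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def percent_point_difference(mean_alt: float, mean_ref: float) -> float:
    """Difference of control-normalized means, in percentage points."""
    if mean_alt <= 0 or mean_ref <= 0:
        raise DataError("normalized means must be positive")
    return (mean_alt - mean_ref) * 100.0


def analyze_reporter(
    dataset: ReporterDataset,
    sd_k: float = 3.0,
    equal_var: bool = False,
    filter_first: bool = True,
) -> ReporterResult:
    """Full reporter analysis: filter, normalize, test, summarize."""
    ratios = normalize_to_control(dataset, sd_k=sd_k, filter_first=filter_first)
    means = {a: float(ratios[a].mean()) for a in ALLELES}
    sems = {
        a: float(ratios[a].std(ddof=1) / np.sqrt(ratios[a].size)) for a in ALLELES
    }
    binding = {a: binding_test(ratios[a]) for a in ALLELES}
    t, p = allele_test(ratios["ref"], ratios["alt"], equal_var=equal_var)
    return ReporterResult(
        ratios=ratios,
        means=means,
        sems=sems,
        binding=binding,
        allele_t=t,
        allele_p=p,
        percent_point_difference=percent_point_difference(means["alt"], means["ref"]),
    )


def read_plates(path: str | Path) -> ReporterDataset:
    """CSV with columns experiment, allele, mirna, replicate, value."""
    df = pd.read_csv(path)
    required = {"experiment", "allele", "mirna", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return ReporterDataset.from_frame(df)


def write_plates(dataset: ReporterDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)
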