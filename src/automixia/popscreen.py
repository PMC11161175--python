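"""Population heterozygosity screen with a generalized ESD outlier test.

Reduced-representation (RAD-seq) cohorts are screened for individuals whose
percent heterozygosity at average-coverage sites is anomalously low — the
population-level signature of parthenogenetic origin. Individuals below a
coverage gate are dropped, percent heterozygosity is computed per individual,
and extreme values are tested with the generalized extreme studentized
deviate (Rosner) procedure, usually on the log scale and within species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .hetscan import percent_from_counts

SCREEN_COLUMNS = ("id", "species", "mean_coverage", "n_het", "n_considered")


@dataclass(frozen=True)
class ESDResult:
    """Trace of the generalized ESD iterations.

    ``r_stats[i]`` and ``critical_values[i]`` are R_{i+1} and lambda_{i+1};
    ``removed_indices`` are positions in the input array in removal order.
    The declared outliers are the first ``n_outliers`` removed points.
    """

    r_stats: np.ndarray
    critical_values: np.ndarray
    removed_indices: np.ndarray
    n_outliers: int
    alpha: float
    log_transformed: bool

    @property
    def outlier_indices(self) -> np.ndarray:
        return self.removed_indices[: self.n_outliers]


@lru_cache(maxsize=None)
def esd_critical_values(n: int, max_outliers: int, alpha: float) -> tuple[float, ...]:
    """Critical values lambda_i, i = 1..k, from Student-t quantiles.

    lambda_i = (n - i) * t_{p, n-i-1} / sqrt((n - i - 1 + t^2) (n - i + 1))
    with p = 1 - alpha / (2 (n - i + 1)).
    """
    lams = []
    for i in range(1, max_outliers + 1):
        df = n - i - 1
        p = 1 - alpha / (2 * (n - i + 1))
        t = stats.t.ppf(p, df)
        lams.append((n - i) * t / np.sqrt((df + t**2) * (n - i + 1)))
    return tuple(lams)


def rosner_esd(
    values,
    max_outliers: int,
    alpha: float = 0.05,
    log_transform: bool = False,
) -> ESDResult:
    """Generalized ESD test for up to ``max_outliers`` outliers.

    Iteratively removes the point with the largest studentized absolute
    deviation, recording R_i, and declares the largest i with R_i exceeding
    its critical value. With ``log_transform`` the test runs on log values;
    zeros are substituted by half the smallest positive value (with a
    warning) so fully homozygous individuals remain testable.
    """
    x = np.asarray(values, dtype=float).copy()
    n = len(x)
    if max_outliers < 1:
        raise ValueError("max_outliers must be >= 1")
    if n <= max_outliers + 1:
        raise ValueError("need n > max_outliers + 1 observations")
    if log_transform:
        if (x < 0).any():
            raise ValueError("log transform requires non-negative values")
        if (x == 0).any():
            pos = x[x > 0]
            if len(pos) == 0:
                raise ValueError("all values are zero; nothing to log-transform")
            warnings.warn(
                "zero values replaced by half the smallest positive value before log",
                stacklevel=2,
            )
            x[x == 0] = pos.min() / 2
        x = np.log(x)

    remaining = np.arange(n)
    work = x.copy()
    r_stats, removed = [], []
    for _ in range(max_outliers):
        mean = work.mean()
        sd = work.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance among remaining values")
        dev = np.abs(work - mean)
        j = int(np.argmax(dev))
        r_stats.append(dev[j] / sd)
        removed.append(int(remaining[j]))
        work = np.delete(work, j)
        remaining = np.delete(remaining, j)

    lams = np.array(esd_critical_values(n, max_outliers, alpha))
    r = np.array(r_stats)
    exceed = np.nonzero(r > lams)[0]
    n_outliers = int(exceed[-1] + 1) if len(exceed) else 0
    return ESDResult(
        r_stats=r,
        critical_values=lams,
        removed_indices=np.array(removed),
        n_outliers=n_outliers,
        alpha=alpha,
        log_transformed=log_transform,
    )


def screen_individuals(
    summaries: pd.DataFrame, min_coverage: float = 20.0
) -> pd.DataFrame:
    """Coverage-gate a cohort and compute per-individual percent heterozygosity.

    ``summaries`` needs columns id, species, mean_coverage, n_het and
    n_considered (heterozygous and total positions at average coverage).
    Individuals with mean coverage below ``min_coverage`` are excluded.
    """
    missing = [c for c in SCREEN_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"summary table lacks columns: {missing}")
    if len(summaries) == 0:
        raise ValueError("empty summary table")
    kept = summaries[summaries["mean_coverage"] >= min_coverage].copy()
    if len(kept) == 0:
        raise ValueError(f"no individuals reach the coverage gate of {min_coverage}")
    kept["percent_heterozygosity"] = [
        percent_from_counts(h, t) for h, t in zip(kept["n_het"], kept["n_considered"])
    ]
    return kept.reset_index(drop=True)


def flag_low_heterozygosity(
    table: pd.DataFrame, threshold_percent: float = 0.05
) -> list[str]:
    """Ids of individuals below an absolute percent-heterozygosity threshold."""
    if len(table) == 0:
        raise ValueError("empty screen table")
    mask = table["percent_heterozygosity"] < threshold_percent
    return list(table.loc[mask, "id"])


def outlier_screen(
    table: pd.DataFrame,
    max_outliers: int = 5,
    alpha: float = 0.05,
    log_transform: bool = True,
    per_species: bool = True,
    side: str = "low",
) -> tuple[list[str], dict[str, ESDResult]]:
    """Run the generalized ESD test over a screened cohort.

    By default the test runs within each species on log-transformed percent
    heterozygosity. The ESD statistic is two-sided; because parthenogenesis
    can only depress heterozygosity, detected outliers are post-filtered to
    the requested ``side`` ("low", "high" or "both").
    """
    if side not in ("low", "high", "both"):
        raise ValueError("side must be 'low', 'high' or 'both'")
    groups = table.groupby("species") if per_species else [("all", table)]
    flagged: list[str] = []
    results: dict[str, ESDResult] = {}
    for name, grp in groups:
        vals = grp["percent_heterozygosity"].to_numpy()
        if len(vals) <= max_outliers + 1:
            continue
        res = rosner_esd(vals, max_outliers, alpha=alpha, log_transform=log_transform)
        results[str(name)] = res
        if res.n_outliers:
            med = np.median(vals)
            for idx in res.outlier_indices:
                v = vals[idx]
                if side == "both" or (side == "low" and v < med) or (side == "high" and v > med):
                    flagged.append(str(grp["id"].iloc[idx]))
    return flagged, results
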