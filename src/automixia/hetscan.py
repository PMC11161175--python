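"""Allele-balance heterozygosity calling and window aggregation.

The caller reproduces a deliberately stringent pileup rule: a site is
heterozygous if and only if it is covered by an even number of reads with
exactly two alleles supported by the same number of reads; odd-coverage
sites are discarded. In ``mean_coverage`` mode the analysis is further
restricted to sites whose coverage equals the sample mean rounded up to the
next even integer, which suppresses the apparent heterozygosity created by
collapsed repeats at above-average coverage. Heterozygous-site counts are
aggregated in fixed-width genome windows (10 kb by default) and summarised
as a percent of considered sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simgenome import BASES, GenomeMap, OffspringGenome, MaternalGenotype

CALL_MODES = ("even_split", "mean_coverage")


@dataclass(frozen=True)
class HetCallConfig:
    """Parameters of the heterozygosity caller.

    mean_coverage_value overrides the mean computed from the pileup (use it
    to reproduce a published x̄); target_override bypasses the even rounding.
    """

    mode: str = "even_split"
    window_size: int = 10_000
    window_step: int | None = None
    mean_coverage_value: float | None = None
    target_override: int | None = None

    def __post_init__(self):
        if self.mode not in CALL_MODES:
            raise ValueError(f"unknown calling mode {self.mode!r}")
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        step = self.window_step if self.window_step is not None else self.window_size
        if not 0 < step <= self.window_size:
            raise ValueError("window_step must satisfy 0 < step <= window_size")

    @property
    def step(self) -> int:
        return self.window_step if self.window_step is not None else self.window_size


@dataclass
class HetCallResult:
    """Per-site heterozygosity flags plus summary counts.

    ``sites`` has columns chrom, pos, coverage, considered, is_het; only
    considered sites can be flagged. ``window_counts`` is filled by
    :func:`window_counts` (chrom, start, end, count).
    """

    mode: str
    mean_cov: float
    target_coverage: int | None
    sites: pd.DataFrame
    n_het_sites: int
    n_sites_considered: int
    n_triallelic: int = 0
    window_counts: pd.DataFrame | None = None


def mean_coverage(pileup: pd.DataFrame) -> float:
    """Arithmetic mean of per-site read coverage over all pileup records."""
    if len(pileup) == 0:
        raise ValueError("cannot compute mean coverage of an empty pileup")
    return float(pileup[list(BASES)].to_numpy().sum(axis=1).mean())


def target_coverage(mean: float) -> int:
    """Smallest even integer >= mean (e.g. a mean of 18.31 targets 20)."""
    if mean <= 0:
        raise ValueError("mean coverage must be > 0")
    c = math.ceil(mean)
    return c + 1 if c % 2 else c


def call_het_sites(pileup: pd.DataFrame, config: HetCallConfig = HetCallConfig()) -> HetCallResult:
    """Flag heterozygous sites under the equal-split coverage rule.

    even_split mode considers every even-coverage site; mean_coverage mode
    considers only sites whose coverage equals the even-rounded mean, so both
    the numerator and denominator of downstream percentages are restricted to
    that coverage stratum.
    """
    counts = pileup[list(BASES)].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative read counts in pileup")
    cov = counts.sum(axis=1)
    n_alleles = (counts > 0).sum(axis=1)
    equal_split = (n_alleles == 2) & (cov % 2 == 0) & (2 * counts.max(axis=1) == cov)

    mean_cov = mean_coverage(pileup) if len(pileup) else 0.0
    if config.mode == "mean_coverage":
        xbar = (
            config.mean_coverage_value if config.mean_coverage_value is not None else mean_cov
        )
        tc = config.target_override if config.target_override is not None else target_coverage(xbar)
        considered = cov == tc
    else:
        tc = None
        considered = cov % 2 == 0

    is_het = equal_split & considered
    sites = pd.DataFrame(
        {
            "chrom": pileup["chrom"].to_numpy(),
            "pos": pileup["pos"].to_numpy(),
            "coverage": cov,
            "considered": considered,
            "is_het": is_het,
        }
    )
    return HetCallResult(
        mode=config.mode,
        mean_cov=mean_cov,
        target_coverage=tc,
        sites=sites,
        n_het_sites=int(is_het.sum()),
        n_sites_considered=int(considered.sum()),
        n_triallelic=int((n_alleles > 2).sum()),
    )


def calls_from_genotype(individual: OffspringGenome | MaternalGenotype) -> HetCallResult:
    """Idealised calls taken directly from a simulated genotype (no reads).

    Useful as ground truth when validating the pileup-based caller and the
    mechanism classifier: every site is considered and flagged by its true
    zygosity.
    """
    frame = individual.to_frame()
    sites = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "pos": frame["pos"],
            "coverage": 0,
            "considered": True,
            "is_het": frame["is_het"].to_numpy(),
        }
    )
    return HetCallResult(
        mode="genotype",
        mean_cov=float("nan"),
        target_coverage=None,
        sites=sites,
        n_het_sites=int(frame["is_het"].sum()),
        n_sites_considered=len(frame),
    )


def window_counts(
    calls: HetCallResult | pd.DataFrame,
    genome_map: GenomeMap,
    window_size: int = 10_000,
    window_step: int | None = None,
) -> pd.DataFrame:
    """Count flagged heterozygous sites in half-open genome windows.

    Windows ``[start, start + size)`` are stepped by ``window_step`` (default:
    tumbling windows, step == size, in which case counts sum to the total
    number of flagged sites). Reported ends are clipped to chromosome length.
    """
    step = window_step if window_step is not None else window_size
    if window_size <= 0 or not 0 < step <= window_size:
        raise ValueError("invalid window parameters")
    sites = calls.sites if isinstance(calls, HetCallResult) else calls
    known = set(genome_map.names)
    unknown = set(sites["chrom"].unique()) - known
    if unknown:
        raise ValueError(f"sites on chromosomes absent from the genome map: {sorted(unknown)}")
    het = sites[sites["is_het"].astype(bool)]
    frames = []
    for chrom in genome_map:
        pos = np.sort(het.loc[het["chrom"] == chrom.name, "pos"].to_numpy())
        starts = np.arange(0, chrom.length, step, dtype=np.int64)
        upper = starts + window_size
        cnt = np.searchsorted(pos, upper, side="left") - np.searchsorted(pos, starts, side="left")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom.name,
                    "start": starts,
                    "end": np.minimum(upper, chrom.length),
                    "count": cnt,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if isinstance(calls, HetCallResult):
        calls.window_counts = out
    return out


def percent_from_counts(n_het: int, n_considered: int) -> float:
    """Heterozygous positions as a percent of all considered positions."""
    if n_considered <= 0:
        raise ValueError("no considered sites: percent heterozygosity undefined")
    return 100.0 * n_het / n_considered


def percent_heterozygosity(calls: HetCallResult) -> float:
    """Percent of considered sites called heterozygous."""
    return percent_from_counts(calls.n_het_sites, calls.n_sites_considered)
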