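"""Mechanism inference from spatial heterozygosity patterns.

The three mechanisms that can restore diploidy in an unfertilised egg leave
different spatial fingerprints in offspring heterozygosity relative to the
mother: central automixis (first-polar-body fusion) retains heterozygosity
near centromeres, terminal automixis (second-polar-body fusion) retains it
near chromosome termini, and post-meiotic gamete duplication erases it
everywhere. This module turns those qualitative expectations into three
statistics — genome-wide retained fraction, a centromere-distance retention
profile, and a window-level interspersion statistic — and a rule-based
classifier over them, validated against an exact enumeration oracle of
single-meiosis chromatid/fusion configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .hetscan import HetCallResult
from .simgenome import (
    GenomeMap,
    MaternalGenotype,
    REPRODUCTION_MODES,
    as_rng,
    derive_paternal_genome,
    make_offspring,
    simulate_meiosis,
)

MECHANISM_LABELS = (
    "sexual",
    "central_automixis",
    "terminal_automixis",
    "post_meiotic_duplication",
    "indeterminate",
)

#: true simulation mode -> classifier label
MODE_TO_LABEL = {
    "sexual": "sexual",
    "central_automixis": "central_automixis",
    "terminal_automixis": "terminal_automixis",
    "gamete_duplication": "post_meiotic_duplication",
}


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds, set from the observed contrasts between
    parthenogenetic offspring and their mothers (FP heterozygous-site counts
    of a few percent of maternal counts; regional window maxima below half
    the maternal level)."""

    sexual_retained: float = 0.8
    sexual_interspersion: float = 0.8
    duplication_retained: float = 0.05
    duplication_interspersion: float = 0.05
    window_ratio: float = 0.5


DEFAULT_THRESHOLDS = ClassifierThresholds()


@dataclass(frozen=True)
class RetentionProfile:
    """Heterozygosity retention binned by normalised centromere distance.

    ``site_distances``/``site_retained`` keep the unbinned per-site values;
    the classifier's rank trend is computed on these (the fine-bin limit of
    the profile, naturally weighted by bin occupancy) so the call does not
    depend on the bin count chosen for display.
    """

    bin_edges: np.ndarray
    retention: np.ndarray  # NaN where a bin holds no maternal het sites
    n_maternal: np.ndarray
    retained_fraction: float
    site_distances: np.ndarray | None = None
    site_retained: np.ndarray | None = None


@dataclass(frozen=True)
class MechanismCall:
    label: str
    retained_fraction: float
    interspersion: float
    trend_statistic: float  # Spearman rho of retention vs distance; NaN if unused

    def __post_init__(self):
        if self.label not in MECHANISM_LABELS:
            raise ValueError(f"unknown mechanism label {self.label!r}")


def _aligned_site_tables(off: pd.DataFrame, mat: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two site tables on (chrom, pos), with a fast path for the
    common simulated case of identical site grids."""
    if len(off) == len(mat) and np.array_equal(
        off["pos"].to_numpy(), mat["pos"].to_numpy()
    ) and np.array_equal(off["chrom"].to_numpy(), mat["chrom"].to_numpy()):
        return pd.DataFrame(
            {
                "considered_off": off["considered"].to_numpy(),
                "is_het_off": off["is_het"].to_numpy(),
                "considered_mat": mat["considered"].to_numpy(),
                "is_het_mat": mat["is_het"].to_numpy(),
            }
        )
    merged = off.merge(mat, on=["chrom", "pos"], suffixes=("_off", "_mat"))
    return merged


def retained_fraction(
    offspring_calls: HetCallResult, maternal_calls: HetCallResult
) -> float:
    """Offspring heterozygous-site count over the mother's, on the sites
    considered in both call sets."""
    merged = _aligned_site_tables(offspring_calls.sites, maternal_calls.sites)
    both = merged["considered_off"].to_numpy() & merged["considered_mat"].to_numpy()
    mat_het = int((merged["is_het_mat"].to_numpy() & both).sum())
    if mat_het == 0:
        raise ValueError("mother has no heterozygous calls on the jointly considered sites")
    off_het = int((merged["is_het_off"].to_numpy() & both).sum())
    return off_het / mat_het


def centromere_profile(
    offspring_calls: HetCallResult,
    maternal: MaternalGenotype,
    genome_map: GenomeMap | None = None,
    n_bins: int = 10,
) -> RetentionProfile:
    """Bin offspring heterozygosity retention by distance from the centromere.

    Distance is normalised per chromosome by its longer arm, so bins partition
    [0, 1]. Retention in a bin is the fraction of the mother's heterozygous
    sites (restricted to sites the offspring caller considered) still called
    heterozygous in the offspring.
    """
    genome_map = genome_map if genome_map is not None else maternal.genome_map
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    for chrom in genome_map:
        if not 0 < chrom.centromere_pos < chrom.length:
            raise ValueError(
                "centromere positions unknown; use the interspersion statistic instead"
            )
    off = offspring_calls.sites
    dist_parts, het_parts = [], []
    for chrom in genome_map:
        block = maternal.sites.get(chrom.name)
        if block is None:
            continue
        het_mask = block.is_het
        pos = block.pos[het_mask]
        sub = off[off["chrom"] == chrom.name]
        off_pos = sub["pos"].to_numpy()
        if len(off_pos) == len(block.pos) and np.array_equal(off_pos, block.pos):
            considered = sub["considered"].to_numpy()[het_mask]
            is_het = sub["is_het"].to_numpy()[het_mask]
        else:
            considered = np.zeros(len(pos), dtype=bool)
            is_het = np.zeros(len(pos), dtype=bool)
            if len(off_pos):
                idx = np.clip(np.searchsorted(off_pos, pos), 0, len(off_pos) - 1)
                hit = off_pos[idx] == pos
                considered[hit] = sub["considered"].to_numpy()[idx[hit]]
                is_het[hit] = sub["is_het"].to_numpy()[idx[hit]]
        keep = considered
        d = np.abs(pos[keep] - chrom.centromere_pos) / chrom.max_arm_length
        dist_parts.append(np.clip(d, 0.0, 1.0))
        het_parts.append(is_het[keep])
    dist = np.concatenate(dist_parts) if dist_parts else np.array([])
    het = np.concatenate(het_parts) if het_parts else np.array([], dtype=bool)
    if len(dist) == 0:
        raise ValueError("no maternal heterozygous sites available for a profile")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(dist, edges[1:-1]), 0, n_bins - 1)
    n_mat = np.bincount(which, minlength=n_bins).astype(float)
    n_ret = np.bincount(which, weights=het.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        retention = np.where(n_mat > 0, n_ret / np.maximum(n_mat, 1), np.nan)
    return RetentionProfile(
        bin_edges=edges,
        retention=retention,
        n_maternal=n_mat.astype(int),
        retained_fraction=float(n_ret.sum() / n_mat.sum()),
        site_distances=dist,
        site_retained=het,
    )


def interspersion_statistic(
    offspring_windows: pd.DataFrame,
    maternal_windows: pd.DataFrame,
    ratio_threshold: float = 0.5,
) -> float:
    """Fraction of maternal-heterozygosity windows the offspring matches.

    Among windows where the mother has at least one heterozygous call, the
    fraction in which the offspring count reaches ``ratio_threshold`` times
    the maternal count. Automictic offspring should match in retained regions
    (value near the retained genome fraction); duplication offspring match
    almost nowhere.
    """
    key = ["chrom", "start", "end"]
    if len(offspring_windows) != len(maternal_windows) or not all(
        np.array_equal(offspring_windows[c].to_numpy(), maternal_windows[c].to_numpy())
        for c in key
    ):
        raise ValueError("offspring and maternal window grids differ")
    mat = maternal_windows["count"].to_numpy()
    off = offspring_windows["count"].to_numpy()
    informative = mat >= 1
    if not informative.any():
        raise ValueError("mother has no windows with heterozygous calls")
    return float((off[informative] >= ratio_threshold * mat[informative]).mean())


def classify_mechanism(
    retained_fraction: float,
    interspersion: float,
    profile: RetentionProfile | None = None,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> MechanismCall:
    """Rule-based mechanism call from the three summary statistics.

    Sexual reproduction preserves both the amount and the spatial pattern of
    maternal heterozygosity (high retained fraction and interspersion);
    post-meiotic duplication erases both. Between those extremes the sign of
    the rank trend of retention against centromere distance separates central
    (decreasing) from terminal (increasing) automixis; without centromere
    information the call is indeterminate rather than a guess.
    """
    rho = float("nan")
    if (
        retained_fraction >= thresholds.sexual_retained
        and interspersion >= thresholds.sexual_interspersion
    ):
        label = "sexual"
    elif (
        retained_fraction <= thresholds.duplication_retained
        and interspersion <= thresholds.duplication_interspersion
    ):
        label = "post_meiotic_duplication"
    elif profile is not None:
        if (
            profile.site_distances is not None
            and profile.site_retained is not None
            and len(profile.site_distances) >= 3
            and len(set(profile.site_retained.tolist())) > 1
        ):
            rho = float(
                spearmanr(profile.site_distances, profile.site_retained.astype(float)).statistic
            )
        else:
            valid = ~np.isnan(profile.retention) & (profile.n_maternal > 0)
            centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
            if valid.sum() >= 3:
                rho = float(spearmanr(centers[valid], profile.retention[valid]).statistic)
        if np.isnan(rho) or rho == 0:
            label = "indeterminate"
        elif rho < 0:
            label = "central_automixis"
        else:
            label = "terminal_automixis"
    else:
        label = "indeterminate"
    return MechanismCall(label, float(retained_fraction), float(interspersion), rho)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------


def retention_oracle(mode: str, n_crossovers: int) -> float:
    """Exact heterozygosity-retention probability at a single site.

    ``n_crossovers`` counts crossovers between the centromere and the site.
    All chromatid-involvement choices (one chromatid of each homolog per
    crossover) and fusion choices (meiosis I/II segregation, polar-body
    product) are enumerated with equal weight. Exact only for small crossover
    counts; use the Monte Carlo simulator beyond 3.
    """
    if mode not in REPRODUCTION_MODES:
        raise ValueError(f"unknown reproduction mode {mode!r}")
    if n_crossovers < 0:
        raise ValueError("n_crossovers must be >= 0")
    if mode == "sexual":
        return 1.0  # paternal gamete always contributes a non-maternal allele
    if mode == "gamete_duplication":
        return 0.0
    if n_crossovers > 3:
        raise ValueError("exact enumeration supports at most 3 crossovers; use Monte Carlo")

    prob = 0.0
    n_config = 4**n_crossovers
    for choices in product(range(4), repeat=n_crossovers):
        origin = [0, 0, 1, 1]  # chromatids 0,1 share centromere A; 2,3 share B
        for c in choices:
            i, j = c // 2, 2 + c % 2
            origin[i], origin[j] = origin[j], origin[i]
        for pair in (0, 1):  # meiosis I outcome
            for e in (0, 1):  # meiosis II outcome
                egg = 2 * pair + e
                if mode == "terminal_automixis":
                    partners = [2 * pair + (1 - e)]
                else:  # central: either first-polar-body chromatid
                    other = 1 - pair
                    partners = [2 * other, 2 * other + 1]
                w = 1.0 / (n_config * 4 * len(partners))
                for p in partners:
                    if origin[egg] != origin[p]:
                        prob += w
    return prob


def expected_retention(
    mode: str,
    crossover_positions: Sequence[float],
    site_positions: Sequence[float],
    centromere_pos: float,
) -> np.ndarray:
    """Oracle retention for sites on one chromosome with fixed crossovers.

    A crossover is proximal to a site when it lies on the same arm, strictly
    between centromere and site; only proximal crossovers affect retention.
    """
    xs = np.asarray(crossover_positions, dtype=float)
    out = []
    for s in site_positions:
        same_arm = (xs - centromere_pos) * (s - centromere_pos) > 0
        proximal = same_arm & (np.abs(xs - centromere_pos) < abs(s - centromere_pos))
        out.append(retention_oracle(mode, int(proximal.sum())))
    return np.asarray(out)


def retention_monte_carlo(
    maternal: MaternalGenotype,
    mode: str,
    n_meioses: int,
    seed=None,
    *,
    crossover_rate: float = 2.5,
    obligate_crossover: bool = True,
    forced_crossovers: Mapping[str, Sequence[int]] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Empirical per-site heterozygosity retention over repeated meioses.

    Returns, per chromosome, the fraction of meioses in which each maternal
    heterozygous site stayed heterozygous in the offspring. Genotypes are read
    directly (no sequencing noise), so this estimates the purely meiotic
    retention probability that :func:`retention_oracle` computes exactly.
    """
    if n_meioses < 1:
        raise ValueError("n_meioses must be >= 1")
    rng = rng if rng is not None else as_rng(seed)
    paternal = derive_paternal_genome(maternal) if mode == "sexual" else None
    het_masks = {name: block.is_het for name, block in maternal.sites.items()}
    acc = {
        name: np.zeros(int(mask.sum()), dtype=np.int64) for name, mask in het_masks.items()
    }
    for _ in range(n_meioses):
        tetrad = simulate_meiosis(
            maternal,
            crossover_rate,
            obligate_crossover,
            forced_crossovers=forced_crossovers,
            rng=rng,
        )
        off = make_offspring(tetrad, mode, maternal, paternal, rng=rng)
        for name, mask in het_masks.items():
            block = off.sites[name]
            acc[name] += (block.allele1 != block.allele2)[mask]
    return {name: counts / n_meioses for name, counts in acc.items()}
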