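"""Plain-text readers/writers, run configuration and the end-to-end pipeline.

Every format is diffable text: pileups and screen tables as TSV, window
tracks as BED (0-based half-open), microsatellite panels and colony records
as CSV, genotypes as a VCF-like table, summaries as JSON. Writers can embed
metadata (seed, config hash) as leading ``#`` comment lines, which readers
skip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hetscan import HetCallConfig, HetCallResult, call_het_sites, window_counts
from .mechinfer import (
    ClassifierThresholds,
    MODE_TO_LABEL,
    MechanismCall,
    centromere_profile,
    classify_mechanism,
    interspersion_statistic,
    retained_fraction,
)
from .msparent import MSPanel
from .simgenome import (
    BASES,
    GenomeMap,
    MaternalGenotype,
    REPRODUCTION_MODES,
    SiteBlock,
    acrocentric_karyotype,
    as_rng,
    derive_paternal_genome,
    make_offspring,
    simulate_maternal_genome,
    simulate_meiosis,
    simulate_pileups,
)

PILEUP_COLUMNS = ("chrom", "pos", *BASES)


def _write_table(df: pd.DataFrame, path, sep: str, header: bool, metadata=None):
    path = Path(path)
    with open(path, "w") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep=sep, index=False, header=header)


def write_pileup(pileup: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """Write a pileup as TSV with columns chrom, pos, A, C, G, T."""
    _write_table(pileup[list(PILEUP_COLUMNS)], path, "\t", True, metadata)


def read_pileup(path) -> pd.DataFrame:
    """Read and validate a pileup TSV; malformed rows are reported by line."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pileup lacks columns {missing}")
    unknown = [c for c in df.columns if c not in PILEUP_COLUMNS]
    if unknown:
        raise ValueError(
            f"{path}: unknown base or column symbols {unknown}; expected {list(PILEUP_COLUMNS)}"
        )
    counts = df[list(BASES)]
    bad = counts.isna().any(axis=1) | (counts < 0).any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed pileup record at line {line}")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        line = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: duplicate position at line {line}")
    df[list(BASES)] = counts.astype(np.int64)
    df["pos"] = df["pos"].astype(np.int64)
    return df


def write_bed(windows: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """Write a window track as BED4 (chrom, start, end, count), half-open."""
    _write_table(windows[["chrom", "start", "end", "count"]], path, "\t", False, metadata)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["chrom", "start", "end", "count"], header=None
    )
    if ((df["start"] < 0) | (df["end"] <= df["start"])).any():
        bad = df[(df["start"] < 0) | (df["end"] <= df["start"])].index[0]
        raise ValueError(f"{path}: coordinate violation at line {int(bad) + 1}")
    return df


def write_panels(panels: Sequence[MSPanel], path, metadata: Mapping | None = None) -> None:
    """Write microsatellite panels as CSV (individual, locus, allele1, allele2)."""
    rows = [
        {"individual": p.individual_id, "locus": locus, "allele1": a, "allele2": b}
        for p in panels
        for locus, (a, b) in p.genotypes.items()
    ]
    _write_table(pd.DataFrame(rows), path, ",", True, metadata)


def read_panels(path) -> list[MSPanel]:
    df = pd.read_csv(path, comment="#")
    need = {"individual", "locus", "allele1", "allele2"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: panel CSV needs columns {sorted(need)}")
    panels = []
    for ind, grp in df.groupby("individual", sort=False):
        geno = {
            str(r.locus): (int(r.allele1), int(r.allele2)) for r in grp.itertuples()
        }
        panels.append(MSPanel(str(ind), geno))
    return panels


def write_genotypes(individual, path, metadata: Mapping | None = None) -> None:
    """Write a diploid genotype as a VCF-like table (CHROM, POS, REF, ALT, GT)."""
    frame = individual.to_frame() if hasattr(individual, "to_frame") else individual
    het = frame["allele1"] != frame["allele2"]
    out = pd.DataFrame(
        {
            "CHROM": frame["chrom"],
            "POS": frame["pos"],
            "REF": frame["allele1"],
            "ALT": np.where(het, frame["allele2"], "."),
            "GT": np.where(het, "0/1", "0/0"),
        }
    )
    _write_table(out, path, "\t", True, metadata)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    het = df["GT"] == "0/1"
    return pd.DataFrame(
        {
            "chrom": df["CHROM"],
            "pos": df["POS"].astype(np.int64),
            "allele1": df["REF"],
            "allele2": np.where(het, df["ALT"], df["REF"]),
            "is_het": het,
        }
    )


def save_het_result(result: HetCallResult, prefix, metadata: Mapping | None = None) -> None:
    """Persist a het-call result as <prefix>.sites.tsv, .json and .windows.bed."""
    prefix = str(prefix)
    _write_table(result.sites, f"{prefix}.sites.tsv", "\t", True, metadata)
    if result.window_counts is not None:
        write_bed(result.window_counts, f"{prefix}.windows.bed", metadata)
    summary = {
        "mode": result.mode,
        "mean_coverage": result.mean_cov,
        "target_coverage": result.target_coverage,
        "n_het_sites": result.n_het_sites,
        "n_sites_considered": result.n_sites_considered,
        "n_triallelic": result.n_triallelic,
    }
    if metadata:
        summary.update(metadata)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def load_het_result(prefix) -> HetCallResult:
    prefix = str(prefix)
    with open(f"{prefix}.json") as fh:
        summary = json.load(fh)
    sites = pd.read_csv(f"{prefix}.sites.tsv", sep="\t", comment="#")
    windows = None
    if Path(f"{prefix}.windows.bed").exists():
        windows = read_bed(f"{prefix}.windows.bed")
    return HetCallResult(
        mode=summary["mode"],
        mean_cov=summary["mean_coverage"],
        target_coverage=summary["target_coverage"],
        sites=sites,
        n_het_sites=summary["n_het_sites"],
        n_sites_considered=summary["n_sites_considered"],
        n_triallelic=summary.get("n_triallelic", 0),
        window_counts=windows,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_COHORT_DEFAULTS = {
    "modes": list(REPRODUCTION_MODES),
    "n_per_mode": 10,
    "het_density": 5e-3,
    "hom_density": 0.0,
    "crossover_rate": 2.5,
    "obligate_crossover": True,
    "mean_coverage": 20.0,
    "error_rate": 1e-3,
}

_HETSCAN_KEYS = {"mode", "window_size", "window_step", "mean_coverage_value", "target_override"}
_CLASSIFY_KEYS = {
    "sexual_retained",
    "sexual_interspersion",
    "duplication_retained",
    "duplication_interspersion",
    "window_ratio",
}
_TOP_KEYS = {"seed", "out_dir", "genome", "cohort", "hetscan", "classify"}


def _check_keys(block: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated pipeline configuration; the seed is stamped on every output."""

    seed: int
    genome_map: GenomeMap
    cohort: dict
    hetscan: HetCallConfig
    thresholds: ClassifierThresholds
    out_dir: str | None = None
    raw: dict = field(default_factory=dict)

    @property
    def sha(self) -> str:
        return config_hash(self.raw)


def config_hash(raw: Mapping) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    payload = {k: v for k, v in raw.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def build_config(raw: Mapping) -> RunConfig:
    """Build and validate a RunConfig from a plain mapping (YAML contents)."""
    _check_keys(raw, _TOP_KEYS, "top level")
    seed = int(raw.get("seed", 0))
    if "genome" in raw:
        genome = GenomeMap.from_records(raw["genome"])
    else:
        genome = acrocentric_karyotype()
    cohort = dict(_COHORT_DEFAULTS)
    if "cohort" in raw:
        _check_keys(raw["cohort"], set(_COHORT_DEFAULTS), "cohort")
        cohort.update(raw["cohort"])
    for mode in cohort["modes"]:
        if mode not in REPRODUCTION_MODES:
            raise ValueError(f"unknown reproduction mode in config: {mode!r}")
    hs_block = dict(raw.get("hetscan", {}))
    _check_keys(hs_block, _HETSCAN_KEYS, "hetscan")
    hetscan = HetCallConfig(**hs_block)
    cl_block = dict(raw.get("classify", {}))
    _check_keys(cl_block, _CLASSIFY_KEYS, "classify")
    thresholds = ClassifierThresholds(**cl_block)
    return RunConfig(
        seed=seed,
        genome_map=genome,
        cohort=cohort,
        hetscan=hetscan,
        thresholds=thresholds,
        out_dir=raw.get("out_dir"),
        raw=dict(raw),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return build_config(raw)


def default_config(seed: int = 0, **overrides) -> RunConfig:
    raw = {"seed": seed, **overrides}
    return build_config(raw)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    summary: dict
    mother_calls: HetCallResult


def run_pipeline(config: RunConfig | str) -> PipelineResult:
    """Simulate a cohort, call heterozygosity, and classify each offspring.

    One maternal genome is simulated, then ``n_per_mode`` offspring per
    requested reproduction mode; each offspring's pileup is called, windowed,
    compared against the mother (retained fraction, centromere profile,
    interspersion) and classified. Deterministic under a fixed seed.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    rng = as_rng(config.seed)
    co = config.cohort
    stage = "simulate maternal genome"
    try:
        mother = simulate_maternal_genome(
            config.genome_map, co["het_density"], hom_density=co["hom_density"], rng=rng
        )
        father = derive_paternal_genome(mother)
        stage = "maternal heterozygosity calls"
        mother_pileup = simulate_pileups(mother, co["mean_coverage"], co["error_rate"], rng=rng)
        mother_calls = call_het_sites(mother_pileup, config.hetscan)
        window_counts(
            mother_calls, config.genome_map, config.hetscan.window_size, config.hetscan.step
        )

        rows = []
        for mode in co["modes"]:
            for i in range(int(co["n_per_mode"])):
                stage = f"offspring {mode}#{i}"
                tetrad = simulate_meiosis(
                    mother, co["crossover_rate"], co["obligate_crossover"], rng=rng
                )
                off = make_offspring(
                    tetrad,
                    mode,
                    mother,
                    father if mode == "sexual" else None,
                    offspring_id=f"{mode}_{i:03d}",
                    rng=rng,
                )
                pileup = simulate_pileups(off, co["mean_coverage"], co["error_rate"], rng=rng)
                calls = call_het_sites(pileup, config.hetscan)
                window_counts(
                    calls, config.genome_map, config.hetscan.window_size, config.hetscan.step
                )
                rf = retained_fraction(calls, mother_calls)
                isp = interspersion_statistic(
                    calls.window_counts,
                    mother_calls.window_counts,
                    config.thresholds.window_ratio,
                )
                profile = centromere_profile(calls, mother, config.genome_map)
                call = classify_mechanism(rf, isp, profile, config.thresholds)
                rows.append(
                    {
                        "offspring_id": off.offspring_id,
                        "true_mode": mode,
                        "expected_label": MODE_TO_LABEL[mode],
                        "label": call.label,
                        "correct": call.label == MODE_TO_LABEL[mode],
                        "retained_fraction": call.retained_fraction,
                        "interspersion": call.interspersion,
                        "trend_statistic": call.trend_statistic,
                        "n_het_calls": calls.n_het_sites,
                    }
                )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from err

    calls_df = pd.DataFrame(rows)
    per_mode = (
        calls_df.groupby("true_mode")["correct"].mean().mul(100).round(2).to_dict()
        if len(calls_df)
        else {}
    )
    summary = {
        "seed": config.seed,
        "config_sha256": config.sha,
        "version": __version__,
        "n_offspring": len(calls_df),
        "n_correct": int(calls_df["correct"].sum()) if len(calls_df) else 0,
        "per_mode_recall_percent": per_mode,
        "mother_n_het_calls": mother_calls.n_het_sites,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"seed": config.seed, "config": config.sha, "version": __version__}
        _write_table(calls_df, out / "mechanism_calls.csv", ",", True, meta)
        save_het_result(mother_calls, out / "mother", meta)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return PipelineResult(calls_df, summary, mother_calls)
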