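"""Microsatellite allele binning, parentage exclusion and colony summaries.

Parentage here is exclusion-based, the way capillary-electrophoresis panels
are scored by eye: a candidate mother must account for the offspring's
alleles, a candidate father is excluded at a locus when he carries none of
the alleles the mother cannot have contributed, and an offspring is called
parthenogenetic (FP) only on the three-part argument — homozygous at every
scored locus, fully maternal-consistent, and every co-housed male excluded
at at least one locus. Single-nucleotide size differences are common binning
artifacts and are merged before scoring.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

PARENTAGE_CALLS = ("FP", "sexual", "ambiguous")


@dataclass(frozen=True)
class MSPanel:
    """One individual's microsatellite genotype: locus -> (size1, size2) in bp."""

    individual_id: str
    genotypes: Mapping[str, tuple[int, int]]

    def __post_init__(self):
        canon = {}
        for locus, pair in self.genotypes.items():
            a, b = int(pair[0]), int(pair[1])
            if a <= 0 or b <= 0:
                raise ValueError(f"{self.individual_id}/{locus}: allele sizes must be > 0")
            canon[locus] = (min(a, b), max(a, b))
        object.__setattr__(self, "genotypes", canon)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.genotypes)

    def alleles(self, locus: str) -> set[int]:
        return set(self.genotypes[locus])

    def is_homozygous(self, locus: str) -> bool:
        a, b = self.genotypes[locus]
        return a == b


@dataclass(frozen=True)
class LocusScore:
    locus: str
    offspring_homozygous: bool
    maternal_consistent: bool
    excluded_fathers: tuple[str, ...]
    informative: bool


@dataclass(frozen=True)
class ParentageResult:
    offspring_id: str
    call: str
    mother_id: str | None
    father_id: str | None
    n_loci_scored: int
    n_homozygous_loci: int
    locus_scores: tuple[LocusScore, ...] = ()
    notes: str = ""

    def __post_init__(self):
        if self.call not in PARENTAGE_CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def bin_alleles(panels: Sequence[MSPanel], tolerance_bp: int = 1) -> list[MSPanel]:
    """Merge allele sizes within ``tolerance_bp`` across the compared panels.

    Within each locus, observed sizes are clustered by single linkage (a gap
    greater than the tolerance starts a new cluster) and every member of a
    cluster is replaced by the cluster's modal size. Chained clusters wider
    than twice the tolerance are left unmerged with a warning, since a single
    binning artifact cannot span them.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    loci = sorted({locus for p in panels for locus in p.loci})
    mapping: dict[str, dict[int, int]] = {}
    for locus in loci:
        observed: list[int] = []
        for p in panels:
            if locus in p.genotypes:
                observed.extend(p.genotypes[locus])
        counts = Counter(observed)
        sizes = sorted(counts)
        mapping[locus] = {}
        cluster: list[int] = []
        for s in sizes + [None]:
            if cluster and (s is None or s - cluster[-1] > tolerance_bp):
                width = cluster[-1] - cluster[0]
                if width > 2 * tolerance_bp:
                    warnings.warn(
                        f"{locus}: allele chain {cluster} wider than {2 * tolerance_bp} bp "
                        "left unmerged",
                        stacklevel=2,
                    )
                    for c in cluster:
                        mapping[locus][c] = c
                else:
                    if width > tolerance_bp:
                        warnings.warn(
                            f"{locus}: single-linkage chain {cluster} merged "
                            f"(width {width} bp at the cap)",
                            stacklevel=2,
                        )
                    modal = max(cluster, key=lambda c: (counts[c], -c))
                    for c in cluster:
                        mapping[locus][c] = modal
                cluster = []
            if s is not None:
                cluster.append(s)
    out = []
    for p in panels:
        geno = {
            locus: (mapping[locus][a], mapping[locus][b])
            for locus, (a, b) in p.genotypes.items()
        }
        out.append(MSPanel(p.individual_id, geno))
    return out


def _mother_scores(offspring: MSPanel, mother: MSPanel):
    """Per-locus compatibility of one candidate mother."""
    shared_all, full_all = True, True
    for locus in offspring.loci:
        if locus not in mother.genotypes:
            continue
        off = offspring.alleles(locus)
        mat = mother.alleles(locus)
        if not off & mat:
            shared_all = False
        if not off <= mat:
            full_all = False
    return shared_all, full_all


def classify_offspring(
    offspring: MSPanel,
    candidate_mothers: Sequence[MSPanel],
    candidate_fathers: Sequence[MSPanel],
    *,
    min_exclusion_loci: int = 1,
    bin_tolerance: int | None = 1,
) -> ParentageResult:
    """Score one offspring panel against co-housed candidate parents.

    With ``bin_tolerance`` set, alleles are binned across the whole comparison
    set first. The FP call requires homozygosity at every scored locus, full
    maternal consistency, and exclusion of every candidate father at at least
    ``min_exclusion_loci`` loci. A heterozygous offspring is assigned a father
    when exactly one candidate can supply the non-maternal allele at every
    locus. Anything else is ambiguous.
    """
    if not offspring.loci:
        raise ValueError("offspring panel has no scored loci")
    if bin_tolerance is not None:
        binned = bin_alleles(
            [offspring, *candidate_mothers, *candidate_fathers], bin_tolerance
        )
        offspring = binned[0]
        candidate_mothers = binned[1 : 1 + len(candidate_mothers)]
        candidate_fathers = binned[1 + len(candidate_mothers) :]

    n_scored = len(offspring.loci)
    n_hom = sum(offspring.is_homozygous(locus) for locus in offspring.loci)

    compatible = []
    for m in candidate_mothers:
        shared, full = _mother_scores(offspring, m)
        if shared:
            compatible.append((m, full))
    if not compatible:
        return ParentageResult(
            offspring.individual_id,
            "ambiguous",
            None,
            None,
            n_scored,
            n_hom,
            notes="no candidate mother shares an allele at every locus",
        )
    # prefer fully consistent mothers; ties are ambiguous
    full_mothers = [m for m, full in compatible if full]
    pool = full_mothers or [m for m, _ in compatible]
    if len(pool) > 1:
        return ParentageResult(
            offspring.individual_id,
            "ambiguous",
            None,
            None,
            n_scored,
            n_hom,
            notes=f"{len(pool)} candidate mothers equally compatible",
        )
    mother = pool[0]
    mother_full = bool(full_mothers)

    scores = []
    exclusions = {f.individual_id: 0 for f in candidate_fathers}
    for locus in offspring.loci:
        off = offspring.alleles(locus)
        mat = mother.alleles(locus) if locus in mother.genotypes else set()
        # alleles the father must have supplied: those whose partner allele
        # can come from the mother
        pair = offspring.genotypes[locus]
        paternal_candidates = {
            x for i, x in enumerate(pair) if pair[1 - i] in mat
        }
        excluded = []
        informative = bool(paternal_candidates)
        for f in candidate_fathers:
            if locus not in f.genotypes or not paternal_candidates:
                continue
            if not (paternal_candidates & f.alleles(locus)):
                excluded.append(f.individual_id)
                exclusions[f.individual_id] += 1
            else:
                informative = False  # a male shares the offspring allele
        scores.append(
            LocusScore(
                locus,
                offspring.is_homozygous(locus),
                off <= mat,
                tuple(excluded),
                informative,
            )
        )

    all_fathers_excluded = all(
        exclusions[f.individual_id] >= min_exclusion_loci for f in candidate_fathers
    )
    if n_hom == n_scored and mother_full and all_fathers_excluded:
        return ParentageResult(
            offspring.individual_id,
            "FP",
            mother.individual_id,
            None,
            n_scored,
            n_hom,
            tuple(scores),
        )

    # sexual: exactly one father whose genotype can supply a partner allele
    # at every scored locus
    sires = []
    for f in candidate_fathers:
        ok = True
        for locus in offspring.loci:
            if locus not in f.genotypes or locus not in mother.genotypes:
                continue
            pair = offspring.genotypes[locus]
            fat = f.alleles(locus)
            mat = mother.alleles(locus)
            if not any(pair[i] in mat and pair[1 - i] in fat for i in (0, 1)):
                ok = False
                break
        if ok:
            sires.append(f.individual_id)
    if len(sires) == 1:
        return ParentageResult(
            offspring.individual_id,
            "sexual",
            mother.individual_id,
            sires[0],
            n_scored,
            n_hom,
            tuple(scores),
        )
    notes = (
        "offspring carries alleles absent from every candidate parent pair"
        if not sires
        else f"{len(sires)} candidate fathers compatible"
    )
    return ParentageResult(
        offspring.individual_id,
        "ambiguous",
        mother.individual_id,
        None,
        n_scored,
        n_hom,
        tuple(scores),
        notes=notes,
    )


@dataclass(frozen=True)
class ColonySummary:
    n_records: int
    n_fp: int
    percent_fp: float
    outcomes: Mapping[str, int]
    fp_outcomes: Mapping[str, int]


def colony_incidence(records: pd.DataFrame) -> ColonySummary:
    """Tally parthenogenesis incidence and hatch outcomes in colony records.

    ``records`` needs either a ``mode`` column (ground truth or inferred
    reproduction mode) or a ``call`` column with "FP" entries, plus an
    ``outcome`` column.
    """
    if len(records) == 0:
        raise ValueError("empty colony record table")
    if "mode" in records.columns:
        fp_mask = records["mode"].ne("sexual") & records["mode"].notna()
    elif "call" in records.columns:
        fp_mask = records["call"].eq("FP")
    else:
        raise ValueError("records need a 'mode' or 'call' column")
    n = len(records)
    n_fp = int(fp_mask.sum())
    outcomes = records["outcome"].value_counts().to_dict() if "outcome" in records else {}
    fp_outcomes = (
        records.loc[fp_mask, "outcome"].value_counts().to_dict()
        if "outcome" in records
        else {}
    )
    return ColonySummary(n, n_fp, 100.0 * n_fp / n, outcomes, fp_outcomes)
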