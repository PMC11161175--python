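"""Forward simulation of oogenesis and diploidy restoration.

This module generates the ground-truth side of the analysis: a phased diploid
maternal genome, meiotic tetrads with crossovers, and offspring produced under
four reproduction modes —

* ``sexual``: egg pronucleus + an independently simulated paternal gamete,
* ``central_automixis``: egg + one first-polar-body product (heterozygosity
  is retained near centromeres because homologs separate at meiosis I),
* ``terminal_automixis``: egg + its sister chromatid from the second polar
  body (heterozygosity survives only distal to a crossover),
* ``gamete_duplication``: post-meiotic duplication of the egg genome, which
  is homozygous everywhere by construction.

Downstream observables (read pileups, microsatellite panels, colony breeding
records, erythrocyte samples, RAD-seq summaries) are simulated with known
truth so that every caller and classifier in the package can be validated
end to end.

Coordinates are 0-based, half-open throughout. All randomness flows through
:func:`numpy.random.default_rng`; passing the same seed reproduces output
bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .msparent import MSPanel
from .ploidyfrac import CellSample

BASES = ("A", "C", "G", "T")

REPRODUCTION_MODES = (
    "sexual",
    "central_automixis",
    "terminal_automixis",
    "gamete_duplication",
)

#: modes that restore diploidy without a father
FP_MODES = REPRODUCTION_MODES[1:]

COLONY_OUTCOMES = ("hatched_normal", "hatched_defect", "died_in_ovum", "no_development")

ORIGIN_A, ORIGIN_B = 0, 1


def as_rng(seed_or_rng) -> np.random.Generator:
    """Return a Generator, passing through one that is already constructed."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# karyotype
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere_pos: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")
        if not 0 < self.centromere_pos < self.length:
            raise ValueError(
                f"chromosome {self.name!r}: centromere must lie strictly inside (0, length)"
            )

    @property
    def max_arm_length(self) -> int:
        return max(self.centromere_pos, self.length - self.centromere_pos)


@dataclass(frozen=True)
class GenomeMap:
    """Ordered karyotype: chromosome names, lengths and centromere positions."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self):
        return len(self.chromosomes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def get(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def from_records(cls, records: Iterable) -> "GenomeMap":
        chroms = []
        for rec in records:
            if isinstance(rec, Mapping):
                chroms.append(
                    Chromosome(str(rec["name"]), int(rec["length"]), int(rec["centromere_pos"]))
                )
            else:
                name, length, cen = rec
                chroms.append(Chromosome(str(name), int(length), int(cen)))
        return cls(tuple(chroms))


def acrocentric_karyotype(
    n_chromosomes: int = 23, length: int = 1_000_000, centromere_frac: float = 0.1
) -> GenomeMap:
    """Karyotype with near-terminal centromeres (long arms dominate).

    The default mirrors a 23-chromosome complement at desk scale; long arms
    maximise the spatial contrast between the two automixis modes.
    """
    cen = max(1, int(round(length * centromere_frac)))
    return GenomeMap(
        tuple(Chromosome(f"chr{i + 1}", length, cen) for i in range(n_chromosomes))
    )


def metacentric_karyotype(
    n_chromosomes: int = 4, length: int = 5_000_000, centromere_frac: float = 0.5
) -> GenomeMap:
    """Karyotype with central centromeres (two equal arms)."""
    cen = max(1, int(round(length * centromere_frac)))
    return GenomeMap(
        tuple(Chromosome(f"chr{i + 1}", length, cen) for i in range(n_chromosomes))
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteBlock:
    """Per-chromosome phased site arrays (positions plus two allele codes)."""

    pos: np.ndarray  # int64, strictly increasing
    allele_a: np.ndarray  # uint8 codes into BASES
    allele_b: np.ndarray

    def __post_init__(self):
        if not (len(self.pos) == len(self.allele_a) == len(self.allele_b)):
            raise ValueError("site arrays must have equal length")
        if len(self.pos) > 1 and not np.all(np.diff(self.pos) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def is_het(self) -> np.ndarray:
        return self.allele_a != self.allele_b

    def __len__(self):
        return len(self.pos)


class _GenotypeMixin:
    """Shared view over per-chromosome diploid genotypes."""

    def genotype_blocks(self):
        """Yield ``(chrom, pos, allele1, allele2)`` arrays per chromosome."""
        raise NotImplementedError

    @property
    def n_sites(self) -> int:
        return sum(len(pos) for _, pos, _, _ in self.genotype_blocks())

    @property
    def n_het_sites(self) -> int:
        return int(sum((a != b).sum() for _, _, a, b in self.genotype_blocks()))

    def to_frame(self) -> pd.DataFrame:
        base = np.array(BASES)
        parts = []
        for chrom, pos, a, b in self.genotype_blocks():
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "allele1": base[a],
                        "allele2": base[b],
                        "is_het": a != b,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["chrom", "pos", "allele1", "allele2", "is_het"])
        return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class MaternalGenotype(_GenotypeMixin):
    """Phased diploid genotype of a parent, indexed by chromosome."""

    genome_map: GenomeMap
    sites: Mapping[str, SiteBlock]
    individual_id: str = "mother"

    def __post_init__(self):
        for name, block in self.sites.items():
            chrom = self.genome_map.get(name)
            if len(block) and (block.pos[0] < 0 or block.pos[-1] >= chrom.length):
                raise ValueError(f"{name}: site positions outside [0, length)")

    def genotype_blocks(self):
        for chrom in self.genome_map:
            block = self.sites.get(chrom.name)
            if block is not None:
                yield chrom.name, block.pos, block.allele_a, block.allele_b

    def het_block(self, name: str) -> SiteBlock:
        block = self.sites[name]
        m = block.is_het
        return SiteBlock(block.pos[m], block.allele_a[m], block.allele_b[m])


@dataclass(frozen=True)
class OffspringGenome(_GenotypeMixin):
    """Diploid offspring genotype with its true reproduction mode attached."""

    genome_map: GenomeMap
    sites: Mapping[str, "GenotypeBlock"]
    true_mode: str
    offspring_id: str = "offspring"
    mother_id: str | None = None
    father_id: str | None = None

    def genotype_blocks(self):
        for chrom in self.genome_map:
            block = self.sites.get(chrom.name)
            if block is not None:
                yield chrom.name, block.pos, block.allele1, block.allele2


@dataclass(frozen=True)
class GenotypeBlock:
    pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray


def simulate_maternal_genome(
    genome_map: GenomeMap,
    het_density: float,
    seed=None,
    *,
    hom_density: float = 0.0,
    individual_id: str = "mother",
    rng: np.random.Generator | None = None,
) -> MaternalGenotype:
    """Draw a phased maternal genome with Poisson-distributed SNP counts.

    ``het_density`` and ``hom_density`` are expected sites per bp; positions
    are uniform, deduplicated and sorted. Heterozygous sites carry two
    distinct bases, monomorphic sites one.
    """
    if het_density < 0 or hom_density < 0:
        raise ValueError("site densities must be >= 0")
    rng = rng if rng is not None else as_rng(seed)
    sites: dict[str, SiteBlock] = {}
    for chrom in genome_map:
        n_het = rng.poisson(het_density * chrom.length)
        n_hom = rng.poisson(hom_density * chrom.length)
        pos_het = np.unique(rng.integers(0, chrom.length, n_het))
        pos_hom = np.unique(rng.integers(0, chrom.length, n_hom))
        pos_hom = np.setdiff1d(pos_hom, pos_het, assume_unique=True)

        a_het = rng.integers(0, 4, len(pos_het)).astype(np.uint8)
        b_het = ((a_het + rng.integers(1, 4, len(pos_het))) % 4).astype(np.uint8)
        a_hom = rng.integers(0, 4, len(pos_hom)).astype(np.uint8)

        pos = np.concatenate([pos_het, pos_hom])
        a = np.concatenate([a_het, a_hom])
        b = np.concatenate([b_het, a_hom])
        order = np.argsort(pos, kind="stable")
        sites[chrom.name] = SiteBlock(pos[order].astype(np.int64), a[order], b[order])
    return MaternalGenotype(genome_map, sites, individual_id)


def derive_paternal_genome(
    maternal: MaternalGenotype,
    seed=None,
    *,
    individual_id: str = "father",
    rng: np.random.Generator | None = None,
) -> MaternalGenotype:
    """Paternal genome on the same site grid with maximally informative alleles.

    At maternal heterozygous sites the father carries the two bases the mother
    does not, so any sexual offspring is heterozygous there regardless of which
    alleles are transmitted. At monomorphic sites both parents agree.
    """
    del seed, rng  # construction is deterministic given the mother
    sites = {}
    for name, block in maternal.sites.items():
        het = block.is_het
        used = np.zeros((len(block), 4), dtype=bool)
        idx = np.arange(len(block))
        used[idx, block.allele_a] = True
        used[idx, block.allele_b] = True
        # the two unused bases, in code order
        free = np.argsort(used, axis=1, kind="stable")[:, :2].astype(np.uint8)
        a = np.where(het, np.minimum(free[:, 0], free[:, 1]), block.allele_a).astype(np.uint8)
        b = np.where(het, np.maximum(free[:, 0], free[:, 1]), block.allele_b).astype(np.uint8)
        sites[name] = SiteBlock(block.pos, a, b)
    return MaternalGenotype(maternal.genome_map, sites, individual_id)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromatid:
    """Origin of each interval of a chromatid as a step function.

    ``bounds`` is ``[0, b1, ..., length]``; ``origins[i]`` applies on
    ``[bounds[i], bounds[i+1])`` and is 0 for homolog A, 1 for homolog B.
    """

    bounds: np.ndarray
    origins: np.ndarray

    def origin_at(self, pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bounds, pos, side="right") - 1
        return self.origins[idx]

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        return [
            (int(self.bounds[i]), int(self.bounds[i + 1]), int(self.origins[i]))
            for i in range(len(self.origins))
        ]


@dataclass(frozen=True)
class ChromosomeTetrad:
    """Four chromatids of one bivalent after crossing over and segregation.

    Chromatids 0 and 1 carry the homolog-A centromere, 2 and 3 the homolog-B
    centromere. ``roles`` maps egg / pb2_sister / pb1_x / pb1_y to indices;
    the egg and pb2_sister share a centromere (they are sisters separated at
    meiosis II), pb1_x/pb1_y form the first polar body.
    """

    chromatids: tuple[Chromatid, Chromatid, Chromatid, Chromatid]
    roles: Mapping[str, int]
    crossover_positions: np.ndarray

    def role(self, name: str) -> Chromatid:
        return self.chromatids[self.roles[name]]


@dataclass(frozen=True)
class Tetrad:
    genome_map: GenomeMap
    per_chromosome: Mapping[str, ChromosomeTetrad]


def _simulate_chrom_tetrad(
    chrom: Chromosome, xs: np.ndarray, rng: np.random.Generator
) -> ChromosomeTetrad:
    xs = np.sort(np.asarray(xs, dtype=np.int64))
    n_seg = len(xs) + 1
    bounds = np.concatenate([[0], xs, [chrom.length]]).astype(np.int64)
    origins = np.zeros((4, n_seg), dtype=np.uint8)
    origins[2:] = 1

    # apply exchanges centromere-outward; each swaps the distal segment
    # between one chromatid of each homolog pair (no chromatid interference)
    order = np.argsort(np.abs(xs - chrom.centromere_pos), kind="stable")
    for t in order:
        i = int(rng.integers(2))
        j = 2 + int(rng.integers(2))
        if xs[t] >= chrom.centromere_pos:
            sel = slice(t + 1, n_seg)  # [x, telomere)
        else:
            sel = slice(0, t + 1)  # [0, x)
        tmp = origins[i, sel].copy()
        origins[i, sel] = origins[j, sel]
        origins[j, sel] = tmp

    egg_pair = int(rng.integers(2))  # meiosis I: which centromere pair stays
    egg_in_pair = int(rng.integers(2))  # meiosis II: which sister stays
    egg = 2 * egg_pair + egg_in_pair
    pb2 = 2 * egg_pair + (1 - egg_in_pair)
    other = 1 - egg_pair
    roles = {"egg": egg, "pb2_sister": pb2, "pb1_x": 2 * other, "pb1_y": 2 * other + 1}
    chromatids = tuple(Chromatid(bounds, origins[r].copy()) for r in range(4))
    return ChromosomeTetrad(chromatids, roles, xs)


def simulate_meiosis(
    maternal: MaternalGenotype | GenomeMap,
    crossover_rate: float = 2.5,
    obligate_crossover: bool = True,
    seed=None,
    *,
    forced_crossovers: Mapping[str, Sequence[int]] | None = None,
    rng: np.random.Generator | None = None,
) -> Tetrad:
    """Simulate one female meiosis for every chromosome.

    Crossover counts are Poisson(``crossover_rate``) per chromosome (minimum 1
    when ``obligate_crossover``), positions uniform along the chromosome, each
    exchange involving one chromatid of either homolog chosen uniformly.
    ``forced_crossovers`` pins exact positions per chromosome (for oracle
    comparisons); segregation randomisation still applies.
    """
    if crossover_rate < 0:
        raise ValueError("crossover_rate must be >= 0")
    genome_map = maternal.genome_map if isinstance(maternal, MaternalGenotype) else maternal
    rng = rng if rng is not None else as_rng(seed)
    per_chrom = {}
    for chrom in genome_map:
        if forced_crossovers is not None and chrom.name in forced_crossovers:
            xs = np.asarray(forced_crossovers[chrom.name], dtype=np.int64)
        else:
            k = int(rng.poisson(crossover_rate))
            if obligate_crossover and k == 0:
                k = 1
            xs = rng.integers(1, chrom.length, k)
        per_chrom[chrom.name] = _simulate_chrom_tetrad(chrom, xs, rng)
    return Tetrad(genome_map, per_chrom)


def make_offspring(
    tetrad: Tetrad,
    mode: str,
    maternal: MaternalGenotype,
    paternal: MaternalGenotype | None = None,
    seed=None,
    *,
    offspring_id: str = "offspring",
    rng: np.random.Generator | None = None,
    paternal_crossover_rate: float = 2.5,
) -> OffspringGenome:
    """Assemble an offspring genotype from a tetrad under one reproduction mode.

    sexual: egg + one random paternal gamete (an independent paternal meiosis
    is simulated internally). terminal_automixis: egg + its sister chromatid.
    central_automixis: egg + one first-polar-body chromatid chosen uniformly
    per chromosome. gamete_duplication: egg doubled.
    """
    if mode not in REPRODUCTION_MODES:
        raise ValueError(f"unknown reproduction mode {mode!r}")
    if mode == "sexual" and paternal is None:
        raise ValueError("sexual mode requires a paternal genome")
    if mode != "sexual" and paternal is not None:
        raise ValueError(f"mode {mode!r} must not receive a paternal genome")
    rng = rng if rng is not None else as_rng(seed)

    paternal_tetrad = None
    if mode == "sexual":
        paternal_tetrad = simulate_meiosis(
            maternal.genome_map, paternal_crossover_rate, True, rng=rng
        )

    sites: dict[str, GenotypeBlock] = {}
    for name, block in maternal.sites.items():
        ct = tetrad.per_chromosome[name]
        egg_or = ct.role("egg").origin_at(block.pos)
        allele1 = np.where(egg_or == ORIGIN_A, block.allele_a, block.allele_b).astype(np.uint8)

        if mode == "gamete_duplication":
            allele2 = allele1.copy()
        elif mode == "terminal_automixis":
            part = ct.role("pb2_sister").origin_at(block.pos)
            allele2 = np.where(part == ORIGIN_A, block.allele_a, block.allele_b).astype(np.uint8)
        elif mode == "central_automixis":
            role = "pb1_x" if int(rng.integers(2)) == 0 else "pb1_y"
            part = ct.role(role).origin_at(block.pos)
            allele2 = np.where(part == ORIGIN_A, block.allele_a, block.allele_b).astype(np.uint8)
        else:  # sexual
            pblock = paternal.sites.get(name)
            if pblock is None or not np.array_equal(pblock.pos, block.pos):
                raise ValueError(
                    f"paternal genome must carry the same site positions as the mother ({name})"
                )
            sperm_or = paternal_tetrad.per_chromosome[name].role("egg").origin_at(block.pos)
            allele2 = np.where(
                sperm_or == ORIGIN_A, pblock.allele_a, pblock.allele_b
            ).astype(np.uint8)
        sites[name] = GenotypeBlock(block.pos, allele1, allele2)

    return OffspringGenome(
        maternal.genome_map,
        sites,
        true_mode=mode,
        offspring_id=offspring_id,
        mother_id=maternal.individual_id,
        father_id=paternal.individual_id if paternal is not None else None,
    )


# ---------------------------------------------------------------------------
# sequencing observables
# ---------------------------------------------------------------------------

_OTHER_BASES = np.array([[b for b in range(4) if b != a] for a in range(4)])


def simulate_pileups(
    individual: _GenotypeMixin,
    mean_coverage: float = 20.0,
    error_rate: float = 0.0,
    seed=None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-site read pileups over an individual's genotyped sites.

    Coverage is Poisson(``mean_coverage``); each read samples one of the two
    genotype alleles with probability 1/2 and is miscalled to a uniformly
    chosen other base with probability ``error_rate``. Returns a table with
    columns chrom, pos, A, C, G, T.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = rng if rng is not None else as_rng(seed)

    chroms, positions, g1s, g2s = [], [], [], []
    for chrom, pos, a1, a2 in individual.genotype_blocks():
        chroms.append(np.full(len(pos), chrom, dtype=object))
        positions.append(pos)
        g1s.append(a1)
        g2s.append(a2)
    chrom_arr = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    pos_arr = np.concatenate(positions) if positions else np.array([], dtype=np.int64)
    g1 = np.concatenate(g1s).astype(np.intp) if g1s else np.array([], dtype=np.intp)
    g2 = np.concatenate(g2s).astype(np.intp) if g2s else np.array([], dtype=np.intp)
    n = len(pos_arr)

    cov = rng.poisson(mean_coverage, n)
    n1 = rng.binomial(cov, 0.5)
    n2 = cov - n1
    counts = np.zeros((n, 4), dtype=np.int64)
    idx = np.arange(n)
    if error_rate > 0:
        e1 = rng.binomial(n1, error_rate)
        e2 = rng.binomial(n2, error_rate)
    else:
        e1 = np.zeros(n, dtype=np.int64)
        e2 = np.zeros(n, dtype=np.int64)
    np.add.at(counts, (idx, g1), n1 - e1)
    np.add.at(counts, (idx, g2), n2 - e2)
    for alleles, errs in ((g1, e1), (g2, e2)):
        mask = errs > 0
        if mask.any():
            split = rng.multinomial(errs[mask], [1 / 3] * 3)
            np.add.at(
                counts,
                (idx[mask][:, None], _OTHER_BASES[alleles[mask]]),
                split,
            )

    df = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr})
    for j, base in enumerate(BASES):
        df[base] = counts[:, j]
    return df


# ---------------------------------------------------------------------------
# microsatellite observables
# ---------------------------------------------------------------------------


def simulate_ms_parents(
    n_loci: int = 8,
    mother_het_prob: float = 5 / 8,
    father_het_prob: float = 6 / 8,
    seed=None,
    *,
    size_range: tuple[int, int] = (150, 320),
    grid_step: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[MSPanel, MSPanel]:
    """Draw mother/father microsatellite genotypes with disjoint allele sizes.

    Allele sizes sit on a ``grid_step`` bp grid (repeat-unit spacing) so that
    ±1 bp binning jitter cannot bridge distinct alleles.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = rng if rng is not None else as_rng(seed)
    grid = np.arange(size_range[0], size_range[1], grid_step)
    mother, father = {}, {}
    for i in range(n_loci):
        locus = f"MS{i + 1}"
        pool = [int(x) for x in rng.choice(grid, size=4, replace=False)]
        if rng.random() < mother_het_prob:
            m = sorted(pool[:2])
        else:
            m = [pool[0], pool[0]]
        if rng.random() < father_het_prob:
            f = sorted(pool[2:])
        else:
            f = [pool[2], pool[2]]
        mother[locus] = (m[0], m[1])
        father[locus] = (f[0], f[1])
    return MSPanel("mother", mother), MSPanel("father", father)


def simulate_ms_panel(
    mother: MSPanel,
    father: MSPanel | None,
    mode: str,
    binning_jitter_prob: float = 0.0,
    seed=None,
    *,
    individual_id: str = "offspring",
    rng: np.random.Generator | None = None,
) -> MSPanel:
    """Simulate an offspring microsatellite panel under one reproduction mode.

    Parthenogenetic offspring inherit one maternal allele per locus, observed
    twice (the genome-wide homozygosity of gamete duplication); sexual
    offspring inherit one maternal and one paternal allele. Each observed size
    is shifted ±1 bp with probability ``binning_jitter_prob`` to emulate
    capillary-electrophoresis binning artifacts.
    """
    if mode not in REPRODUCTION_MODES:
        raise ValueError(f"unknown reproduction mode {mode!r}")
    if mode == "sexual" and father is None:
        raise ValueError("sexual mode requires a father panel")
    rng = rng if rng is not None else as_rng(seed)
    genotypes = {}
    for locus, (m1, m2) in mother.genotypes.items():
        m_allele = m1 if rng.random() < 0.5 else m2
        if mode == "sexual":
            f1, f2 = father.genotypes[locus]
            p_allele = f1 if rng.random() < 0.5 else f2
            pair = [m_allele, p_allele]
        else:
            pair = [m_allele, m_allele]
        if binning_jitter_prob > 0:
            pair = [
                int(a) + (int(rng.integers(2)) * 2 - 1) if rng.random() < binning_jitter_prob else int(a)
                for a in pair
            ]
        genotypes[locus] = (min(pair), max(pair))
    return MSPanel(individual_id, genotypes)


# ---------------------------------------------------------------------------
# colony records and cell samples
# ---------------------------------------------------------------------------


def simulate_colony(
    n_eggs: int,
    fp_rate: float,
    hatch_normal_given_fp: float = 6 / 16,
    seed=None,
    *,
    died_in_ovum_given_fp: float = 9 / 23,
    sexual_defect_rate: float = 0.02,
    n_mothers: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate colony breeding records with a Bernoulli parthenogenesis rate.

    Parthenogenetic eggs hatch defect-free at ``hatch_normal_given_fp``
    (default 6/16), die in ovum at ``died_in_ovum_given_fp`` (default 9/23),
    and hatch with defects otherwise; sexual eggs show defects at
    ``sexual_defect_rate``. Returns a table with egg_id, mother_id, father_id,
    outcome and mode columns.
    """
    for name, v in (
        ("fp_rate", fp_rate),
        ("hatch_normal_given_fp", hatch_normal_given_fp),
        ("died_in_ovum_given_fp", died_in_ovum_given_fp),
        ("sexual_defect_rate", sexual_defect_rate),
    ):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if hatch_normal_given_fp + died_in_ovum_given_fp > 1:
        raise ValueError("FP outcome fractions sum to more than 1")
    rng = rng if rng is not None else as_rng(seed)

    is_fp = rng.random(n_eggs) < fp_rate
    u = rng.random(n_eggs)
    outcome = np.where(u < sexual_defect_rate, "hatched_defect", "hatched_normal").astype(object)
    fp_out = np.where(
        u < hatch_normal_given_fp,
        "hatched_normal",
        np.where(u < hatch_normal_given_fp + died_in_ovum_given_fp, "died_in_ovum", "hatched_defect"),
    )
    outcome[is_fp] = fp_out[is_fp]
    mothers = np.array([f"F{i % n_mothers:03d}" for i in range(n_eggs)], dtype=object)
    return pd.DataFrame(
        {
            "egg_id": [f"egg{i:05d}" for i in range(n_eggs)],
            "mother_id": mothers,
            "father_id": np.where(is_fp, None, "M000"),
            "outcome": outcome,
            "mode": np.where(is_fp, "gamete_duplication", "sexual"),
        }
    )


def colony_from_counts(
    n_records: int,
    n_fp: int,
    fp_outcomes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Reconstruct a colony record table from published marginal counts.

    ``fp_outcomes`` optionally fixes outcome counts among the parthenogenetic
    records (e.g. ``{"hatched_normal": 6, "hatched_defect": 10}``); remaining
    records hatch normally.
    """
    if n_fp > n_records:
        raise ValueError("n_fp cannot exceed n_records")
    modes = ["gamete_duplication"] * n_fp + ["sexual"] * (n_records - n_fp)
    outcomes = ["hatched_normal"] * n_records
    if fp_outcomes is not None:
        if sum(fp_outcomes.values()) != n_fp:
            raise ValueError("fp_outcomes must sum to n_fp")
        pos = 0
        for out, cnt in fp_outcomes.items():
            if out not in COLONY_OUTCOMES:
                raise ValueError(f"unknown outcome {out!r}")
            outcomes[pos : pos + cnt] = [out] * cnt
            pos += cnt
    return pd.DataFrame(
        {
            "egg_id": [f"egg{i:05d}" for i in range(n_records)],
            "mother_id": "F000",
            "father_id": [None if m != "sexual" else "M000" for m in modes],
            "outcome": outcomes,
            "mode": modes,
        }
    )


def simulate_cell_sample(
    n_cells: int,
    haploid_frac: float = 87 / 943,
    binucleated_frac: float = 12 / 943,
    seed=None,
    *,
    rng: np.random.Generator | None = None,
) -> CellSample:
    """Draw erythrocyte class counts from a multinomial over three classes."""
    if not 0 <= haploid_frac <= 1 or not 0 <= binucleated_frac <= 1:
        raise ValueError("fractions must be in [0, 1]")
    if haploid_frac + binucleated_frac > 1:
        raise ValueError("class fractions sum to more than 1")
    rng = rng if rng is not None else as_rng(seed)
    n_dip, n_hap, n_bi = rng.multinomial(
        n_cells, [1 - haploid_frac - binucleated_frac, haploid_frac, binucleated_frac]
    )
    return CellSample(int(n_dip), int(n_hap), int(n_bi))


def simulate_dna_content(
    n_events: int = 44_060,
    haploid_fraction: float = 0.0962,
    reference_2n: float = 100.0,
    cv: float = 0.04,
    seed=None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate flow-cytometry DNA-content intensities as a Gaussian mixture.

    Events split between a 1n peak at half the 2n position and the 2n peak;
    ``cv`` is the coefficient of variation of the stain signal.
    """
    if not 0 <= haploid_fraction <= 1:
        raise ValueError("haploid_fraction must be in [0, 1]")
    rng = rng if rng is not None else as_rng(seed)
    n_hap = rng.binomial(n_events, haploid_fraction)
    hap = rng.normal(0.5 * reference_2n, cv * 0.5 * reference_2n, n_hap)
    dip = rng.normal(reference_2n, cv * reference_2n, n_events - n_hap)
    events = np.concatenate([hap, dip])
    rng.shuffle(events)
    return np.clip(events, 1e-9, None)


# ---------------------------------------------------------------------------
# RAD-seq cohort summaries
# ---------------------------------------------------------------------------


def simulate_rad_summaries(
    species_sizes: Mapping[str, int],
    mean_het_percent: float = 0.261,
    log_sd: float = 0.28,
    seed=None,
    *,
    n_considered_mean: int = 40_000,
    coverage_mean: float = 27.0,
    coverage_sd: float = 4.0,
    planted_low: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-individual RAD-seq heterozygosity summaries.

    Per-individual heterozygosity percentages are lognormal with mean
    ``mean_het_percent`` and log-scale spread ``log_sd`` (chosen so a cohort
    of ~320 spans roughly 0.1-0.6%). ``planted_low`` maps individual ids
    (``"<species>_<index>"``) to multiplicative factors emulating
    parthenogenesis-driven heterozygosity loss. Counts come from a binomial
    over the considered-site total, coverages from a clipped normal so some
    individuals fall under the standard coverage-20 gate.
    """
    rng = rng if rng is not None else as_rng(seed)
    mu = np.log(mean_het_percent) - log_sd**2 / 2
    rows = []
    for species, n in species_sizes.items():
        pct = np.exp(rng.normal(mu, log_sd, n))
        cov = np.clip(rng.normal(coverage_mean, coverage_sd, n), 5.0, None)
        n_considered = rng.poisson(n_considered_mean, n)
        for i in range(n):
            ident = f"{species}_{i:03d}"
            p = pct[i]
            if planted_low and ident in planted_low:
                p = p * planted_low[ident]
            n_het = rng.binomial(n_considered[i], min(p / 100.0, 1.0))
            rows.append(
                {
                    "id": ident,
                    "species": species,
                    "mean_coverage": float(cov[i]),
                    "n_het": int(n_het),
                    "n_considered": int(n_considered[i]),
                }
            )
    return pd.DataFrame(rows)
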