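# Methods

## The inference problem

When an unfertilised egg develops, something must restore diploidy. The three
candidate mechanisms leave distinct spatial fingerprints in the offspring's
heterozygosity relative to its mother:

* **Central automixis** (fusion with a first-polar-body product). Homologs
  separate at meiosis I, so at any locus with no crossover between it and the
  centromere the egg and the polar-body product carry different homologs:
  heterozygosity is retained near centromeres and eroded distally.
* **Terminal automixis** (fusion of the egg with its second polar body, i.e.
  its sister chromatid). Sisters are identical except distal to crossovers:
  heterozygosity survives only near chromosome termini.
* **Post-meiotic gamete duplication** (replication of the haploid egg genome
  without division). The product is homozygous at every site, everywhere.

Sexual offspring, by contrast, retain essentially all maternal heterozygosity.
`automixia` simulates all four outcomes with known ground truth, reproduces a
deliberately stringent read-pileup heterozygosity caller, and classifies the
mechanism from three statistics computed on mother/offspring call sets.

## Meiosis model (`simgenome`)

Each chromosome is a bivalent of four chromatids; chromatids 0–1 share one
centromere, 2–3 the other. Crossover counts are Poisson per chromosome
(default rate 2.5, with an obligate minimum of one — chiasma assurance);
positions are uniform along the chromosome; each crossover involves one
chromatid of either homolog chosen uniformly (no chromatid interference, no
gene conversion, no crossover interference). Exchanges are applied
centromere-outward, each swapping the distal segment of the two chromatids
involved, so the centromere identity of a chromatid never changes. Meiosis I
and II segregation are independent fair choices per chromosome: which
centromere pair stays in the egg lineage, then which sister becomes the egg.

Offspring assembly: sexual = egg + the egg-lineage product of an independent
paternal meiosis; terminal automixis = egg + its sister; central automixis =
egg + one first-polar-body chromatid (uniform per chromosome, since the polar
body's own division segregates chromosomes independently); duplication = egg
doubled. The default paternal genome carries, at every maternal heterozygous
site, the two bases the mother lacks — the most informative configuration, so
sexual offspring are heterozygous there with probability 1.

This model reproduces the classical second-division-segregation algebra. With
k crossovers between the centromere and a site, exact enumeration over all
chromatid-involvement and fusion choices (`mechinfer.retention_oracle`)
gives retention probabilities

* central: 2/3 + (1/3)(−1/2)^k → 1, 1/2, 3/4, 5/8, …
* terminal: 2/3 − (2/3)(−1/2)^k → 0, 1, 1/2, 3/4, …

Both converge to 2/3 as crossovers accumulate. A single proximal crossover
yields 100% second-division segregation, so terminal fusion *retains*
heterozygosity there with probability 1 — the intuition that terminal fusion
is "mostly homozygosing" is true only because most loci have no proximal
crossover. The Monte-Carlo simulator agrees with the enumeration to within
Monte-Carlo error for 0–3 forced crossovers in every mode (tested at n = 10⁴
meioses), which validates the segment-swapping machinery against an
independent single-site computation.

## Heterozygosity calling (`hetscan`)

A site is called heterozygous iff its coverage is even, exactly two bases
have non-zero read counts, and the two counts are equal; odd-coverage sites
are discarded. In `mean_coverage` mode the analysis is restricted to sites
whose coverage equals the sample mean rounded **up** to the next even integer
(the only reading consistent with a mean of 18.31 producing a target of 20);
this suppresses the spurious heterozygosity of collapsed repeats at
above-average coverage. The rule is intentionally insensitive: at 20× an
error-free true heterozygous site is accepted with probability
C(20,10)/2²⁰ ≈ 0.1762 (the central binomial term). The caller is therefore a
*thinning* of true heterozygosity — fine for contrasts and spatial patterns,
not an absolute heterozygosity estimate. No genotype likelihoods are
computed, deliberately.

Window aggregation uses half-open, 0-based windows of 10 kb, tumbling by
default (`--step` gives sliding windows); with step = size the window counts
sum exactly to the flagged-site total. Percent heterozygosity is
100 × heterozygous / considered sites, with the denominator restricted to
the same coverage stratum as the numerator.

## Mechanism classification (`mechinfer`)

Three statistics per mother–offspring pair:

* **retained fraction** — offspring heterozygous-call count over the
  mother's, on sites considered in both call sets;
* **interspersion** — among 10-kb windows where the mother has ≥1
  heterozygous call, the fraction where the offspring reaches 50% of her
  count (automictic offspring should match the mother inside retained
  regions; duplication offspring match almost nowhere);
* **spatial trend** — the rank correlation (Spearman) of the per-site
  retained indicator against normalised centromere distance
  |pos − centromere| / longest arm. This is the fine-bin limit of a binned
  retention profile and is insensitive to the display bin count; the binned
  profile (default 10 bins partitioning [0, 1]) is kept for reporting, and
  bin-level Spearman is the fallback when only a binned profile is
  available. The site-level form was chosen because central-automixis
  retention is non-monotone in distance (1 → 1/2 → 3/4 → … → 2/3 with
  proximal-crossover count), which makes the flat distal bins rank-unstable.

Decision rules (all thresholds configurable): retained ≥ 0.8 **and**
interspersion ≥ 0.8 → sexual; retained ≤ 0.05 and interspersion ≤ 0.05 →
post-meiotic duplication; otherwise the sign of the trend separates central
(negative) from terminal (positive) automixis, and anything without
centromere information or a clear sign is *indeterminate*, never a guess.
The 0.05 / 0.8 / 50% values mirror the observed real-data contrasts
(parthenogen heterozygous-site counts of ~2% of maternal counts; regional
window maxima below half the maternal level).

A caveat the tests exposed: with noiseless (genotype-truth) calls the
interspersion statistic collapses onto the retained fraction, and
high-retention central-automixis realisations (retained ≈ 0.8–0.87) can
enter the sexual decision region. The thresholds are designed for
read-thinned counts, where window matching is depressed relative to
retention; classification should always be run on caller output, as the
pipeline does.

## Microsatellite parentage (`msparent`)

Allele sizes within 1 bp are binning artifacts of capillary electrophoresis
and are merged before scoring: single-linkage clustering per locus across
the compared panels, replacement by the cluster's modal size, chains wider
than 2 bp left unmerged with a warning. Merging is per comparison set
(trio/enclosure), not per study.

The parthenogenesis call requires the full three-part argument: homozygosity
at every scored locus, every offspring allele present in the mother, and
every co-housed male excluded at ≥1 locus (configurable), where a male is
excluded when he carries none of the alleles the mother cannot have
supplied. Loci where mother and male share the offspring allele are scored
uninformative. A heterozygous offspring is assigned a sire only when exactly
one candidate can supply the non-maternal allele at every locus; everything
else is ambiguous. No likelihood-based (LOD) parentage is attempted — the
logic is exclusion-based by design.

## Population screen (`popscreen`)

Individuals below 20× mean coverage are dropped; percent heterozygosity at
average-coverage sites is computed per individual; and low outliers are
found with the generalized extreme studentized deviate (Rosner) test:
iteratively remove the point maximising |x − x̄|/s, compare each R_i to

λ_i = (n − i) · t_{p, n−i−1} / √((n − i − 1 + t²)(n − i + 1)),
p = 1 − α / (2(n − i + 1)),

and declare the largest i with R_i > λ_i. The test runs within species on
log-transformed percentages by default (heterozygosity spreads
multiplicatively); zeros are replaced by half the smallest positive value,
with a warning, so fully homozygous individuals remain testable. The ESD
statistic is two-sided while parthenogenesis can only depress
heterozygosity, so detected outliers are post-filtered to the low side. The
λ formula is verified against the standard published reference values
(n = 54, α = 0.05: 3.158, 3.151, 3.144), and simulation shows the ≥1-outlier
rate under an i.i.d. normal null is ≈0.05 at n = 75, k = 5 (tested against a
3σ band around α over 10⁴ cohorts).

## Mixoploidy (`ploidyfrac`)

Two deliberately separate estimators, reported side by side: class
percentages from scored blood-smear counts (diploid / smaller haploid /
binucleated), and peak detection on flow-cytometry DNA-content intensities.
The histogram uses Freedman–Diaconis bins, light smoothing, and non-maximum
suppression over a window of 0.2 × the 2n reference (a peak must dominate
its neighbourhood — plain local maxima produce noise shoulders on a single
Gaussian); events are assigned to the nearest surviving peak and peaks
holding <1% of events are dropped. The haploid call fires when a peak lies
within ±15% of half the 2n reference, a window sized to tolerate stain CV.
No mixture model is fitted by default; on well-separated peaks nearest-peak
assignment recovers generating proportions to ±0.02 at the 44,000-event
scale.

## Synthetic data: what it does and does not emulate

The generator's defaults are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| karyotype | 23 acrocentric chromosomes, 1 Mb, centromere at 10% | a 23-chromosome complement at desk scale; long arms maximise the automixis contrast (a metacentric karyotype ships for sensitivity checks) |
| heterozygous-site density | 5×10⁻³ /bp | puts ~50 heterozygous sites per 10-kb window so window statistics carry signal after the ~0.18 call-rate thinning |
| crossovers | Poisson(2.5)/chromosome, obligate ≥1 | 2–3.5 chiasmata per chromosome; concentrates the central-automixis retained fraction near 0.67, inside the (0.05, 0.8) decision band |
| coverage | Poisson, mean 20× | the stratum the caller targets |
| sequencing error | 10⁻³ /read | below-reference-quality miscall rate; at 20× it almost never fabricates an equal split |
| microsatellites | 8 loci, 4-bp allele grid, mother het at 5/8, males at 6/8 | panel informativeness matching the enclosure analyses; repeat-unit spacing keeps ±1 bp jitter from bridging alleles |
| colony | FP outcomes 6/16 defect-free, 9/23 died in ovum; sexual defects 2% | observed hatch margins |
| erythrocytes | haploid 87/943, binucleated 12/943; flow mixture 9.62% at 0.5×2n, CV 4% | observed count and event structure |
| RAD cohort | lognormal percent heterozygosity, mean 0.261%, log-sd 0.28 | reproduces the reported cohort mean with a ~0.1–0.6% span at n ≈ 320 |

What the simulation does **not** emulate — hence what passing tests do not
show about real data: alignment and assembly artifacts (collapsed paralogs
are the dominant source of apparent heterozygosity in real parthenogen
genomes and are absent here), mapping bias, coverage autocorrelation along
the genome, linkage between the site grid and repeat content, crossover
interference and gene conversion, somatic mutation, and population structure
in the RAD cohort. Real-data classification also lacks scaffold-anchored
centromere positions, so it defaults to the interspersion route; the
centromere-distance profile is only available where centromeres are known
(simulation, or a user-supplied table). Mixoploid development is represented
only at the observable level (cell-class fractions), not as a cell-lineage
model — the developmental timing of diploidisation is not parameterised.

## Numerical and interface conventions

Coordinates are 0-based, half-open everywhere (BED-compatible). All
randomness flows from one `numpy.random.Generator` per entry point; the same
seed gives bitwise-identical output, and pipeline outputs embed the seed and
a hash of the scientific configuration (output paths excluded from the
hash). Degenerate inputs raise instead of guessing: empty pileups, zero
considered sites, zero maternal heterozygous calls, missing centromeres,
zero variance in the ESD iteration, cell samples of size zero. Ties in
allele binning resolve to the smaller modal size; the enumeration oracle
refuses >3 crossovers rather than approximating (use the Monte-Carlo
estimator). Problem sizes in the test suite and acceptance script (3-Mb
call-rate genome, 8-chromosome contrast genome, 4×200 and 4×50 cohorts,
10⁴ ESD null cohorts, 44,000 flow events) were chosen to make every
statistical band a ≥3σ statement while keeping a full run in minutes.

## Known limitations

* The equal-split caller's absolute sensitivity (~18% at 20×) makes percent
  heterozygosity a relative, not absolute, measure; comparisons are only
  valid within a coverage stratum.
* The classifier is rule-based with fixed default thresholds, not a
  likelihood model; near-threshold cases return labels without uncertainty
  quantification (the `indeterminate` label is the only guard).
* Central vs terminal discrimination needs centromere positions; with
  unanchored scaffolds only the sexual / duplication / indeterminate
  distinction is available.
* The published within-species outlier statistics (R = 5.127, λ = 3.928 for
  74 conspecifics) depend on a per-individual table that is not public;
  the implementation reproduces the procedure and its calibration, not that
  specific value.
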