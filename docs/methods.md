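# Methods

## Scope and model

`mesodemog` reconstructs female effective population size (Nef) through time
from haploid mtDNA control-region alignments and derives per-generation
growth rates from the reconstruction. Nef here is the haploid effective
count of maternal lineages: a pair of lineages in a population of size Nef
coalesces at rate 1/Nef per generation, so with k lineages the total hazard
is k(k−1)/(2·Nef). All analysis stages treat the control region as a single
non-recombining locus with contemporaneous sampling (all tips at 0 ybp).

### Coalescent skyline

The estimator is a piecewise-constant coalescent skyline conditional on a
genealogy. The genealogy's (k, Δt) interval decomposition is the sufficient
statistic; an epoch of size N containing c coalescences and hazard integral
W = Σ k(k−1)Δt/2 contributes −W/N − c·ln N to the log-likelihood. The
sampler groups the pooled coalescent events of one or more genealogies into
m contiguous groups and runs Metropolis–Hastings with two move types:
multiplicative (log-space symmetric) scale moves on one group's Nef, and
swaps of a single coalescent event between adjacent groups. The prior is
scale-invariant (log-uniform, bounded at e⁻⁵..e³⁰ for propriety) on the
most recent group and Exponential(mean = previous group's Nef) on each
subsequent group — the standard smoothing prior. Under a flat likelihood
the chain reproduces this prior (tested by Kolmogorov–Smirnov), and on a
single 2-lineage interval of length T it reproduces the closed-form
posterior N = T/U, U ~ Exp(1), to sampling accuracy.

Joint inference over tree space (as a full Bayesian phylogenetic sampler
would do) is deliberately out of scope. Skylines are computed either on the
simulator's true genealogies or on a UPGMA estimate from corrected
distances; the conditional-likelihood core is the defining computation and
is validated by parameter recovery against an independent simulator.
Consequences of conditioning on a point genealogy are discussed under
limitations.

Defaults: m = 5 groups (pipeline), 200,000 iterations thinned every 100
with 10% burn-in for library use; analyses in the tests scale these to the
problem (50k–150k iterations), always reporting effective sample sizes and
warning below ESS 100. Trajectories report per-gridpoint posterior medians
with 95% highest-posterior-density intervals (shortest-interval estimator).

### Genealogy estimation

`estimate_genealogy` computes pairwise distances corrected for multiple
hits with the closed-form TN93 estimator (the analytically tractable member
of the HKY family, with empirical base frequencies), then UPGMA (average
linkage). Node heights are half the merge distance, converted to
generations by 1/(μ·g). Saturated pairs raise an error naming the pair;
an alignment with no variation yields a zero-height star tree flagged
degenerate. UPGMA assumes clocklike data — appropriate here because the
underlying genealogies are ultrametric by construction; on a known 8-tip
tree whose internal edges all carry several expected substitutions the true
topology is recovered in ≥ 90% of simulated alignments. Random coalescent
topologies routinely contain near-zero internal edges that no method can
resolve from finite sequence; this is a property of the data, not the
estimator, and is why the recovery test fixes the tree.

### Clock and units

Strict molecular clock at μ = 3.02×10⁻⁷ substitutions/site/year for the
control region and 25-year generations; both are configurable. Times are
carried in generations internally and reported in years before present
(present = sampling time; the chronology anchor for calendar conversion is
1950 CE). Rate and generation time affect only the scale of the skyline,
not its shape.

### IGR and trend inversion

Skyline medians are resampled to the 25-year generation grid by
step-function evaluation (no interpolation), then
IGR_n = 100·(Nef_n − Nef_{n−1})/Nef_{n−1} with n−1 the older generation.
The series is scale-invariant in Nef and satisfies the compounding identity
Nef_last = Nef_first·Π(1 + IGR_n/100) to 1e-9. Extrema (Nef and IGR maxima
and minima) break ties toward the most recent generation and are mapped to
chronological periods.

The trend inversion — the moment growth turns to decline or the converse —
is detected on a smoothed IGR series (centred moving average; window 5
generations by default, 21 generations ≈ 500 years recommended for skyline
output, whose step-wise medians make raw rates impulsive). Because an
estimated plateau always carries small persistent tilts, a pure
sign-crossing rule is unstable: the implementation instead takes the
*dominant* reversal — the sign change between the global smoothed IGR
maximum and minimum — and reports its onset as the first generation, moving
forward in time, at which the trajectory has left the neighbourhood of its
extreme (within `peak_tolerance`, default 15% of the span's dynamic range,
matching the typical relative wobble of a skyline plateau) and the opposite
trend has taken over. A raw, unsmoothed mode is available for constructed
series. On the canonical growth-then-decline scenario the detected onset
lands within ±500 years of the true decline in ≥ 80% of replicates.

### Periods

Default Mesoamerican chronology (ybp, anchor 1950 CE): Lithic 15000–2500,
Preclassic 2500–1750, Classic 1750–1050, Postclassic 1050–429, Colonial
429–0. A boundary year belongs to the older period (2000 ybp is Preclassic
because 2500 > 2000 ≥ 1750); times older than 15000 ybp map to
"pre-chronology". The Colonial boundary converts 1521 CE; sources vary on
this date and on the Preclassic/Classic boundary (150–200 CE; the midpoint
1750 ybp is used), so the table is a YAML config, not a constant.

## Statistics

* **θ** is the mean number of pairwise differences (not Watterson's
  estimator, which appears only as S/a₁ inside Tajima's D). Missing data
  are excluded pairwise, per standard practice for control-region data.
* **Ĥ** = n/(n−1)(1 − Σp²) with Nei's (1987) sampling variance;
  **π** = θ/L with Tajima's (1983) variance — the π standard-deviation
  estimator is a documented choice, since conventions differ.
* **Tajima's D** uses the standard a₁…e₂ constants; undefined at S = 0
  (returned as missing, with the reason). Neutral constant-size calibration
  (200 simulations, n=25, θ≈5) keeps the mean within ±0.3 of zero and the
  |D| > 2 rate at or below 8%.
* **Fu's F_S** = ln(S′/(1−S′)) with S′ = P(K ≥ k | θ, n) under the Ewens
  sampling distribution, θ being the mean pairwise differences plug-in.
  Computation uses log-space unsigned Stirling numbers of the first kind;
  agreement with exact integer Stirling numbers is 1e-9 for n ≤ 12, and
  with a permutation-cycle-counting oracle at n = 5. k = 1 (or numerical
  S′ ∈ {0,1}) returns a signed-infinity sentinel.
* **Φst / AMOVA**: Excoffier–Smouse–Quattro variance components computed
  from pairwise difference counts used as squared distances (the Arlequin
  convention for haplotype data — "Fst" in this package always means this
  Φst). Three permutation schemes: whole populations among groups (F_CT),
  individuals among populations within groups (F_SC), individuals among
  populations (F_ST); p = (b+1)/(m+1), default m = 10,000, seeded. Negative
  components are reported as computed and flagged, not truncated (they are
  clipped to 0 only when a Φst matrix feeds MDS). With 4 populations in two
  groups the F_CT permutation floor is 1/3 — small designs cannot reach
  conventional significance, which the tests assert rather than hide.
* **Mantel**: Pearson r over the off-diagonal upper triangle, p by jointly
  permuting one matrix's rows and columns (two-sided on |r|); agrees with
  exhaustive enumeration at n = 6. Geographic distances are great-circle
  kilometres from population mean coordinates.
* **MDS** is classical (metric) principal-coordinates analysis; negative
  eigenvalues are dropped and reported through the goodness-of-fit. The
  metric-vs-nonmetric choice is recorded in the solution metadata.
* **Chi-square heterogeneity** of haplogroup counts drops zero rows/columns
  with a warning and flags expected counts below 1.

## Haplogroup calling

Sequences are coded EMPOP-style as (position, allele) differences from a
reference; indels and ambiguity codes are excluded (control-region indel
nomenclature is dialect-ridden, and the analyses use substitutions only).
Coordinates follow the mtDNA convention: the 1122-site simulated block maps
to 16024–16569 + 1–576, with HVRI = 16024–16365 and HVRII = 73–340.
A call scores each haplogroup by the fraction of its diagnostic variants
present; best label wins at score ≥ 0.8 (ties to the larger motif, then
lexicographic), otherwise "unassigned" — and unassigned samples appear as
their own frequency-table row, so column sums always equal n. The shipped
motif table is explicitly illustrative (Phylotree-style, but not asserted
as real-world truth); calling accuracy is only ever tested against motifs
the simulator itself planted.

## The synthetic-data generator

Genealogies come from msprime with haploid lineages (so the coalescent rate
convention above holds exactly), single-deme with piecewise-constant Nef or
structured with backward migration; a disconnected migration graph raises a
non-coalescence error. Sequence evolution is implemented in this package:
exact HKY transition matrices per branch (matrix exponential of the scaled
generator) under a 4-category discrete gamma (median-of-category rates,
mean normalised to 1), with optional per-branch lognormal rate multipliers
(mean 1) emulating a relaxed clock — inference always assumes a strict
clock, a logged limitation. Defaults: 1122 sites, κ = 22, α = 0.40,
base frequencies (0.31, 0.33, 0.13, 0.23) — values typical of human
control-region studies, chosen once and documented here.

Study fixtures emulate a multi-population survey: each population draws
haplogroup membership from a requested mixture, simulates one genealogy per
haplogroup cluster under the population's demographic model, plants the
cluster's diagnostic motif at the root and evolves sequences from a fixed
synthetic reference (a pseudo-rCRS stand-in carrying no real-world
information, adjusted so every diagnostic allele is derived relative to
it). Outputs are FASTA, a metadata TSV (sample, population, region,
language, lat, lon), Newick genealogies in generations, and a truth sidecar
(JSON) recording mixtures, realised counts, demographic models and trees
for recovery tests. One master seed drives everything; per-population
streams derive by stable hashing of the population name, so outputs are
byte-identical across reruns.

The canonical recovery scenario mirrors the qualitative Mesoamerican
history: stable ancient Nef (1,000), growth beginning ~13,000 ybp with the
fastest growth between ~7,000 and ~3,000 ybp, a peak of 20,000 around
2,500 ybp, and a roughly ten-fold decline to the present. End-to-end tests
pool six genealogies of 80 lineages — one cultural area's worth of
populations sharing a history, the pooled mode of skyline analysis.

What the generator does **not** emulate: recombination, heteroplasmy,
sequencing error, selection, population admixture with outside sources, and
real hotspot structure (site rates are gamma-distributed, not positionally
calibrated). Passing tests therefore demonstrate statistical correctness of
the estimators under the stated model, not robustness to these real-data
complications.

## Numerical choices

* Permutation p-values: (b+1)/(m+1), seeded generators throughout; seeds
  handed to external libraries stay below 2³¹.
* HPD: shortest-window empirical interval on sorted draws.
* Zero-length coalescent intervals (simultaneous heights) are legal;
  the classic skyline returns N̂ = 0 there with a warning.
* UPGMA heights are clamped monotone against floating-point jitter;
  genealogies are ultrametric within 1e-9 by representation (tip heights
  exactly zero).
* Ties in extrema and period boundaries resolve toward the most recent
  time and the older period respectively.
* Problem sizes in the test suite (e.g. 200 neutral simulations, 20
  skyline-recovery replicates, 50k–150k MCMC iterations) are chosen so the
  Monte-Carlo error is small relative to each assertion's tolerance.

## Known limitations

* Conditioning on a single estimated genealogy understates uncertainty
  relative to joint tree-and-parameter inference; HPD intervals are
  accordingly too narrow on real data. Averaging over several independent
  genealogies (supported) mitigates but does not remove this.
* The skyline localises changes only where coalescent events occur; epochs
  of large Nef are data-poor, so peak times carry hundreds of years of
  uncertainty even with pooled genealogies. The inversion detector's
  peak-tolerance rule compensates for the resulting plateau wobble but
  cannot beat the information limit.
* UPGMA topology estimation degrades when internal branches are short;
  for real analyses a fixed genealogy from external phylogenetic software
  can be supplied as Newick.
* The default motif table is illustrative; real studies must supply a
  curated table.
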