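# Methods

## Data model and cleaning

A `TemporalAlignment` couples an aligned character matrix (A/C/G/T, IUPAC
ambiguity codes, N, gap) with one metadata record per row: population,
sampling period (`pleistocene`, `historical`, `modern`), an optional
calendar age (CE or years BP) and a sampling time in generations before
present. When the metadata omits the sampling generation it defaults to 0
for modern and 40 for historical samples (the two-pulse sampling scheme
used throughout), and to `round(age_BP / g)` for Pleistocene samples with a
BP age.

Coordinates are 1-based with inclusive ranges (GenBank convention). Masks
are logical: excluded regions (e.g. an unresolvable tandem repeat) and
single suspect sites (e.g. a numt-derived variant) are recorded as a column
set and never mutate the sequence data, so masks compose and are auditable.

Missing data are handled by **complete deletion**: any analyzed column with
a non-ACGT character in the chosen sample subset is dropped for the whole
subset before haplotypes are collapsed or statistics computed. Gaps and
ambiguity codes are treated as missing, not as extra states. This matches
the most common default of desktop population-genetic tools; a
pairwise-deletion mode is deliberately out of scope, and any residual
ambiguity therefore shrinks the analyzed column set rather than creating
spurious haplotypes.

## Diversity statistics

* **Segregating sites** S: analyzed columns with ≥ 2 states.
* **Nucleotide diversity** π: mean per-site pairwise difference over all
  C(n,2) pairs. Computed per column as (n² − Σ c_b²)/2 mismatching pairs,
  which makes a bootstrap over columns cheap. The SE is a seeded bootstrap
  (default B = 1000) because the provenance of published SEs from desktop
  tools is typically unstated; resampling columns treats sites as the
  exchangeable unit, which is the usual choice for a single
  non-recombining locus.
* **Haplotype diversity** Hd = n/(n−1)(1 − Σ p_i²) with Nei's analytic
  sampling variance
  2/(n(n−1)) { 2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)² }. Here the formula is
  unambiguous, so no bootstrap is used.
* **Decline test**: t = (π_A − π_B)/√(se_A² + se_B²). Default is Welch with
  Welch–Satterthwaite df; a pooled variant (df = n_A + n_B − 2, pooled
  variance recovered from the SEs) and an explicit df override are
  provided because published analyses sometimes report a df matching
  neither convention. P-values are two-sided; with only two tests per
  analysis no multiplicity correction is applied.
* **Accumulation curves**: for each k ≤ n, the mean and SD (ddof = 1) over
  `n_perm` random orderings of the number of distinct haplotypes among the
  first k samples. At k = n the mean equals the total haplotype count and
  the SD is exactly 0, which is the plateau criterion used in the tests.

## Haplotype networks

Full median-joining network construction (median-vector insertion) is
intentionally not implemented: for descriptive figures of intraspecific
mitochondrial data, a **minimum spanning network** preserves the
mutation-count edges and the temporal sharing structure. Edges are sorted
by (weight, node pair) and grown Kruskal-style; with `keep_ties` every edge
whose endpoints' components were still separate at the start of its weight
class is retained (the ε = 0 network), otherwise a deterministic minimum
spanning tree is returned. Tie-breaking is therefore fully deterministic.

The temporal presence table labels each haplotype exactly once:
`shared` (≥ 2 periods), `private_<latest period>` (only in the most recent
period present in the dataset), or `lost` (only in an earlier period).

## Coalescent model

Mitochondrial DNA is maternally inherited and effectively haploid, so the
model tracks the **female effective population size** N_ef and the
coalescence rate for k active lineages is k(k−1)/(2N) per generation — N,
not 2N. The demography is a single instantaneous decline: backward in
time, size N_cur until T_decline generations before present, N_anc
earlier. Samples are heterochronous: each sampling pulse (time, n)
activates its lineages at that time; default 21 tips at t = 0 and 16 tips
at t = 40 generations (3-year generations place t = 40 roughly 120 years
ago). Epoch boundaries are the sampling times and T_decline; within an
epoch waiting times are exponential and the simulation proceeds event by
event until one lineage remains after all activations.

Mutations follow an **infinite-sites** model: Poisson(μ · L · total branch
length) mutations, each assigned to a branch with probability proportional
to its length and to a distinct site. If a pathological draw produces more
mutations than sites, sites are resampled with replacement and a warning
is raised. The binary derived/ancestral states are expanded to ACGT only
when an alignment is materialized; the summary statistics need only the
genotype incidence matrix. No transition/transversion structure is
modelled — the chosen summaries are insensitive to it.

Validation: mean TMRCA and mean S match the closed forms E[T₂] = N,
E[TMRCA_n] = 2N(1 − 1/n) and Watterson's E[S] = μL·2N·Σ1/i within
3 Monte-Carlo SEs, and the two-epoch serial-sampling TMRCA distribution is
indistinguishable from msprime's under the identical demography (KS test);
msprime is used only as an oracle, never as the engine.

## ABC

Seven default summary statistics: per-period haplotype count, Hd and π
(six), plus the number of haplotypes shared between periods. The
supplementary material enumerating the original choice of statistics was
unavailable, so this set was chosen to be computable from routinely
reported quantities; it is configurable by name. Observed and simulated
summaries run through literally the same kernels (`hd_from_counts`,
`pi_from_hap_counts`), eliminating observed/simulated skew.

Priors: log-uniform N_cur ∈ [20, 20 000] and N_anc ∈ [100, 100 000] (wide,
scale-free, bracketing plausible posteriors), decline time uniform over
90–120 years converted to generations (g = 3 → [30, 40]), μ uniform on
[1.85 × 10⁻⁷, 3.00 × 10⁻⁷] per site per generation. One master
`SeedSequence` spawns a child stream per simulation, so reference tables
are bit-reproducible and order-independent.

Rejection: each statistic standardized by its reference-table SD
(ddof = 1; zero-variance statistics dropped with a warning), Euclidean
distance, exactly `round(retention · n_sims)` accepted with ties at the
cutoff broken by row index. No local-linear regression adjustment is
applied — plain rejection keeps the acceptance bookkeeping exact and
auditable. Posterior summaries report the 2.5/25/50/75/97.5% quantiles per
parameter and for the per-row fold decline N_anc/N_cur.

### What a single locus can and cannot tell you

A mitogenome is one non-recombining locus: every dataset is a single draw
from the coalescent. Under the default bottleneck demography the realized
per-period π has a coefficient of variation near 0.55 and the per-period
haplotype counts scatter by ±2 across replicate genealogies. Consequently
the ABC posterior is approximately **calibrated** (in repeated experiments
at a known truth, ≥ 80% of 95% posterior intervals for N_anc and N_cur
cover it — asserted in the test suite at 100 000 simulations and 1%
retention) but the posterior **median is not a stable point estimate**:
across pseudo-observed replicates the median fold decline varies by a
factor of several either way, tracking the genealogy each dataset happened
to realize. Point estimates from any single mitochondrial dataset should
therefore be read with the full posterior interval, not the median alone.

## Synthetic data

`generate_bottleneck_dataset` writes FASTA + metadata + a truth JSON for
one simulation of the default demography (N_anc = 3650, N_cur = 220,
T = 35 generations, μ = 2.4 × 10⁻⁷, L = 13 224, 16@t40 + 21@t0). It
reuses the coalescent and mutation machinery verbatim; the truth record
stores parameters, seed and realized summaries, and is the single source
for recovery tests. Optional uniform injection of N characters exercises
the complete-deletion path. The generator emulates the statistical
structure of a two-period dataset — it does not emulate read-level
artifacts (damage, coverage, contamination), so passing tests demonstrate
correctness of the statistical pipeline, not robustness to upstream
consensus-calling errors.

`generate_structured_dataset` is deterministic: 16 historical samples over
10 haplotypes (counts 4,3,2,1×7 → Hd = 0.917) and 21 modern samples over 5
haplotypes (counts 8,6,4,2,1 → Hd = 0.762), 3 shared, 2 modern-private, 7
lost — a fixed instance of the qualitative temporal pattern used in the
structure and network tests.

## Problem sizes and numerical choices

The test suite uses 10⁴-replicate Monte-Carlo checks for closed forms, a
10⁴-row reference table for exact rejection bookkeeping, and a 10⁵-row
table with 20 pseudo-observed replicates for the recovery and calibration
experiments; the acceptance script uses the same sizes. Column bootstraps
default to B = 1000. Quantiles use numpy's default linear interpolation.
Integer statistics (S, haplotype counts) carry no SE. Degenerate inputs
(single-sample groups, zero usable columns, zero-variance statistics,
empty distance matrices) raise explicit `ValueError`s rather than
returning NaNs.

## Known limitations

* Single instantaneous decline only; no growth, recovery or structure.
* Infinite-sites mutations without rate heterogeneity or a substitution
  model; unsuitable for saturated or deeply divergent alignments.
* Complete deletion can discard many columns in low-quality datasets;
  there is no pairwise-deletion fallback.
* The minimum spanning network omits inferred median nodes; path lengths
  between distant haplotypes can exceed those a median-joining network
  would draw.
* Rejection ABC without regression adjustment needs large reference
  tables; the defaults are sized for a single mitochondrial locus.
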