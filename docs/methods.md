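# Methods

`ibdnet` implements the analytical chain used to study relatedness structure in
ancient-DNA cohorts: identity-by-descent (IBD) sharing networks with community
detection and topology metrics, f4-statistics with block-jackknife errors, and a
transparent two-way admixture-proportion estimator — together with the synthetic
generators needed to validate every stage against exact ground truth.

## Genetic map

All coordinates are genetic (centimorgans). The default map is a fixed table of
sex-averaged lengths for the 22 human autosomes totalling 3545.4 cM
(`ibdnet.genmap.DEFAULT_AUTOSOME_CM`). It is a documented stand-in, not a
reconstruction of any capture panel's map: every quantity the package validates
(segment-length distributions, sharing fractions, jackknife block counts)
depends only on chromosome lengths, not on local recombination-rate variation.
Custom maps are accepted everywhere a map is used. The X chromosome is excluded;
all analyses are autosomal.

## Pedigree simulation and ground-truth IBD

Pedigrees are built from founder couples; each couple has a configurable number
of children, children marry fresh unrelated founders or (at a configurable rate,
or an exact count) members of another family. The meiotic distance between any
two members — the number of meioses on the shortest genealogical path
(parent–child 1, full sibs 2, first cousins 4) — is available as ground truth.

Haplotypes are dropped through the pedigree under the Haldane model: crossover
counts per chromosome are Poisson(length/100), positions uniform, no
interference, starting haplotype fair-coin. Haldane was chosen because it is
the model under which segment lengths between relatives at m meioses are
(approximately) exponential with mean 100/m cM, which is the closed form the
validation suite leans on. Each founder carries two uniquely labelled
haplotypes, so IBD is exact bookkeeping, not inference.

IBD between two diploid individuals is reported **half-identical**: a position
is shared when at least one of the four haplotype pairings carries the same
founder label, and regions identical on both pairings (IBD2) are counted once.
This mirrors what imputation-based segment callers detect in ancient genomes;
haplotype-resolved IBD1/IBD2 is deliberately not reported. Consequences worth
knowing:

- Parent–offspring sharing covers every chromosome end to end; the summed total
  equals the map length exactly, every replicate (this is asserted, not
  approximate).
- Full sibs cover 3/4 of the genome in expectation (a locus is shared on at
  least one pairing with probability 3/4).
- Segment lengths follow the exponential theory only approximately. For
  ancestor–descendant chains at m = 4 the mean length of segments ≥ 12 cM runs
  ~6% *above* the memoryless value 12 + 25 cM (shared material re-entered after
  short excursions is merged), while for first cousins it runs ~10% *below* it
  (cousin sharing is an intersection/union over the two grandparental paths and
  is not a Markov tract process). The validation suite checks the first-cousin
  value at the 10% tolerance; the deviation is a property of half-identical
  sharing itself, stable across seeds, and should be expected on real caller
  output too.

The simulator reports segments above a configurable floor (default 8 cM in the
pipeline, matching the shortest segments such callers emit; 0 in the library
primitive so tests can see everything).

## Metadata

Each individual carries a date interval in years CE (the style of mixed
radiocarbon/archaeological dating), a group label aligned with its family, and
optional coordinates. True years are `base_year + 30·generation + N(0, jitter)`
by default (30 y/generation, jitter 10 y, interval half-width 50 y) — wide
enough to exercise the temporal filter, narrow enough that within-cohort edges
survive it. The true year is recorded alongside the interval so temporal
filters can be validated.

## IBD network

Pair summaries count segments ≥ 8, ≥ 9 and ≥ 12 cM, the longest segment, and
the summed length of segments > 12 cM. The graph is then de-noised in a fixed
order:

1. an edge exists iff the pair shares ≥ 1 segment ≥ 9 cM (edge weight = longest
   segment);
2. edges between individuals separated by more than 600 years are dropped — by
   default the absolute difference of date-interval midpoints; an interval-gap
   mode is provided because the operand of such temporal filters is usually
   under-specified in practice;
3. nodes of degree < 2 are dropped in a single pass (the filter is not
   iterated, and it runs before largest-component extraction, which is a
   separate operation).

The pipeline is idempotent (re-applying it to its own output changes nothing)
and monotone in its thresholds; both are asserted on randomized inputs.

Communities come from the Leiden algorithm (leidenalg, RB-configuration
quality, which equals weighted modularity at the default resolution 1.0),
seeded for determinism, with the weighted Newman modularity reported as the
partition quality. Edge weight for clustering is the longest-segment weight;
module strengths instead sum the > 12 cM totals — the two weights are kept
explicit and are never mixed. Node metrics are unweighted: degree k, its
within/between-module split kW + kB = k, and the local clustering coefficient
(0 for degree < 2). Module metrics attribute inter-module link weight to both
endpoint modules and leave per-link averages undefined (NaN) when a module has
no links of that kind.

Relative pairs are flagged when they share strictly more than two segments
≥ 12 cM (the stricter of the two conventions in circulation; `min_segments=2`
selects the laxer one). Flagged pairs carry an *approximate* degree class
looked up from expected sums of > 12 cM sharing per meiotic distance; the
lookup constants were Monte-Carlo derived from this package's own simulator
(400 replicates per distance, ancestor chains, default map) and class
boundaries are geometric midpoints. Collateral relatives share roughly twice
the chain expectation at the same distance, which is one reason the class is
labelled approximate rather than an estimate.

Graphs export to GEXF (timestamps pinned so output is byte-stable) plus
node/edge CSVs that round-trip to an identical graph.

## f4-statistics

f4(A, B; C, D) is the mean over SNPs of (pA − pB)(pC − pD), computed
complete-case (a SNP missing in any of the four populations is excluded —
exact no-op relative to dropping the row). Standard errors come from a
weighted delete-one block jackknife: blocks are contiguous ≤ 5 cM windows
within chromosomes (field convention; configurable), weighted by SNP count,
with the pseudovalue variance formula that reduces to the ordinary delete-one
jackknife at equal weights. Affinity profiles call a target toward a reference
only at |Z| ≥ 3, the conventional significance band; under a symmetric null
the band fires in well under 1% of replicates (calibration is part of the
test suite). Sign convention: in f4(base, target; ref1, ref2) shared drift
between target and ref1 drives the statistic negative.

No small-sample bias correction is applied when mixing pseudo-haploid and
diploid calls through frequency averaging: f4 contrasts across populations
sampled independently, where within-population sampling noise cancels in
expectation.

## Two-way admixture estimator

Under target = α·S1 + (1−α)·S2, the identity
f4(base, O; target, S2) = α · f4(base, O; S1, S2) holds exactly for every
outgroup O. α is therefore estimated by regression through the origin of the
left-hand statistics on the right-hand ones across outgroups, with the whole
fit re-estimated under delete-one-block jackknife for its SE. α is *not*
clamped to [0, 1]; out-of-range estimates are diagnostic and only flagged
(`admissible=False`). The residual statistic sums squared standardized
residuals and is referred to chi-square with (n_outgroups − 1) degrees of
freedom; it is labelled `fit_p_approx` in all outputs because it approximates,
and does not replicate, the fit test of likelihood-based admixture tools.
When the outgroups cannot distinguish the sources (all identifying f4 jointly
consistent with zero at the 0.1% level) the fit is refused with a diagnostic
rather than returning an unidentified α.

## Drift simulator

Populations sit on a rooted tree; each branch applies Balding–Nichols drift
(child frequency Beta-distributed around the parent's with variance
F·p(1−p)); ancestral frequencies are Uniform(0.05, 0.95). The admixed
population's frequencies are the *exact* mixture of its sources — no
post-admixture drift by default — so α recovery error reflects only sampling
noise and estimator behaviour. The standard experimental layout
(`two_way_tree`) splits two internal lineages off the root and hangs each
source with half the outgroups off one of them, making the outgroups
differentially related to the sources (the identifying condition); a deep
outgroup off the root plays the base role. Default drift F = 0.02 per branch
spans the 0.01–0.05 regime used in the recovery experiments. Pseudo-haploid
sampling draws one allele per individual per SNP (never a heterozygote) with
independent missingness, default 10 individuals per population and 10%
missingness.

What the generator does **not** emulate: linkage disequilibrium between SNPs
(sites are independent given the frequencies, so the block jackknife is if
anything conservative on real data), ascertainment bias of capture panels,
reference bias, and post-mortem damage. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to those artefacts.

## Pipeline and reproducibility

The pipeline derives named sub-seeds from one master seed via
`numpy.random.SeedSequence`, so stages are individually re-runnable. Every
output artefact (TSV/CSV/GEXF/JSON/summary) is byte-identical across reruns of
the same configuration; timings go to the log only. The demo configuration —
2 families × 4 generations (~100 individuals), 20 000 SNPs, α = 0.7 — runs in
a few seconds on one CPU; validation experiments (10 000 sib pairs, 200-replicate
null calibration, 50 admixture fits at 50 000 SNPs) each stay in the tens of
seconds to low minutes.

Problem sizes in the test and acceptance suites were chosen so the full
validation runs at desk scale: they are large enough that Monte-Carlo error is
small against every tolerance asserted (e.g. sib-fraction SE ≈ 0.0004 against
a ±0.01 band) and no larger.

## Known limitations

- Community recovery is scored against family labels; households formed by a
  cross-family marriage are genuinely assignable to either family, so the
  adjusted Rand index against labels can dip below 1 even when the partition
  is defensible. The planted-recovery check therefore scores the mean ARI
  across seeds.
- The degree-class annotation is a coarse lookup, deliberately not a
  likelihood-based kinship estimate.
- The chi-square fit probability of the admixture model is approximate (see
  above) and should not be compared numerically against likelihood-based
  tools' p-values.
- Half-identical IBD cannot separate IBD1 from IBD2, so close-relative classes
  (parent–child vs full sibs) overlap in summed sharing.
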