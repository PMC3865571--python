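# Methods

`founderscan` packages the statistical machinery needed to find a recessive
disease mutation by exome sequencing in a small family from an endogamous
founder population, where the textbook filtering recipe breaks down: the
genome-wide excess of homozygous rare "deleterious" variants produced by
unreported consanguinity and historical endogamy floods the candidate list,
and in-silico pathogenicity predictors cannot separate a private causal
mutation from a drifted founder polymorphism. The package implements the
four analysis layers that resolve this situation — inbreeding estimation,
spaced-marker panel construction, a step-wise filter cascade with family
and population-control constraints, and population-screen plausibility
statistics — together with a pedigree genotype simulator that provides
ground truth for all of them.

## Synthetic cohorts (`founderscan.simulate`)

The generator emulates a founder-population study, not any particular real
dataset. Its components:

**Founder frequency spectrum.** Alternate-allele frequencies are drawn from
Beta(0.2, 2) — heavily skewed toward rare alleles with a drifted common
tail — and truncated to [10⁻³, 1−10⁻³] so every marker is usable in
likelihood computations. An external-"database" frequency is a
multiplicative log-normal perturbation of q (σ = 0.5), with 5% of variants
set to db_af = 0, modelling population-private variants absent from public
databases. The Beta shapes are a qualitative emulation of drift and
limited diversity; nothing downstream depends on their exact values.

**Gene dropping.** Founders receive two haplotypes from a pool of
`founder_pool_size` (default 100) label-tagged haplotypes whose alleles are
independent Bernoulli(q) draws (linkage equilibrium among founders).
Haplotypes are assigned *without replacement* whenever the pool is large
enough, so identical labels arise only through the pedigree and realized
autozygosity is exactly the pedigree-descent quantity; a smaller pool
recycles haplotypes and models background endogamy. Meioses place
crossovers as a Poisson process on the cM scale (Haldane model, no
interference) — the simplest model consistent with cM-based marker
spacing. Transmission copies allele *and* label arrays, so per-marker IBD
status (label equality) is known exactly for every individual. Population
controls additionally carry a configurable self-kinship
(`control_inbreeding`, default 0.02): with that probability a control's two
haplotypes are the same pool haplotype, which reproduces the
within-individual homozygosity excess of an endogamous isolate. Dosage
error is a symmetric perturbation (hom→het, het→random hom) at rate ε
(default 0.005); missingness is independent per call.

Supported parental consanguinity loops and their analytic offspring
inbreeding coefficients: first cousins (1/16), second cousins (1/64),
avuncular (1/8), none (0). Calibration of realized autozygosity against
these values is part of the test suite (500 replicate families on a
30 × 100 cM genome, tolerance 0.01).

**Planted candidate pair.** Two novel missense variants are inserted at
neighbouring positions on one chromosome, both homozygous in every
affected, heterozygous in both parents (the alternate allele descends a
real ancestor chain, so all trios stay Mendelian-consistent), absent from
databases, and annotated with maximal predictor scores (PolyPhen-2 1.00;
SIFT 0.00 and 0.05). They differ only in the population: the causal variant
is private; the confounder segregates among controls at a 14% carrier /
1.1% homozygote rate — visible as heterozygotes in the small control-exome
set (which does not exclude it from the cascade) and resolvable only by a
large population screen. These rates, and the screen sizes of 721 and 566
controls, are the study conditions the generator emulates.

**What the generator does not model:** linkage disequilibrium among founder
haplotypes (markers are independent given the pool), sex chromosomes,
genotyping error that correlates with allele frequency or depth,
variable recombination maps (1 cM/Mb uniform), and mutation. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to real-exome artefacts such as LD between
panel markers or batch-specific error.

## Marker panel (`founderscan.panel`)

The HMM assumes approximate linkage equilibrium between consecutive
markers, so panels are built by a greedy left-to-right scan per chromosome:
accept a marker iff its expected heterozygosity 2q(1−q) is at least
`min_het` (default 0.3) and it lies at least `min_spacing_cm` (default
0.15 cM) beyond the last accepted marker. Expected heterozygosity comes
from population allele frequencies, never from the family itself, whose
observed heterozygosity is biased downward by autozygosity. The greedy rule
is deterministic, order-stable, and yields a maximum-size spaced subset
(verified against exhaustive enumeration in tests); spacing is the sole
operationalisation of linkage equilibrium — no r² pruning is attempted.
cM positions are linearly interpolated between map anchors, extrapolating
at the local rate beyond the outermost anchors.

## Autozygosity HMM (`founderscan.inbreeding`)

A two-state hidden Markov chain along each chromosome models whether the
two alleles of one individual are IBD. Parameters: the inbreeding
coefficient f (stationary IBD probability) and the switch rate a per
Morgan; over a genetic distance d Morgans,

    P(IBD→IBD)    = e^(−ad) + (1 − e^(−ad)) f
    P(nonIBD→IBD) = (1 − e^(−ad)) f.

Emissions are Hardy–Weinberg genotype probabilities in the non-IBD state
and {1−q, 0, q} under IBD; a mixing weight ε (default 0.005, bounded at
0.1) replaces the IBD emission by (1−ε)·IBD + ε·HWE so that isolated
miscalled heterozygotes inside autozygous tracts do not zero the
likelihood. Missing genotypes emit probability 1 in both states.
Chromosomes are independent and start from the stationary distribution
(f, 1−f); numerically this is implemented by giving the first marker of
each chromosome an infinite predecessor distance, which collapses the
transition to the stationary vector.

The forward pass is scaled per marker (no underflow at ≥10⁴ markers) and
broadcasts over arrays of (f, a), so a full parameter grid costs one sweep
over the markers. `fit()` scans f ∈ {0, 0.01, …, 0.5} × a on a 13-point
log grid over [0.01, 10], then refines by successively zoomed 9 × 9 local
grids (three rounds, spans shrinking fourfold). A zoom window re-centres
while its optimum sits on a window edge and still improves the likelihood,
so refinement can walk to the f ∈ {0, 1} boundary even though the coarse
scan is capped at 0.5. The procedure is entirely deterministic; a flat
likelihood (e.g. all genotypes missing) is reported as f̂ = 0 with a
`non_identifiable` flag rather than an arbitrary interior point.
Per-marker posterior IBD probabilities come from a scaled forward–backward
pass at the optimum; their genome average tracks f̂ and is reported
alongside it.

Population allele frequencies are taken from the founder/control table;
estimating q from the family members themselves is deliberately
unsupported, because autozygosity biases within-family frequencies.

## Filter cascade (`founderscan.cascade`)

Four stages in fixed order, each recording input/output counts and
surviving variant ids:

1. **rare_deleterious** — db_af strictly below 0.01 AND (class ∈
   {nonsense, frameshift_indel, inframe_indel, splice_site} OR missense
   with PolyPhen-2 ≥ 0.85 and SIFT ≤ 0.05). The conjunction ("both") is the
   default reading of requiring agreement between the two predictors;
   "either" is available because real pipelines differ. Cutoffs are the
   conventional "probably damaging" / "deleterious" thresholds, inclusive
   at the boundary.
2. **homozygous_affected** — dosage 2 in every affected.
3. **parents_het** — dosage 1 in both parents; skipped with an explicit
   trace note if parent samples are absent.
4. **control_exomes** — no homozygote among population controls;
   heterozygous controls never exclude, since carriers of a founder allele
   are expected in an isolate.

Missing genotypes fail the zygosity stages by default ("strict" — the
conservative choice for a diagnostic shortlist); the "permissive" policy
passes and flags them. The per-variant predicates commute, so stage order
changes intermediate counts but never the final set (a tested property).
The trace's metadata reports the per-affected count of rare-deleterious
homozygotes both before and after the sharing requirement, since either
reading of a "per-patient candidate load" can be of interest. An optional
call-rate pre-filter (genotype present in ≥80% of samples) exists but is
off by default: the cascade assumes a quality-passed VCF.

## Population screen (`founderscan.screen`)

Genotype counts (n_total, n_het, n_hom) from screening one candidate in
healthy population controls are modelled binomially. Reported quantities:
carrier frequency n_het/n (carriers = heterozygotes only; homozygotes are
listed separately), homozygote frequency n_hom/n, allele frequency
q = (n_het + 2·n_hom)/(2n), the Hardy–Weinberg homozygote expectation q²,
and exact Clopper–Pearson 95% confidence intervals (conservative, the
standard choice for rare counts). Under complete penetrance the homozygote
frequency among *healthy* controls directly estimates the disease
prevalence the variant would imply; the verdict compares its exact CI with
a rare-disease prevalence ceiling (default 10⁻⁴):

* `implausibly_common` — the CI lower bound exceeds the ceiling;
* `consistent_with_pathogenic` — the CI upper bound is below it;
* `indeterminate` — the screen cannot decide. Note that 0 homozygotes in
  566 controls is *indeterminate* (rule-of-three upper bound ≈ 0.0065
  > 10⁻⁴): a few hundred controls can expose an implausibly common
  "mutation" but cannot certify a private one.

Both q² and the observed homozygote frequency are reported because their
gap measures homozygosity excess, itself a signature of endogamy.

The burden comparison between population samples (per-individual
proportions of homozygous rare-deleterious variants) uses Welch's
unequal-variance t statistic with Welch–Satterthwaite degrees of freedom
and a one-sided alternative, implemented from the explicit formulas and
cross-checked against an independent reference implementation to 10⁻⁹.

## Pipeline and formats (`founderscan.io`, `founderscan.pipeline`)

The orchestrated order is panel → inbreeding (confirming the autozygosity
assumption before trusting a homozygosity-based filter) → cascade →
screen. The JSON report is schema-versioned, always prints counts
alongside frequencies so rounding is auditable, and is byte-identical for
a fixed seed. Formats: VCF v4.2 (GT only, 1-based, biallelic records —
multi-allelic input is rejected with advice to pre-split), PLINK 6-column
PED and 4-column map (cM in column 3), TSV annotation/frequency/panel
tables, and a BED-like posterior track with 0-based half-open intervals.
Role inference from a PED file: affected individuals by phenotype 2,
"parent" means parent of an affected, unrelated singleton founders are
population controls, everyone else (loop ancestors) is "other".

## Problem sizes used in the checks

The heavy checks run at deliberately chosen scales: HMM recovery uses 100
replicate genomes of 30 chromosomes × 100 cM with 5 000 markers (mean f̂
within 0.01 of the simulated 1/16; 100 outbred replicates with f̂ < 0.01 in
≥95%); simulator calibration uses 500 replicate first-cousin families at
100 markers/chromosome; the end-to-end narrative runs the full default
cohort (20 000 variants, 22 chromosomes). These sizes keep the complete
suite comfortably within a coffee break on one CPU while leaving
Monte-Carlo error well inside the stated tolerances.

## Known limitations

* The HMM estimates realized autozygosity, whose sampling variance around
  the pedigree expectation is large for a single individual (SD ≈ 0.035
  for a first-cousin offspring on a 30 M genome); statements about an
  individual's ancestry from one f̂ are correspondingly soft.
* With ~0.15 cM marker spacing inside an exome, residual LD exists in real
  data and is not modelled; the spacing heuristic only approximates
  linkage equilibrium.
* The cascade covers the autosomal recessive homozygous-by-descent model
  only — no compound heterozygotes, X-linked inheritance, de novo
  variants, or structural variation.
* The screen's prevalence logic assumes complete penetrance and a
  well-mixed control panel; incomplete penetrance weakens the
  `implausibly_common` verdict, and subisolate structure can distort
  carrier frequencies in either direction.
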