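# founderscan

Diagnostic exome analysis for recessive disease in **inbred founder
populations** — genetic isolates with strong founder effects, drift, and
historical endogamy. In such populations the standard trio-filtering recipe
struggles twice over: unreported consanguinity floods each exome with
hundreds of homozygous rare "deleterious" variants, and a drifted founder
polymorphism can look exactly like a private pathogenic mutation to every
in-silico predictor. `founderscan` provides the statistical layers that
resolve both problems, plus a simulator that generates founder-population
cohorts with known ground truth to validate them.

The package is aimed at statistical geneticists and diagnostic
bioinformaticians analysing small consanguineous families with ethnically
matched controls, and at anyone who needs a tested, seedable founder-
population genotype simulator.

## What it computes

**Inbreeding estimation.** A two-state autozygosity HMM along the genome:
at each marker the individual's alleles are identical by descent (IBD) or
not. With inbreeding coefficient *f* and switch rate *a* per Morgan, the
transition over *d* Morgans is P(IBD→IBD) = e^(−ad) + (1 − e^(−ad))·f and
P(nonIBD→IBD) = (1 − e^(−ad))·f; emissions are Hardy–Weinberg
{(1−q)², 2q(1−q), q²} in the non-IBD state and {1−q, 0, q} under IBD, with
an ε-mixture absorbing genotyping error. `InbreedingHMM(...).fit()`
maximises the forward likelihood over (f, a) and returns per-marker
posterior IBD probabilities — statsmodels-style Model/Results objects.

**Marker panels.** Greedy extraction of a spaced (≥0.15 cM), polymorphic
(expected heterozygosity ≥0.3) marker panel from exome calls, the input
the HMM needs to be approximately valid under linkage equilibrium.

**Step-wise filter cascade.** Rare (<1% in databases) and putatively
damaging (nonsense / indel / splice-site, or missense with PolyPhen-2
≥0.85 and SIFT ≤0.05) → homozygous in every affected → heterozygous in
both parents → no homozygote among control exomes. Full per-stage
accounting; heterozygous controls never exclude a variant, because
carriers of a founder allele are expected in an isolate.

**Population-screen plausibility.** For a candidate genotyped in *n*
population controls with n_het heterozygotes and n_hom homozygotes:
carrier and homozygote frequencies with exact Clopper–Pearson intervals,
allele frequency q and the HWE expectation q², and — under complete
penetrance — the disease prevalence the variant would imply, compared
against a rare-disease ceiling (default 10⁻⁴). Also Welch's one-sided
unequal-variance t-test for homozygous-deleterious burden comparisons.

**Simulation.** Gene-dropping through configurable pedigrees
(first-cousin, second-cousin, avuncular loops) with Haldane crossovers on
a genetic map, label-tracked founder haplotypes (exact realized
autozygosity), a drifted Beta(0.2, 2) frequency spectrum, endogamous
population controls, and a planted causal/confounder variant pair.

## Worked example

A candidate mutation with perfect predictor scores is genotyped in 721
population controls: 101 heterozygotes and 8 homozygotes.

```
$ founderscan screen --n 721 --het 101 --hom 8
Population screen — binomial model with exact CIs
======================================================
controls genotyped        721
carriers (het)            101  (14%; 11.56–16.76%)
homozygotes               8  (1.1%; 0.48–2.17%)
alternate allele freq q   0.0811
HWE homozygote expect q²  0.00658
expected prevalence       0.0111 (complete penetrance)
verdict (ceiling 0.0001)   implausibly_common
```

14% of healthy controls carry the allele and 1.1% are homozygous; if the
variant caused a fully penetrant recessive disease, about 1 in 100 of the
population would be affected. The verdict `implausibly_common` says the
exact 95% CI of that implied prevalence sits entirely above the 10⁻⁴
rare-disease ceiling: the variant is a founder polymorphism, whatever the
predictors claim. (Contrast 0 carriers in 566 controls, which returns
`indeterminate` — a screen that size can refute a candidate but cannot
certify one.)

The same logic end-to-end on a synthetic study (two affected sibs,
first-cousin parents, 10 control exomes, 20 000 variants, a planted causal
variant and a planted founder-polymorphism confounder):

```
$ founderscan run --simulate --seed 0 --out-dir demo/
cascade candidates: ['chr9:2600000:G:T', 'chr9:2750000:A:C']
after screen:       ['chr9:2600000:G:T']
report: demo/report.json
```

Both planted variants survive every exome-filter stage — they are
constructed to be indistinguishable there — and only the 721-control
population screen removes the confounder, leaving the causal variant. The
report also contains each family member's fitted inbreeding coefficient
(the affecteds' f̂ is elevated, consistent with first-cousin parents) and
the per-stage filter trace.

Library use mirrors the CLI:

```python
from founderscan import ScreenCounts, PopulationScreen
res = PopulationScreen(ScreenCounts(n_total=721, n_het=101, n_hom=8)).fit()
res.expected_prevalence   # 0.0111
res.verdict(1e-4)         # 'implausibly_common'
```

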