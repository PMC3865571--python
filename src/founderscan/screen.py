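"""Population-screen statistics and carrier-frequency plausibility.

When exome filtering leaves more than one fully segregating candidate, the
decisive evidence is population-level: genotype the variant in a large
panel of ethnically matched healthy controls and ask whether its
homozygote frequency is compatible with causing a rare recessive disease.
Under complete penetrance, the homozygote frequency among healthy controls
is a direct estimate of the disease prevalence the variant would imply; a
"pathogenic" allele observed homozygous in ~1% of healthy adults is a
polymorphism, whatever the in-silico predictors say.

The screen is a binomial model fitted to genotype counts, reported with
exact (Clopper–Pearson) confidence intervals::

    res = PopulationScreen(ScreenCounts(n_total=721, n_het=101, n_hom=8)).fit()
    res.carrier_freq, res.hom_freq, res.verdict(1e-4)

The module also provides the homozygous-deleterious burden comparison
between population samples (Welch's unequal-variance one-sided t-test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

VERDICTS = ("consistent_with_pathogenic", "implausibly_common", "indeterminate")
DEFAULT_PREVALENCE_CEILING = 1e-4


@dataclass(frozen=True)
class ScreenCounts:
    """Genotype counts from screening one variant in population controls."""

    n_total: int
    n_het: int
    n_hom: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_het, self.n_hom) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_het + self.n_hom > self.n_total:
            raise ValueError("n_het + n_hom exceeds n_total")


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


class PopulationScreen:
    """Binomial model of a variant's genotype counts in healthy controls."""

    def __init__(self, counts: ScreenCounts, conf_level: float = 0.95):
        if counts.n_total == 0:
            raise ValueError("cannot screen zero controls")
        if not 0.0 < conf_level < 1.0:
            raise ValueError("conf_level must lie in (0, 1)")
        self.counts = counts
        self.conf_level = conf_level

    def fit(self) -> "ScreenResults":
        c = self.counts
        n = c.n_total
        q = (c.n_het + 2 * c.n_hom) / (2 * n)
        return ScreenResults(
            counts=c,
            conf_level=self.conf_level,
            carrier_freq=c.n_het / n,
            hom_freq=c.n_hom / n,
            allele_freq=q,
            hwe_hom=q * q,
            carrier_ci=clopper_pearson(c.n_het, n, self.conf_level),
            hom_ci=clopper_pearson(c.n_hom, n, self.conf_level),
        )


@dataclass
class ScreenResults:
    """Frequencies, exact CIs and the prevalence-plausibility verdict.

    ``expected_prevalence`` (complete penetrance) is the observed
    homozygote frequency itself; ``hwe_hom`` = q² is the random-mating
    expectation, and their gap measures the homozygosity excess typical of
    an endogamous population.
    """

    counts: ScreenCounts
    conf_level: float
    carrier_freq: float
    hom_freq: float
    allele_freq: float
    hwe_hom: float
    carrier_ci: tuple[float, float]
    hom_ci: tuple[float, float]

    @property
    def expected_prevalence(self) -> float:
        return self.hom_freq

    @property
    def carrier_pct(self) -> float:
        """Carrier frequency in %, rounded to the nearest integer."""
        return round(100.0 * self.carrier_freq)

    @property
    def hom_pct(self) -> float:
        """Homozygote frequency in %, rounded to one decimal."""
        return round(100.0 * self.hom_freq, 1)

    def verdict(self, prevalence_ceiling: float = DEFAULT_PREVALENCE_CEILING) -> str:
        return plausibility_verdict(self, prevalence_ceiling)

    def to_dict(self) -> dict:
        return {
            "n_total": self.counts.n_total,
            "n_het": self.counts.n_het,
            "n_hom": self.counts.n_hom,
            "carrier_freq": self.carrier_freq,
            "hom_freq": self.hom_freq,
            "allele_freq": self.allele_freq,
            "hwe_hom": self.hwe_hom,
            "expected_prevalence": self.expected_prevalence,
            "carrier_ci": list(self.carrier_ci),
            "hom_ci": list(self.hom_ci),
            "conf_level": self.conf_level,
            "verdict": self.verdict(),
        }

    def summary(self) -> str:
        c = self.counts
        pct = 100.0
        return "\n".join([
            "Population screen — binomial model with exact CIs",
            "=" * 54,
            f"controls genotyped        {c.n_total}",
            f"carriers (het)            {c.n_het}  ({self.carrier_pct:.0f}%; "
            f"{pct * self.carrier_ci[0]:.2f}–{pct * self.carrier_ci[1]:.2f}%)",
            f"homozygotes               {c.n_hom}  ({self.hom_pct:.1f}%; "
            f"{pct * self.hom_ci[0]:.2f}–{pct * self.hom_ci[1]:.2f}%)",
            f"alternate allele freq q   {self.allele_freq:.4f}",
            f"HWE homozygote expect q²  {self.hwe_hom:.5f}",
            f"expected prevalence       {self.expected_prevalence:.4f} "
            f"(complete penetrance)",
            f"verdict (ceiling {DEFAULT_PREVALENCE_CEILING:g})   {self.verdict()}",
        ])


def screen_stats(counts: ScreenCounts, conf_level: float = 0.95) -> ScreenResults:
    """Functional wrapper: ``PopulationScreen(counts).fit()``."""
    return PopulationScreen(counts, conf_level).fit()


def plausibility_verdict(result: ScreenResults,
                         prevalence_ceiling: float = DEFAULT_PREVALENCE_CEILING) -> str:
    """Compare the implied disease prevalence with a rare-disease ceiling.

    ``implausibly_common`` when even the lower CI bound of the homozygote
    frequency exceeds the ceiling; ``consistent_with_pathogenic`` when the
    upper bound stays below it; ``indeterminate`` otherwise (the screen was
    too small to decide — the honest outcome for 0 homozygotes in a few
    hundred controls).
    """
    if not 0.0 < prevalence_ceiling < 1.0:
        raise ValueError("prevalence_ceiling must lie in (0, 1)")
    lo, hi = result.hom_ci
    if lo > prevalence_ceiling:
        return "implausibly_common"
    if hi < prevalence_ceiling:
        return "consistent_with_pathogenic"
    return "indeterminate"


# ---------------------------------------------------------------------------
# homozygous-deleterious burden
# ---------------------------------------------------------------------------

def homozygous_deleterious_proportion(cohort, sample: str, annotations,
                                      config=None) -> float:
    """Per-individual proportion of variants that are homozygous alternate
    and pass the rare-deleterious filter."""
    from .cascade import CascadeConfig, stage_rare_deleterious

    config = config or CascadeConfig()
    total = cohort.n_variants
    if total == 0:
        raise ValueError("individual has no variants")
    qualifying = stage_rare_deleterious(cohort.variant_ids, annotations, config)
    dos = cohort.subset_variants(qualifying).dosage_of(sample)
    return float((dos == 2).sum() / total)


@dataclass
class BurdenResult:
    """Welch's unequal-variance one-sided comparison of two burden samples."""

    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_one_sided: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {"mean_a": self.mean_a, "mean_b": self.mean_b,
                "t_stat": self.t_stat, "df": self.df,
                "p_one_sided": self.p_one_sided, "n_a": self.n_a, "n_b": self.n_b}

    def summary(self) -> str:
        return (f"Welch one-sided t-test (H1: mean_a > mean_b)\n"
                f"  mean_a = {self.mean_a:.5f} (n={self.n_a}), "
                f"mean_b = {self.mean_b:.5f} (n={self.n_b})\n"
                f"  t = {self.t_stat:.3f}, df = {self.df:.3f}, "
                f"P = {self.p_one_sided:.3g}")


def welch_one_sided(group_a, group_b) -> BurdenResult:
    """Welch t statistic, Welch–Satterthwaite df, one-sided p (mean_a > mean_b).

    t = (x̄_a − x̄_b) / sqrt(s²_a/n_a + s²_b/n_b), with sample variances
    (ddof 1); df follows the Welch–Satterthwaite approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return BurdenResult(float(a.mean()), float(b.mean()), 0.0,
                                float(len(a) + len(b) - 2), 0.5, len(a), len(b))
        raise ValueError("both groups degenerate (zero variance)")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    p = float(stats.t.sf(t, df))
    return BurdenResult(float(a.mean()), float(b.mean()), float(t), float(df),
                        p, len(a), len(b))
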