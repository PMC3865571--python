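"""Founder-population cohort simulator with known autozygosity ground truth.

The generator emulates the statistical structure of an endogamous genetic
isolate: a drifted allele-frequency spectrum (Beta-distributed founder
frequencies, skewed toward rare alleles), a nuclear family whose parents are
related through an undeclared consanguinity loop, a panel of population
controls, and two planted variants — a private causal recessive mutation and
a high-frequency founder polymorphism that mimics one.

Gene dropping transmits founder haplotypes down the pedigree with crossovers
placed as a Poisson process on the cM scale (Haldane model, no
interference).  Founder-haplotype labels are carried alongside alleles, so
realized autozygosity (both labels identical by descent) is known exactly
for every individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (MISSING, AlleleFreqTable, AnnotationTable, CohortGenotypes,
                     make_variant_frame, variant_key)
from .genmap import GeneticMap
from .pedigree import LOOP_INBREEDING, Pedigree, quad_family

# rng sub-streams, so each operation is independently reproducible
_STREAM_FREQS = 1
_STREAM_GENO = 2
_STREAM_PLANT = 3
_STREAM_ANNOT = 4
_STREAM_SCREEN = 5

# labels for planted haplotypes sit above any founder-pool index
_PLANT_ANCESTRAL_BASE = 9_000_000
_PLANT_UNIQUE_BASE = 10_000_000

_CLASS_PROBS = {
    "missense": 0.50,
    "synonymous": 0.30,
    "other": 0.13,
    "nonsense": 0.02,
    "frameshift_indel": 0.02,
    "splice_site": 0.02,
    "inframe_indel": 0.01,
}

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; a fixed seed gives byte-identical outputs.

    Defaults describe the emulated study: an exome-scale marker set on 22
    autosomes, a founder pool of 100 haplotypes, first-cousin parents, two
    affected sibs, a small set of ethnically matched control exomes, and a
    rare-skewed Beta(0.2, 2) founder frequency spectrum.
    """

    n_variants: int = 20_000
    n_chromosomes: int = 22
    map_length_cm: float = 120.0
    founder_pool_size: int = 100
    beta_shape_a: float = 0.2
    beta_shape_b: float = 2.0
    consanguinity_loop: str = "first_cousin"
    genotyping_error_rate: float = 0.005
    missing_rate: float = 0.01
    seed: int = 0
    # cohort composition
    n_affected: int = 2
    n_pop_controls: int = 10
    # probability a population control's two haplotypes are IBD (background
    # endogamy of the isolate, beyond the family's declared loop)
    control_inbreeding: float = 0.02
    # database-frequency model
    db_absent_fraction: float = 0.05
    db_noise_sigma: float = 0.5
    q_floor: float = 1e-3
    # planted variants
    confounder_carrier_fraction: float = 0.14
    confounder_hom_fraction: float = 0.011
    screen_n_confounder: int = 721
    screen_n_causal: int = 566

    def __post_init__(self) -> None:
        if self.beta_shape_a <= 0 or self.beta_shape_b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        for name in ("genotyping_error_rate", "missing_rate", "db_absent_fraction",
                     "confounder_carrier_fraction", "confounder_hom_fraction",
                     "control_inbreeding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.consanguinity_loop not in LOOP_INBREEDING:
            raise ValueError(f"unknown consanguinity loop {self.consanguinity_loop!r}")
        if self.n_variants < 1 or self.n_chromosomes < 1 or self.founder_pool_size < 2:
            raise ValueError("n_variants, n_chromosomes >= 1 and founder_pool_size >= 2 required")


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


# ---------------------------------------------------------------------------
# sites and frequencies
# ---------------------------------------------------------------------------

def default_map(params: SimParams) -> GeneticMap:
    return GeneticMap.uniform(params.n_chromosomes, params.map_length_cm)


def simulate_variant_sites(params: SimParams, gmap: Optional[GeneticMap] = None,
                           rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Uniformly scattered biallelic SNV sites, sorted by (chrom, pos)."""
    gmap = gmap or default_map(params)
    rng = rng or _rng(params, _STREAM_FREQS)
    chroms = gmap.chromosomes
    which = rng.integers(0, len(chroms), params.n_variants)
    span = params.map_length_cm * 1e6  # uniform 1 cM/Mb map
    pos = rng.integers(1, int(span), params.n_variants)
    ref_i = rng.integers(0, 4, params.n_variants)
    alt_i = (ref_i + rng.integers(1, 4, params.n_variants)) % 4
    df = make_variant_frame([chroms[w] for w in which], pos, _BASES[ref_i], _BASES[alt_i])
    order = np.lexsort((df["pos"].to_numpy(), which))
    df = df.iloc[order]
    df = df[~df.index.duplicated()]
    return df


def simulate_founder_frequencies(params: SimParams, variants: Optional[pd.DataFrame] = None,
                                 gmap: Optional[GeneticMap] = None
                                 ) -> tuple[pd.DataFrame, AlleleFreqTable]:
    """Draw founder frequencies q ~ Beta(a, b) and a noisy database copy.

    ``db_af`` models the allele frequency seen in outbred public databases:
    a multiplicative log-normal perturbation of q, with a configurable
    fraction of population-private variants absent from the database
    (db_af = 0).  q is truncated away from {0, 1} so every marker is usable
    by the HMM.
    """
    rng = _rng(params, _STREAM_FREQS)
    if variants is None:
        variants = simulate_variant_sites(params, gmap, rng)
    n = len(variants)
    q = rng.beta(params.beta_shape_a, params.beta_shape_b, n)
    q = np.clip(q, params.q_floor, 1.0 - params.q_floor)
    db = np.clip(q * rng.lognormal(0.0, params.db_noise_sigma, n), 0.0, 1.0)
    db[rng.random(n) < params.db_absent_fraction] = 0.0
    freqs = AlleleFreqTable(pd.DataFrame({"q": q, "db_af": db}, index=variants.index))
    return variants, freqs


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _meiosis(hap: np.ndarray, lab: np.ndarray, pos_cm: np.ndarray,
             chrom_bounds: list[tuple[int, int, float]],
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent's two haplotypes (Haldane crossovers)."""
    out_h = np.empty(hap.shape[1], dtype=hap.dtype)
    out_l = np.empty(lab.shape[1], dtype=lab.dtype)
    for start, stop, length_cm in chrom_bounds:
        k = rng.poisson(length_cm / 100.0)
        points = np.sort(rng.uniform(0.0, length_cm, k))
        phase0 = rng.integers(0, 2)
        rel = pos_cm[start:stop] - pos_cm[start]
        phase = (phase0 + np.searchsorted(points, rel, side="right")) % 2
        idx = np.arange(start, stop)
        out_h[idx] = hap[phase, idx]
        out_l[idx] = lab[phase, idx]
    return out_h, out_l


def simulate_pedigree_genotypes(ped: Pedigree, variants: pd.DataFrame,
                                freqs: AlleleFreqTable, gmap: GeneticMap,
                                params: SimParams) -> CohortGenotypes:
    """Gene-drop founder haplotypes down the pedigree.

    Founders receive two haplotypes from a pool of ``founder_pool_size``
    label-tagged haplotypes whose alleles are independent Bernoulli(q)
    draws (linkage equilibrium among founders).  When the pool is large
    enough, haplotypes are assigned without replacement, so identical labels
    arise only through the pedigree; smaller pools recycle haplotypes and
    model background endogamy.  Genotyping error perturbs dosage
    symmetrically (hom→het, het→random hom) at rate ε and missingness is
    applied independently.
    """
    rng = _rng(params, _STREAM_GENO)
    q = freqs.q_for(variants.index, require_polymorphic=False)
    m = len(variants)

    # cM positions, ordered per chromosome; markers must sit on the map
    pos_cm = np.empty(m)
    chrom_bounds: list[tuple[int, int, float]] = []
    start = 0
    for chrom, grp in variants.groupby("chrom", sort=False):
        cm = gmap.interpolate(chrom, grp["pos"].to_numpy())
        stop = start + len(grp)
        pos_cm[start:stop] = cm
        chrom_bounds.append((start, stop, gmap.length_cm(chrom)))
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"{chrom}: markers not ordered along the map")
        if np.any(cm < -1e-9) or np.any(cm > gmap.length_cm(chrom) + 1e-9):
            raise ValueError(f"{chrom}: marker off the genetic map")
        start = stop

    pool = (rng.random((params.founder_pool_size, m)) < q).astype(np.int8)

    founders = ped.founders
    need = 2 * len(founders)
    if params.founder_pool_size >= need:
        assign = rng.choice(params.founder_pool_size, size=need, replace=False)
    else:
        assign = rng.integers(0, params.founder_pool_size, size=need)

    haps: dict[str, np.ndarray] = {}
    labs: dict[str, np.ndarray] = {}
    fi = 0
    for ind in ped.topological_order():
        if ind.is_founder:
            ia, ib = assign[2 * fi], assign[2 * fi + 1]
            fi += 1
            if (ind.role == "pop_control"
                    and rng.random() < params.control_inbreeding):
                ib = ia  # background endogamy: self-kinship of the isolate
            haps[ind.iid] = pool[[ia, ib]].copy()
            labs[ind.iid] = np.broadcast_to(
                np.array([[ia], [ib]], dtype=np.int32), (2, m)).copy()
        else:
            h0, l0 = _meiosis(haps[ind.father], labs[ind.father], pos_cm, chrom_bounds, rng)
            h1, l1 = _meiosis(haps[ind.mother], labs[ind.mother], pos_cm, chrom_bounds, rng)
            haps[ind.iid] = np.stack([h0, h1])
            labs[ind.iid] = np.stack([l0, l1])

    samples = ped.ids
    dosage = np.stack([haps[s].sum(axis=0) for s in samples], axis=1).astype(np.int8)
    hap_labels = np.stack([labs[s].T for s in samples], axis=1)

    eps = params.genotyping_error_rate
    if eps > 0:
        hit = rng.random(dosage.shape) < eps
        coin = rng.integers(0, 2, dosage.shape).astype(np.int8)
        err = dosage.copy()
        err[hit & (dosage != 1)] = 1
        err[hit & (dosage == 1)] = (2 * coin)[hit & (dosage == 1)]
        dosage = err
    if params.missing_rate > 0:
        dosage = dosage.copy()
        dosage[rng.random(dosage.shape) < params.missing_rate] = MISSING

    return CohortGenotypes(variants, samples, dosage, ped, hap_labels)


def realized_autozygosity(cohort: CohortGenotypes) -> pd.Series:
    """Per-sample fraction of markers with both haplotype labels IBD.

    Markers without ground-truth labels are excluded.  With markers spread
    uniformly on the genetic map this is the realized autozygous genome
    fraction.
    """
    if cohort.hap_labels is None:
        raise ValueError("cohort carries no haplotype labels")
    lab = cohort.hap_labels
    known = (lab >= 0).all(axis=2)
    ibd = (lab[:, :, 0] == lab[:, :, 1]) & known
    frac = ibd.sum(axis=0) / np.maximum(known.sum(axis=0), 1)
    return pd.Series(frac, index=cohort.samples, name="realized_autozygosity")


# ---------------------------------------------------------------------------
# planted variants
# ---------------------------------------------------------------------------

@dataclass
class PlantedVariants:
    causal_id: str
    confounder_id: str


def _ancestral_carrier_path(ped: Pedigree, parent_iid: str) -> list[str]:
    """Chain of ancestors (child-to-founder) through which the allele descends."""
    idx = {i.iid: i for i in ped}
    path = []
    cur = idx[parent_iid]
    while not cur.is_founder:
        fa, mo = idx[cur.father], idx[cur.mother]
        cur = fa if not fa.is_founder else mo if not mo.is_founder else fa
        path.append(cur.iid)
    return path


def _planted_row(ped: Pedigree, samples: list[str], carrier_controls: np.ndarray,
                 ancestral_label: int, unique_start: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Dosage row and label pairs for one planted recessive variant.

    Affecteds are homozygous alternate (autozygous: both labels ancestral);
    both parents and one ancestor chain up to a founder are heterozygous, so
    every trio in the family is Mendelian-consistent; the given controls are
    carriers; everyone else is reference.
    """
    affecteds = {i.iid for i in ped.affecteds}
    parents = {i.iid for i in ped.by_role("parent")}
    hets = set(parents)
    for p in parents:
        hets.update(_ancestral_carrier_path(ped, p))
    controls = [i.iid for i in ped.by_role("pop_control")]
    hets.update(np.array(controls)[carrier_controls] if len(controls) else [])

    dosage = np.zeros(len(samples), dtype=np.int8)
    labels = np.empty((len(samples), 2), dtype=np.int32)
    u = unique_start
    for j, s in enumerate(samples):
        if s in affecteds:
            dosage[j] = 2
            labels[j] = (ancestral_label, ancestral_label)
        elif s in hets:
            dosage[j] = 1
            labels[j] = (ancestral_label, u)
            u += 1
        else:
            labels[j] = (u, u + 1)
            u += 2
    return dosage, labels


def plant_causal_and_confounder(cohort: CohortGenotypes, freqs: AlleleFreqTable,
                                params: SimParams
                                ) -> tuple[CohortGenotypes, AlleleFreqTable, PlantedVariants]:
    """Insert the causal mutation and the founder-polymorphism confounder.

    Both are novel missense changes in neighbouring positions on one
    chromosome, homozygous in every affected and heterozygous in both
    parents.  The causal variant is private (absent from controls); the
    confounder segregates among population controls at
    ``confounder_carrier_fraction`` heterozygotes with no homozygote in the
    control-exome set — so only a large population screen can separate them.
    """
    ped = cohort.pedigree
    if ped is None:
        raise ValueError("cohort has no pedigree")
    for role in ("affected", "parent", "pop_control"):
        if not ped.by_role(role):
            raise ValueError(f"cohort pedigree has no {role!r} individuals")
    rng = _rng(params, _STREAM_PLANT)

    chrom = f"chr{min(9, params.n_chromosomes)}"
    bp_causal, bp_conf = 2_600_000, 2_750_000
    causal = make_variant_frame([chrom], [bp_causal], ["G"], ["T"])
    conf = make_variant_frame([chrom], [bp_conf], ["A"], ["C"])

    n_ctrl = len(ped.by_role("pop_control"))
    carriers_conf = rng.random(n_ctrl) < params.confounder_carrier_fraction
    carriers_causal = np.zeros(n_ctrl, dtype=bool)

    d_causal, l_causal = _planted_row(ped, cohort.samples, carriers_causal,
                                      _PLANT_ANCESTRAL_BASE + 1, _PLANT_UNIQUE_BASE)
    d_conf, l_conf = _planted_row(ped, cohort.samples, carriers_conf,
                                  _PLANT_ANCESTRAL_BASE + 2, _PLANT_UNIQUE_BASE + 10_000)

    variants = pd.concat([cohort.variants, causal, conf])
    dosage = np.vstack([cohort.dosage, d_causal[None, :], d_conf[None, :]])
    if cohort.hap_labels is not None:
        hap = np.vstack([cohort.hap_labels, l_causal[None], l_conf[None]])
    else:
        hap = None

    # keep (chrom, pos) sorted with the chromosome order of the input
    chrom_order = {c: i for i, c in enumerate(pd.unique(variants["chrom"]))}
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].map(chrom_order).to_numpy()))
    cohort2 = CohortGenotypes(variants.iloc[order], cohort.samples, dosage[order],
                              ped, None if hap is None else hap[order])

    # founder frequency of the planted alleles: rare private (causal) vs a
    # drifted founder polymorphism (confounder); both absent from databases
    q_conf = params.confounder_carrier_fraction / 2 + params.confounder_hom_fraction
    extra = pd.DataFrame({"q": [0.005, q_conf], "db_af": [0.0, 0.0]},
                         index=[causal.index[0], conf.index[0]])
    ftab = pd.concat([freqs.table, extra]).reindex(cohort2.variants.index)
    return cohort2, AlleleFreqTable(ftab), PlantedVariants(causal.index[0], conf.index[0])


# ---------------------------------------------------------------------------
# annotations and population-screen counts
# ---------------------------------------------------------------------------

def simulate_annotations(variants: pd.DataFrame, freqs: AlleleFreqTable,
                         params: SimParams,
                         planted: Optional[PlantedVariants] = None) -> AnnotationTable:
    """Random functional classes and deleteriousness scores.

    Planted variants are annotated the way the emulated candidates were
    seen: novel missense with the maximal PolyPhen-2 score (1.00) and SIFT
    0.00 (causal) / 0.05 (confounder) — bioinformatically indistinguishable.
    """
    rng = _rng(params, _STREAM_ANNOT)
    n = len(variants)
    classes = rng.choice(list(_CLASS_PROBS), p=list(_CLASS_PROBS.values()), size=n)
    pph2 = np.where(classes == "missense", rng.random(n), np.nan)
    sift = np.where(classes == "missense", rng.random(n), np.nan)
    tab = pd.DataFrame({
        "class": classes,
        "db_af": freqs.table["db_af"].reindex(variants.index).to_numpy(),
        "score_pph2": pph2,
        "score_sift": sift,
    }, index=variants.index)
    if planted is not None:
        tab.loc[planted.causal_id] = ("missense", 0.0, 1.00, 0.00)
        tab.loc[planted.confounder_id] = ("missense", 0.0, 1.00, 0.05)
    return AnnotationTable(tab)


def simulate_screen_counts(n_total: int, carrier_freq: float, hom_freq: float,
                           rng: np.random.Generator):
    """Genotype a variant in ``n_total`` population controls (multinomial)."""
    from .screen import ScreenCounts

    if carrier_freq + hom_freq > 1:
        raise ValueError("carrier_freq + hom_freq must not exceed 1")
    n_hom, n_het, _ = rng.multinomial(
        n_total, [hom_freq, carrier_freq, 1.0 - carrier_freq - hom_freq])
    return ScreenCounts(n_total=n_total, n_het=int(n_het), n_hom=int(n_hom))


# ---------------------------------------------------------------------------
# one-call cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Everything the pipeline needs, plus ground truth."""

    params: SimParams
    pedigree: Pedigree
    gmap: GeneticMap
    cohort: CohortGenotypes
    freqs: AlleleFreqTable
    annotations: AnnotationTable
    planted: PlantedVariants
    screen_counts: dict  # variant_id -> ScreenCounts
    ground_truth: dict = field(default_factory=dict)


def simulate_cohort(params: SimParams, ped: Optional[Pedigree] = None) -> SimResult:
    """Full study emulation: family + controls + planted candidate pair."""
    if ped is None:
        ped = quad_family(params.consanguinity_loop, params.n_affected,
                          params.n_pop_controls)
    gmap = default_map(params)
    variants, freqs = simulate_founder_frequencies(params)
    cohort = simulate_pedigree_genotypes(ped, variants, freqs, gmap, params)
    cohort, freqs, planted = plant_causal_and_confounder(cohort, freqs, params)
    annotations = simulate_annotations(cohort.variants, freqs, params, planted)
    rng = _rng(params, _STREAM_SCREEN)
    screen_counts = {
        planted.causal_id: simulate_screen_counts(params.screen_n_causal, 0.0, 0.0, rng),
        planted.confounder_id: simulate_screen_counts(
            params.screen_n_confounder, params.confounder_carrier_fraction,
            params.confounder_hom_fraction, rng),
    }
    auto = realized_autozygosity(cohort)
    gt = {
        "causal_id": planted.causal_id,
        "confounder_id": planted.confounder_id,
        "expected_inbreeding": LOOP_INBREEDING[params.consanguinity_loop],
        "realized_autozygosity": auto.to_dict(),
    }
    return SimResult(params, ped, gmap, cohort, freqs, annotations, planted,
                     screen_counts, gt)


def with_seed(params: SimParams, seed: int) -> SimParams:
    return replace(params, seed=seed)
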