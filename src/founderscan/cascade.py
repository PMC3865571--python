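"""Step-wise recessive-variant filter cascade with per-stage accounting.

The cascade encodes the diagnostic filtering logic for an autosomal
recessive disorder in a consanguineous family:

1. ``rare_deleterious`` — keep variants rare in external databases
   (db_af < 1% by default) whose functional class is putatively damaging:
   nonsense, exonic indels, splice-site changes, or missense predicted
   deleterious by PolyPhen-2 and SIFT;
2. ``homozygous_affected`` — homozygous alternate in every affected;
3. ``parents_het`` — heterozygous in both parents (unaffected carriers);
4. ``control_exomes`` — no homozygote among ethnically matched control
   exomes (heterozygous controls are expected in a founder population and
   do not exclude).

Every stage records input/output counts and the surviving variant ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import MISSING, AnnotationTable, CohortGenotypes
from .pedigree import Pedigree

log = logging.getLogger(__name__)

DELETERIOUS_CLASSES = ("nonsense", "frameshift_indel", "inframe_indel", "splice_site")


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and policies of the filter cascade."""

    rarity_threshold: float = 0.01     # strict <
    pph2_min: float = 0.85             # "probably damaging", inclusive >=
    sift_max: float = 0.05             # inclusive <=
    deleterious_rule: str = "both"     # missense must fail both predictors' cutoffs
    missing_genotype_policy: str = "strict"   # strict: missing fails; permissive: passes
    control_exclusion_rule: str = "homozygote"
    unannotated_policy: str = "error"  # or "drop"
    min_call_rate: Optional[float] = None  # optional pre-filter, off by default

    def __post_init__(self) -> None:
        for name in ("rarity_threshold", "pph2_min", "sift_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.deleterious_rule not in ("both", "either"):
            raise ValueError("deleterious_rule must be 'both' or 'either'")
        if self.missing_genotype_policy not in ("strict", "permissive"):
            raise ValueError("missing_genotype_policy must be 'strict' or 'permissive'")
        if self.unannotated_policy not in ("error", "drop"):
            raise ValueError("unannotated_policy must be 'error' or 'drop'")


@dataclass
class Stage:
    name: str
    input_count: int
    surviving_count: int
    survivors: list[str]
    note: str = ""


@dataclass
class FilterTrace:
    """Ordered per-stage record of the cascade run."""

    stages: list[Stage] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    flagged_missing: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def add(self, name: str, before: pd.Index, after: pd.Index, note: str = "") -> None:
        if not set(after) <= set(before):
            raise ValueError(f"stage {name}: survivors not a subset of input")
        self.stages.append(Stage(name, len(before), len(after), list(after), note))
        log.info("stage %-20s %6d -> %d %s", name, len(before), len(after), note)

    def to_dict(self) -> dict:
        return {
            "stages": [{"name": s.name, "input_count": s.input_count,
                        "surviving_count": s.surviving_count,
                        "survivors": s.survivors, "note": s.note}
                       for s in self.stages],
            "candidates": self.candidates,
            "flagged_missing": self.flagged_missing,
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_rare_deleterious(variant_ids: pd.Index, annotations: AnnotationTable,
                           config: CascadeConfig = CascadeConfig()) -> pd.Index:
    """Rare (db_af < threshold) AND putatively damaging."""
    missing = annotations.covers(variant_ids)
    if missing:
        if config.unannotated_policy == "error":
            raise ValueError(f"unannotated variants: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        log.warning("dropping %d unannotated variants", len(missing))
        variant_ids = variant_ids.difference(missing, sort=False)
    tab = annotations.table.loc[variant_ids]
    rare = tab["db_af"] < config.rarity_threshold
    by_class = tab["class"].isin(DELETERIOUS_CLASSES)
    pph2_hit = tab["score_pph2"] >= config.pph2_min
    sift_hit = tab["score_sift"] <= config.sift_max
    pred = (pph2_hit & sift_hit) if config.deleterious_rule == "both" else (pph2_hit | sift_hit)
    damaging_missense = (tab["class"] == "missense") & pred.fillna(False)
    keep = rare & (by_class | damaging_missense)
    return variant_ids[keep.to_numpy()]


def _zygosity_stage(variant_ids: pd.Index, cohort: CohortGenotypes,
                    sample_ids: list[str], wanted: int,
                    config: CascadeConfig) -> tuple[pd.Index, list[str]]:
    sub = cohort.subset_variants(variant_ids)
    cols = [sub.sample_index(s) for s in sample_ids]
    dos = sub.dosage[:, cols]
    hit = dos == wanted
    miss = dos == MISSING
    if config.missing_genotype_policy == "permissive":
        ok = (hit | miss).all(axis=1)
        return variant_ids[ok], list(variant_ids[ok & miss.any(axis=1)])
    return variant_ids[hit.all(axis=1)], []


def stage_homozygous_affected(variant_ids: pd.Index, cohort: CohortGenotypes,
                              ped: Pedigree,
                              config: CascadeConfig = CascadeConfig()
                              ) -> tuple[pd.Index, list[str]]:
    """Dosage 2 in every affected individual."""
    affecteds = [i.iid for i in ped.affecteds if i.iid in cohort.samples]
    if not affecteds:
        raise ValueError("no affected individuals in the cohort")
    return _zygosity_stage(variant_ids, cohort, affecteds, 2, config)


def stage_parents_het(variant_ids: pd.Index, cohort: CohortGenotypes,
                      ped: Pedigree,
                      config: CascadeConfig = CascadeConfig()
                      ) -> tuple[pd.Index, list[str]]:
    """Dosage 1 in both parents (obligate carriers)."""
    parents = [i.iid for i in ped.by_role("parent") if i.iid in cohort.samples]
    if not parents:
        raise ValueError("parent samples absent")
    return _zygosity_stage(variant_ids, cohort, parents, 1, config)


def stage_control_exomes(variant_ids: pd.Index,
                         control_genotypes: CohortGenotypes) -> pd.Index:
    """Remove variants homozygous alternate in any population control.

    Heterozygous controls do not exclude: carriers of a founder mutation
    are expected in an endogamous population.
    """
    missing = [v for v in variant_ids if v not in control_genotypes.variant_ids]
    if missing:
        raise ValueError(f"variants absent from control genotypes: {missing[:5]}")
    sub = control_genotypes.subset_variants(variant_ids)
    any_hom = (sub.dosage == 2).any(axis=1)
    return variant_ids[~any_hom]


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def run_cascade(cohort: CohortGenotypes, annotations: AnnotationTable,
                ped: Optional[Pedigree] = None,
                control_genotypes: Optional[CohortGenotypes] = None,
                config: CascadeConfig = CascadeConfig()) -> FilterTrace:
    """Apply the four stages in order with full per-stage accounting.

    ``control_genotypes`` defaults to the cohort's own ``pop_control``
    samples; if neither is available the control stage is skipped with an
    explicit note in the trace.  The trace's metadata also reports the
    per-affected counts of rare-deleterious homozygotes and the number
    shared by all affecteds, the two readings of a per-patient candidate
    load.
    """
    ped = ped or cohort.pedigree
    if ped is None:
        raise ValueError("a pedigree is required (cohort.pedigree or ped argument)")
    trace = FilterTrace()
    ids = cohort.variant_ids

    if config.min_call_rate is not None:
        called = (cohort.dosage != MISSING).mean(axis=1)
        kept = ids[called >= config.min_call_rate]
        trace.add("call_rate", ids, kept, f">= {config.min_call_rate:.2f}")
        ids = kept

    try:
        survivors = stage_rare_deleterious(ids, annotations, config)
        trace.add("rare_deleterious", ids, survivors)

        # per-patient load, before the sharing requirement
        affecteds = [i.iid for i in ped.affecteds if i.iid in cohort.samples]
        sub = cohort.subset_variants(survivors)
        per_aff = {a: int((sub.dosage[:, sub.sample_index(a)] == 2).sum())
                   for a in affecteds}

        prev = survivors
        survivors, flagged = stage_homozygous_affected(prev, cohort, ped, config)
        trace.add("homozygous_affected", prev, survivors,
                  f"shared by all {len(affecteds)} affecteds")
        trace.flagged_missing += flagged
        trace.metadata["rare_deleterious_hom_per_affected"] = per_aff
        trace.metadata["rare_deleterious_hom_shared"] = len(survivors)

        prev = survivors
        parents = [i.iid for i in ped.by_role("parent") if i.iid in cohort.samples]
        if parents:
            survivors, flagged = stage_parents_het(prev, cohort, ped, config)
            trace.add("parents_het", prev, survivors)
            trace.flagged_missing += flagged
        else:
            trace.add("parents_het", prev, prev, "SKIPPED: parent samples absent")
            log.warning("parents_het stage skipped: no parent samples")

        if control_genotypes is None and ped.by_role("pop_control"):
            ctrl_ids = [i.iid for i in ped.by_role("pop_control")
                        if i.iid in cohort.samples]
            control_genotypes = cohort.subset_samples(ctrl_ids) if ctrl_ids else None
        prev = survivors
        if control_genotypes is not None and control_genotypes.samples:
            survivors = stage_control_exomes(prev, control_genotypes)
            trace.add("control_exomes", prev, survivors,
                      f"{len(control_genotypes.samples)} control exomes")
        else:
            trace.add("control_exomes", prev, prev, "SKIPPED: no control genotypes")
            log.warning("control_exomes stage skipped: no control genotypes")
    except Exception as exc:
        stage = trace.stages[-1].name if trace.stages else "input"
        raise RuntimeError(f"cascade failed after stage '{stage}': {exc}") from exc

    trace.candidates = list(survivors)
    return trace
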