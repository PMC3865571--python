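"""End-to-end orchestration: panel → inbreeding → cascade → screen.

The pipeline reproduces the analysis arc for a recessive disorder in an
endogamous family: extract a spaced marker panel, estimate each family
member's inbreeding coefficient (confirming the autozygosity assumption),
run the step-wise filter cascade, and — when population-screen genotype
counts are available for surviving candidates — issue a carrier-frequency
plausibility verdict for each.

Everything is driven by a :class:`PipelineConfig` (YAML-serialisable) and
produces a single versioned JSON report; a fixed seed gives byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as fio
from .cascade import CascadeConfig, run_cascade
from .cohort import AlleleFreqTable, AnnotationTable, CohortGenotypes
from .genmap import GeneticMap
from .inbreeding import DEFAULT_EPS, estimate_f_cohort
from .panel import DEFAULT_MIN_HET, DEFAULT_MIN_SPACING_CM, extract_panel, panel_summary
from .pedigree import Pedigree
from .screen import (DEFAULT_PREVALENCE_CEILING, PopulationScreen, ScreenCounts)
from .simulate import SimParams, simulate_cohort

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Paths, thresholds and settings for one pipeline run."""

    vcf: Optional[str] = None
    ped: Optional[str] = None
    genetic_map: Optional[str] = None
    annotations: Optional[str] = None
    freqs: Optional[str] = None
    controls_vcf: Optional[str] = None
    screen_counts: Optional[str] = None  # TSV: variant_id n_total n_het n_hom

    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    hmm_eps: float = DEFAULT_EPS
    panel_min_spacing_cm: float = DEFAULT_MIN_SPACING_CM
    panel_min_het: float = DEFAULT_MIN_HET
    estimate_roles: tuple[str, ...] = ("affected", "parent")
    prevalence_ceiling: float = DEFAULT_PREVALENCE_CEILING

    sim: Optional[SimParams] = None
    out_dir: str = "founderscan_out"
    seed: int = 0
    log_level: str = "INFO"

    # -- (de)serialisation -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cascade"] = dataclasses.asdict(self.cascade)
        d["sim"] = None if self.sim is None else dataclasses.asdict(self.sim)
        d["estimate_roles"] = list(self.estimate_roles)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("cascade"):
            d["cascade"] = CascadeConfig(**d["cascade"])
        if d.get("sim"):
            d["sim"] = SimParams(**d["sim"])
        if d.get("estimate_roles"):
            d["estimate_roles"] = tuple(d["estimate_roles"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def read_screen_counts(path) -> dict[str, ScreenCounts]:
    df = pd.read_csv(path, sep="\t")
    req = {"variant_id", "n_total", "n_het", "n_hom"}
    if not req <= set(df.columns):
        raise ValueError(f"screen-counts TSV needs columns {sorted(req)}")
    return {r.variant_id: ScreenCounts(int(r.n_total), int(r.n_het), int(r.n_hom))
            for r in df.itertuples()}


# ---------------------------------------------------------------------------
# core run (in-memory objects)
# ---------------------------------------------------------------------------

def run_pipeline_objects(cohort: CohortGenotypes, ped: Pedigree, gmap: GeneticMap,
                         freqs: AlleleFreqTable, annotations: AnnotationTable,
                         screen_counts: Optional[dict[str, ScreenCounts]] = None,
                         controls: Optional[CohortGenotypes] = None,
                         config: Optional[PipelineConfig] = None) -> dict:
    """Run panel extraction, inbreeding estimation, cascade and screen."""
    config = config or PipelineConfig()
    notes: list[str] = []

    panel = extract_panel(cohort, freqs, gmap,
                          config.panel_min_spacing_cm, config.panel_min_het)
    log.info("panel: %d markers", len(panel))

    roles = set(config.estimate_roles)
    targets = [i.iid for i in ped if i.role in roles and i.iid in cohort.samples]
    estimates = estimate_f_cohort(cohort, panel, freqs, targets, eps=config.hmm_eps)
    log.info("inbreeding: estimated f for %d individuals", len(estimates))
    max_aff_f = max((r.f_hat for s, r in estimates.items()
                     if ped[s].role == "affected"), default=None)
    autozygosity_supported = max_aff_f is not None and max_aff_f > 0.03
    if not autozygosity_supported:
        notes.append("inbreeding estimates do not support the autozygosity "
                     "assumption; cascade results may be incomplete")

    trace = run_cascade(cohort, annotations, ped, controls, config.cascade)
    if any("SKIPPED" in s.note for s in trace.stages):
        notes.extend(f"stage {s.name}: {s.note}" for s in trace.stages
                     if "SKIPPED" in s.note)

    screen_reports: dict[str, dict] = {}
    if screen_counts:
        for vid in trace.candidates:
            if vid in screen_counts:
                res = PopulationScreen(screen_counts[vid]).fit()
                d = res.to_dict()
                d["verdict"] = res.verdict(config.prevalence_ceiling)
                screen_reports[vid] = d
        missing = [v for v in trace.candidates if v not in screen_counts]
        if missing:
            notes.append(f"no screen counts for candidate(s): {missing}")
    else:
        notes.append("population screen skipped: no screen counts provided")

    final = [v for v in trace.candidates
             if screen_reports.get(v, {}).get("verdict") != "implausibly_common"]

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "panel": panel_summary(panel),
        "inbreeding": {s: r.to_dict() for s, r in sorted(estimates.items())},
        "autozygosity_supported": autozygosity_supported,
        "cascade": trace.to_dict(),
        "screen": screen_reports,
        "candidates_after_cascade": trace.candidates,
        "candidates_after_screen": final,
        "notes": notes,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """File-driven entry point: read inputs, run, write ``report.json``.

    With ``config.sim`` set and no VCF given, the synthetic cohort is
    generated first and written alongside the report.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    if config.vcf is None and config.sim is None:
        raise ValueError("config needs either input paths (vcf/ped/map/...) "
                         "or sim parameters")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.vcf is None:
        sim = simulate_cohort(dataclasses.replace(config.sim, seed=config.seed))
        cohort, ped, gmap = sim.cohort, sim.pedigree, sim.gmap
        freqs, annotations = sim.freqs, sim.annotations
        screen_counts = sim.screen_counts
        controls = None
        fio.write_cohort(cohort, ped, gmap, annotations, out_dir,
                         freqs=freqs, ground_truth=sim.ground_truth)
    else:
        for name in ("ped", "genetic_map", "annotations", "freqs"):
            if getattr(config, name) is None:
                raise ValueError(f"config.{name} is required when vcf is given")
        ped = fio.read_ped(config.ped)
        cohort = fio.read_vcf(config.vcf, pedigree=ped)
        gmap = fio.read_map(config.genetic_map)
        annotations = fio.read_annotations(config.annotations)
        freqs = fio.read_freqs(config.freqs)
        controls = (fio.read_vcf(config.controls_vcf)
                    if config.controls_vcf else None)
        screen_counts = (read_screen_counts(config.screen_counts)
                         if config.screen_counts else None)

    report = run_pipeline_objects(cohort, ped, gmap, freqs, annotations,
                                  screen_counts, controls, config)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("report written to %s", out_dir / "report.json")
    return report
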