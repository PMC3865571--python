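"""Readers and writers for the pipeline's on-disk formats.

Formats and coordinate conventions:

* VCF v4.2, GT field only, 1-based positions; ``./.`` is missing; records
  must be biallelic (multi-allelic records are rejected with guidance to
  pre-split, e.g. with ``bcftools norm -m-``).  Reading goes through cyvcf2.
* PLINK-style 6-column PED (FID IID PAT MAT SEX PHENO; 0 = missing parent,
  phenotype 2 = affected).
* PLINK-style 4-column .map: chrom, marker id, cM (column 3), bp.
* Annotation TSV: variant_id, class, db_af, score_pph2, score_sift.
* Ground-truth JSON sidecar written by the simulator (planted ids,
  per-sample realized autozygosity).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (MISSING, AlleleFreqTable, AnnotationTable, CohortGenotypes,
                     make_variant_frame)
from .genmap import GeneticMap
from .panel import MarkerPanel
from .pedigree import Individual, Pedigree, infer_roles

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(cohort: CohortGenotypes, path) -> None:
    """Minimal VCF v4.2 with GT; deterministic byte-for-byte output."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(cohort.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                          "INFO", "FORMAT"] + cohort.samples)
        fh.write(cols + "\n")
        v = cohort.variants
        for i, (vid, row) in enumerate(v.iterrows()):
            gts = "\t".join(_GT_CODE[int(d)] for d in cohort.dosage[i])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}"
                     f"\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, pedigree: Optional[Pedigree] = None) -> CohortGenotypes:
    """Read a GT-only VCF into a :class:`CohortGenotypes`.

    Positions stay 1-based; ``./.`` becomes missing; the sample order of the
    header is preserved.  Multi-allelic records raise with the offending
    record named.
    """
    from cyvcf2 import VCF

    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"({rec.REF}>{','.join(rec.ALT) or '.'}): pre-split with "
                "'bcftools norm -m-' before loading")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    vcf.close()
    variants = make_variant_frame(chroms, poss, refs, alts)
    dosage = (np.vstack(rows) if rows
              else np.empty((0, len(samples)), dtype=np.int8))
    return CohortGenotypes(variants, samples, dosage, pedigree)


# ---------------------------------------------------------------------------
# PED / MAP / annotations / frequencies
# ---------------------------------------------------------------------------

def write_ped(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for ind in ped:
            pheno = 2 if ind.affected else 1
            fh.write(f"{ind.fid}\t{ind.iid}\t{ind.father or 0}\t{ind.mother or 0}"
                     f"\t{ind.sex}\t{pheno}\n")


def read_ped(path) -> Pedigree:
    """6-column PED; roles inferred from structure and phenotype."""
    inds = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            fid, iid, pat, mat, sex, pheno = parts[:6]
            inds.append(Individual(
                iid,
                None if pat == "0" else pat,
                None if mat == "0" else mat,
                int(sex) if sex in "012" else 0,
                affected=(pheno == "2"),
                fid=fid,
            ))
    return Pedigree(infer_roles(inds))


def write_map(cohort: CohortGenotypes, gmap: GeneticMap, path) -> None:
    """PLINK 4-column map for every variant in the cohort."""
    with open(path, "w") as fh:
        for chrom, grp in cohort.variants.groupby("chrom", sort=False):
            cm = gmap.interpolate(chrom, grp["pos"].to_numpy())
            for (vid, row), c in zip(grp.iterrows(), cm):
                fh.write(f"{chrom}\t{vid}\t{c:.6f}\t{row['pos']}\n")


def read_map(path) -> GeneticMap:
    """Build a :class:`GeneticMap` from PLINK map rows (anchors = markers)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "id", "cm", "bp"])
    anchors = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy(dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        keep = np.concatenate([[True], (np.diff(bp) > 0) & (np.diff(cm) > 0)])
        if np.any(np.diff(bp) < 0) or np.any(np.diff(cm) < 0):
            raise ValueError(f"{path}: {chrom}: map positions must be non-decreasing")
        anchors[chrom] = (bp[keep], cm[keep])
    return GeneticMap(anchors)


def write_annotations(annotations: AnnotationTable, path) -> None:
    annotations.table.to_csv(path, sep="\t", index_label="variant_id",
                             float_format="%.6g")


def read_annotations(path) -> AnnotationTable:
    tab = pd.read_csv(path, sep="\t", index_col="variant_id")
    return AnnotationTable(tab)


def write_freqs(freqs: AlleleFreqTable, path) -> None:
    freqs.table.to_csv(path, sep="\t", index_label="variant_id",
                       float_format="%.8g")


def read_freqs(path) -> AlleleFreqTable:
    return AlleleFreqTable(pd.read_csv(path, sep="\t", index_col="variant_id"))


def write_panel(panel: MarkerPanel, path) -> None:
    panel.markers.to_csv(path, sep="\t", index_label="variant_id",
                         float_format="%.6g")


def read_panel(path, min_spacing_cm: float, min_het: float) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    return MarkerPanel(df, min_spacing_cm, min_het)


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortGenotypes, ped: Pedigree, gmap: GeneticMap,
                 annotations: Optional[AnnotationTable], out_dir,
                 freqs: Optional[AlleleFreqTable] = None,
                 ground_truth: Optional[dict] = None,
                 prefix: str = "cohort") -> dict[str, Path]:
    """Write the VCF/PED/map/annotation (+ freq, ground-truth) bundle.

    Round-trips losslessly through the readers in this module.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in cohort.samples if s not in set(ped.ids)]
    if unknown:
        raise ValueError(f"cohort samples missing from pedigree: {unknown}")
    paths = {
        "vcf": out_dir / f"{prefix}.vcf",
        "ped": out_dir / f"{prefix}.ped",
        "map": out_dir / f"{prefix}.map",
    }
    write_vcf(cohort, paths["vcf"])
    write_ped(ped, paths["ped"])
    write_map(cohort, gmap, paths["map"])
    if annotations is not None:
        paths["annotations"] = out_dir / f"{prefix}.annotations.tsv"
        write_annotations(annotations, paths["annotations"])
    if freqs is not None:
        paths["freqs"] = out_dir / f"{prefix}.freqs.tsv"
        write_freqs(freqs, paths["freqs"])
    if ground_truth is not None:
        paths["ground_truth"] = out_dir / f"{prefix}.ground_truth.json"
        with open(paths["ground_truth"], "w") as fh:
            json.dump(ground_truth, fh, indent=2, sort_keys=True)
    return paths


def read_cohort(out_dir, prefix: str = "cohort"):
    """Read back a bundle written by :func:`write_cohort`."""
    out_dir = Path(out_dir)
    ped = read_ped(out_dir / f"{prefix}.ped")
    cohort = read_vcf(out_dir / f"{prefix}.vcf", pedigree=ped)
    gmap = read_map(out_dir / f"{prefix}.map")
    ann_path = out_dir / f"{prefix}.annotations.tsv"
    annotations = read_annotations(ann_path) if ann_path.exists() else None
    fq_path = out_dir / f"{prefix}.freqs.tsv"
    freqs = read_freqs(fq_path) if fq_path.exists() else None
    return cohort, ped, gmap, annotations, freqs
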