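"""Marker-panel extraction for inbreeding estimation.

From exome-scale genotype data, extract an ordered subset of polymorphic
markers with a minimum intermarker genetic distance (a proxy for
approximate linkage equilibrium) and a minimum expected heterozygosity,
suitable for a sparse-marker autozygosity HMM.

Expected heterozygosity is 2q(1−q) from the founder/control allele
frequencies, never from the small family itself (observed heterozygosity in
an inbred family is biased downward by autozygosity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import AlleleFreqTable, CohortGenotypes
from .genmap import GeneticMap

DEFAULT_MIN_SPACING_CM = 0.15
DEFAULT_MIN_HET = 0.3


@dataclass
class MarkerPanel:
    """Ordered, spaced marker subset with per-marker cM and heterozygosity.

    ``markers`` has columns chrom, pos, cm, het, q and is sorted by
    (chromosome, cM); consecutive same-chromosome markers are at least
    ``min_spacing_cm`` apart.
    """

    markers: pd.DataFrame
    min_spacing_cm: float
    min_het: float

    def __post_init__(self) -> None:
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            d = np.diff(grp["cm"].to_numpy())
            if len(d) and d.min() < self.min_spacing_cm - 1e-12:
                raise ValueError(f"{chrom}: panel violates min spacing")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def variant_ids(self) -> pd.Index:
        return self.markers.index

    def summary(self) -> dict:
        return panel_summary(self)


def _expected_het(q: np.ndarray) -> np.ndarray:
    return 2.0 * q * (1.0 - q)


def extract_panel(cohort: CohortGenotypes, freqs: AlleleFreqTable, gmap: GeneticMap,
                  min_spacing_cm: float = DEFAULT_MIN_SPACING_CM,
                  min_het: float = DEFAULT_MIN_HET) -> MarkerPanel:
    """Greedy left-to-right panel selection per chromosome.

    A marker is accepted iff its expected heterozygosity is at least
    ``min_het`` and its cM position is at least ``min_spacing_cm`` beyond
    the last accepted marker on the same chromosome.  The greedy scan is
    deterministic and keeps the earliest eligible marker of every spacing
    window.
    """
    if min_spacing_cm <= 0:
        raise ValueError("min_spacing_cm must be positive")
    variants = cohort.variants
    q = freqs.q_for(variants.index, require_polymorphic=False)
    het = _expected_het(q)
    poly = (q > 0) & (q < 1)
    eligible = poly & (het >= min_het)
    if not eligible.any():
        raise ValueError(f"no marker satisfies min_het={min_het}")

    rows = []
    for chrom, grp in variants.groupby("chrom", sort=False):
        cm = gmap.interpolate(chrom, grp["pos"].to_numpy())
        order = np.argsort(cm, kind="stable")
        mask = eligible[variants.index.get_indexer(grp.index)]
        last = -np.inf
        for k in order:
            if not mask[k]:
                continue
            if cm[k] - last >= min_spacing_cm:
                i = variants.index.get_indexer([grp.index[k]])[0]
                rows.append((grp.index[k], chrom, int(grp["pos"].iloc[k]),
                             float(cm[k]), float(het[i]), float(q[i])))
                last = cm[k]
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "cm", "het", "q"]
                      ).set_index("variant_id")
    return MarkerPanel(df, min_spacing_cm, min_het)


def panel_summary(panel: MarkerPanel) -> dict:
    """Marker count, mean expected heterozygosity, minimum same-chromosome spacing.

    ``min_spacing_cm`` is ``None`` when no chromosome holds two markers
    (spacing is undefined across chromosomes).
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    spacings = [np.diff(grp["cm"].to_numpy())
                for _, grp in panel.markers.groupby("chrom", sort=False)]
    spacings = np.concatenate([s for s in spacings if len(s)]) if any(
        len(s) for s in spacings) else np.array([])
    return {
        "count": int(len(panel)),
        "mean_het": float(panel.markers["het"].mean()),
        "min_spacing_cm": float(spacings.min()) if spacings.size else None,
    }
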