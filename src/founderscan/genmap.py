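"""Genetic map: physical (bp) vs genetic (cM) coordinates per chromosome."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GeneticMap:
    """Per-chromosome anchors mapping 1-based bp positions to cM.

    ``anchors`` maps a chromosome name to two parallel arrays ``(bp, cm)``,
    each strictly increasing.  Positions between anchors interpolate
    linearly; positions beyond the outermost anchors extrapolate with the
    local cM/bp rate of the nearest interval.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size != cm.size or bp.size == 0:
                raise ValueError(f"{chrom}: bp and cM anchor arrays must match and be non-empty")
            if bp.size > 1 and (np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0)):
                raise ValueError(f"{chrom}: map positions must be strictly increasing")
            clean[chrom] = (bp, cm)
        self.anchors = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def length_cm(self, chrom: str) -> float:
        bp, cm = self.anchors[chrom]
        return float(cm[-1] - cm[0])

    def interpolate(self, chrom: str, positions_bp) -> np.ndarray:
        """cM positions for 1-based bp coordinates on one chromosome."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not on the genetic map")
        bp, cm = self.anchors[chrom]
        pos = np.atleast_1d(np.asarray(positions_bp, dtype=float))
        if bp.size == 1:
            # single anchor: assume the human-average 1 cM/Mb local rate
            return cm[0] + (pos - bp[0]) * 1e-6
        out = np.interp(pos, bp, cm)
        lo = pos < bp[0]
        hi = pos > bp[-1]
        if np.any(lo):
            rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
            out[lo] = cm[0] + (pos[lo] - bp[0]) * rate
        if np.any(hi):
            rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
            out[hi] = cm[-1] + (pos[hi] - bp[-1]) * rate
        return out

    @classmethod
    def uniform(cls, n_chromosomes: int, length_cm: float,
                rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map: chromosomes ``chr1..chrN``, 0..length_cm each."""
        span_bp = length_cm / rate_cm_per_mb * 1e6
        anchors = {
            f"chr{c + 1}": (np.array([1.0, 1.0 + span_bp]), np.array([0.0, length_cm]))
            for c in range(n_chromosomes)
        }
        return cls(anchors)
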