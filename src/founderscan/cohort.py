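"""In-memory containers: genotype matrix, allele frequencies, annotations.

Conventions used throughout the package:

* variant identity is ``(chrom, pos, ref, alt)`` with 1-based VCF
  coordinates, flattened to the string key ``"chrom:pos:ref:alt"``;
* dosage counts alternate alleles: 0, 1, 2, or :data:`MISSING` (−1);
* founder-haplotype labels, when the simulator records them, are
  non-negative integers; −1 means no label is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

MISSING = -1

FUNCTIONAL_CLASSES = (
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice_site",
    "missense",
    "synonymous",
    "other",
)


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def make_variant_frame(chrom, pos, ref, alt) -> pd.DataFrame:
    df = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
                       "ref": ref, "alt": alt})
    df.index = pd.Index(
        [variant_key(c, p, r, a) for c, p, r, a in
         zip(df["chrom"], df["pos"], df["ref"], df["alt"])],
        name="variant_id",
    )
    return df


@dataclass
class CohortGenotypes:
    """Variants × samples allele-dosage matrix with pedigree roles attached.

    Parameters
    ----------
    variants : DataFrame with columns chrom, pos, ref, alt, indexed by
        variant id.
    samples : ordered sample ids (columns of ``dosage``).
    dosage : int8 array of shape (n_variants, n_samples); −1 is missing.
    pedigree : optional :class:`~founderscan.pedigree.Pedigree` whose ids
        cover the samples.
    hap_labels : optional (n_variants, n_samples, 2) int32 founder-haplotype
        labels (simulation ground truth); −1 where unknown.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    pedigree: Optional[Pedigree] = None
    hap_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_v, n_s = self.dosage.shape
        if n_v != len(self.variants) or n_s != len(self.samples):
            raise ValueError("dosage shape does not match variants x samples")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or missing (-1)")
        if self.hap_labels is not None:
            self.hap_labels = np.asarray(self.hap_labels, dtype=np.int32)
            if self.hap_labels.shape != (n_v, n_s, 2):
                raise ValueError("hap_labels must have shape (n_variants, n_samples, 2)")
        if self.pedigree is not None:
            known = set(self.pedigree.ids)
            unknown = [s for s in self.samples if s not in known]
            if unknown:
                raise ValueError(f"samples not in pedigree: {unknown}")

    # -- accessors ---------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def sample_index(self, iid: str) -> int:
        try:
            return self.samples.index(iid)
        except ValueError:
            raise KeyError(f"sample {iid!r} not in cohort") from None

    def dosage_of(self, iid: str) -> np.ndarray:
        return self.dosage[:, self.sample_index(iid)]

    def dosage_by_role(self, role: str) -> np.ndarray:
        """(n_variants, n_role_samples) slice for every sample with `role`."""
        if self.pedigree is None:
            raise ValueError("cohort has no pedigree; roles unavailable")
        ids = [i.iid for i in self.pedigree.by_role(role) if i.iid in self.samples]
        cols = [self.sample_index(i) for i in ids]
        return self.dosage[:, cols]

    def subset_variants(self, ids: Sequence[str]) -> "CohortGenotypes":
        pos = self.variants.index.get_indexer(list(ids))
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"variants not in cohort: {missing[:5]}")
        return CohortGenotypes(
            self.variants.iloc[pos],
            self.samples,
            self.dosage[pos],
            self.pedigree,
            None if self.hap_labels is None else self.hap_labels[pos],
        )

    def subset_samples(self, ids: Sequence[str]) -> "CohortGenotypes":
        cols = [self.sample_index(i) for i in ids]
        return CohortGenotypes(
            self.variants,
            list(ids),
            self.dosage[:, cols],
            self.pedigree,
            None if self.hap_labels is None else self.hap_labels[:, cols],
        )

    def equals(self, other: "CohortGenotypes") -> bool:
        return (
            self.samples == other.samples
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True))
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class AlleleFreqTable:
    """Founder alternate-allele frequency q and external-database frequency.

    ``q`` must lie strictly inside (0, 1) for markers consumed by the
    autozygosity HMM; ``db_af`` may be 0 (absent from the database).
    """

    table: pd.DataFrame  # index variant_id; columns q, db_af

    def __post_init__(self) -> None:
        missing = {"q", "db_af"} - set(self.table.columns)
        if missing:
            raise ValueError(f"frequency table missing columns: {sorted(missing)}")
        if ((self.table["db_af"] < 0) | (self.table["db_af"] > 1)).any():
            raise ValueError("db_af outside [0, 1]")

    def q_for(self, ids, require_polymorphic: bool = True) -> np.ndarray:
        q = self.table["q"].reindex(ids).to_numpy(dtype=float)
        if np.isnan(q).any():
            raise KeyError("variants without a frequency entry")
        if require_polymorphic and ((q <= 0) | (q >= 1)).any():
            raise ValueError("q must lie strictly in (0, 1) for these markers")
        return q


@dataclass
class AnnotationTable:
    """Per-variant functional class, database AF and deleteriousness scores.

    ``score_pph2`` / ``score_sift`` may be NaN for non-missense classes.
    """

    table: pd.DataFrame  # index variant_id; columns class, db_af, score_pph2, score_sift

    def __post_init__(self) -> None:
        req = {"class", "db_af", "score_pph2", "score_sift"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        bad = ~self.table["class"].isin(FUNCTIONAL_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown functional class(es): {sorted(self.table['class'][bad].unique())}")
        is_mis = self.table["class"] == "missense"
        if (self.table.loc[is_mis, ["score_pph2", "score_sift"]].isna().any().any()):
            raise ValueError("missense variants must carry both deleteriousness scores")

    def covers(self, ids) -> list[str]:
        """Variant ids from `ids` that lack an annotation row."""
        return [i for i in ids if i not in self.table.index]
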