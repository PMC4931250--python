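"""Core in-memory containers shared by the simulator and the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneAnnotation",
    "ChromatinSegmentation",
    "CHROMATIN_STATES",
    "ENHANCER_STATES",
    "ACTIVE_STATES",
]

# 11-state chromatin vocabulary (ChromHMM-style segmentation labels)
CHROMATIN_STATES = (
    "Active_TSS",
    "Weak_TSS",
    "Flanking_TSS",
    "Strong_transcription",
    "Weak_transcription",
    "Genic_enhancer",
    "Active_enhancer_1",
    "Active_enhancer_2",
    "Weak_enhancer",
    "Repressed_polycomb",
    "Quiescent_low",
)

ENHANCER_STATES = frozenset(
    {"Genic_enhancer", "Active_enhancer_1", "Active_enhancer_2", "Weak_enhancer"}
)

# states counted as "active" when judging tissue specificity of an interval
ACTIVE_STATES = ENHANCER_STATES | {"Active_TSS", "Weak_TSS", "Flanking_TSS"}


@dataclass
class GenotypeMatrix:
    """Variant records plus per-sample allele dosages.

    ``variants``: DataFrame with columns ``chrom, pos, id, ref, alt``
    (1-based positions, sorted within chromosome).
    ``dosages``: array of shape (n_variants, n_samples), values in [0, 2]
    counting alternate-allele copies.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.variants) != self.dosages.shape[0]:
            raise ValueError("variant table and dosage matrix disagree on n_variants")
        if len(self.sample_ids) != self.dosages.shape[1]:
            raise ValueError("sample ids and dosage matrix disagree on n_samples")
        if self.dosages.size and (
            self.dosages.min() < 0 or self.dosages.max() > 2
        ):
            raise ValueError("dosages outside [0, 2]")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("variant positions not sorted within chromosome")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency implied by the dosages."""
        return self.dosages.mean(axis=1) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    def index_of(self, variant_ids) -> np.ndarray:
        """Row indices of the given variant ids (error on unknown ids)."""
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(np.atleast_1d(variant_ids))
        if (idx < 0).any():
            missing = np.atleast_1d(variant_ids)[idx < 0]
            raise KeyError(f"unknown variant ids: {list(missing)[:5]}")
        return idx


@dataclass
class GeneAnnotation:
    """Gene coordinates with strand-aware cis-window anchors.

    ``genes``: DataFrame with columns ``gene_id, chrom, strand, tss_list``
    where ``tss_list`` is a list/tuple of 1-based TSS positions. The window
    anchor is the most upstream TSS: the smallest position on the + strand,
    the largest on the - strand (a ``most_distal`` override flips this).
    """

    genes: pd.DataFrame
    anchor_rule: str = "most_upstream"

    def __post_init__(self) -> None:
        if self.anchor_rule not in ("most_upstream", "most_distal"):
            raise ValueError("anchor_rule must be most_upstream or most_distal")
        if (self.genes["tss_list"].map(len) == 0).any():
            raise ValueError("gene with empty TSS list")

    @property
    def window_anchor(self) -> pd.Series:
        def anchor(row):
            upstream = min(row.tss_list) if row.strand == "+" else max(row.tss_list)
            if self.anchor_rule == "most_upstream":
                return upstream
            return max(row.tss_list) if row.strand == "+" else min(row.tss_list)

        return pd.Series(
            [anchor(r) for r in self.genes.itertuples()],
            index=self.genes.index,
            name="window_anchor",
        )


@dataclass
class ChromatinSegmentation:
    """Non-overlapping labelled intervals (0-based, half-open) for one tissue."""

    tissue_id: str
    intervals: pd.DataFrame  # columns chrom, start, end, state

    def __post_init__(self) -> None:
        iv = self.intervals
        if (iv["end"] <= iv["start"]).any():
            raise ValueError("interval with end <= start")
        unknown = set(iv["state"]) - set(CHROMATIN_STATES)
        if unknown:
            raise ValueError(
                f"unknown chromatin states {sorted(unknown)}; "
                f"vocabulary: {list(CHROMATIN_STATES)}"
            )
        self.intervals = iv.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )
        for _, grp in self.intervals.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals in tissue {self.tissue_id}")
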