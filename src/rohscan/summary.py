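"""Descriptive ROH statistics: length bins and classes, per-chromosome and
per-individual counts, cohort means.

Lengths in Mb are (end - start + 1) / 1e6. Bins are the six 1-Mb intervals
<1, 1-2, 2-3, 3-4, 4-5, >5 Mb, left-closed ([1,2) etc.) except that a run of
exactly 5 Mb falls in 4-5: the long class is strictly > 5 Mb, the short
class strictly < 1 Mb, and medium is everything in [1, 5] Mb, so classes are
exact unions of bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import RohSegment
from .genotypes import ChromMap

BIN_LABELS = ["<1", "1-2", "2-3", "3-4", "4-5", ">5"]
CLASS_LABELS = ["short", "medium", "long"]
_BIN_EDGES_MB = np.array([1.0, 2.0, 3.0, 4.0, 5.0])

#: which class each bin belongs to
BIN_CLASS = {"<1": "short", "1-2": "medium", "2-3": "medium",
             "3-4": "medium", "4-5": "medium", ">5": "long"}


def segment_bin(length_mb: float) -> str:
    """Length-interval label of one segment."""
    if length_mb == 5.0:  # boundary: exactly 5 Mb is 4-5, long is strictly >5
        return "4-5"
    idx = int(np.searchsorted(_BIN_EDGES_MB, length_mb, side="right"))
    return BIN_LABELS[idx]


def segment_class(length_mb: float) -> str:
    if length_mb < 1.0:
        return "short"
    if length_mb > 5.0:
        return "long"
    return "medium"


@dataclass
class BinCounts:
    counts: dict[str, int]
    proportions: dict[str, float]
    class_counts: dict[str, int]
    class_proportions: dict[str, float]
    total: int
    empty: bool


def bin_segments(segments: Sequence[RohSegment]) -> BinCounts:
    """Count segments per 1-Mb length interval and per length class."""
    counts = dict.fromkeys(BIN_LABELS, 0)
    class_counts = dict.fromkeys(CLASS_LABELS, 0)
    for seg in segments:
        counts[segment_bin(seg.length_mb)] += 1
        class_counts[segment_class(seg.length_mb)] += 1
    total = len(segments)
    denom = total if total else 1
    return BinCounts(
        counts=counts,
        proportions={k: v / denom for k, v in counts.items()},
        class_counts=class_counts,
        class_proportions={k: v / denom for k, v in class_counts.items()},
        total=total,
        empty=total == 0,
    )


@dataclass
class CohortSummary:
    total_segments: int
    n_samples: int
    mean_segments_per_individual: float
    mean_length_mb: float
    sd_length_mb: float
    per_chromosome: pd.Series = field(repr=False)
    per_individual: pd.Series = field(repr=False)
    bins: BinCounts = field(repr=False)

    def to_frame_per_chromosome(self) -> pd.DataFrame:
        return self.per_chromosome.rename("n_roh").rename_axis("chrom").reset_index()

    def to_frame_per_individual(self) -> pd.DataFrame:
        return self.per_individual.rename("n_roh").rename_axis("sample").reset_index()

    def to_frame_bins(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_mb": list(self.bins.counts),
                "n_roh": list(self.bins.counts.values()),
                "proportion": list(self.bins.proportions.values()),
                "length_class": [BIN_CLASS[b] for b in self.bins.counts],
            }
        )


def summarize_cohort(
    segments: Sequence[RohSegment],
    samples: Sequence[str],
    chrom_map: ChromMap | None = None,
) -> CohortSummary:
    """Cohort-level ROH summary.

    Individuals without any segment stay in the denominator of the
    per-individual mean (a zero-ROH individual is a real observation, not
    missing data). Chromosome rows cover the autosomes of ``chrom_map`` when
    given, otherwise the chromosomes observed in the segments.
    """
    if not samples:
        raise ValueError("sample list must be non-empty")
    lengths = np.array([s.length_mb for s in segments], dtype=float)
    chrom_index = (
        chrom_map.autosome_names()
        if chrom_map is not None
        else sorted({s.chrom for s in segments})
    )
    per_chrom = pd.Series(0, index=pd.Index(chrom_index, dtype=object), dtype=int)
    per_ind = pd.Series(0, index=pd.Index(list(samples), dtype=object), dtype=int)
    for seg in segments:
        if seg.chrom not in per_chrom.index:
            per_chrom.loc[seg.chrom] = 0
        per_chrom.loc[seg.chrom] += 1
        if seg.sample not in per_ind.index:
            raise ValueError(f"segment sample {seg.sample!r} not in sample list")
        per_ind.loc[seg.sample] += 1
    return CohortSummary(
        total_segments=len(segments),
        n_samples=len(samples),
        mean_segments_per_individual=len(segments) / len(samples),
        mean_length_mb=float(lengths.mean()) if len(lengths) else 0.0,
        sd_length_mb=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        per_chromosome=per_chrom,
        per_individual=per_ind,
        bins=bin_segments(segments),
    )
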