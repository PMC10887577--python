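"""ROH incidence track, top-percentile threshold, and ROH islands.

The incidence (ROH ratio) of a SNP is the fraction of individuals in the
cohort that carry at least one run of homozygosity covering its position.
SNPs whose incidence reaches the top-1% nearest-rank threshold are
"high-frequency"; runs of high-frequency SNPs, split at large gaps, form
ROH islands — candidate footprints of shared selection or drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import RohSegment
from .genotypes import GenotypeMatrix


@dataclass
class RohIsland:
    """Merged above-threshold interval (first to last high-frequency SNP)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("island start after end")
        if self.n_snps < 1:
            raise ValueError("island without SNPs")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def incidence_track(
    segments: Sequence[RohSegment],
    sites: pd.DataFrame,
    samples: Sequence[str],
) -> pd.DataFrame:
    """Per-SNP fraction of individuals covered by at least one ROH.

    ``sites`` needs columns ``chrom`` and ``pos`` (the QC-surviving SNP
    universe). Individuals are counted once per SNP no matter how many of
    their segments cover it. Returns a frame (chrom, pos, incidence).
    """
    if not samples:
        raise ValueError("need at least one individual")
    sample_idx = {s: i for i, s in enumerate(samples)}
    n_sites = len(sites)
    coverage = np.zeros(n_sites, dtype=np.int32)

    by_chrom: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    # site positions per chromosome, remembering the global row offset
    for chrom, group in sites.groupby("chrom", sort=False):
        by_chrom[chrom] = group["pos"].to_numpy()
        offsets[chrom] = int(group.index[0])

    segs_by_ind: dict[int, list[RohSegment]] = {}
    for seg in segments:
        if seg.sample not in sample_idx:
            raise ValueError(f"segment sample {seg.sample!r} not in cohort")
        segs_by_ind.setdefault(sample_idx[seg.sample], []).append(seg)

    for segs in segs_by_ind.values():
        covered = np.zeros(n_sites, dtype=bool)
        for seg in segs:
            pos = by_chrom.get(seg.chrom)
            if pos is None:
                continue
            lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
            hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
            off = offsets[seg.chrom]
            covered[off + lo : off + hi] = True
        coverage += covered

    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "incidence": coverage / len(samples),
        }
    )


def island_threshold(track: pd.DataFrame, top_fraction: float = 0.01) -> float:
    """Nearest-rank top-percentile incidence threshold.

    The threshold is the incidence of the ceil(top_fraction * N)-th largest
    SNP; SNPs with incidence >= threshold are high-frequency (ties at the
    boundary are included).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    values = track["incidence"].to_numpy()
    if len(values) == 0:
        raise ValueError("empty incidence track")
    k = math.ceil(top_fraction * len(values))
    return float(np.sort(values)[::-1][k - 1])


def call_islands(
    track: pd.DataFrame,
    threshold: float,
    max_gap_kb: float = 500.0,
    min_snps: int = 2,
) -> list[RohIsland]:
    """Group high-frequency SNPs into islands.

    Within each chromosome, consecutive high-frequency SNPs stay in one
    island while their spacing is at most ``max_gap_kb``; groups smaller than
    ``min_snps`` are discarded. Island coordinates span the first to last SNP
    of the group.
    """
    islands: list[RohIsland] = []
    for chrom, group in track.groupby("chrom", sort=False):
        high = group[group["incidence"] >= threshold]
        if high.empty:
            continue
        pos = high["pos"].to_numpy()
        inc = high["incidence"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap_kb * 1000.0)[0]
        start = 0
        for stop in list(breaks) + [len(pos) - 1]:
            n = stop - start + 1
            if n >= min_snps:
                islands.append(
                    RohIsland(
                        chrom=chrom,
                        start_bp=int(pos[start]),
                        end_bp=int(pos[stop]),
                        n_snps=int(n),
                        peak_incidence=float(inc[start : stop + 1].max()),
                    )
                )
            start = stop + 1
    return islands


def islands_pipeline(
    segments: Sequence[RohSegment],
    matrix: GenotypeMatrix,
    top_fraction: float = 0.01,
    max_gap_kb: float = 500.0,
    min_snps: int = 2,
) -> tuple[pd.DataFrame, float, list[RohIsland]]:
    """Convenience wrapper: track -> threshold -> islands."""
    track = incidence_track(segments, matrix.sites, matrix.samples)
    threshold = island_threshold(track, top_fraction)
    return track, threshold, call_islands(track, threshold, max_gap_kb, min_snps)
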