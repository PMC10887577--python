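"""Sliding-window runs-of-homozygosity detection (PLINK --homozyg style).

The scan slides a fixed window of ``window_snp`` SNPs along each chromosome
of each individual. A window is a *hit* when it contains at most
``window_het_max`` heterozygous and at most ``window_missing_max`` missing
calls. Each SNP is scored by the fraction of the windows containing it that
are hits; maximal stretches of SNPs whose fraction reaches
``window_hit_threshold`` form candidate runs, which are split at inter-SNP
gaps above ``max_gap_kb`` and then kept only if they satisfy the minimum SNP
count, minimum length and maximum kb-per-SNP density criteria.

Defaults reproduce a medium-density SNP-array protocol for livestock:
50-SNP windows allowing 1 heterozygote and 5 missing calls, runs of at least
50 SNPs and 100 kb, density cap 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .genotypes import HET, MISSING, GenotypeMatrix


@dataclass
class RohParams:
    """Detection criteria; see module docstring for semantics.

    ``max_density`` is interpreted per ``density_units``: "kb_per_snp" caps
    the run's kb-per-SNP ratio (the SNP-array tool's density option), while
    "bp_per_snp" reads the same number literally as a maximum of
    ``max_density`` bp per SNP.
    """

    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.05
    min_snp: int = 50
    min_length_kb: float = 100.0
    max_density: float = 1000.0
    density_units: Literal["kb_per_snp", "bp_per_snp"] = "kb_per_snp"
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if self.window_snp < 1:
            raise ValueError("window_snp must be >= 1")
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if self.min_length_kb <= 0 or self.max_density <= 0 or self.max_gap_kb <= 0:
            raise ValueError("min_length_kb, max_density and max_gap_kb must be > 0")
        if self.density_units not in ("kb_per_snp", "bp_per_snp"):
            raise ValueError(f"unknown density_units {self.density_units!r}")

    def density_ok(self, length_bp: int, n_snps: int) -> bool:
        if self.density_units == "kb_per_snp":
            return (length_bp / 1000.0) / n_snps <= self.max_density
        return length_bp / n_snps <= self.max_density


@dataclass
class RohSegment:
    """One run of homozygosity: first/last SNP positions, 1-based inclusive."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start after end")
        if self.n_snps < 1:
            raise ValueError("segment with no SNPs")


def window_is_hit(codes: np.ndarray, params: RohParams) -> bool:
    """Whether one full window of genotype codes supports homozygosity."""
    codes = np.asarray(codes)
    if codes.shape[0] != params.window_snp:
        raise ValueError(f"window must hold exactly {params.window_snp} codes")
    return bool(
        (codes == HET).sum() <= params.window_het_max
        and (codes == MISSING).sum() <= params.window_missing_max
    )


def _window_hits(codes: np.ndarray, params: RohParams) -> np.ndarray:
    """Hit flag for every window start (length n - window_snp + 1)."""
    n = codes.shape[0]
    w = params.window_snp
    if n < w:
        return np.zeros(0, dtype=bool)
    het_cum = np.concatenate(([0], np.cumsum(codes == HET)))
    mis_cum = np.concatenate(([0], np.cumsum(codes == MISSING)))
    het_in = het_cum[w:] - het_cum[:-w]
    mis_in = mis_cum[w:] - mis_cum[:-w]
    return (het_in <= params.window_het_max) & (mis_in <= params.window_missing_max)


def snp_hit_fraction(codes: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-SNP fraction of containing windows that are hits.

    Windows are every contiguous stretch of ``window_snp`` SNPs; SNPs near the
    chromosome ends sit in fewer windows. A chromosome shorter than one
    window has no windows and every fraction is defined as 0.
    """
    codes = np.asarray(codes)
    n = codes.shape[0]
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=float)
    hits = _window_hits(codes, params)
    n_windows = n - w + 1
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)          # first window start containing SNP i
    hi = np.minimum(idx, n_windows - 1)      # last window start containing SNP i
    hit_cum = np.concatenate(([0], np.cumsum(hits)))
    contained = hi - lo + 1
    hit_count = hit_cum[hi + 1] - hit_cum[lo]
    return hit_count / contained


def _candidate_bounds(
    in_run: np.ndarray, positions: np.ndarray, params: RohParams
) -> list[tuple[int, int]]:
    """Index bounds [i, j] of candidate runs after gap splitting."""
    bounds: list[tuple[int, int]] = []
    max_gap_bp = params.max_gap_kb * 1000.0
    n = len(in_run)
    i = 0
    while i < n:
        if not in_run[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and in_run[j + 1]:
            j += 1
        # split the stretch [i, j] at large inter-SNP gaps
        start = i
        for k in range(i, j):
            if positions[k + 1] - positions[k] > max_gap_bp:
                bounds.append((start, k))
                start = k + 1
        bounds.append((start, j))
        i = j + 1
    return bounds


def call_roh_individual(
    chrom: str,
    positions: np.ndarray,
    codes: np.ndarray,
    params: RohParams,
    sample: str,
) -> list[RohSegment]:
    """Call ROH for one individual on one chromosome.

    ``positions`` must be strictly increasing (hard error otherwise);
    ``codes`` is the matching 1-D genotype code vector.
    """
    positions = np.asarray(positions, dtype=np.int64)
    codes = np.asarray(codes)
    if positions.shape != codes.shape:
        raise ValueError("positions and codes differ in length")
    if len(positions) > 1 and not (np.diff(positions) > 0).all():
        raise ValueError(f"positions not strictly increasing on {chrom}")

    frac = snp_hit_fraction(codes, params)
    in_run = frac >= params.window_hit_threshold
    segments: list[RohSegment] = []
    for i, j in _candidate_bounds(in_run, positions, params):
        n_snps = j - i + 1
        length_bp = int(positions[j] - positions[i] + 1)
        if (
            n_snps >= params.min_snp
            and length_bp / 1000.0 >= params.min_length_kb
            and params.density_ok(length_bp, n_snps)
        ):
            segments.append(
                RohSegment(sample, chrom, int(positions[i]), int(positions[j]), n_snps)
            )
    return segments


def call_roh_cohort(
    matrix: GenotypeMatrix, params: RohParams | None = None
) -> list[RohSegment]:
    """Call ROH for every individual over every chromosome in the matrix.

    QC is assumed to have been applied already. Output is ordered by sample,
    then chromosome appearance order, then position; deterministic for a
    fixed input.
    """
    params = params or RohParams()
    segments: list[RohSegment] = []
    per_chrom = [
        (chrom, *matrix.chrom_arrays(chrom)) for chrom in matrix.chromosomes()
    ]
    for j, sample in enumerate(matrix.samples):
        for chrom, positions, codes in per_chrom:
            segments.extend(
                call_roh_individual(chrom, positions, codes[:, j], params, sample)
            )
    return segments
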