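"""Literal reference implementation of the ROH scan, for equivalence checks.

``oracle_call_roh`` shares the scan's contract but none of its code: every
window is enumerated with explicit loops, every SNP's hit fraction is tallied
by re-visiting each containing window, and candidate runs are re-derived by
plain scanning. It is intentionally slow and only suitable for small
instances (a few thousand SNPs); its job is to make the vectorized scanner
falsifiable.
"""

from __future__ import annotations

from .detect import RohParams, RohSegment
from .genotypes import HET, MISSING, GenotypeMatrix


def oracle_call_roh(matrix: GenotypeMatrix, params: RohParams | None = None) -> list[RohSegment]:
    params = params or RohParams()
    segments: list[RohSegment] = []
    for sample_idx, sample in enumerate(matrix.samples):
        for chrom in matrix.chromosomes():
            positions, code_block = matrix.chrom_arrays(chrom)
            positions = [int(p) for p in positions]
            codes = [int(c) for c in code_block[:, sample_idx]]
            segments.extend(
                _oracle_one(chrom, positions, codes, params, sample)
            )
    return segments


def _oracle_one(chrom, positions, codes, params, sample):
    w = params.window_snp
    n = len(codes)
    if n > 1:
        for a, b in zip(positions, positions[1:]):
            if b <= a:
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # hit flag of every window, one explicit count per window
    hits = []
    for start in range(max(0, n - w + 1)):
        window = codes[start : start + w]
        n_het = sum(1 for c in window if c == HET)
        n_mis = sum(1 for c in window if c == MISSING)
        hits.append(n_het <= params.window_het_max and n_mis <= params.window_missing_max)

    # per-SNP fraction by enumerating the windows containing each SNP
    fractions = []
    for i in range(n):
        containing = [s for s in range(len(hits)) if s <= i <= s + w - 1]
        if not containing:
            fractions.append(0.0)
        else:
            fractions.append(sum(1 for s in containing if hits[s]) / len(containing))

    # maximal stretches above threshold
    stretches = []
    i = 0
    while i < n:
        if fractions[i] >= params.window_hit_threshold:
            j = i
            while j + 1 < n and fractions[j + 1] >= params.window_hit_threshold:
                j += 1
            stretches.append((i, j))
            i = j + 1
        else:
            i += 1

    # split at large gaps
    candidates = []
    for i, j in stretches:
        start = i
        for k in range(i, j):
            if positions[k + 1] - positions[k] > params.max_gap_kb * 1000.0:
                candidates.append((start, k))
                start = k + 1
        candidates.append((start, j))

    # final per-run criteria
    out = []
    for i, j in candidates:
        n_snps = j - i + 1
        length_bp = positions[j] - positions[i] + 1
        length_kb = length_bp / 1000.0
        if n_snps < params.min_snp:
            continue
        if length_kb < params.min_length_kb:
            continue
        if params.density_units == "kb_per_snp":
            if length_kb / n_snps > params.max_density:
                continue
        else:
            if length_bp / n_snps > params.max_density:
                continue
        out.append(RohSegment(sample, chrom, positions[i], positions[j], n_snps))
    return out
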