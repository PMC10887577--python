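"""Genomic (F_ROH) and pedigree (F_PED) inbreeding coefficients.

F_ROH is the fraction of the autosomal genome covered by an individual's
runs of homozygosity:

    F_ROH = sum(L_ROH) / L_AUTO

F_PED follows Wright's path-counting method: for an individual X with sire S
and dam D,

    F_PED(X) = sum over common ancestors A and over path pairs
               (S -> A of n1 steps, D -> A of n2 steps)
               sharing no individual besides A of
               (1/2)^(n1 + n2 + 1) * (1 + F_A)

with paths truncated ``max_generations`` parent steps above X and ancestors
beyond the horizon treated as non-inbred founders. ``f_ped_recursive`` is
the tabular kinship recurrence over the full pedigree; on complete pedigrees
within the horizon the two agree to floating-point precision, which the test
suite exploits as a dual-method check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

from .detect import RohSegment
from .genotypes import ChromMap
from .pedigree import Pedigree


def f_roh(segments: Iterable[RohSegment], chrom_map: ChromMap) -> float:
    """Total autosomal ROH length over total autosomal genome length.

    Segments on non-autosomal chromosomes are ignored; segments must lie
    within their chromosome and (per RohSegment invariants) not overlap.
    """
    l_auto = chrom_map.autosome_length_bp
    if l_auto == 0:
        raise ValueError("autosomal genome length is zero")
    total = 0
    for seg in segments:
        if seg.chrom not in chrom_map.autosomes:
            continue
        if seg.end_bp > chrom_map.lengths[seg.chrom]:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start_bp}-{seg.end_bp} exceeds chromosome length"
            )
        total += seg.length_bp
    return total / l_auto


def _ancestral_paths(
    ped: Pedigree, start: str, max_steps: int
) -> Iterator[tuple[str, ...]]:
    """All upward paths from ``start`` of at most ``max_steps`` parent steps.

    Yields every path (including the length-0 path (start,)); the last
    element of each path is the ancestor it reaches.
    """
    stack: list[tuple[str, ...]] = [(start,)]
    while stack:
        path = stack.pop()
        yield path
        if len(path) - 1 >= max_steps:
            continue
        for parent in ped.parents[path[-1]]:
            if parent is not None:
                stack.append(path + (parent,))


def f_ped_path(
    ped: Pedigree,
    ind: str,
    max_generations: int = 5,
    _memo: dict[str, float] | None = None,
) -> float:
    """Wright path-counting inbreeding coefficient with generation truncation.

    ``max_generations`` counts parent steps from the individual; an ancestor
    reachable only beyond that horizon contributes nothing. An individual
    with any unknown parent has F = 0 (unrecorded ancestry is treated as
    unrelated). A common ancestor's own F is computed the same way, with the
    horizon re-anchored at that ancestor.
    """
    if ind not in ped.parents:
        raise KeyError(f"individual {ind!r} not in pedigree")
    if max_generations < 1:
        return 0.0
    memo = _memo if _memo is not None else {}
    if ind in memo:
        return memo[ind]
    if ind in ped.founder_f:
        memo[ind] = ped.founder_f[ind]
        return memo[ind]
    sire, dam = ped.parents[ind]
    if sire is None or dam is None:
        memo[ind] = 0.0
        return 0.0
    memo[ind] = 0.0  # break self-reference on (impossible) revisit during recursion
    sire_paths = list(_ancestral_paths(ped, sire, max_generations - 1))
    dam_paths_by_end: dict[str, list[tuple[str, ...]]] = {}
    for p in _ancestral_paths(ped, dam, max_generations - 1):
        dam_paths_by_end.setdefault(p[-1], []).append(p)
    total = 0.0
    for p1 in sire_paths:
        ancestor = p1[-1]
        for p2 in dam_paths_by_end.get(ancestor, ()):
            if set(p1) & set(p2) != {ancestor}:
                continue  # Wright's rule: no shared individual besides A
            n1, n2 = len(p1) - 1, len(p2) - 1
            f_a = f_ped_path(ped, ancestor, max_generations, memo)
            total += 0.5 ** (n1 + n2 + 1) * (1.0 + f_a)
    memo[ind] = total
    return total


def f_ped_recursive(ped: Pedigree, ind: str) -> float:
    """Inbreeding via the tabular kinship recurrence (untruncated oracle).

    F(X) = kinship(sire, dam), with kinship(a, a) = (1 + F(a)) / 2,
    kinship expanded through the parents of the deeper individual, and
    unknown parents contributing 0.
    """
    if ind not in ped.parents:
        raise KeyError(f"individual {ind!r} not in pedigree")
    memo: dict[tuple[str, str], float] = {}

    def kinship(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if a == b:
            return 0.5 * (1.0 + inbreeding(a))
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        # expand the deeper individual; parents are strictly shallower
        if ped.depth(a) < ped.depth(b):
            a, b = b, a
        sire, dam = ped.parents[a]
        value = 0.5 * (kinship(sire, b) + kinship(dam, b))
        memo[key] = value
        return value

    def inbreeding(x: str) -> float:
        if x in ped.founder_f:
            return ped.founder_f[x]
        sire, dam = ped.parents[x]
        if sire is None or dam is None:
            return 0.0
        return kinship(sire, dam)

    return inbreeding(ind)


@dataclass
class CorrelationResult:
    r: float
    t: float
    p: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with its t statistic and two-sided p value.

    t = r * sqrt((n - 2) / (1 - r^2)), p from Student's t with n - 2 df.
    Degenerate inputs (n < 3 or zero variance) raise rather than returning
    a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r=float(np.sign(r)), t=float(np.sign(r) * np.inf), p=0.0, n=n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, t=float(t), p=p, n=n)


def cohort_inbreeding(
    segments: Sequence[RohSegment],
    samples: Sequence[str],
    chrom_map: ChromMap,
    pedigree: Pedigree | None = None,
    max_generations: int = 5,
) -> "pd.DataFrame":
    """Per-individual F_ROH (and F_PED when a pedigree is supplied)."""
    import pandas as pd

    by_sample: dict[str, list[RohSegment]] = {s: [] for s in samples}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    rows = []
    for sample in samples:
        row: dict[str, object] = {
            "sample": sample,
            "f_roh": f_roh(by_sample.get(sample, []), chrom_map),
        }
        if pedigree is not None:
            row["f_ped"] = (
                f_ped_path(pedigree, sample, max_generations)
                if sample in pedigree.parents
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
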