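"""Synthetic cohorts with known autozygosity: pedigree simulation, gene-drop
inheritance with tracked identity-by-descent, genotype synthesis, and
annotation fixtures.

The generator emulates the study design this package targets: a small cohort
(~12 diploid individuals) genotyped on 18 autosomes, descending from a
5-generation pedigree that contains inbreeding loops, with SNPs every few kb,
genotyping error, and missingness. Founders carry uniquely labeled haplotype
copies; every meiosis draws a Poisson number of crossovers (no interference)
placed uniformly, so an individual is autozygous exactly where its two
haplotype labels coincide — that interval set is the TruthSet the ROH
detector is measured against.

Coordinates inside this module are 0-based half-open; the exported TruthSet,
genotype matrix and fixture files use the package-wide 1-based inclusive
convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import SITE_COLUMNS, ChromMap, GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING
from .io import FeatureRecord, write_pedigree, write_vcf
from .pedigree import Pedigree

# a haplotype along one chromosome: interval boundaries [0, ..., L] and the
# founder-copy label of each interval
Haplotype = tuple[list[int], list[int]]


@dataclass
class SimGenomeConfig:
    """Genome and noise model for the synthetic cohort.

    Defaults mirror the target study at desk scale: 18 autosomes (10 Mb each
    rather than full pig chromosomes), one SNP per ~3 kb, ~1 cM/Mb
    recombination, U-shaped array-like allele frequencies, 0.1% genotype
    error and 1% missingness.
    """

    n_chromosomes: int = 18
    chrom_length_bp: int = 10_000_000
    chrom_lengths: list[int] | None = None  # per-chromosome override
    snp_spacing_bp: float = 3000.0
    recomb_rate_per_mb: float = 0.01  # expected crossovers per Mb per meiosis
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    genotype_error_rate: float = 0.001
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        for rate in (self.recomb_rate_per_mb, self.genotype_error_rate, self.missing_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.chrom_lengths is not None and len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths length must equal n_chromosomes")
        if min(self.lengths().values()) <= 0:
            raise ValueError("chromosome lengths must be > 0")

    def names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def lengths(self) -> dict[str, int]:
        if self.chrom_lengths is not None:
            return dict(zip(self.names(), self.chrom_lengths))
        return {name: self.chrom_length_bp for name in self.names()}

    def chrom_map(self) -> ChromMap:
        return ChromMap.from_lengths(self.lengths())


# ---------------------------------------------------------------------------
# pedigree simulation


def simulate_pedigree(
    founders: int = 8,
    generations: int = 5,
    loop_spec: Sequence[tuple[str, int]] | None = None,
    seed: int = 0,
    offspring_per_generation: int | None = None,
) -> Pedigree:
    """Random mating pedigree with optional forced inbreeding loops.

    Generation 0 holds ``founders`` individuals of alternating sex; each of
    the ``generations`` later generations holds ``offspring_per_generation``
    individuals with parents drawn from the previous generation.

    ``loop_spec`` is a sequence of ("full_sib" | "half_sib" | "cousin", g)
    directives; each creates, at generation g, one individual whose parents
    are full sibs, half sibs, or first cousins (expected inbreeding 1/4, 1/8,
    1/16), building the required relatives in the intervening generations.
    Infeasible directives (too few founders or too shallow a generation)
    raise ValueError. Deterministic for a fixed seed.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if founders < 2:
        raise ValueError("need at least 2 founders (one of each sex)")
    rng = np.random.default_rng(seed)
    n_off = offspring_per_generation or max(founders, 4)

    parents: dict[str, tuple[str | None, str | None]] = {}
    sex: dict[str, str] = {}
    gens: list[list[str]] = [[]]
    for i in range(founders):
        ind = f"F{i + 1:02d}"
        parents[ind] = (None, None)
        sex[ind] = "M" if i % 2 == 0 else "F"
        gens[0].append(ind)

    def males(g: int) -> list[str]:
        return [i for i in gens[g] if sex[i] == "M"]

    def females(g: int) -> list[str]:
        return [i for i in gens[g] if sex[i] == "F"]

    def add(g: int, sire: str, dam: str, s: str) -> str:
        ind = f"G{g}_{len(gens[g]) + 1:02d}"
        parents[ind] = (sire, dam)
        sex[ind] = s
        gens[g].append(ind)
        return ind

    for g in range(1, generations + 1):
        gens.append([])
        for k in range(n_off):
            # random mating, but re-draw a few times to avoid full-sib pairs so
            # that close inbreeding comes from loop_spec rather than drift
            sire = str(rng.choice(males(g - 1)))
            dam = str(rng.choice(females(g - 1)))
            for _ in range(8):
                if parents[sire] != parents[dam] or parents[sire] == (None, None):
                    break
                dam = str(rng.choice(females(g - 1)))
            add(g, sire, dam, "M" if k % 2 == 0 else "F")

    for kind, g in loop_spec or []:
        if kind == "full_sib":
            if g < 2:
                raise ValueError("full_sib loop needs generation >= 2")
            sire0, dam0 = males(g - 2)[0], females(g - 2)[0]
            sib_m = add(g - 1, sire0, dam0, "M")
            sib_f = add(g - 1, sire0, dam0, "F")
            add(g, sib_m, sib_f, "M")
        elif kind == "half_sib":
            if g < 2:
                raise ValueError("half_sib loop needs generation >= 2")
            if len(females(g - 2)) < 2:
                raise ValueError("half_sib loop needs two dams in the grandparent generation")
            sire0 = males(g - 2)[0]
            dam0, dam1 = females(g - 2)[:2]
            hs_m = add(g - 1, sire0, dam0, "M")
            hs_f = add(g - 1, sire0, dam1, "F")
            add(g, hs_m, hs_f, "F")
        elif kind == "cousin":
            if g < 3:
                raise ValueError("cousin loop needs generation >= 3")
            if len(males(g - 3)) < 2 or len(females(g - 3)) < 2:
                raise ValueError("cousin loop needs two couples in generation g-3")
            gp_m, gp_f = males(g - 3)[0], females(g - 3)[0]
            sib1 = add(g - 2, gp_m, gp_f, "M")
            sib2 = add(g - 2, gp_m, gp_f, "F")
            spouse1 = females(g - 3)[1]
            spouse2 = males(g - 3)[1]
            c1 = add(g - 1, sib1, spouse1, "M")
            c2 = add(g - 1, spouse2, sib2, "F")
            add(g, c1, c2, "M")
        else:
            raise ValueError(f"unknown loop kind {kind!r}")

    ped = Pedigree(parents)
    ped.sex = sex
    return ped


# ---------------------------------------------------------------------------
# gene drop


def _slice_hap(hap: Haplotype, a: int, b: int) -> list[tuple[int, int, int]]:
    """Sub-intervals (start, end, label) of ``hap`` restricted to [a, b)."""
    bounds, labels = hap
    out = []
    for k in range(len(labels)):
        lo, hi = max(bounds[k], a), min(bounds[k + 1], b)
        if lo < hi:
            out.append((lo, hi, labels[k]))
    return out


def _from_intervals(intervals: list[tuple[int, int, int]]) -> Haplotype:
    """Build a haplotype from contiguous intervals, merging equal labels."""
    bounds = [intervals[0][0]]
    labels: list[int] = []
    for lo, hi, lab in intervals:
        if labels and lab == labels[-1]:
            bounds[-1] = hi
        else:
            labels.append(lab)
            bounds.append(hi)
    return bounds, labels


def _meiosis(hap_a: Haplotype, hap_b: Haplotype, length: int, rng, rate_per_mb: float) -> Haplotype:
    n_x = rng.poisson(rate_per_mb * length / 1e6)
    cuts = sorted(set(int(x) for x in rng.integers(1, length, size=n_x)))
    current = int(rng.integers(0, 2))
    pieces: list[tuple[int, int, int]] = []
    edges = [0] + cuts + [length]
    for a, b in zip(edges[:-1], edges[1:]):
        if a < b:
            pieces.extend(_slice_hap(hap_a if current == 0 else hap_b, a, b))
        current ^= 1
    return _from_intervals(pieces)


def _autozygous_intervals(hap0: Haplotype, hap1: Haplotype) -> list[tuple[int, int]]:
    """Maximal [start, end) intervals where the two label tracks coincide."""
    edges = sorted(set(hap0[0]) | set(hap1[0]))
    out: list[tuple[int, int]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        lab0 = hap0[1][np.searchsorted(hap0[0], a, side="right") - 1]
        lab1 = hap1[1][np.searchsorted(hap1[0], a, side="right") - 1]
        if lab0 == lab1:
            if out and out[-1][1] == a:
                out[-1] = (out[-1][0], b)
            else:
                out.append((a, b))
    return out


@dataclass
class TruthSet:
    """Realized autozygous tracts per individual, 1-based inclusive bp."""

    tracts: dict[str, list[tuple[str, int, int]]]
    fractions: dict[str, float]
    l_auto: int

    def tracts_of(self, ind: str) -> list[tuple[str, int, int]]:
        return self.tracts.get(ind, [])


@dataclass
class GeneDropResult:
    """Labeled haplotypes for every individual and chromosome."""

    config: SimGenomeConfig
    pedigree: Pedigree
    haplotypes: dict[str, dict[str, tuple[Haplotype, Haplotype]]]
    founder_labels: dict[str, tuple[int, int]]

    @property
    def n_labels(self) -> int:
        return 2 * len(self.founder_labels)

    def truth(self) -> TruthSet:
        """Re-derive autozygous tracts from the stored labels."""
        lengths = self.config.lengths()
        l_auto = sum(lengths.values())
        tracts: dict[str, list[tuple[str, int, int]]] = {}
        fractions: dict[str, float] = {}
        for ind, by_chrom in self.haplotypes.items():
            ind_tracts = []
            covered = 0
            for chrom in self.config.names():
                for a, b in _autozygous_intervals(*by_chrom[chrom]):
                    ind_tracts.append((chrom, a + 1, b))
                    covered += b - a
            tracts[ind] = ind_tracts
            fractions[ind] = covered / l_auto
        return TruthSet(tracts=tracts, fractions=fractions, l_auto=l_auto)


def gene_drop(
    pedigree: Pedigree,
    config: SimGenomeConfig,
    rng: np.random.Generator | None = None,
) -> GeneDropResult:
    """Transmit labeled founder haplotypes through the pedigree.

    Each founder receives two unique labels reused on every chromosome; each
    meiosis recombines the parent's two haplotypes with Poisson crossovers.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = config.lengths()
    founder_labels: dict[str, tuple[int, int]] = {}
    haplotypes: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = {}
    for ind in pedigree.topological_order():
        sire, dam = pedigree.parents[ind]
        by_chrom: dict[str, tuple[Haplotype, Haplotype]] = {}
        if sire is None or dam is None:
            lab = (2 * len(founder_labels), 2 * len(founder_labels) + 1)
            founder_labels[ind] = lab
            for chrom, length in lengths.items():
                by_chrom[chrom] = (
                    ([0, length], [lab[0]]),
                    ([0, length], [lab[1]]),
                )
        else:
            for chrom, length in lengths.items():
                pat = _meiosis(*haplotypes[sire][chrom], length, rng, config.recomb_rate_per_mb)
                mat = _meiosis(*haplotypes[dam][chrom], length, rng, config.recomb_rate_per_mb)
                by_chrom[chrom] = (pat, mat)
        haplotypes[ind] = by_chrom
    return GeneDropResult(config, pedigree, haplotypes, founder_labels)


def implant_tracts(
    result: GeneDropResult,
    implants: Sequence[tuple[str, str, int, int]],
) -> GeneDropResult:
    """Force autozygosity over chosen intervals (in place).

    Each implant (individual, chrom, start_bp, end_bp), 1-based inclusive,
    copies the maternal label track from the paternal one over the interval,
    so the region becomes autozygous by construction and appears in the
    TruthSet re-derived afterwards.
    """
    for ind, chrom, start_bp, end_bp in implants:
        length = result.config.lengths()[chrom]
        a, b = start_bp - 1, end_bp
        if not (0 <= a < b <= length):
            raise ValueError(f"implant {chrom}:{start_bp}-{end_bp} outside chromosome")
        hap0, hap1 = result.haplotypes[ind][chrom]
        pieces = _slice_hap(hap1, 0, a) + _slice_hap(hap0, a, b) + _slice_hap(hap1, b, length)
        result.haplotypes[ind][chrom] = (hap0, _from_intervals(pieces))
    return result


# ---------------------------------------------------------------------------
# genotype synthesis


def _snp_positions(length: int, spacing: float, rng) -> np.ndarray:
    """Strictly increasing 1-based positions with exponential spacing."""
    n_expected = int(length / spacing * 1.3) + 10
    gaps = np.maximum(1, rng.exponential(spacing, size=n_expected).astype(np.int64))
    pos = np.cumsum(gaps)
    pos = pos[pos <= length]
    while len(pos) and pos[-1] + spacing < length:  # rare under-draw
        extra = np.maximum(1, rng.exponential(spacing, size=16).astype(np.int64))
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos <= length]
    return pos


def synthesize_genotypes(
    result: GeneDropResult,
    rng: np.random.Generator | None = None,
    samples: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, ChromMap, TruthSet]:
    """Turn gene-drop inheritance into a genotype matrix with noise.

    Founder haplotype alleles are drawn per SNP from a Beta allele-frequency
    distribution; an individual's genotype is the pair of alleles carried by
    its two labels. Genotyping error flips a call to a random different
    (non-missing) code; missingness masks calls. ``samples`` restricts the
    matrix columns (default: every pedigree member, topological order).
    """
    config = result.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    samples = list(samples) if samples is not None else result.pedigree.topological_order()
    a, b = config.allele_freq_beta

    chroms_out: list[np.ndarray] = []
    pos_out: list[np.ndarray] = []
    code_blocks: list[np.ndarray] = []
    for chrom, length in config.lengths().items():
        pos = _snp_positions(length, config.snp_spacing_bp, rng)
        n = len(pos)
        freqs = rng.beta(a, b, size=n)
        founder_alleles = (rng.random((result.n_labels, n)) < freqs).astype(np.int8)
        block = np.empty((n, len(samples)), dtype=np.int8)
        pos0 = pos - 1  # 0-based for haplotype interval lookup
        for j, ind in enumerate(samples):
            hap0, hap1 = result.haplotypes[ind][chrom]
            lab0 = np.asarray(hap0[1])[np.searchsorted(hap0[0], pos0, side="right") - 1]
            lab1 = np.asarray(hap1[1])[np.searchsorted(hap1[0], pos0, side="right") - 1]
            block[:, j] = founder_alleles[lab0, np.arange(n)] + founder_alleles[lab1, np.arange(n)]
        if config.genotype_error_rate > 0:
            err = rng.random(block.shape) < config.genotype_error_rate
            shift = rng.integers(1, 3, size=block.shape).astype(np.int8)
            block[err] = (block[err] + shift[err]) % 3
        if config.missing_rate > 0:
            block[rng.random(block.shape) < config.missing_rate] = MISSING
        chroms_out.append(np.full(n, chrom, dtype=object))
        pos_out.append(pos)
        code_blocks.append(block)

    n_total = sum(len(p) for p in pos_out)
    sites = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms_out) if n_total else np.array([], dtype=object),
            "pos": np.concatenate(pos_out) if n_total else np.array([], dtype=np.int64),
            "ref": np.full(n_total, "A", dtype=object),
            "alt": np.full(n_total, "G", dtype=object),
            "qd": np.full(n_total, np.nan),
            "fs": np.full(n_total, np.nan),
            "mq": np.full(n_total, np.nan),
        },
        columns=SITE_COLUMNS,
    )
    matrix = GenotypeMatrix(
        sites=sites,
        samples=list(samples),
        codes=np.vstack(code_blocks) if code_blocks else np.zeros((0, len(samples)), np.int8),
    )
    matrix.validate()
    return matrix, config.chrom_map(), result.truth()


# ---------------------------------------------------------------------------
# deterministic worked-example cohort


def matrix_with_roh_counts(
    counts: Sequence[int],
    block_snps: int = 60,
    background_snps: int = 100,
    spacing_bp: int = 3000,
) -> tuple[GenotypeMatrix, ChromMap]:
    """Noise-free cohort engineered to yield a prescribed ROH count per individual.

    The single chromosome alternates heterozygous background stretches with
    homozygous blocks of ``block_snps`` SNPs; individual i is homozygous in
    its first ``counts[i]`` block slots and heterozygous elsewhere, so the
    default detector emits exactly ``counts[i]`` runs for it. Used for
    worked examples where the cohort's total ROH count must be exact.
    """
    n_slots = max(counts) if counts else 0
    layout: list[int] = [-1] * background_snps  # -1 marks background
    for slot in range(n_slots):
        layout += [slot] * block_snps + [-1] * background_snps
    n_sites = len(layout)
    pos = np.arange(1, n_sites + 1, dtype=np.int64) * spacing_bp
    codes = np.full((n_sites, len(counts)), HET, dtype=np.int8)
    slot_arr = np.array(layout)
    for j, c in enumerate(counts):
        codes[(slot_arr >= 0) & (slot_arr < c), j] = HOM_REF
    sites = pd.DataFrame(
        {
            "chrom": np.full(n_sites, "1", dtype=object),
            "pos": pos,
            "ref": np.full(n_sites, "A", dtype=object),
            "alt": np.full(n_sites, "G", dtype=object),
            "qd": np.full(n_sites, np.nan),
            "fs": np.full(n_sites, np.nan),
            "mq": np.full(n_sites, np.nan),
        },
        columns=SITE_COLUMNS,
    )
    samples = [f"BS-{j + 1}" for j in range(len(counts))]
    matrix = GenotypeMatrix(sites=sites, samples=samples, codes=codes)
    matrix.validate()
    chrom_map = ChromMap.from_lengths({"1": int(pos[-1] + spacing_bp) if n_sites else spacing_bp})
    return matrix, chrom_map


# ---------------------------------------------------------------------------
# annotation fixtures


def make_annotation_fixtures(
    config: SimGenomeConfig,
    n_genes: int,
    n_qtl: int,
    seed: int = 0,
) -> tuple[list[FeatureRecord], list[FeatureRecord], list[dict]]:
    """Uniformly placed gene and QTL features plus a manifest for oracles.

    QTL trait texts are drawn from the packaged trait-category table so that
    downstream categorization is exercised over all four categories.
    """
    from .annotate import load_category_map

    rng = np.random.default_rng(seed)
    lengths = config.lengths()
    names = config.names()
    trait_table = sorted(load_category_map().items())

    def place(kind: str, idx: int, min_len: int, max_len: int) -> FeatureRecord:
        chrom = names[int(rng.integers(0, len(names)))]
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, lengths[chrom])
        start = int(rng.integers(1, lengths[chrom] - length + 2))
        trait = ""
        if kind == "qtl":
            trait = trait_table[int(rng.integers(0, len(trait_table)))][0]
        return FeatureRecord(chrom, start, start + length - 1, kind, f"{kind}{idx + 1}", trait)

    genes = sorted(
        (place("gene", i, 5_000, 100_000) for i in range(n_genes)),
        key=lambda f: (f.chrom, f.start, f.end),
    )
    qtls = sorted(
        (place("qtl", i, 50_000, 2_000_000) for i in range(n_qtl)),
        key=lambda f: (f.chrom, f.start, f.end),
    )
    manifest = [asdict(f) for f in genes + qtls]
    return genes, qtls, manifest


def write_gff(features: Sequence[FeatureRecord], path: str | Path) -> None:
    """Write features as GFF3 (QTL traits in a ``trait=`` attribute)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.name};Name={f.name}"
            if f.trait:
                attrs += f';trait="{f.trait}"'
            ftype = "gene" if f.kind == "gene" else "QTL"
            fh.write(f"{f.chrom}\tsim\t{ftype}\t{f.start}\t{f.end}\t.\t+\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# full fixture bundle


def simulate_dataset(
    out_dir: str | Path,
    config: SimGenomeConfig | None = None,
    founders: int = 8,
    generations: int = 5,
    loop_spec: Sequence[tuple[str, int]] | None = (("full_sib", 4), ("half_sib", 5)),
    cohort_size: int = 12,
    n_genes: int = 60,
    n_qtl: int = 40,
) -> dict:
    """Simulate and write a complete fixture bundle; returns the manifest.

    Emits VCF, pedigree TSV, chrom-sizes TSV, per-individual truth BEDs,
    gene/QTL GFF files and a JSON manifest. The cohort is the last
    ``cohort_size`` individuals in topological order (the most recent
    generations), mirroring a genotyped tail of a deeper pedigree.
    """
    config = config or SimGenomeConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = simulate_pedigree(founders, generations, loop_spec, seed=config.seed)
    drop = gene_drop(ped, config)
    order = ped.topological_order()
    cohort = order[-cohort_size:] if cohort_size else order
    matrix, chrom_map, truth = synthesize_genotypes(drop, samples=cohort)

    write_vcf(matrix, chrom_map, out / "cohort.vcf")
    write_pedigree(ped, out / "pedigree.tsv")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for name, length in chrom_map.lengths.items():
            fh.write(f"{name}\t{length}\n")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for ind in cohort:
        with open(truth_dir / f"{ind}.bed", "w") as fh:
            for chrom, start, end in truth.tracts_of(ind):
                fh.write(f"{chrom}\t{start - 1}\t{end}\tautozygous\n")
    genes, qtls, feat_manifest = make_annotation_fixtures(config, n_genes, n_qtl, seed=config.seed + 2)
    write_gff(genes, out / "genes.gff")
    write_gff(qtls, out / "qtl.gff")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "cohort": cohort,
        "n_sites": matrix.n_sites,
        "truth_fractions": {ind: truth.fractions[ind] for ind in cohort},
        "features": feat_manifest,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
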