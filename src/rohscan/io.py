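"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Internal coordinates are 1-based inclusive everywhere. BED's 0-based
  half-open convention is converted at the file boundary only.
* Chromosome names are matched exactly; no "chr" stripping. An alias map may
  be supplied where joins between differently-named sources are needed.
* Multi-allelic VCF sites are excluded at read time and counted; half-calls
  (e.g. ``./1``) are conservatively coded MISSING.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SITE_COLUMNS,
    ChromMap,
    GenotypeMatrix,
    is_autosome_name,
)
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

ROH_TABLE_COLUMNS = ["IID", "CHR", "POS1", "POS2", "KB", "NSNP", "DENSITY_KB_PER_SNP"]

MISSING_PARENT_TOKENS = {"0", "NA", "na", ".", ""}


@dataclass
class FeatureRecord:
    """A gene or QTL interval, stored 1-based inclusive."""

    chrom: str
    start: int
    end: int
    kind: str  # "gene" or "qtl"
    name: str
    trait: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.name}: start {self.start} > end {self.end}")


@dataclass
class VcfReadLog:
    """Counts of records excluded while reading a VCF."""

    records_in: int = 0
    multiallelic_excluded: int = 0
    non_autosomal_excluded: int = 0
    sites_out: int = 0


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, length = line.split()[:2]
        sizes[name] = int(length)
    return sizes


def _code_from_gt(alleles: Sequence[int]) -> int:
    """Map one GT allele pair to a genotype code (half-calls -> MISSING)."""
    a = [x for x in alleles[:2]]
    if len(a) < 2 or any(x is None or x < 0 for x in a):
        return MISSING
    if a[0] == 0 and a[1] == 0:
        return HOM_REF
    if a[0] == 1 and a[1] == 1:
        return HOM_ALT
    return HET


def read_vcf_genotypes(
    path: str | Path,
    autosomes_only: bool = False,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[GenotypeMatrix, ChromMap, VcfReadLog]:
    """Read GT genotypes (plus QD/FS/MQ INFO and GQ FORMAT) from a VCF v4.2.

    Contig lengths come from ``##contig`` headers, with ``chrom_sizes``
    filling any gap; a contig carrying records but with no known length is a
    hard error. Phase separators are ignored; any allele beyond the first ALT
    marks the site multi-allelic and the site is dropped (counted in the log).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    log = VcfReadLog()

    lengths: dict[str, int] = {}
    for name, ln in zip(vcf.seqnames, vcf.seqlens or []):
        if ln and ln > 0:
            lengths[name] = int(ln)
    if chrom_sizes:
        lengths.update(chrom_sizes)

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    qd: list[float] = []
    fs: list[float] = []
    mq: list[float] = []
    codes_rows: list[list[int]] = []
    gq_rows: list[np.ndarray] = []
    any_gq = False

    for v in vcf:
        log.records_in += 1
        if samples and "GT" not in (v.FORMAT or []):
            raise ValueError(f"record {v.CHROM}:{v.POS} has no GT in FORMAT")
        if v.CHROM not in lengths:
            raise ValueError(
                f"contig {v.CHROM!r} has no length: add a ##contig header or a chrom-sizes file"
            )
        if autosomes_only and not is_autosome_name(v.CHROM):
            log.non_autosomal_excluded += 1
            continue
        if len(v.ALT) != 1 or any(
            max((x for x in g[:2] if x is not None and x >= 0), default=0) > 1
            for g in v.genotypes
        ):
            log.multiallelic_excluded += 1
            continue
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qd.append(_info_float(v, "QD"))
        fs.append(_info_float(v, "FS"))
        mq.append(_info_float(v, "MQ"))
        codes_rows.append([_code_from_gt(g) for g in v.genotypes])
        gq_row = _gq_row(v, len(samples))
        gq_rows.append(gq_row)
        if (gq_row >= 0).any():
            any_gq = True

    sites = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=object),
            "pos": pd.Series(pos, dtype=np.int64),
            "ref": pd.Series(ref, dtype=object),
            "alt": pd.Series(alt, dtype=object),
            "qd": pd.Series(qd, dtype=float),
            "fs": pd.Series(fs, dtype=float),
            "mq": pd.Series(mq, dtype=float),
        },
        columns=SITE_COLUMNS,
    )
    codes = (
        np.array(codes_rows, dtype=np.int8)
        if codes_rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    gq = np.array(gq_rows, dtype=np.int16) if any_gq else None
    log.sites_out = len(sites)

    if autosomes_only:
        lengths = {c: l for c, l in lengths.items() if is_autosome_name(c)}
    chrom_map = ChromMap.from_lengths(lengths)

    matrix = GenotypeMatrix(sites=sites, samples=samples, codes=codes, gq=gq)
    matrix.validate()
    return matrix, chrom_map, log


def _info_float(variant, key: str) -> float:
    val = variant.INFO.get(key)
    return float(val) if val is not None else float("nan")


def _gq_row(variant, n_samples: int) -> np.ndarray:
    try:
        raw = variant.format("GQ")
    except KeyError:
        raw = None
    if raw is None:
        return np.full(n_samples, -1, dtype=np.int16)
    row = np.asarray(raw, dtype=float).reshape(n_samples, -1)[:, 0]
    out = np.where(np.isfinite(row) & (row >= 0), row, -1)
    return out.astype(np.int16)


def write_vcf(
    matrix: GenotypeMatrix, chrom_map: ChromMap, path: str | Path
) -> None:
    """Serialize a GenotypeMatrix as an uncompressed VCF v4.2 with ##contig headers."""
    code_to_gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Qual by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias FS">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for name, length in chrom_map.lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + matrix.samples) + "\n")
        fmt = "GT" if matrix.gq is None else "GT:GQ"
        sites = matrix.sites
        for i in range(matrix.n_sites):
            info_parts = []
            for key, col in (("QD", "qd"), ("FS", "fs"), ("MQ", "mq")):
                val = sites[col].iat[i]
                if np.isfinite(val):
                    info_parts.append(f"{key}={val:g}")
            info = ";".join(info_parts) or "."
            fields = [
                str(sites["chrom"].iat[i]),
                str(int(sites["pos"].iat[i])),
                ".",
                str(sites["ref"].iat[i]),
                str(sites["alt"].iat[i]),
                ".",
                ".",
                info,
                fmt,
            ]
            for j in range(matrix.n_samples):
                gt = code_to_gt[int(matrix.codes[i, j])]
                if matrix.gq is not None:
                    gq = int(matrix.gq[i, j])
                    gt += ":" + (str(gq) if gq >= 0 else ".")
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def read_pedigree(path: str | Path) -> Pedigree:
    """3-column delimited text (id, sire, dam); 0/NA/. mean unknown parent."""
    parents: dict[str, tuple[str | None, str | None]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        ind, sire, dam = fields[:3]
        if ind in parents:
            raise ValueError(f"{path}:{lineno}: duplicate individual id {ind!r}")
        parents[ind] = (
            None if sire in MISSING_PARENT_TOKENS else sire,
            None if dam in MISSING_PARENT_TOKENS else dam,
        )
    return Pedigree(parents)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id\tsire\tdam\n")
        for ind in pedigree.topological_order():
            sire, dam = pedigree.parents[ind]
            fh.write(f"{ind}\t{sire or 0}\t{dam or 0}\n")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    """Parse GFF3 / AnimalQTLdb-dialect attribute strings.

    Accepts both ``key=value`` and the older ``key "value"`` form; values are
    unquoted and percent-decoding is left alone (names pass through verbatim).
    """
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, value = chunk.partition("=")
        elif " " in chunk:
            key, _, value = chunk.partition(" ")
        else:
            continue
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def read_features(
    path: str | Path, kind: str, aliases: dict[str, str] | None = None
) -> list[FeatureRecord]:
    """Read gene or QTL intervals from GFF3 or BED.

    BED intervals (0-based half-open) are converted to 1-based inclusive.
    Records whose interval is empty after conversion are rejected with a
    warning and counted in the module log. ``kind`` is "gene" or "qtl".
    ``aliases`` maps file chromosome names to the genome's names (e.g.
    ``{"chr1": "1"}``) — renaming is always explicit, never inferred.
    """
    if kind not in ("gene", "qtl"):
        raise ValueError(f"kind must be 'gene' or 'qtl', got {kind!r}")
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    records: list[FeatureRecord] = []
    rejected = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("browser") or line.startswith("track"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            if is_bed:
                chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"{kind}_{lineno}"
                start, end = start0 + 1, end0
                trait = ""
            else:
                chrom = fields[0]
                start, end = int(fields[3]), int(fields[4])
                attrs = _parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
                name = attrs.get("Name") or attrs.get("ID") or f"{kind}_{lineno}"
                trait = attrs.get("trait") or attrs.get("Trait") or ""
            if start > end:
                raise ValueError("empty interval")
            if aliases:
                chrom = aliases.get(chrom, chrom)
            records.append(FeatureRecord(chrom, start, end, kind, name, trait))
        except (ValueError, IndexError) as exc:
            rejected += 1
            logger.warning("%s:%d: rejected feature record (%s)", path, lineno, exc)
    if rejected:
        logger.info("%s: %d feature records rejected", path, rejected)
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def write_roh_table(segments: Iterable, path: str | Path) -> None:
    """Write ROH segments as a PLINK .hom-like TSV."""
    rows = [
        {
            "IID": s.sample,
            "CHR": s.chrom,
            "POS1": s.start_bp,
            "POS2": s.end_bp,
            "KB": round(s.length_kb, 3),
            "NSNP": s.n_snps,
            "DENSITY_KB_PER_SNP": round(s.length_kb / s.n_snps, 4),
        }
        for s in segments
    ]
    df = pd.DataFrame(rows, columns=ROH_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_roh_table(path: str | Path) -> list:
    from .detect import RohSegment  # deferred: io <-> detect layering

    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "IID": str})
    return [
        RohSegment(
            sample=row.IID,
            chrom=row.CHR,
            start_bp=int(row.POS1),
            end_bp=int(row.POS2),
            n_snps=int(row.NSNP),
        )
        for row in df.itertuples()
    ]


def write_islands_bed(islands: Sequence, path: str | Path, stats_path: str | Path | None = None) -> None:
    """Write islands as BED (0-based half-open) plus an optional stats TSV."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start_bp - 1}\t{isl.end_bp}\tisland\t{isl.peak_incidence:.4f}\n")
    if stats_path is not None:
        df = pd.DataFrame(
            [
                {
                    "CHR": isl.chrom,
                    "POS1": isl.start_bp,
                    "POS2": isl.end_bp,
                    "LENGTH_KB": round((isl.end_bp - isl.start_bp + 1) / 1000, 3),
                    "NSNP": isl.n_snps,
                    "PEAK_INCIDENCE": round(isl.peak_incidence, 6),
                }
                for isl in islands
            ],
            columns=["CHR", "POS1", "POS2", "LENGTH_KB", "NSNP", "PEAK_INCIDENCE"],
        )
        df.to_csv(stats_path, sep="\t", index=False)
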