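"""End-to-end workflow: QC -> ROH detection -> summaries -> inbreeding ->
islands -> annotation, with a run manifest for reproducibility.

Configuration is a TOML file with sections [inputs], [qc], [roh],
[inbreeding], [islands], [annotation]; unknown keys are rejected so a typo
cannot silently fall back to a default. Every defaulted parameter is echoed
into the manifest, and reruns on identical inputs and config are
bit-identical (no stage is stochastic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import categorize_qtl, load_category_map, overlap_features
from .detect import RohParams, call_roh_cohort
from .inbreeding import cohort_inbreeding, pearson_correlation
from .io import (
    read_chrom_sizes,
    read_features,
    read_pedigree,
    read_vcf_genotypes,
    write_islands_bed,
    write_roh_table,
)
from .islands import islands_pipeline
from .qc import QcThresholds, apply_qc
from .summary import summarize_cohort

logger = logging.getLogger(__name__)

_SECTION_FIELDS = {
    "inputs": {"vcf", "pedigree", "chrom_sizes", "genes", "qtl", "categories"},
    "qc": {f.name for f in dataclasses.fields(QcThresholds)},
    "roh": {f.name for f in dataclasses.fields(RohParams)},
    "inbreeding": {"max_generations"},
    "islands": {"top_fraction", "max_gap_kb", "min_snps"},
    "annotation": set(),
}
_TOP_LEVEL = {"out_dir", "log_level", "autosomes_only"} | set(_SECTION_FIELDS)


@dataclass
class RunConfig:
    vcf: str
    out_dir: str
    pedigree: str | None = None
    chrom_sizes: str | None = None
    genes: str | None = None
    qtl: str | None = None
    categories: str | None = None
    autosomes_only: bool = True
    log_level: str = "INFO"
    qc: QcThresholds = field(default_factory=QcThresholds)
    roh: RohParams = field(default_factory=RohParams)
    max_generations: int = 5
    islands_top_fraction: float = 0.01
    islands_max_gap_kb: float = 500.0
    islands_min_snps: int = 2

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        unknown = set(raw) - _TOP_LEVEL
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SECTION_FIELDS.items():
            extra = set(raw.get(section, {})) - allowed
            if extra:
                raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")
        inputs = raw.get("inputs", {})
        if "vcf" not in inputs:
            raise ValueError("config must set inputs.vcf")
        roh_kwargs = dict(raw.get("roh", {}))
        if "density_units" in roh_kwargs:
            roh_kwargs["density_units"] = str(roh_kwargs["density_units"])
        return cls(
            vcf=inputs["vcf"],
            out_dir=raw.get("out_dir", "rohscan_out"),
            pedigree=inputs.get("pedigree"),
            chrom_sizes=inputs.get("chrom_sizes"),
            genes=inputs.get("genes"),
            qtl=inputs.get("qtl"),
            categories=inputs.get("categories"),
            autosomes_only=raw.get("autosomes_only", True),
            log_level=raw.get("log_level", "INFO"),
            qc=QcThresholds(**raw.get("qc", {})),
            roh=RohParams(**roh_kwargs),
            max_generations=raw.get("inbreeding", {}).get("max_generations", 5),
            islands_top_fraction=raw.get("islands", {}).get("top_fraction", 0.01),
            islands_max_gap_kb=raw.get("islands", {}).get("max_gap_kb", 500.0),
            islands_min_snps=raw.get("islands", {}).get("min_snps", 2),
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    A missing pedigree input degrades gracefully: F_PED and the correlation
    are skipped and logged, F_ROH is still produced. Any stage error aborts
    with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "rohscan_version": __version__,
        "config": {
            "qc": dataclasses.asdict(config.qc),
            "roh": dataclasses.asdict(config.roh),
            "inbreeding": {"max_generations": config.max_generations},
            "islands": {
                "top_fraction": config.islands_top_fraction,
                "max_gap_kb": config.islands_max_gap_kb,
                "min_snps": config.islands_min_snps,
            },
            "autosomes_only": config.autosomes_only,
        },
        "inputs": {},
        "stages": {},
    }
    stage = "inputs"
    try:
        for name in ("vcf", "pedigree", "chrom_sizes", "genes", "qtl", "categories"):
            path = getattr(config, name)
            if path:
                manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

        stage = "qc"
        sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
        matrix, chrom_map, read_log = read_vcf_genotypes(
            config.vcf, autosomes_only=config.autosomes_only, chrom_sizes=sizes
        )
        matrix, qc_report = apply_qc(matrix, config.qc)
        report = qc_report.to_dict()
        report["vcf_read"] = dataclasses.asdict(read_log)
        (out / "qc_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"]["qc"] = report

        stage = "detect"
        segments = call_roh_cohort(matrix, config.roh)
        write_roh_table(segments, out / "roh.tsv")
        manifest["stages"]["detect"] = {"n_segments": len(segments)}

        stage = "summarize"
        summary = summarize_cohort(segments, matrix.samples, chrom_map)
        summary.to_frame_per_chromosome().to_csv(out / "roh_per_chromosome.tsv", sep="\t", index=False)
        summary.to_frame_per_individual().to_csv(out / "roh_per_individual.tsv", sep="\t", index=False)
        summary.to_frame_bins().to_csv(out / "roh_length_bins.tsv", sep="\t", index=False)
        manifest["stages"]["summarize"] = {
            "total_segments": summary.total_segments,
            "mean_segments_per_individual": summary.mean_segments_per_individual,
            "mean_length_mb": summary.mean_length_mb,
            "sd_length_mb": summary.sd_length_mb,
        }

        stage = "inbreeding"
        pedigree = read_pedigree(config.pedigree) if config.pedigree else None
        if pedigree is None:
            logger.info("no pedigree input: F_PED skipped, F_ROH only")
        coeffs = cohort_inbreeding(
            segments, matrix.samples, chrom_map, pedigree, config.max_generations
        )
        coeffs.to_csv(out / "inbreeding.tsv", sep="\t", index=False, float_format="%.6f")
        stage_info: dict = {"f_roh_mean": float(coeffs["f_roh"].mean())}
        if pedigree is not None:
            both = coeffs.dropna(subset=["f_ped"])
            stage_info["f_ped_mean"] = float(both["f_ped"].mean())
            try:
                corr = pearson_correlation(both["f_roh"], both["f_ped"])
                stage_info["pearson"] = {"r": corr.r, "t": corr.t, "p": corr.p, "n": corr.n}
            except ValueError as exc:
                stage_info["pearson"] = {"error": str(exc)}
            (out / "correlation.json").write_text(json.dumps(stage_info, indent=2))
        else:
            stage_info["f_ped"] = "skipped (no pedigree)"
        manifest["stages"]["inbreeding"] = stage_info

        stage = "islands"
        track, threshold, islands = islands_pipeline(
            segments,
            matrix,
            config.islands_top_fraction,
            config.islands_max_gap_kb,
            config.islands_min_snps,
        )
        track.to_csv(out / "incidence.tsv", sep="\t", index=False, float_format="%.6f")
        write_islands_bed(islands, out / "islands.bed", out / "islands.tsv")
        manifest["stages"]["islands"] = {"threshold": threshold, "n_islands": len(islands)}

        stage = "annotate"
        if config.genes or config.qtl:
            features = []
            if config.genes:
                features += read_features(config.genes, "gene")
            if config.qtl:
                features += read_features(config.qtl, "qtl")
            annotations = overlap_features(islands, features)
            category_map = load_category_map(config.categories)
            totals = categorize_qtl(annotations, category_map)
            rows = []
            for ann in annotations:
                rows.append(
                    {
                        "CHR": ann.island.chrom,
                        "POS1": ann.island.start_bp,
                        "POS2": ann.island.end_bp,
                        "GENES": ",".join(ann.gene_names),
                        "N_QTL": len(ann.qtls),
                    }
                )
            import pandas as pd

            pd.DataFrame(rows, columns=["CHR", "POS1", "POS2", "GENES", "N_QTL"]).to_csv(
                out / "island_annotation.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                [{"category": k, "n_qtl": v} for k, v in totals.items()]
            ).to_csv(out / "qtl_categories.tsv", sep="\t", index=False)
            manifest["stages"]["annotate"] = {
                "n_genes_overlapping": sum(len(a.genes) for a in annotations),
                "qtl_categories": totals,
            }
        else:
            manifest["stages"]["annotate"] = "skipped (no gene/QTL inputs)"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
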