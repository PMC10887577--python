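"""Hard-filter quality control applied before ROH detection.

Site filters follow the GATK VariantFiltration convention: a site is removed
iff an available annotation fails its strict inequality (QD < 4.0, FS > 60.0
or MQ < 40.0 by default); a missing annotation cannot fail its criterion and
the site is retained for it (the number of such sites is reported so the
pass-through can be audited). Genotypes with GQ below 20 are set MISSING.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class QcThresholds:
    qd_min: float = 4.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    gq_min: int = 20

    def __post_init__(self) -> None:
        for name in ("qd_min", "fs_max", "mq_min", "gq_min"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite")
        if self.qd_min < 0 or self.mq_min < 0 or self.gq_min < 0:
            raise ValueError("qd_min, mq_min and gq_min must be >= 0")


@dataclass
class QcReport:
    sites_in: int = 0
    sites_removed_by: dict[str, int] = field(
        default_factory=lambda: {"qd": 0, "fs": 0, "mq": 0}
    )
    sites_with_missing_info: dict[str, int] = field(
        default_factory=lambda: {"qd": 0, "fs": 0, "mq": 0}
    )
    genotypes_set_missing_by_gq: int = 0
    sites_out: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def apply_site_filters(
    matrix: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove sites failing QD/FS/MQ hard filters (strict inequalities).

    A site is removed iff QD < qd_min OR FS > fs_max OR MQ < mq_min, each
    criterion evaluated only where the annotation is present. Removal counts
    are attributed to the first failing criterion in (qd, fs, mq) order.
    """
    thresholds = thresholds or QcThresholds()
    report = QcReport(sites_in=matrix.n_sites)

    qd = matrix.sites["qd"].to_numpy()
    fs = matrix.sites["fs"].to_numpy()
    mq = matrix.sites["mq"].to_numpy()

    fail_qd = np.isfinite(qd) & (qd < thresholds.qd_min)
    fail_fs = np.isfinite(fs) & (fs > thresholds.fs_max)
    fail_mq = np.isfinite(mq) & (mq < thresholds.mq_min)

    report.sites_with_missing_info = {
        "qd": int((~np.isfinite(qd)).sum()),
        "fs": int((~np.isfinite(fs)).sum()),
        "mq": int((~np.isfinite(mq)).sum()),
    }
    report.sites_removed_by = {
        "qd": int(fail_qd.sum()),
        "fs": int((fail_fs & ~fail_qd).sum()),
        "mq": int((fail_mq & ~fail_qd & ~fail_fs).sum()),
    }
    keep = ~(fail_qd | fail_fs | fail_mq)
    out = matrix.subset_sites(keep)
    report.sites_out = out.n_sites
    return out, report


def apply_genotype_gq_filter(
    matrix: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, int]:
    """Set calls with GQ < gq_min to MISSING; absent GQ layer is a no-op.

    Returns the filtered matrix and the number of genotypes masked. GQ values
    of -1 mark per-call absence and never fail the filter.
    """
    thresholds = thresholds or QcThresholds()
    if matrix.gq is None:
        return matrix.copy(), 0
    out = matrix.copy()
    low = (out.gq >= 0) & (out.gq < thresholds.gq_min) & (out.codes != MISSING)
    out.codes[low] = MISSING
    return out, int(low.sum())


def apply_qc(
    matrix: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Site filters then genotype GQ filter (order does not affect the result)."""
    thresholds = thresholds or QcThresholds()
    filtered, report = apply_site_filters(matrix, thresholds)
    filtered, n_masked = apply_genotype_gq_filter(filtered, thresholds)
    report.genotypes_set_missing_by_gq = n_masked
    return filtered, report
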