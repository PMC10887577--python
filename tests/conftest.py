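"""Shared fixtures: small genotype matrices and random-instance generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohscan.detect import RohParams
from rohscan.genotypes import SITE_COLUMNS, ChromMap, GenotypeMatrix


def make_matrix(
    codes: np.ndarray,
    positions: np.ndarray | None = None,
    chrom: str = "1",
    samples: list[str] | None = None,
    spacing: int = 2000,
    **site_overrides,
) -> GenotypeMatrix:
    """Build a single-chromosome matrix from a code array (sites x samples)."""
    codes = np.atleast_2d(np.asarray(codes, dtype=np.int8))
    if codes.shape[0] == 1 and codes.shape[1] > 1 and samples is None:
        codes = codes.T  # a 1-D vector means one sample
    n_sites, n_samples = codes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1, dtype=np.int64) * spacing
    sites = pd.DataFrame(
        {
            "chrom": np.full(n_sites, chrom, dtype=object),
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": np.full(n_sites, "A", dtype=object),
            "alt": np.full(n_sites, "G", dtype=object),
            "qd": np.full(n_sites, np.nan),
            "fs": np.full(n_sites, np.nan),
            "mq": np.full(n_sites, np.nan),
        },
        columns=SITE_COLUMNS,
    )
    for col, values in site_overrides.items():
        sites[col] = values
    matrix = GenotypeMatrix(
        sites=sites,
        samples=samples or [f"s{i + 1}" for i in range(n_samples)],
        codes=codes,
    )
    matrix.validate()
    return matrix


def random_scan_instance(rng: np.random.Generator, n_snps: int, n_samples: int = 3):
    """Genotypes with ROH-like and outbred stretches, plus randomized params.

    Regime switching produces realistic long homozygous tracts so the run
    caller's gap/length/density logic is actually exercised.
    """
    codes = np.empty((n_snps, n_samples), dtype=np.int8)
    for j in range(n_samples):
        i = 0
        while i < n_snps:
            run = int(rng.geometric(1 / 150.0))
            stop = min(n_snps, i + run)
            if rng.random() < 0.5:  # autozygous-like stretch
                p = [0.58, 0.01, 0.38, 0.03]
            else:  # outbred stretch
                p = [0.34, 0.33, 0.30, 0.03]
            codes[i:stop, j] = rng.choice([0, 1, 2, 3], size=stop - i, p=p)
            i = stop
    gaps = rng.integers(1, 8000, size=n_snps)
    if rng.random() < 0.3:  # occasionally insert a huge gap to hit the splitter
        gaps[rng.integers(0, n_snps)] = int(2.5e6)
    positions = np.cumsum(gaps) + 1
    params = RohParams(
        window_snp=int(rng.integers(10, 81)),
        window_het_max=int(rng.integers(0, 3)),
        window_missing_max=int(rng.integers(0, 7)),
        window_hit_threshold=float(rng.uniform(0.02, 0.25)),
        min_snp=int(rng.integers(20, 81)),
        min_length_kb=float(rng.uniform(50, 300)),
        max_density=float(rng.uniform(5, 50)) if rng.random() < 0.5 else 1000.0,
        density_units="bp_per_snp" if rng.random() < 0.2 else "kb_per_snp",
        max_gap_kb=float(rng.uniform(100, 2000)),
    )
    if params.density_units == "bp_per_snp":
        params.max_density *= 1000
    return make_matrix(codes, positions), params


@pytest.fixture
def simple_chrom_map() -> ChromMap:
    return ChromMap.from_lengths({str(i): 10_000_000 for i in range(1, 19)})
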