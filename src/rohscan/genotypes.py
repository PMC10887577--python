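"""Core in-memory containers: genotype matrix and chromosome map.

Genotype calls are stored as a dense ``int8`` site x sample matrix using the
four codes below. Coordinates are 1-based inclusive everywhere inside the
package; conversions to other conventions happen only at file boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = 3

CODE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

#: columns every GenotypeMatrix.sites frame carries, in order
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qd", "fs", "mq"]

_AUTOSOME_RE = re.compile(r"^(chr)?\d+$", re.IGNORECASE)


def is_autosome_name(name: str) -> bool:
    """Classify a contig name as autosomal (purely numeric, optional chr prefix).

    This is classification only -- names are never rewritten (exact string
    matching is used for all joins).
    """
    return bool(_AUTOSOME_RE.match(name))


@dataclass
class ChromMap:
    """Chromosome name -> length (bp), with an autosome subset.

    ``autosome_length_bp`` is the denominator L_AUTO of the genomic inbreeding
    coefficient F_ROH.
    """

    lengths: dict[str, int]
    autosomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        unknown = self.autosomes - set(self.lengths)
        if unknown:
            raise ValueError(f"autosome names absent from length map: {sorted(unknown)}")

    @classmethod
    def from_lengths(cls, lengths: dict[str, int]) -> "ChromMap":
        """Build a map classifying autosomes by name."""
        return cls(dict(lengths), {c for c in lengths if is_autosome_name(c)})

    @property
    def autosome_length_bp(self) -> int:
        return sum(self.lengths[c] for c in self.autosomes)

    def autosome_names(self) -> list[str]:
        return [c for c in self.lengths if c in self.autosomes]


@dataclass
class GenotypeMatrix:
    """Per-site, per-sample genotype codes with site metadata.

    Attributes
    ----------
    sites:
        DataFrame with columns ``chrom, pos, ref, alt, qd, fs, mq`` (the
        last three are floats, NaN when the INFO field was absent). Sites are
        sorted by (chrom, pos) with strictly increasing pos within chrom.
    samples:
        Sample identifiers, one per matrix column.
    codes:
        ``int8`` array of shape (n_sites, n_samples) over
        {HOM_REF, HET, HOM_ALT, MISSING}.
    gq:
        Optional ``int16`` genotype-quality layer of the same shape;
        -1 marks an absent GQ value.
    """

    sites: pd.DataFrame
    samples: list[str]
    codes: np.ndarray
    gq: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        if list(self.sites.columns) != SITE_COLUMNS:
            raise ValueError(f"sites columns must be {SITE_COLUMNS}")
        if self.codes.shape != (self.n_sites, self.n_samples):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{self.n_sites} sites x {self.n_samples} samples"
            )
        if self.n_sites and not np.isin(self.codes, [HOM_REF, HET, HOM_ALT, MISSING]).all():
            raise ValueError("genotype codes outside {HOM_REF, HET, HOM_ALT, MISSING}")
        if self.gq is not None and self.gq.shape != self.codes.shape:
            raise ValueError("gq layer shape differs from codes")
        if self.n_sites and (self.sites["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        for _, pos in self.sites.groupby("chrom", sort=False)["pos"]:
            if not (np.diff(pos.to_numpy()) > 0).all():
                raise ValueError("positions not strictly increasing within chromosome")

    def chromosomes(self) -> list[str]:
        """Chromosome names in site order (first appearance)."""
        return list(dict.fromkeys(self.sites["chrom"]))

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            codes=self.codes[mask].copy(),
            gq=None if self.gq is None else self.gq[mask].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sites.copy(), list(self.samples), self.codes.copy(),
            None if self.gq is None else self.gq.copy(),
        )

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, codes) for one chromosome; codes shape (n, n_samples)."""
        mask = (self.sites["chrom"] == chrom).to_numpy()
        return self.sites["pos"].to_numpy()[mask], self.codes[mask]
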