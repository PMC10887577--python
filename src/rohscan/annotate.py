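"""Island-to-gene/QTL annotation and QTL trait categorization.

Overlap is plain interval intersection: a feature annotates an island iff
they share at least one base pair (no reciprocal-fraction requirement).
QTL trait names are mapped to four broad categories — reproduction, growth,
meat_and_carcass, health — through a user-editable table; traits without a
mapping land in an explicit "unclassified" bucket rather than being dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .io import FeatureRecord
from .islands import RohIsland

logger = logging.getLogger(__name__)

CATEGORIES = ["reproduction", "growth", "meat_and_carcass", "health"]
UNCLASSIFIED = "unclassified"


def load_category_map(path: str | Path | None = None) -> dict[str, str]:
    """Load trait -> category mapping from a 2-column TSV.

    Matching is case-insensitive on the full trait text. Without a path the
    packaged default table (seeded with AnimalQTLdb-style trait classes and
    common trait names) is used.
    """
    if path is None:
        text = (
            resources.files("rohscan").joinpath("data/qtl_trait_categories.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        trait, _, category = line.partition("\t")
        category = category.strip()
        if category not in CATEGORIES:
            raise ValueError(
                f"line {lineno}: category {category!r} not one of {CATEGORIES}"
            )
        mapping[trait.strip().lower()] = category
    return mapping


@dataclass
class IslandAnnotation:
    island: RohIsland
    genes: list[FeatureRecord] = field(default_factory=list)
    qtls: list[FeatureRecord] = field(default_factory=list)

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]


def overlap_features(
    islands: Sequence[RohIsland], features: Sequence[FeatureRecord]
) -> list[IslandAnnotation]:
    """Attach overlapping genes/QTL to each island (>= 1 shared bp).

    A feature may annotate several islands. Features on chromosomes with no
    island are logged at debug level; feature chromosomes entirely absent
    from the island set raise only a warning (a naming mismatch is likelier
    than an empty chromosome).
    """
    annotations = [IslandAnnotation(island=isl) for isl in islands]
    trees: dict[str, IntervalTree] = {}
    for idx, isl in enumerate(islands):
        # interval tree is half-open; +1 makes the inclusive end queryable
        trees.setdefault(isl.chrom, IntervalTree()).addi(isl.start_bp, isl.end_bp + 1, idx)

    island_chroms = set(trees)
    missing = sorted({f.chrom for f in features} - island_chroms)
    if missing and island_chroms:
        logger.warning("features on chromosomes without islands: %s", ", ".join(missing))

    for feat in features:
        tree = trees.get(feat.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(feat.start, feat.end + 1):
            ann = annotations[hit.data]
            (ann.genes if feat.kind == "gene" else ann.qtls).append(feat)
    for ann in annotations:
        ann.genes.sort(key=lambda f: (f.start, f.end, f.name))
        ann.qtls.sort(key=lambda f: (f.start, f.end, f.name))
    return annotations


def categorize_qtl(
    annotations: Sequence[IslandAnnotation],
    category_map: dict[str, str] | None = None,
) -> dict[str, int]:
    """Tally overlapping QTL into the four trait categories.

    Returns counts for each category plus "unclassified"; the values sum to
    the total number of island-QTL overlaps.
    """
    if category_map is None:
        category_map = load_category_map()
    totals = dict.fromkeys(CATEGORIES + [UNCLASSIFIED], 0)
    for ann in annotations:
        for qtl in ann.qtls:
            category = category_map.get(qtl.trait.strip().lower(), UNCLASSIFIED)
            totals[category] += 1
    return totals
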