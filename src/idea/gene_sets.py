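"""Gene-set collections: GMT parsing, merging, and universe restriction.

A :class:`GeneSetCollection` supplies the membership indicators used by
every enrichment computation: for a category (e.g. a transcription factor's
ChIP-derived target set) and a gene, membership is 1 iff the gene belongs to
the category's set.  Contingency tables are always formed against the
collection's *universe* — the genes that could have been observed — so the
collection carries its universe explicitly.

Identifiers are normalized to upper case with surrounding whitespace
stripped, because TF-target compendia mix symbol casing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "normalize_gene_id",
    "read_gmt",
    "read_universe",
    "write_gmt",
    "merge_collections",
    "restrict_to_universe",
]


def normalize_gene_id(gene: str) -> str:
    """Case/whitespace normalization applied to every gene identifier."""
    return gene.strip().upper()


@dataclass
class GeneSetCollection:
    """Named categories of genes plus the universe they are tested against.

    Parameters
    ----------
    categories
        Mapping of category name to the set of member gene identifiers.
    universe
        Set of gene identifiers eligible for contingency tables.  May be
        wider than the union of category members.
    source_labels
        Optional provenance tags per category (e.g. which database a TF's
        target set came from); merged collections concatenate tags.
    """

    categories: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)
    source_labels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.categories)

    def category_names(self) -> list[str]:
        return sorted(self.categories)


def read_gmt(
    path: str | Path,
    min_set_size: int = 3,
    max_set_size: int | None = None,
    source_label: str | None = None,
) -> GeneSetCollection:
    """Read a GMT file (one category per line: name, description, members...).

    Duplicate genes within a line are deduplicated after normalization.
    Categories whose post-deduplication size falls outside
    ``[min_set_size, max_set_size]`` are dropped (and logged).  Lines with
    fewer than three tab-separated fields, and duplicate category names, are
    errors.

    The returned collection's universe is the union of all retained members;
    callers normally widen/replace it via :func:`restrict_to_universe`.
    """
    path = Path(path)
    label = source_label if source_label is not None else path.stem
    categories: dict[str, set[str]] = {}
    source_labels: dict[str, tuple[str, ...]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected at least 3 (name, description, genes...)"
                )
            name = fields[0].strip()
            if name in categories:
                raise ValueError(f"{path}:{lineno}: duplicate category name {name!r}")
            members = {normalize_gene_id(g) for g in fields[2:] if g.strip()}
            if len(members) < min_set_size or (
                max_set_size is not None and len(members) > max_set_size
            ):
                n_dropped += 1
                logger.info(
                    "dropping category %s (size %d outside [%s, %s])",
                    name, len(members), min_set_size, max_set_size,
                )
                continue
            categories[name] = members
            source_labels[name] = (label,)
    if n_dropped:
        logger.info("%s: dropped %d categories by size filter", path, n_dropped)
    universe = set().union(*categories.values()) if categories else set()
    return GeneSetCollection(categories, universe, source_labels)


def read_universe(path: str | Path) -> set[str]:
    """Read a universe file: one gene per line, '#' comment lines ignored."""
    universe: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            universe.add(normalize_gene_id(line))
    return universe


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members sorted for reproducible output."""
    with open(path, "w") as fh:
        for name in sorted(collection.categories):
            desc = ";".join(collection.source_labels.get(name, ())) or "na"
            members = "\t".join(sorted(collection.categories[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def merge_collections(a: GeneSetCollection, b: GeneSetCollection) -> GeneSetCollection:
    """Union two collections (e.g. ChEA + ENCODE) to increase coverage.

    Same-named categories are merged by set union; universes are unioned;
    provenance tags are concatenated.  Commutative and associative on
    category contents.
    """
    categories = {name: set(genes) for name, genes in a.categories.items()}
    labels = dict(a.source_labels)
    for name, genes in b.categories.items():
        if name in categories:
            categories[name] = categories[name] | genes
        else:
            categories[name] = set(genes)
        labels[name] = labels.get(name, ()) + b.source_labels.get(name, ())
    return GeneSetCollection(categories, a.universe | b.universe, labels)


def restrict_to_universe(
    collection: GeneSetCollection, universe: set[str]
) -> GeneSetCollection:
    """Intersect every category with ``universe``; drop emptied categories.

    The resulting collection's universe is exactly the supplied one, so the
    background of each contingency table reflects the measured genes.
    Idempotent.  An empty universe is an error.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    categories: dict[str, set[str]] = {}
    labels: dict[str, tuple[str, ...]] = {}
    for name, genes in collection.categories.items():
        kept = genes & universe
        if kept:
            categories[name] = kept
            if name in collection.source_labels:
                labels[name] = collection.source_labels[name]
        else:
            logger.warning("category %s has no members in the universe; dropped", name)
    return GeneSetCollection(categories, set(universe), labels)
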