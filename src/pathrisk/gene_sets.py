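"""Pathway gene sets: GMT parsing, validation, and universe restriction.

A pathway here is a named set of gene symbols (KEGG / MSigDB / curated
article lists). Gene identity is by uppercased symbol string; no alias
resolution is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    """Raised for a malformed GMT line or a duplicate set name."""


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: gene symbols stored uppercased and deduplicated."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)
    source_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GMTParseError(f"duplicate gene-set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def universe(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)


def _normalize_genes(raw: Iterable[str]) -> frozenset[str]:
    return frozenset(g.strip().upper() for g in raw if g.strip())


def read_gmt(path: str | Path, source_tag: str = "") -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...).

    Gene symbols are uppercased and deduplicated; empty gene fields are
    dropped. Raises :class:`GMTParseError` naming the offending line for
    lines with fewer than three fields or for duplicate set names.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1]
            if name in seen:
                raise GMTParseError(f"{path.name}:{lineno}: duplicate gene-set name {name!r}")
            genes = _normalize_genes(fields[2:])
            if not genes:
                raise GMTParseError(f"{path.name}:{lineno}: gene set {name!r} has no genes")
            seen.add(name)
            sets.append(GeneSet(name=name, description=description, genes=genes))
    tags = {s.name: source_tag for s in sets} if source_tag else {}
    return GeneSetCollection(sets=sets, source_tags=tags)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT (genes in sorted order for determinism)."""
    path = Path(path)
    with path.open("w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def restrict_to_universe(
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_size: int = 5,
) -> GeneSetCollection:
    """Intersect every set with the measured gene universe.

    Sets with fewer than ``min_size`` surviving genes are dropped (logged).
    Idempotent, and never grows a set. An empty result is a warning, not an
    error — downstream stages simply see no pathways.
    """
    uni = frozenset(g.upper() for g in universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    kept: list[GeneSet] = []
    dropped: list[str] = []
    for s in collection:
        genes = s.genes & uni
        if len(genes) >= min_size:
            kept.append(GeneSet(name=s.name, description=s.description, genes=genes))
        else:
            dropped.append(s.name)
    if dropped:
        logger.info("restrict_to_universe dropped %d sets below min_size=%d", len(dropped), min_size)
    if not kept:
        warnings.warn("restrict_to_universe produced an empty collection", stacklevel=2)
    tags = {s.name: collection.source_tags.get(s.name, "") for s in kept} if collection.source_tags else {}
    return GeneSetCollection(sets=kept, source_tags=tags)
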