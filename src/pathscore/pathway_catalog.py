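"""Curated pathway gene sets: GMT loading, validation, and querying.

A catalog is a list of named gene sets plus the minimum gene count a set
needs before the rank-based group test is applied to it (default 6; sets
below the floor are kept but reported as not testable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

DEFAULT_MIN_TESTABLE_GENES = 6


def _canon(symbol: str) -> str:
    """Canonical form used for matching: trimmed, case-folded."""
    return symbol.strip().casefold()


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set.

    ``genes`` preserves input order but contains no duplicates under
    case-insensitive matching.
    """

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("pathway name must be non-empty")
        if len({_canon(g) for g in self.genes}) != len(self.genes):
            raise ValueError(f"pathway {self.name!r}: duplicate gene symbols")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_keys(self) -> frozenset[str]:
        return frozenset(_canon(g) for g in self.genes)


@dataclass(frozen=True)
class PathwayCatalog:
    """An ordered collection of pathways with unique names."""

    pathways: tuple[PathwayDefinition, ...]
    min_testable_genes: int = DEFAULT_MIN_TESTABLE_GENES
    coverage: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_testable_genes < 1:
            raise ValueError("min_testable_genes must be >= 1")
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate pathway names: {dupes}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    def __getitem__(self, name: str) -> PathwayDefinition:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)


def load_gmt(path: str | Path, min_testable_genes: int = DEFAULT_MIN_TESTABLE_GENES) -> PathwayCatalog:
    """Parse a GMT file (name TAB description TAB gene...) into a catalog.

    Within-set duplicate symbols (case-insensitive) are dropped with a
    warning; a line with fewer than 3 fields or a repeated pathway name is
    an error.
    """
    path = Path(path)
    pathways: list[PathwayDefinition] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line, expected >=3 "
                    f"tab-separated fields, got {len(fields)}"
                )
            name, description, *genes = fields
            seen: set[str] = set()
            unique: list[str] = []
            for g in genes:
                g = g.strip()
                if not g:
                    continue
                key = _canon(g)
                if key in seen:
                    logger.warning(
                        "%s:%d: duplicate gene %r in pathway %r dropped",
                        path, lineno, g, name,
                    )
                    continue
                seen.add(key)
                unique.append(g)
            if not unique:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways.append(PathwayDefinition(name=name.strip(), description=description, genes=tuple(unique)))
    return PathwayCatalog(pathways=tuple(pathways), min_testable_genes=min_testable_genes)


def write_gmt(catalog: PathwayCatalog, path: str | Path) -> None:
    """Write a catalog back out as GMT (round-trips with :func:`load_gmt`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in catalog:
            fh.write("\t".join([p.name, p.description, *p.genes]) + "\n")


def default_catalog(min_testable_genes: int = DEFAULT_MIN_TESTABLE_GENES) -> PathwayCatalog:
    """The 23-pathway metabolic catalog shipped with the package.

    Gene memberships are a reconstruction from standard pathway references;
    see the bundled GMT descriptions.
    """
    with resources.as_file(resources.files("pathscore.data") / "metabolic_pathways.gmt") as p:
        return load_gmt(p, min_testable_genes=min_testable_genes)


def intersect_with_matrix(catalog: PathwayCatalog, measured_genes: Iterable[str]) -> PathwayCatalog:
    """Restrict every pathway to the genes actually measured.

    Matching is case-insensitive after trimming; the measured spelling wins
    so downstream matrix lookups are direct. Pathways with zero overlap are
    retained (coverage 0) but will be excluded from scoring.
    """
    measured = {_canon(g): g for g in measured_genes}
    if not measured:
        raise ValueError("measured_genes must be non-empty")
    out: list[PathwayDefinition] = []
    coverage: dict[str, float] = {}
    for p in catalog:
        kept = tuple(measured[_canon(g)] for g in p.genes if _canon(g) in measured)
        coverage[p.name] = len(kept) / p.n_genes
        if not kept:
            logger.warning("pathway %r has no measured genes", p.name)
        out.append(replace(p, genes=kept) if kept else _empty_pathway(p))
    return PathwayCatalog(
        pathways=tuple(out),
        min_testable_genes=catalog.min_testable_genes,
        coverage=coverage,
    )


def _empty_pathway(p: PathwayDefinition) -> PathwayDefinition:
    # bypass the non-empty invariant check deliberately: an empty-flagged
    # pathway records that it was requested but is unmeasurable
    obj = object.__new__(PathwayDefinition)
    object.__setattr__(obj, "name", p.name)
    object.__setattr__(obj, "genes", ())
    object.__setattr__(obj, "description", p.description)
    return obj


def testable(catalog: PathwayCatalog) -> list[str]:
    """Names of pathways meeting the gene-count floor for rank testing."""
    return [p.name for p in catalog if p.n_genes >= catalog.min_testable_genes]
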