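"""Taxonomic lineages and phylostratigraphic age indices.

A gene's phylostratigraphic age index (PAI) is the depth, counted from the
root of the taxonomy, of the most recent common ancestor of the target
species and its most distantly related ortholog-bearing species.  Depth is
1-based: the shared root taxon is depth 1, the terminal species taxon of a
lineage of length L is depth L.  Smaller PAI means evolutionarily older.

Lineages are name-prefix paths (root -> species), not rank-aligned columns;
the last common ancestor of two species is simply the longest common prefix
of their lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonomicLineage",
    "TaxonomyTable",
    "PhylostratumAssignment",
    "LineageParseError",
    "parse_lineage_table",
    "lca_depth",
    "pai",
]


class LineageParseError(ValueError):
    """Raised for malformed lineage tables (names the offending row)."""


@dataclass(frozen=True)
class TaxonomicLineage:
    """One species' root-to-species taxon path.

    Parameters
    ----------
    species_code : str
        Short species identifier (KEGG-style, e.g. ``"hsa"``).
    taxa : tuple of str
        Ordered taxon names; ``taxa[0]`` is the root (depth 1), the last
        element is the terminal species taxon.
    """

    species_code: str
    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError(f"lineage for {self.species_code!r} is empty")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(
                f"lineage for {self.species_code!r} repeats a taxon name"
            )

    def __len__(self) -> int:
        return len(self.taxa)

    @property
    def root(self) -> str:
        return self.taxa[0]


@dataclass
class TaxonomyTable:
    """Map species_code -> :class:`TaxonomicLineage` with a shared root."""

    entries: dict[str, TaxonomicLineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = {lin.root for lin in self.entries.values()}
        if len(roots) > 1:
            raise ValueError(f"lineages disagree on the root taxon: {sorted(roots)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, species_code: str) -> bool:
        return species_code in self.entries

    def __getitem__(self, species_code: str) -> TaxonomicLineage:
        return self.entries[species_code]

    def species(self) -> list[str]:
        return list(self.entries)


@dataclass
class PhylostratumAssignment:
    """A gene's PAI with provenance.

    ``most_distant_species`` is the ortholog-bearing species attaining the
    minimal shared depth with the target (lexicographically smallest code on
    ties); ``skipped_species`` lists codes absent from the taxonomy that were
    ignored in non-strict mode.
    """

    gene_id: str
    pai: int
    method: str  # "KO" or "BST"
    most_distant_species: str = ""
    skipped_species: list[str] = field(default_factory=list)


def parse_lineage_table(stream: IO[str] | Iterable[str]) -> TaxonomyTable:
    """Parse a two-column lineage TSV into a :class:`TaxonomyTable`.

    Column 1 is the species code, column 2 the semicolon-delimited lineage
    from root to species.  ``#``-prefixed lines and blank lines are ignored.

    Raises
    ------
    LineageParseError
        On a duplicate species code, an empty lineage, or a root taxon that
        differs between rows; the message names the offending row.
    """
    entries: dict[str, TaxonomicLineage] = {}
    root: str | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise LineageParseError(f"row {lineno}: expected 2 tab-separated columns")
        code = parts[0].strip()
        taxa = tuple(t.strip() for t in parts[1].split(";") if t.strip())
        if not code:
            raise LineageParseError(f"row {lineno}: empty species code")
        if not taxa:
            raise LineageParseError(f"row {lineno}: empty lineage for {code!r}")
        if code in entries:
            raise LineageParseError(f"row {lineno}: duplicate species code {code!r}")
        if root is None:
            root = taxa[0]
        elif taxa[0] != root:
            raise LineageParseError(
                f"row {lineno}: root taxon {taxa[0]!r} for {code!r} "
                f"differs from {root!r}"
            )
        try:
            entries[code] = TaxonomicLineage(code, taxa)
        except ValueError as exc:
            raise LineageParseError(f"row {lineno}: {exc}") from exc
    return TaxonomyTable(entries)


def lca_depth(a: TaxonomicLineage, b: TaxonomicLineage) -> int:
    """1-based depth of the last common ancestor of two lineages.

    Equals the length of the longest common prefix of the two taxon paths;
    identical lineages return the full lineage length.
    """
    if a.root != b.root:
        raise ValueError(
            f"lineages of {a.species_code!r} and {b.species_code!r} "
            "do not share a root taxon"
        )
    depth = 0
    for ta, tb in zip(a.taxa, b.taxa):
        if ta != tb:
            break
        depth += 1
    return depth


def pai(
    target: str,
    ortholog_species: Iterable[str],
    table: TaxonomyTable,
    *,
    strict: bool = False,
    gene_id: str = "",
    method: str = "KO",
) -> PhylostratumAssignment:
    """PAI of a gene of ``target`` given the species bearing its orthologs.

    The PAI is ``min_s lca_depth(lineage(target), lineage(s))`` over the
    ortholog-bearing species ``s``; the target itself is always implicitly a
    member, so a gene with orthologs only in the target species (or none at
    all) gets the full lineage length — the youngest possible stratum.

    Species absent from the taxonomy raise an error in strict mode and are
    otherwise skipped with a warning and recorded in ``skipped_species``.
    """
    if target not in table:
        raise KeyError(f"target species {target!r} not in the taxonomy table")
    target_lin = table[target]
    best_depth = len(target_lin)
    best_species = target
    skipped: list[str] = []
    for code in sorted(set(ortholog_species)):
        if code == target:
            continue
        if code not in table:
            if strict:
                raise KeyError(f"species {code!r} not in the taxonomy table")
            skipped.append(code)
            logger.warning("species %r absent from taxonomy; skipped", code)
            continue
        depth = lca_depth(target_lin, table[code])
        if depth < best_depth:  # sorted iteration => lexicographic tie-break
            best_depth = depth
            best_species = code
    return PhylostratumAssignment(
        gene_id=gene_id,
        pai=best_depth,
        method=method,
        most_distant_species=best_species,
        skipped_species=skipped,
    )
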