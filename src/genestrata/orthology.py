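"""Ortholog-bearing species per gene: KO groups, similarity filtering, and a
native affine-gap Smith–Waterman scorer for building similarity tables.

Two homology sources feed the PAI computation:

* KO-group membership — genes sharing a curated orthology group; the species
  set of a gene is the union of member species over its groups.
* a best-similarity table — per-gene cross-species matches with a protein
  identity fraction and a Smith–Waterman score, filtered by inclusive
  thresholds (identity >= 0.5 and score >= 100 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .taxonomy import PhylostratumAssignment, TaxonomyTable, pai

logger = logging.getLogger(__name__)

__all__ = [
    "KOGroupMap",
    "SimilarityRecord",
    "HomologFilterThresholds",
    "ScoringScheme",
    "nucleotide_scheme",
    "blosum62_scheme",
    "parse_ko_table",
    "parse_similarity_table",
    "species_with_orthologs_ko",
    "filter_homologs",
    "pai_bst",
    "smith_waterman",
    "build_similarity_table",
    "NoKOAssignmentError",
]


class NoKOAssignmentError(KeyError):
    """The gene has no KO group (not all genes carry a KO assignment)."""


@dataclass
class KOGroupMap:
    """KO-group membership: gene -> groups and group -> (species, gene) members."""

    gene_to_groups: dict[str, set[str]] = field(default_factory=dict)
    group_members: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, group_id: str, species_code: str, gene_id: str) -> None:
        self.gene_to_groups.setdefault(gene_id, set()).add(group_id)
        self.group_members.setdefault(group_id, set()).add((species_code, gene_id))

    def species_of_gene(self, gene_id: str) -> set[str]:
        species = set()
        for group in self.gene_to_groups.get(gene_id, ()):
            species |= {sp for sp, _ in self.group_members[group]}
        return species


@dataclass(frozen=True)
class SimilarityRecord:
    """One row of a best-similarity table."""

    query_gene: str
    subject_gene: str
    subject_species: str
    identity: float
    sw_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.sw_score < 0:
            raise ValueError(f"negative Smith-Waterman score {self.sw_score}")


@dataclass(frozen=True)
class HomologFilterThresholds:
    """Inclusive thresholds for keeping similarity records.

    ``identity_min`` defaults to 0.5 and ``sw_min`` to 100; a record passes
    when identity >= identity_min AND sw_score >= sw_min.
    """

    identity_min: float = 0.5
    sw_min: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_min <= 1.0:
            raise ValueError(f"identity_min {self.identity_min} outside [0, 1]")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend`` (both non-positive).
    """

    substitution: Mapping[tuple[str, str], int]
    gap_open: int
    gap_extend: int
    alphabet: frozenset[str]
    name: str = "custom"

    def score(self, x: str, y: str) -> int:
        return self.substitution[(x, y)]


def nucleotide_scheme(
    match: int = 1, mismatch: int = -1, gap_open: int = 0, gap_extend: int = -1
) -> ScoringScheme:
    """Simple match/mismatch nucleotide scheme (default +1/-1, linear -1 gaps)."""
    alphabet = frozenset("ACGT")
    sub = {
        (x, y): (match if x == y else mismatch) for x in alphabet for y in alphabet
    }
    return ScoringScheme(sub, gap_open, gap_extend, alphabet, name="nt")


def blosum62_scheme(gap_open: int = -10, gap_extend: int = -1) -> ScoringScheme:
    """BLOSUM62 protein scheme with affine gaps (open -10 / extend -1)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    residues = [r for r in mat.alphabet if r.isalpha()]
    sub = {
        (x, y): int(mat[x, y]) for x in residues for y in residues
    }
    return ScoringScheme(
        sub, gap_open, gap_extend, frozenset(residues), name="BLOSUM62"
    )


def parse_ko_table(stream: IO[str] | Iterable[str]) -> KOGroupMap:
    """Parse a KO membership TSV: group_id, species_code, gene_id."""
    komap = KOGroupMap()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"row {lineno}: expected 3 columns (group, species, gene)")
        komap.add(parts[0].strip(), parts[1].strip(), parts[2].strip())
    return komap


def parse_similarity_table(stream: IO[str] | Iterable[str]) -> list[SimilarityRecord]:
    """Parse a similarity TSV: query_gene, subject_gene, subject_species,
    identity, sw_score.  A header row starting with 'query' is skipped."""
    records = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].strip().lower().startswith("query") and lineno == 1:
            continue
        if len(parts) < 5:
            raise ValueError(f"row {lineno}: expected 5 columns")
        try:
            records.append(
                SimilarityRecord(
                    query_gene=parts[0].strip(),
                    subject_gene=parts[1].strip(),
                    subject_species=parts[2].strip(),
                    identity=float(parts[3]),
                    sw_score=float(parts[4]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {lineno}: {exc}") from exc
    return records


def species_with_orthologs_ko(
    gene: str, komap: KOGroupMap, *, paralog_filter: bool = False
) -> set[str]:
    """Species bearing orthologs of ``gene`` according to KO membership.

    The species set is the union of member species over the gene's own KO
    groups.  Paralogs (several member genes of one species) collapse to one
    species either way; with ``paralog_filter`` the gene's own species is
    still counted exactly once — the flag is exposed as a hook for the DI
    comparison set, where paralog handling can matter.
    """
    if gene not in komap.gene_to_groups:
        raise NoKOAssignmentError(f"gene {gene!r} has no KO assignment")
    return komap.species_of_gene(gene)


def filter_homologs(
    records: Iterable[SimilarityRecord],
    thresholds: HomologFilterThresholds = HomologFilterThresholds(),
) -> list[SimilarityRecord]:
    """Keep records with identity >= identity_min and sw_score >= sw_min
    (both inclusive); input order preserved."""
    return [
        r
        for r in records
        if r.identity >= thresholds.identity_min and r.sw_score >= thresholds.sw_min
    ]


def pai_bst(
    gene: str,
    records: Iterable[SimilarityRecord],
    thresholds: HomologFilterThresholds,
    table: TaxonomyTable,
    target: str,
    *,
    strict: bool = False,
) -> PhylostratumAssignment:
    """PAI of ``gene`` from a best-similarity table.

    Records are filtered by the thresholds, collapsed to the subject-species
    set (a species with many passing homologs counts once), and the depth is
    delegated to :func:`genestrata.taxonomy.pai`.
    """
    mine = [r for r in records if r.query_gene == gene]
    species = {r.subject_species for r in filter_homologs(mine, thresholds)}
    return pai(
        target, species | {target}, table, strict=strict, gene_id=gene, method="BST"
    )


def smith_waterman(
    a: str, b: str, scheme: ScoringScheme
) -> tuple[float, float]:
    """Best local-alignment score and identity under affine gaps (Gotoh).

    Returns ``(score, identity)`` where identity is identical columns over
    aligned columns of one optimal traceback (diagonal moves preferred on
    ties).  The score floor is 0; a zero score means the empty alignment and
    identity 0.

    Raises
    ------
    ValueError
        If either sequence contains a symbol outside the scheme's alphabet.
    """
    for name, seq in (("first", a), ("second", b)):
        for pos, sym in enumerate(seq):
            if sym not in scheme.alphabet:
                raise ValueError(
                    f"symbol {sym!r} at position {pos} of the {name} sequence "
                    "is outside the scoring alphabet"
                )
    m, n = len(a), len(b)
    NEG = float("-inf")
    # H: best ending in a match/mismatch or fresh start; E: gap in b (up);
    # F: gap in a (left).  Gap of length L costs open + L*extend.
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, best_ij = 0.0, (0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(
                H[i - 1][j] + scheme.gap_open + scheme.gap_extend,
                E[i - 1][j] + scheme.gap_extend,
            )
            F[i][j] = max(
                H[i][j - 1] + scheme.gap_open + scheme.gap_extend,
                F[i][j - 1] + scheme.gap_extend,
            )
            diag = H[i - 1][j - 1] + scheme.score(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_ij = H[i][j], (i, j)
    if best <= 0:
        return 0.0, 0.0
    # Traceback one optimal alignment, preferring diagonal on ties.
    i, j = best_ij
    state = "H"
    identical = columns = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + scheme.score(a[i - 1], b[j - 1])
            if H[i][j] == diag:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    identical += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i - 1][j] + scheme.gap_open + scheme.gap_extend:
                state = "H"
            i -= 1
        else:  # F
            columns += 1
            if F[i][j] == H[i][j - 1] + scheme.gap_open + scheme.gap_extend:
                state = "H"
            j -= 1
    identity = identical / columns if columns else 0.0
    return best, identity


def build_similarity_table(
    query_species: str,
    sequences: Mapping[str, Mapping[str, str]],
    scheme: ScoringScheme,
) -> list[SimilarityRecord]:
    """Score every query-species gene against every other species' genes.

    ``sequences`` maps species_code -> {gene_id -> residue string}.  For each
    (query gene, subject species) the best-scoring subject gene is kept —
    the shape of a best-similarity table.
    """
    records: list[SimilarityRecord] = []
    queries = sequences.get(query_species, {})
    for qgene, qseq in queries.items():
        for species, genes in sequences.items():
            if species == query_species:
                continue
            best: SimilarityRecord | None = None
            for sgene, sseq in genes.items():
                score, identity = smith_waterman(qseq, sseq, scheme)
                if best is None or score > best.sw_score:
                    best = SimilarityRecord(qgene, sgene, species, identity, score)
            if best is not None:
                records.append(best)
    return records
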