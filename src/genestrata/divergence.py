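"""Pairwise dN/dS by Nei–Gojobori (1986) codon counting and the Divergence
Index (DI).

The estimator is the classic counting method: per-codon synonymous and
nonsynonymous site fractions (averaged over the two sequences), difference
counts averaged over all substitution pathways of each multi-hit codon
(pathways through stop codons excluded), and the Jukes–Cantor correction
d = -(3/4) ln(1 - (4/3) p) applied to the raw proportions pS = Sd/S and
pN = Nd/N.  The DI of a gene is the arithmetic mean of the defined dN/dS
ratios against its homologs in a chosen comparison set; a DI below 1
indicates purifying selection, about 1 neutral evolution, above 1 positive
selection.

Sequences must be in-frame, codon-aligned CDS over {A,C,G,T} with no indels
and no internal stop codons; only the standard genetic code is supported.
The result records the estimator name ("NG86-JC") so its values are not
mistaken for maximum-likelihood (codeml/yn00) estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .taxonomy import TaxonomyTable, lca_depth

__all__ = [
    "CodonSequence",
    "DnDsResult",
    "ComparisonSpec",
    "DivergenceIndex",
    "STANDARD_CODE",
    "STOP_CODONS",
    "ng86_pair",
    "jukes_cantor",
    "select_comparison_species",
    "divergence_index",
]

# Standard genetic code (translation table 1) from Biopython; stops are
# mapped to "*" so codons translate uniformly.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STANDARD_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    STANDARD_CODE[_stop] = "*"


@dataclass(frozen=True)
class CodonSequence:
    """An in-frame coding sequence tagged with its gene and species."""

    gene_id: str
    species_code: str
    nt: str

    def __post_init__(self) -> None:
        seq = self.nt.upper()
        object.__setattr__(self, "nt", seq)
        if not seq:
            raise ValueError(f"{self.gene_id}: empty coding sequence")
        if len(seq) % 3:
            raise ValueError(
                f"{self.gene_id}: length {len(seq)} not divisible by 3"
            )
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"{self.gene_id}: non-ACGT symbols {sorted(bad)}")
        for pos in range(0, len(seq) - 3, 3):
            if seq[pos : pos + 3] in STOP_CODONS:
                raise ValueError(
                    f"{self.gene_id}: internal stop codon at nt {pos + 1}"
                )

    @property
    def codons(self) -> list[str]:
        return [self.nt[i : i + 3] for i in range(0, len(self.nt), 3)]


@dataclass
class DnDsResult:
    """NG86 site and difference counts with corrected distances.

    ``ratio`` is dN/dS; it is ``None`` when excluded, with ``excluded``
    holding the reason (``"dS_zero"`` when no synonymous divergence, or
    ``"correction_out_of_range"`` when a raw proportion reaches the
    Jukes–Cantor saturation bound of 3/4).
    """

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    ratio: float | None
    excluded: str | None
    estimator: str = "NG86-JC"


@dataclass(frozen=True)
class ComparisonSpec:
    """Which species to compare against: a taxonomic level or explicit codes.

    ``level`` counts steps up from the tip of the target lineage: level 1
    keeps species within the target's genus, level 2 within its family, and
    so on.  Exactly one of ``level`` / ``organisms`` must be set.
    """

    level: int | None = None
    organisms: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if (self.level is None) == (self.organisms is None):
            raise ValueError("set exactly one of level / organisms")
        if self.level is not None and self.level < 1:
            raise ValueError("level must be a positive integer")


@dataclass
class DivergenceIndex:
    """Mean dN/dS of a gene over its homolog comparisons."""

    gene_id: str
    di: float | None
    n_pairs_used: int
    n_pairs_excluded: int


def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous, so
    the two counts always sum to 3.
    """
    aa = STANDARD_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if STANDARD_CODE[mutant] == aa and mutant not in STOP_CODONS:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) of one codon pair, averaged over substitution pathways.

    Pathways visiting a stop codon are excluded; if every pathway is blocked
    (only possible for multi-hit codons) all pathways are used instead so the
    pair still contributes its differences.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = c1
        steps = []
        for p in order:
            nxt = current[:p] + c2[p] + current[p + 1 :]
            steps.append((current, nxt))
            current = nxt
        paths.append(steps)
    valid = [
        steps
        for steps in paths
        if all(b not in STOP_CODONS for _, b in steps[:-1])
        and all(a not in STOP_CODONS for a, _ in steps[1:])
    ]
    if not valid:
        valid = paths
    syn = nonsyn = 0.0
    for steps in valid:
        for a, b in steps:
            if STANDARD_CODE[a] == STANDARD_CODE[b]:
                syn += 1
            else:
                nonsyn += 1
    k = len(valid)
    return syn / k, nonsyn / k


def jukes_cantor(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; ``None`` when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - p / 0.75)


def ng86_pair(a: CodonSequence, b: CodonSequence) -> DnDsResult:
    """NG86 dN/dS between two codon-aligned coding sequences.

    Raises
    ------
    ValueError
        On unequal lengths (sequence validity itself is enforced by
        :class:`CodonSequence`).
    """
    if len(a.nt) != len(b.nt):
        raise ValueError(
            f"{a.gene_id} and {b.gene_id} differ in length "
            f"({len(a.nt)} vs {len(b.nt)}); codon alignment required"
        )
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(a.codons, b.codons):
        sa, na = _codon_site_fractions(ca)
        sb, nb = _codon_site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        s, n = _pathway_counts(ca, cb)
        Sd += s
        Nd += n
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    excluded: str | None = None
    ratio: float | None = None
    if dS is None or dN is None:
        excluded = "correction_out_of_range"
    elif dS == 0.0:
        excluded = "dS_zero"
    else:
        ratio = dN / dS
    return DnDsResult(
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=Sd,
        nonsyn_diffs=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        ratio=ratio,
        excluded=excluded,
    )


def select_comparison_species(
    target: str, table: TaxonomyTable, spec: ComparisonSpec
) -> set[str]:
    """Species to compare ``target`` against, per a :class:`ComparisonSpec`.

    With explicit ``organisms`` the codes are validated against the taxonomy
    and returned.  With ``level`` k, every other species whose lineage shares
    at least the first L - k taxa with the target lineage (length L) is
    returned: level 1 restricts to the target's genus, level 2 to its family,
    and so on up the lineage.
    """
    if target not in table:
        raise KeyError(f"target species {target!r} not in the taxonomy table")
    target_lin = table[target]
    if spec.organisms is not None:
        unknown = [c for c in spec.organisms if c not in table]
        if unknown:
            raise KeyError(f"unknown species codes: {unknown}")
        return {c for c in spec.organisms if c != target}
    L = len(target_lin)
    if spec.level >= L:
        raise ValueError(
            f"level {spec.level} >= target lineage length {L}"
        )
    need = L - spec.level
    return {
        code
        for code, lin in table.entries.items()
        if code != target and lca_depth(target_lin, lin) >= need
    }


def divergence_index(
    target: CodonSequence, homologs: Sequence[CodonSequence] | Iterable[CodonSequence]
) -> DivergenceIndex:
    """DI of ``target``: arithmetic mean of defined dN/dS ratios over all
    pairwise comparisons with its homologs.

    Pairs flagged ``dS_zero`` or ``correction_out_of_range`` are excluded
    from the mean and counted in ``n_pairs_excluded``; with no usable pair
    the DI is undefined (``None``).
    """
    ratios: list[float] = []
    excluded = 0
    for hom in homologs:
        result = ng86_pair(target, hom)
        if result.ratio is None:
            excluded += 1
        else:
            ratios.append(result.ratio)
    di = sum(ratios) / len(ratios) if ratios else None
    return DivergenceIndex(
        gene_id=target.gene_id,
        di=di,
        n_pairs_used=len(ratios),
        n_pairs_excluded=excluded,
    )
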