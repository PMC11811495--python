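"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: the local-alignment
oracle enumerates monotone residue matchings instead of running dynamic
programming, and the codon oracle translates with Biopython and walks
substitution orderings recursively.
"""

from __future__ import annotations

from itertools import combinations, permutations

from Bio.Seq import Seq


def sw_oracle(a: str, b: str, scheme) -> float:
    """Best local affine-gap alignment score by exhaustive matching enumeration.

    Any gapped local alignment is determined (up to gap placement, which never
    scores better than one merged gap per side) by the monotone set of
    residue-residue columns it contains: the score is the sum of substitution
    scores plus, between consecutive columns, one affine gap per side for the
    unmatched residues.  Flanking residues are free (local alignment).
    """

    def gap_cost(length: int) -> float:
        return scheme.gap_open + length * scheme.gap_extend if length else 0.0

    m, n = len(a), len(b)
    best = 0.0
    for k in range(1, min(m, n) + 1):
        for ai in combinations(range(m), k):
            for bj in combinations(range(n), k):
                score = 0.0
                for t in range(k):
                    score += scheme.score(a[ai[t]], b[bj[t]])
                    if t:
                        score += gap_cost(ai[t] - ai[t - 1] - 1)
                        score += gap_cost(bj[t] - bj[t - 1] - 1)
                best = max(best, score)
    return best


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def codon_site_oracle(codon: str) -> tuple[float, float]:
    """(S, N) of one codon: per position, the fraction of the three possible
    changes that preserve the amino acid (changes to stops count as
    nonsynonymous)."""
    aa = _translate(codon)
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _translate(mut) == aa and _translate(mut) != "*":
                syn += 1 / 3
    return syn, 3 - syn


def codon_path_oracle(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) of one codon pair, averaged over substitution orderings that
    avoid stop-codon intermediates (all orderings if none avoids them)."""
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    tallies = []
    blocked = []
    for order in permutations(positions):
        cur = c1
        syn = nonsyn = 0.0
        hit_stop = False
        for step, p in enumerate(order):
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if step < len(order) - 1 and _translate(nxt) == "*":
                hit_stop = True
            if _translate(cur) == _translate(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if hit_stop else tallies).append((syn, nonsyn))
    pool = tallies or (tallies + blocked)
    sd = sum(s for s, _ in pool) / len(pool)
    nd = sum(n for _, n in pool) / len(pool)
    return sd, nd


def ng86_diff_oracle(nt1: str, nt2: str) -> tuple[float, float]:
    """Total (Sd, Nd) over all codons of an aligned pair."""
    sd = nd = 0.0
    for i in range(0, len(nt1), 3):
        s, n = codon_path_oracle(nt1[i : i + 3], nt2[i : i + 3])
        sd += s
        nd += n
    return sd, nd


def ng86_site_oracle(nt: str) -> tuple[float, float]:
    """Total (S, N) of one sequence."""
    s_tot = n_tot = 0.0
    for i in range(0, len(nt), 3):
        s, n = codon_site_oracle(nt[i : i + 3])
        s_tot += s
        n_tot += n
    return s_tot, n_tot
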