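"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a random taxonomy
(a rooted system of lineage paths), ortholog data (KO membership plus a
best-similarity table) with a planted PAI per gene, codon-sequence pairs
with exact planted synonymous/nonsynonymous substitution counts, expression
matrices, and STRING-dialect network TSVs.  All generators are pure
functions of their seed and parameters (``numpy.random.default_rng``; no
global random state), so recovery tests are exact and reruns byte-identical.

The generators emulate the *structure* of curated orthology data — nested
lineages, orthologs planted exactly down to a chosen stratum, similarity
scores above/below the default thresholds — not realistic sequence
evolution: no transition/transversion bias, no indels, no rate
heterogeneity, and at most one substitution per codon so NG86 pathway
averaging recovers the planted counts exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .divergence import STANDARD_CODE, STOP_CODONS, CodonSequence
from .orthology import KOGroupMap, SimilarityRecord
from .phylotranscriptomics import ExpressionMatrix
from .taxonomy import TaxonomicLineage, TaxonomyTable, lca_depth

__all__ = [
    "FixtureBundle",
    "gen_taxonomy",
    "gen_ortholog_data",
    "gen_codon_pair",
    "gen_expression",
    "gen_network",
    "gen_bundle",
    "write_bundle",
]


@dataclass
class FixtureBundle:
    """A complete synthetic input set with its planted truth."""

    target_species: str
    taxonomy: TaxonomyTable
    komap: KOGroupMap
    similarity: list[SimilarityRecord]
    cds: list[CodonSequence]
    expression: ExpressionMatrix
    network_tsv: str
    truth: dict = field(default_factory=dict)


def gen_taxonomy(seed: int, n_species: int, max_depth: int) -> TaxonomyTable:
    """Random rooted lineage system with a shared root.

    Species codes are ``sp000 .. spNNN``; internal taxon names are unique
    node labels of a random prefix tree.  At least two species reach depth
    ``max_depth`` so the deepest stratum is always comparable.
    """
    if n_species < 2 or max_depth < 2:
        raise ValueError("need n_species >= 2 and max_depth >= 2")
    rng = np.random.default_rng(seed)
    root = "Root"
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"T{counter[0]:04d}"

    # Internal paths available for extension, keyed by depth (root = depth 1).
    internal: list[tuple[str, ...]] = [(root,)]
    lineages: dict[str, TaxonomicLineage] = {}
    # Force two species at full depth by growing one deep backbone first.
    backbone = [(root,)]
    while len(backbone[-1]) < max_depth - 1:
        backbone.append(backbone[-1] + (fresh(),))
    internal.extend(backbone[1:])
    forced_parent = backbone[-1]
    for idx in range(n_species):
        code = f"sp{idx:03d}"
        if idx < 2:
            path = forced_parent
        else:
            path = internal[rng.integers(0, len(internal))]
            # occasionally deepen the tree below the chosen node
            while len(path) < max_depth - 1 and rng.random() < 0.35:
                path = path + (fresh(),)
                internal.append(path)
        lineages[code] = TaxonomicLineage(code, path + (f"{code}_sp",))
    return TaxonomyTable(lineages)


def _achievable_depths(target: str, taxonomy: TaxonomyTable) -> dict[int, list[str]]:
    """Map lca-depth -> other species attaining it against the target."""
    depths: dict[int, list[str]] = {}
    target_lin = taxonomy[target]
    for code, lin in taxonomy.entries.items():
        if code == target:
            continue
        depths.setdefault(lca_depth(target_lin, lin), []).append(code)
    return depths


def gen_ortholog_data(
    seed: int,
    taxonomy: TaxonomyTable,
    n_genes: int,
    target_species: str | None = None,
    age_distribution: str = "uniform",
) -> tuple[KOGroupMap, list[SimilarityRecord], dict]:
    """KO membership + similarity table with a planted PAI per gene.

    For each gene a true stratum d is drawn from the depths actually
    attainable against the target lineage (plus the full lineage length for
    species-restricted genes); orthologs are placed in *exactly* the species
    whose lca-depth with the target is >= d, so the minimum over the planted
    set equals d by construction.  True orthologs get similarity records
    passing the default thresholds (identity >= 0.5, score >= 100); decoy
    records into shallower species fail the identity threshold.
    """
    rng = np.random.default_rng(seed)
    codes = sorted(taxonomy.entries)
    if target_species is None:
        # deepest lineage, ties broken lexicographically
        target_species = max(codes, key=lambda c: (len(taxonomy[c]), c))
    target_lin = taxonomy[target_species]
    by_depth = _achievable_depths(target_species, taxonomy)
    L = len(target_lin)
    choices = sorted(by_depth) + [L]  # L = orthologs only in the target
    if age_distribution == "uniform":
        probs = None
    elif age_distribution == "old_biased":
        w = np.linspace(2.0, 1.0, len(choices))
        probs = w / w.sum()
    else:
        raise ValueError(f"unknown age_distribution {age_distribution!r}")

    komap = KOGroupMap()
    records: list[SimilarityRecord] = []
    truth: dict[str, dict] = {}
    lca_of = {
        c: lca_depth(target_lin, taxonomy[c]) for c in codes if c != target_species
    }
    for g in range(n_genes):
        gene = f"{target_species}:g{g:04d}"
        d = int(rng.choice(choices, p=probs))
        group = f"K{g:05d}"
        komap.add(group, target_species, gene)
        ortholog_species = [c for c, dep in lca_of.items() if dep >= d]
        for sp in sorted(ortholog_species):
            komap.add(group, sp, f"{sp}:g{g:04d}")
            records.append(
                SimilarityRecord(
                    query_gene=gene,
                    subject_gene=f"{sp}:g{g:04d}",
                    subject_species=sp,
                    identity=float(np.round(rng.uniform(0.55, 0.95), 3)),
                    sw_score=float(np.round(rng.uniform(150, 600), 1)),
                )
            )
        decoys = sorted(c for c, dep in lca_of.items() if dep < d)
        for sp in decoys[: int(rng.integers(0, 3))]:
            records.append(
                SimilarityRecord(
                    query_gene=gene,
                    subject_gene=f"{sp}:decoy{g:04d}",
                    subject_species=sp,
                    identity=float(np.round(rng.uniform(0.05, 0.45), 3)),
                    sw_score=float(np.round(rng.uniform(120, 400), 1)),
                )
            )
        truth[gene] = {"pai": d}
    return komap, records, {"target_species": target_species, "genes": truth}


def _random_codon(rng: np.random.Generator) -> str:
    bases = "ACGT"
    while True:
        codon = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if codon not in STOP_CODONS:
            return codon


def _single_step_changes(codon: str) -> list[tuple[str, bool]]:
    """All single-nucleotide mutants of a codon (excluding stops) with a flag
    for synonymy."""
    out = []
    aa = STANDARD_CODE[codon]
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            out.append((mutant, STANDARD_CODE[mutant] == aa))
    return out


def gen_codon_pair(
    seed: int,
    n_codons: int,
    syn_subs: int,
    nonsyn_subs: int,
    gene_id: str = "g",
    species_a: str = "spA",
    species_b: str = "spB",
) -> tuple[CodonSequence, CodonSequence, dict]:
    """Ancestor + derived coding sequence with exact substitution counts.

    The derived copy differs by exactly ``syn_subs`` synonymous and
    ``nonsyn_subs`` nonsynonymous single-nucleotide substitutions, at most
    one per codon and never creating a stop, so NG86 difference counting
    recovers the planted counts exactly.
    """
    total = syn_subs + nonsyn_subs
    if total > n_codons:
        raise ValueError(
            f"{total} substitutions do not fit in {n_codons} codons "
            "(one per codon)"
        )
    rng = np.random.default_rng(seed)
    # draw ancestor codons ensuring enough codons admit a synonymous or
    # nonsynonymous single-step change respectively
    for _ in range(1000):
        ancestor = [_random_codon(rng) for _ in range(n_codons)]
        syn_capable = [
            i
            for i, c in enumerate(ancestor)
            if any(s for _, s in _single_step_changes(c))
        ]
        nonsyn_capable = [
            i
            for i, c in enumerate(ancestor)
            if any(not s for _, s in _single_step_changes(c))
        ]
        if len(syn_capable) >= syn_subs and len(nonsyn_capable) >= nonsyn_subs:
            # a greedy disjoint assignment: synonymous picks first
            syn_sites = list(
                rng.choice(syn_capable, size=syn_subs, replace=False)
            ) if syn_subs else []
            remaining = [i for i in nonsyn_capable if i not in set(syn_sites)]
            if len(remaining) >= nonsyn_subs:
                nonsyn_sites = list(
                    rng.choice(remaining, size=nonsyn_subs, replace=False)
                ) if nonsyn_subs else []
                break
    else:
        raise ValueError("could not place the requested substitutions")
    derived = list(ancestor)
    for i in syn_sites:
        options = [m for m, s in _single_step_changes(ancestor[i]) if s]
        derived[i] = options[rng.integers(0, len(options))]
    for i in nonsyn_sites:
        options = [m for m, s in _single_step_changes(ancestor[i]) if not s]
        derived[i] = options[rng.integers(0, len(options))]
    a = CodonSequence(gene_id, species_a, "".join(ancestor))
    b = CodonSequence(gene_id, species_b, "".join(derived))
    return a, b, {"syn": syn_subs, "nonsyn": nonsyn_subs}


def gen_expression(
    seed: int,
    genes: list[str],
    conditions: list[str],
    profile: str = "random",
    pai_by_gene: dict[str, int] | None = None,
) -> ExpressionMatrix:
    """Non-negative expression matrix.

    ``uniform`` makes every entry equal (so TAI reduces to the mean PAI);
    ``random`` draws log-normal-ish positive values; ``oldest_biased``
    up-weights genes of the oldest strata (smallest PAI; requires
    ``pai_by_gene``), pulling TAI below the uniform value.
    """
    if not genes or not conditions:
        raise ValueError("need at least one gene and one condition")
    rng = np.random.default_rng(seed)
    n, m = len(genes), len(conditions)
    if profile == "uniform":
        values = np.ones((n, m))
    elif profile == "random":
        values = np.exp(rng.normal(0.0, 1.0, size=(n, m)))
    elif profile == "oldest_biased":
        if pai_by_gene is None:
            raise ValueError("oldest_biased needs pai_by_gene")
        pais = np.array([pai_by_gene[g] for g in genes], dtype=float)
        # weight inversely with stratum depth: old (small PAI) genes dominate
        weights = 1.0 / pais
        values = np.tile(weights[:, None], (1, m)) * rng.uniform(
            0.9, 1.1, size=(n, m)
        )
    else:
        raise ValueError(f"unknown profile {profile!r}")
    frame = pd.DataFrame(np.round(values, 6), index=genes, columns=conditions)
    frame.index.name = "Gene"
    return ExpressionMatrix(frame)


def gen_network(seed: int, genes: list[str], n_edges: int) -> str:
    """STRING-dialect network TSV over ``genes`` with weights in [0, 1]."""
    n = len(genes)
    capacity = n * (n - 1) // 2
    if n_edges > capacity:
        raise ValueError(f"{n_edges} edges exceed simple-graph capacity {capacity}")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    lines = ["node1\tnode2\tcombined_score"]
    for k in sorted(chosen):
        i, j = pairs[k]
        weight = np.round(rng.uniform(0.0, 1.0), 3)
        lines.append(f"{genes[i]}\t{genes[j]}\t{weight:.3f}")
    return "\n".join(lines) + "\n"


def gen_bundle(
    seed: int,
    n_species: int = 50,
    max_depth: int = 8,
    n_genes: int = 100,
    n_conditions: int = 4,
    n_codons: int = 120,
) -> FixtureBundle:
    """A complete, internally consistent fixture bundle.

    CDS pairs are planted per gene with drawn synonymous/nonsynonymous
    counts recorded in the truth map; the homolog CDS lives in one of the
    gene's planted ortholog species (when the gene has any) under the same
    gene label, matching the pipeline's homolog pairing convention.
    """
    rng = np.random.default_rng(seed)
    taxonomy = gen_taxonomy(seed, n_species, max_depth)
    komap, similarity, ortho_truth = gen_ortholog_data(
        seed + 1, taxonomy, n_genes
    )
    target = ortho_truth["target_species"]
    genes = sorted(ortho_truth["genes"])
    cds: list[CodonSequence] = []
    for i, gene in enumerate(genes):
        syn = int(rng.integers(1, 6))
        nonsyn = int(rng.integers(0, 4))
        group = f"K{i:05d}"
        partner_species = sorted(
            sp
            for sp, gid in komap.group_members.get(group, ())
            if sp != target
        )
        short = gene.split(":", 1)[1]
        partner = partner_species[0] if partner_species else "outgrp"
        a, b, counts = gen_codon_pair(
            seed + 100 + i, n_codons, syn, nonsyn, gene_id=short,
            species_a=target, species_b=partner,
        )
        cds.extend([a, b])
        ortho_truth["genes"][gene].update(counts)
    expression = gen_expression(seed + 2, genes, [f"cond{c+1}" for c in range(n_conditions)], "random")
    network_tsv = gen_network(seed + 3, genes, min(3 * n_genes, n_genes * (n_genes - 1) // 2))
    return FixtureBundle(
        target_species=target,
        taxonomy=taxonomy,
        komap=komap,
        similarity=similarity,
        cds=cds,
        expression=expression,
        network_tsv=network_tsv,
        truth=ortho_truth,
    )


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component as plain text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    lineage = outdir / "lineages.tsv"
    with lineage.open("w") as fh:
        for code in sorted(bundle.taxonomy.entries):
            fh.write(f"{code}\t{';'.join(bundle.taxonomy[code].taxa)}\n")
    paths["lineages"] = lineage

    ko = outdir / "ko_groups.tsv"
    with ko.open("w") as fh:
        for group in sorted(bundle.komap.group_members):
            for sp, gene in sorted(bundle.komap.group_members[group]):
                fh.write(f"{group}\t{sp}\t{gene}\n")
    paths["ko"] = ko

    sim = outdir / "similarity.tsv"
    with sim.open("w") as fh:
        fh.write("query_gene\tsubject_gene\tsubject_species\tidentity\tsw_score\n")
        for r in bundle.similarity:
            fh.write(
                f"{r.query_gene}\t{r.subject_gene}\t{r.subject_species}\t"
                f"{r.identity}\t{r.sw_score}\n"
            )
    paths["similarity"] = sim

    fasta = outdir / "cds.fasta"
    with fasta.open("w") as fh:
        for seq in bundle.cds:
            fh.write(f">{seq.species_code}|{seq.gene_id}\n")
            for i in range(0, len(seq.nt), 60):
                fh.write(seq.nt[i : i + 60] + "\n")
    paths["cds"] = fasta

    expr = outdir / "expression.tsv"
    bundle.expression.to_tsv(expr)
    paths["expression"] = expr

    net = outdir / "network.tsv"
    net.write_text(bundle.network_tsv)
    paths["network"] = net

    genelist = outdir / "genes.txt"
    genelist.write_text("\n".join(sorted(bundle.truth["genes"])) + "\n")
    paths["genes"] = genelist

    truth = outdir / "truth.json"
    truth.write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    paths["truth"] = truth
    return paths
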