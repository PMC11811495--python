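# genestrata

Evolutionary index computation for genes and gene networks, fully offline:

- **PAI** — the *phylostratigraphic age index* of a gene: the depth, counted
  from the root of a taxonomy, of the most recent common ancestor of the
  target species and the most distantly related species bearing an ortholog
  of the gene. Smaller PAI = evolutionarily older gene. Orthologs come
  either from curated orthology-group membership (KO-style tables) or from a
  best-similarity table filtered by protein identity and Smith–Waterman
  score thresholds.
- **DI** — the *divergence index*: the mean dN/dS (Ka/Ks) of a gene against
  its homologs in a chosen comparison set, estimated by Nei–Gojobori (1986)
  codon counting with the Jukes–Cantor correction. DI < 1 indicates
  purifying selection, ≈ 1 neutral evolution, > 1 positive selection.
- **TAI / TDI** — condition-wise *transcriptome age / divergence indices*:

      TAI_c = Σ_i ps_i · e_ic / Σ_i e_ic        TDI_c = Σ_i DI_i · e_ic / Σ_i e_ic

  the expression-weighted mean PAI (`ps_i`) or DI of the transcriptome under
  condition `c`, where `e_ic` is the normalised expression of gene `i`.
- **Network annotation** — STRING-dialect edge-list TSV import
  (`node1`/`node2`/`combined_score`, weights in [0, 1]), per-node PAI/DI
  attributes and a monotone stratum color, exported as annotated TSV,
  GraphML and Cytoscape-JSON.

The package is aimed at molecular evolution and phylotranscriptomics work
where gene ages and selection regimes are layered onto expression data and
interaction networks. All inputs are plain text; a seeded simulator
(`genestrata simulate`) generates complete, internally consistent input
bundles with planted ground truth for testing and method exploration.

## Worked example

Simulate a 12-species bundle and run the full pipeline (the simulator
reports the target species, `sp009` here, in `simulate.meta.json`):

```bash
genestrata simulate --seed 42 --n-species 12 --max-depth 6 --n-genes 8 --out sim
genestrata pai   --genes sim/genes.txt --taxonomy sim/lineages.tsv \
                 --target sp009 --method ko --ko sim/ko_groups.tsv --out pai
genestrata di    --genes sim/genes.txt --taxonomy sim/lineages.tsv \
                 --cds sim/cds.fasta --target sp009 \
                 --indices pai/gene_indices.tsv --out di
genestrata phylo --expression sim/expression.tsv \
                 --indices di/gene_indices.tsv --out phylo
```

`di/gene_indices.tsv`:

```
Gene	Label	PAI	DI
sp009:g0000		5	0.941174
sp009:g0001		4	0.0781953
sp009:g0002		5	0.333283
sp009:g0003		6	NA
sp009:g0004		4	0
sp009:g0007		1	0.230908
```

`sp009:g0007` has PAI 1: an ortholog exists in a species that shares only
the taxonomy root with the target, so the gene dates back to the deepest
stratum. `sp009:g0003` has PAI 6 (the full lineage length): its orthologs
are restricted to the target species, the youngest possible stratum; its DI
is `NA` because no homolog falls in the comparison set. DI values below 1
(e.g. 0.078 for `g0001`) reflect predominantly synonymous divergence from
the simulated homolog, i.e. purifying selection.

`phylo/phylo_profile.tsv`:

```
Data	TAI	TDI
cond1	3.89805	0.444803
cond2	4.6933	0.278998
cond3	4.79174	0.351096
cond4	4.64512	0.442252
```

One row per expression condition, in input column order: `cond1` expresses
older (low-PAI) genes relatively more than the other conditions, giving the
lowest transcriptome age index.

`genestrata network --network sim/network.tsv --indices di/gene_indices.tsv
--out net` writes the annotated TSV/GraphML/Cytoscape-JSON triple, with each
gene node colored by its stratum and unscored nodes in neutral white.

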