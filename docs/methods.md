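# Methods

## Phylostratigraphic age index (PAI)

A taxonomy is supplied as lineage paths: for each species code, the ordered
list of taxon names from a shared root down to the terminal species taxon.
Depth is 1-based — the root taxon is depth 1, a lineage of length L ends at
depth L. Lineages are compared as *name-prefix paths*, not rank-aligned
columns: the last common ancestor of two species sits at the length of the
longest common prefix of their paths, so ranks need not be uniform across
species. Whatever stratum system the supplied lineage table encodes (KEGG
taxonomy nodes, curated phylostrata, ...) is taken at face value.

For a gene of target species t with ortholog-bearing species set O (t is
always implicitly in O):

    PAI = min over s in O of lca_depth(lineage(t), lineage(s))

A gene whose orthologs are confined to the target species gets PAI = L, the
youngest stratum. `most_distant_species` records a species attaining the
minimum (lexicographically smallest code on ties, for determinism). Species
codes absent from the taxonomy are skipped with a warning and recorded;
`strict` mode raises instead — partial lineage tables are common, so
robustness is the default.

Two ortholog sources are supported. **KO mode** takes the union of member
species over the gene's orthology groups; paralogs (multiple member genes of
one species) collapse to a single species either way, so the
`paralog_filter` flag cannot change the species set — it exists as an
explicit hook because paralog handling can matter for downstream comparison
sets, and the original semantics of such a filter are genuinely open.
**BST mode** filters a best-similarity table by *inclusive* thresholds
(identity ≥ 0.5 and Smith–Waterman score ≥ 100 by default — inclusivity
makes the printed default usable as an exact boundary), collapses passing
records to their subject-species set, and proceeds identically. The score
default of 100 is a package choice (only the identity default is
standard); both thresholds are echoed into the run metadata.

## Smith–Waterman scorer

A native affine-gap (Gotoh) local aligner backs on-the-fly similarity-table
construction. A gap of length ℓ costs `gap_open + ℓ·gap_extend`, both
non-positive; the score floor is 0. Identity is computed over the aligned
columns of one optimal traceback, preferring diagonal moves on ties — the
convention of similarity tables, not query-length normalisation. Default
schemes: BLOSUM62 with open −10 / extend −1 for proteins, match +1 /
mismatch −1 with linear −1 gaps for nucleotides. The test suite checks the
aligner against an enumeration oracle that maximises over monotone
residue matchings (every gapped local alignment reduces to one, and merging
gaps never lowers an affine score), which keeps the oracle free of dynamic
programming.

## NG86 dN/dS and the divergence index (DI)

dN/dS is estimated by Nei–Gojobori (1986) counting with the Jukes–Cantor
correction. Inputs must be equal-length, in-frame, codon-aligned CDS over
{A,C,G,T} with no internal stops; indel handling and codon-aware alignment
are out of scope, and only the standard genetic code is accepted.

- **Sites.** Each codon position contributes the fraction of its three
  possible changes that preserve the amino acid, averaged over the two
  sequences of a pair. Changes to stop codons count as nonsynonymous, so
  S + N equals the nucleotide length exactly — a convenient conservation
  invariant that the tests assert to 1e-9.
- **Differences.** Codons differing at k positions are scored by averaging
  the synonymous/nonsynonymous step counts over all k! substitution
  orderings; orderings passing through a stop codon are excluded. In the
  rare case where every ordering is blocked, all orderings are used so the
  pair still contributes.
- **Correction.** d = −(3/4)·ln(1 − (4/3)p) applied to pS = Sd/S and
  pN = Nd/N; a proportion at or beyond 3/4 saturates the formula and the
  pair is excluded with the `correction_out_of_range` flag. Note that very
  short pairs saturate easily: a single synonymous difference in a pair
  with S = 1/3 synonymous sites already gives pS = 3.
- **DI.** The DI of a gene is the arithmetic mean of the *defined* ratios
  over its homolog comparisons; with a single homolog it equals that pair's
  dN/dS. Pairs with dS = 0 are excluded and counted rather than treated as
  infinite — this keeps the index finite and matches its reading as an
  average over comparisons — and exclusion counts are reported. With no
  usable pair the DI is undefined (`NA` in output).

The comparison set is chosen either explicitly (species codes) or by a
taxonomic level k: all species sharing at least the first L − k taxa with
the target lineage, so level 1 stays within the genus, level 2 within the
family, and so on. When neither is given the CLI compares against every
species in the taxonomy. The result object and run metadata record the
estimator name (`NG86-JC`) so outputs are not mistaken for
maximum-likelihood (codeml/yn00) values, which will differ numerically.

## TAI / TDI

TAI = Σᵢ psᵢeᵢ / Σᵢeᵢ and TDI = Σᵢ DIᵢeᵢ / Σᵢeᵢ per condition — weighted
means, hence scale-invariant in the expression column and bounded by the
per-gene extremes; uniform expression reduces TAI to the arithmetic mean
PAI exactly. Expression values are expected normalised and non-negative;
no internal normalisation is applied. Genes without a PAI/DI are dropped
with a warning (strict mode errors), and an all-zero condition yields `NA`
cells rather than aborting the profile.

## Network annotation

Edges are undirected (STRING semantics); duplicate (u,v)/(v,u) rows merge
keeping the maximum weight; self-loops are allowed but logged. Confidence
weights must lie in [0, 1]. Node colors come from a fixed 10-entry
colorblind-safe sequential palette mapped monotonically over the observed
stratum range — injective whenever the range fits the palette, evenly
binned otherwise; nodes without a PAI stay neutral white (#FFFFFF).
Annotated TSV export round-trips node/edge/weight sets losslessly; GraphML
and Cytoscape-JSON carry the node attributes. Isolated nodes cannot be
represented in an edge-list TSV, which is the one lossy corner of that
format.

## Synthetic data

The generators produce every pipeline input from an explicit seed
(`numpy.random.default_rng`; no global state), with planted truth:

- **Taxonomy**: a random prefix tree of unique taxon labels with a shared
  root; at least two species reach the maximum depth so the deepest stratum
  is always attainable.
- **Ortholog data**: per gene a true stratum d is drawn from the depths
  attainable against the target lineage; orthologs are placed in exactly
  the species whose LCA depth with the target is ≥ d, so the PAI recovery
  is exact by construction. True orthologs get similarity records with
  identity in [0.55, 0.95] and score in [150, 600] (above the default
  thresholds); decoy records into shallower species get identity in
  [0.05, 0.45] (below the threshold).
- **Codon pairs**: an ancestor of stop-free random codons and a derived
  copy with exact counts of synonymous and nonsynonymous single-nucleotide
  substitutions, at most one per codon and never creating a stop — which
  makes NG86 pathway averaging recover the planted counts exactly.
  Multi-hit codons are exercised by the enumeration oracle instead.
- **Expression**: uniform (the TAI-reduction hook), log-normal random, or
  old-gene-biased profiles.
- **Network**: simple-graph STRING-dialect TSV with uniform weights.

What the simulator does **not** emulate: realistic sequence evolution
(no transition/transversion bias, rate heterogeneity or indels), noisy or
incomplete orthology calls, and missing-data patterns of real annotation
pipelines. Passing recovery tests therefore demonstrates correctness of
the index computations under their own definitions, not robustness to the
error modes of real ortholog detection.

## Problem sizes and numerical choices

The standard recovery bundle uses 50 species, lineage depth ≤ 8, 100 genes,
120 codons per CDS and 4 conditions — large enough that every code path
(all strata, NA cells, excluded pairs) is exercised while the full suite
runs in seconds. Alignment-oracle checks enumerate all sequence pairs of
length ≤ 3 exhaustively plus 500 random pairs of length ≤ 6; codon oracles
use pairs of ≤ 5 codons where pathway enumeration is exact. Floating-point
tolerances: 1e-9 on site conservation, 1e-12 on oracle count equality and
scale invariance. Undefined values are `None` in the API and `NA` in all
tabular output.

## Known limitations

- NG86 is a counting estimator; it ignores transition/transversion bias and
  codon frequencies, and diverges from ML estimates at high divergence.
- PAI inherits every bias of its ortholog source; the package computes the
  index, it does not detect homology beyond the provided tables or the
  built-in aligner.
- The taxonomic-level comparison selector assumes the supplied lineage
  depths are meaningful proxies for genus/family/... levels.
- Developmental-stage significance testing for TAI profiles (flat-line or
  hourglass tests) is out of scope.
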