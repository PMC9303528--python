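# Methods

This note records the models, conventions and numerical choices behind
`phylomode`, in the package's own words. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Homology groups by Markov clustering

Protein similarity from an all-vs-all search (outfmt-6 tabular input,
optionally gzipped) is converted to an undirected weighted graph. The
weighting scheme is a package decision — the transform used with
graph-based clustering of BLAST output in practice — because only the
clustering granularity, not the weighting, is usually reported:

* edge weight for a pair = `-log10(E)` maximized over the two hit
  directions, with E-values floored at `1e-200` (so a reported E of 0
  contributes weight 200) and weights floored at `1e-3` to stay strictly
  positive;
* a self-loop on every node equal to its maximum incident weight (1.0
  for isolated nodes), the standard guard against spurious absorption of
  weakly connected nodes;
* hits are kept at `E ≤ 1e-5` by default; self-hits are tolerated on
  input and overwritten during finalization.

The MCL iteration is the canonical one on a column-stochastic matrix:
expansion (matrix squaring), inflation (entrywise power `I`, default
2.0, then column renormalization), and pruning of entries below `1e-5`
(the per-column maximum is always kept, then columns are renormalized).
Iteration stops when the largest entrywise change drops below `1e-6` or
after 100 rounds; non-convergence is logged and the final matrix is
interpreted anyway. Clusters are attractor systems: attractors are nodes
with diagonal mass above `1e-7`; attractors sharing a column are merged
(union-find); each node follows the attractors in its column, ties going
to the system containing the smallest-index attractor, which makes the
partition deterministic. Group ids are assigned by decreasing cluster
size (ties by smallest member id).

A deliberately naive dense implementation without pruning
(`phylomode.reference.dense_mcl_partition`, clusters read as connected
components of the limit-matrix support) serves as the independent
cross-check; the two share no code.

## Occupancy and reciprocal-best-hit augmentation

Occupancy is a three-state table: *present* (2) requires at least one
genome-derived member, *partial* (1) transcriptome-derived evidence
only, *absent* (0) otherwise. Equating the intermediate (grey) state
with transcriptome-only evidence is a documented convention of this
package: transcriptomes are inherently incomplete samples of a genome,
so their evidence is kept one grade below genome evidence.

Transcriptome membership is attached per database by reciprocal best
hit. The best forward hit is taken **per query and per database
species** — a multi-species database contributes one candidate per
species per query, which is what makes a per-database species cap
meaningful — while the reverse best hit is global over the query
proteome. Ranking uses bitscore, then alignment length, then the
lexicographically smallest subject id (deterministic under tied
floating-point scores); that is why the parsed hit record carries the
alignment-length column. At most 20 distinct transcriptome species are
kept per database, by descending best forward bitscore. The cap ranks
the full candidate set rather than only first-time additions, so
reapplying the same tables is a no-op (idempotence).

The species code of a protein is the prefix of its id before `|`
(configurable delimiter).

## Origin inference (single-gain parsimony)

Presence/absence rows are explained under Dollo parsimony: one gain,
any number of heritable losses. The loss-minimizing gain node is exactly
the LCA of the presence tips, and the implied losses are the maximal
all-absent subtrees below it (each is one heritable event; children of a
multifurcation are counted independently). Partial evidence counts as
presence by default — the point of expanded transcriptome sampling is
precisely to detect presence in lineages without genomes — with a flag
to restrict to genome evidence. All-absent rows are skipped with a
warning. The exhaustive oracle
(`phylomode.reference.dollo_origin_bruteforce`) scans every candidate
gain node covering the presence tips and returns the loss-count
minimizer; the acceptance check enumerates all 4095 non-empty patterns
on a 12-tip restriction of the backbone (tips `GLA` and `MON2` dropped;
any twelve would do — twelve keeps the enumeration at 2¹²−1 patterns).

## Gene trees, rooting and duplications

Gene trees arrive as Newick (leaf convention `SPECIES|protein`,
bootstrap support as internal labels). Rooting places the root on the
branch separating the most outgroup-ward species present, where the
outgroup order is the species tree's root-ward ladder (tips ordered by
divergence depth, ties alphabetic). A multi-leaf outgroup must be
monophyletic in the unrooted sense; otherwise its first leaf is used
with a warning. With no listed outgroup present the tree is
midpoint-rooted (unit lengths assumed where branch lengths are absent).
A tree whose root is not strictly bifurcating is treated as unrooted and
rejected by the duplication mapper — root it first.

Duplications are called by species overlap: an internal node is a
duplication iff at least two child subtrees contain copies of
overlapping species sets. This is chosen over full
duplication-loss reconciliation because it is robust to gene-tree /
species-tree discordance at deep nodes; on the concordant trees the
simulator emits the two criteria coincide, which the LCA-mapping oracle
(`phylomode.reference.lca_mapping_duplications`) verifies. Events map to
the species-tree LCA of the node's descendant species (a single species
maps to its terminal branch); a multifurcation contributes one
conservative event. No support threshold is applied by default
(`min_support = 0`); events below a requested threshold are flagged
`low_support` but retained. Expansion counts at a designated ancestor
include only events mapped exactly to that node, not to descendants.

## Mode classification

For a trait anchored at node *T*: *novel* iff origin = *T*; *coopted*
iff origin is a strict ancestor of *T* and the retention fraction —
genome-evidence present species of the *T* clade divided by the
genome-sequenced species of that clade in the catalog — reaches the
threshold (default 1.0, i.e. retained by every sequenced genome;
configurable because transcriptome-era sampling noise makes exact
saturation brittle on real data); *expanded* iff at least one
duplication maps to a designated expansion node. Novel and coopted are
mutually exclusive; expanded combines with either. An origin younger
than *T* yields the `post_origin` label so such groups are reported
rather than silently dropped. Traits are classified independently; one
group may be coopted for one trait and novel for another. The counting
unit is the HG: when several query genes share a group (tandem
paralogues often do), per-gene tables repeat the group's row with a
`shared_hg` flag, and per-HG summaries count the group once.

## The synthetic generator

Each family draws a gain node (default: uniform over Viridiplantae,
Streptophyta, Embryophyta, Tracheophyta, Euphyllophyta, Spermatophyta),
then walks the subtree losing the family on each branch with probability
`loss_prob` (losses heritable; a family extinct below its gain is
resampled and the resamples reported). Duplications are Bernoulli at
designated surviving nodes (default Euphyllophyta and Spermatophyta at
0.3). Surviving genome tips are *present*; surviving transcriptome tips
(default charophyte, hornwort, fern at detection 0.7) are *partial* with
the detection probability and otherwise absent. Gene trees are emitted
topology-true over the detected tips; a duplication splits the lineage
in two, with remaining deeper planted duplications continuing in the
first copy only so each planted event appears exactly once. Hit tables
realize a planted-block graph: reciprocal within-family hits with
weights `N(50, 5)` (clipped to [5, 200]) written as `E = 10^-w`, plus
Poisson cross-family noise edges (weights near 1). Sequence content is
not simulated — the clustering consumes a graph, and generating hits
directly from family structure keeps the truth ledger exact.

What passing recovery tests shows, and what it does not: the simulator
emulates phylogenetic signal structure (single gains, heritable loss,
planted duplications, partial transcriptome detection, similarity-block
structure with noise), not sequence-level reality. Alignment error,
rate heterogeneity, gene-tree estimation error (an optional concern the
emitted trees deliberately exclude), lateral transfer, gene fusion and
whole-genome duplication are all outside the model, so perfect recovery
here bounds, rather than predicts, performance on real data.

## Problem sizes and numerical conventions

Validation uses sizes chosen to make the checks exhaustive where
exhaustion is feasible and statistically stable where it is not: 20
random graphs of ≤ 30 nodes for the MCL cross-check, 20 planted-block
graphs, all 4095 presence patterns on 12 tips, 100 simulated gene trees
of ≤ 16 leaves for the reconciliation cross-check, 200 lossless and
1000 noisy families for recovery, with the loss grid
{0, 0.05, 0.1, 0.2}. Column sums are held to 1 within 1e-9 after every
normalization; all simulation randomness flows from the single config
seed (emission uses an independent stream derived from it), and
identical seeds yield byte-identical output bundles. Known limitations:
origins can only move tipward under data loss (the LCA of surviving
evidence), so origin recovery degrades monotonically with loss
probability, and duplication events whose basal descendants are lost map
below their true node — both visible in the reported noisy-regime
numbers.
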