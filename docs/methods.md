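# Methods

## Model and procedure

The pipeline treats literature co-mention as a proxy for a probe's
capacity to perturb a protein network. Its unit of analysis is the
*protein swarm*: a connected fragment of at most five proteins cut from
the PPI subgraph induced by one tissue's proteome. Small fragments keep
descriptors local (a hub's neighborhood, a signaling triad) while still
being frequent enough in text to accumulate counts.

1. **Swarm construction.** For each tissue, take the PPI subgraph
   induced by its proteome. Within each connected component, repeatedly
   seed a fragment at the unassigned node with the highest remaining
   degree (ties: lexicographically smallest symbol) and grow it
   breadth-first over unassigned neighbors in lexicographic order until
   five members or exhaustion. Fragments with identical member sets
   arising in different tissues merge into one swarm. The rule is a
   design choice — any deterministic, connected, hub-centered
   fragmentation serves the descriptor role; this one is reproducible to
   the bit. Proteome proteins missing from the network are kept as
   singleton swarms (logged), so descriptors cover the proteome.
   Within-tissue fragments never overlap; an overlapping variant (one
   protein in several swarms of a tissue) would be a different, equally
   defensible reading, and is deliberately not implemented.

2. **Co-citation counting.** A document *hits* a swarm when it mentions
   at least one member (default) or at least *k* members (`min_k` rule).
   Entry (probe, swarm) of the count matrix is the number of documents
   mentioning the probe and hitting the swarm — each document counts at
   most once per pair. Requiring all members co-mentioned would make the
   matrix vanishingly sparse; the one-member rule treats any member
   mention as evidence the fragment is in play, and the rule is
   configurable for sensitivity analysis. Zero rows/columns are retained
   through counting (auditable shape) and dropped only at similarity
   computation, where a zero vector has no direction.

3. **Clustering.** Profiles are compared by cosine similarity (scale-
   free: a heavily-published probe and a rare one with proportional
   profiles are identical), agglomerated by UPGMA on the dissimilarity
   `d = 1 − s`. The linkage is implemented in-package via the
   Lance–Williams average update with an explicit determinism contract:
   exact ties break on the lexicographically smallest pair of cluster
   labels (a cluster labelled by its smallest member). `d = 1 − s`
   rather than an angular or chordal transform keeps merge heights
   readable as similarities. **CCSV** (confidence in cluster similarity
   value) of a cluster is defined as `1 −` the merge dissimilarity at
   its root — the average cosine similarity at which its members were
   last joined; singletons score 1. This is an interpretation: the
   score is reported in the reference analysis on [0, 1] but never
   defined there, and a bootstrap-style confidence is a possible
   alternative reading. Cutting a dendrogram at a CCSV threshold takes
   the maximal subtrees whose root similarity exceeds the threshold;
   because UPGMA heights are monotone, the result is a partition,
   contiguous in leaf order, labelled "first–last" by 1-based leaf
   positions.

4. **Two-round cause–effect analysis.** Round 1 clusters the swarm axis
   and cuts at CCSV > 0.92; clusters containing at least one swarm that
   intersects the *seed proteins* (the receptors of interest — one
   qualifying swarm suffices, no minimum count) are kept, and the union
   of their swarms' members is the seed-receptor interactome. Round 2
   restricts counting to the selected swarms (a pure projection —
   retained counts are unchanged), re-clusters both axes, cuts the probe
   axis at CCSV > 0.76 into disease groups, and reports the swarm axis
   at CCSV > 0.69; the doubly-ordered count matrix is the heatmap
   source. The three thresholds are the reference analysis' printed
   operating points and are plain configuration here.

5. **Overlap and enrichment.** A query protein set against curated
   function gene sets yields a boolean membership grid; *core proteins*
   are those in every selected function (an empty selection returns all
   proteins — vacuous truth, documented). Enrichment is the one-sided
   upper-tail hypergeometric probability computed with exact integer
   arithmetic (`math.comb` accumulated as a rational), controlled by
   Benjamini–Hochberg across functions. The universe defaults to the
   union of gene sets and query and should be overridden with a curated
   background when one exists; membership is annotation membership —
   requiring additionally a physical edge to the query network is left
   to callers composing `direct_interactors` with the grid.

## Synthetic studies and what they show

The generator plants the statistical structure the method assumes:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` / `n_pathways` | 120 / 6 | proteins, assigned round-robin to pathways |
| `p_in` / `p_out` | 0.5 / 0.02 | within/between-pathway PPI edge probability |
| `n_tissues` / `coverage` | 5 / 0.8 | tissues, fraction of proteome each expresses |
| `n_probes` | 40 | disease probes, one pathway each (round-robin) |
| `n_docs` | 5,000 | documents; each picks one probe uniformly |
| `p_assoc` / `p_bg` | 0.6 / 0.02 | per-protein mention rate in/outside the probe's pathway |

Defaults are desk scale: 125 documents per probe give pathway-swarm
counts around 75–124 against background counts below ~12, which is
comfortably above the noise floor for cosine separation — the regime a
corpus of millions of abstracts provides for well-studied diseases. One
designated receptor per pathway (its smallest member symbol) plays the
seed-receptor role in round 1. Each operation draws from a pseudo-random
stream keyed by `(seed, operation name)`, so stages regenerate
independently and serialized outputs are byte-stable.

The generator emulates block-structured co-mention, not literature:
there are no synonyms, no MeSH hierarchy, no citation-age or journal
effects, no multi-probe documents, and mention extraction is assumed
perfect. Passing recovery tests therefore shows the *pipeline* is
correct and well-conditioned under the planted model — not that real
Medline profiles are this clean. Equal probe prevalence and exactly one
pathway per probe are the simplest study conditions; both are
parameters. The generator accepts `p_assoc == p_bg` (the null model used
to verify absence of block structure), although planted studies require
a strict gap.

Under the reference conditions the pipeline recovers the planted probe
blocks with adjusted Rand index 1.0 in all ten seeds tested
(`analysis/03_two_round_pipeline.py`); the acceptance script recomputes
this at every run. The published scale (4,821 probes × 7,371 swarms)
depends on live Medline/HPA/STRING snapshots and is out of scope; the
full-scale configuration is a stress setting only, not a test.

## Printed-table fixtures

`swarmcite/data/` packages machine-readable transcriptions of the
reference study's tables: the 29-column swarm-cluster table (aggregating
to 363 unique proteins), three protein × function overlap grids, the
three-figure function gene sets, and the membrane receptor's printed
partner list. Transcriptions are cell-for-cell faithful, including
typographic case variants (normalized on read) and the partner list's
printed duplicate and self-reference — the reader collapses the
duplicate edge and drops the self-loop, leaving 13 unique symbols and 12
physical partners. One documented divergence: the overlap grid marks
MTOR in both the macrophage-autophagy and polarization columns, while
the corresponding figure's caption names ATG5, AKT1 and PTEN as the only
proteins shared by all three displayed functions; the figure gene-set
fixture follows the figure (its GMT description field records the
difference), and the grid fixture keeps the printed mark.

## Numerical choices

- Cosine values are clamped to [0, 1] against rounding; the similarity
  matrix is symmetrized by averaging and its diagonal pinned to 1.
- UPGMA monotonicity is asserted on every build with a 1e-10 tolerance
  for floating error in the Lance–Williams accumulation.
- CCSV cuts use strict inequality (`ccsv > threshold`), matching the
  "> 0.92"-style operating points; a threshold of 1.0 therefore yields
  all singletons.
- Matrix round-trips are exact for integers and good to 12 significant
  digits for reals (`%.12g`).
- Hypergeometric p-values are exact rationals converted to float once;
  BH uses the step-up with an explicit running minimum, and the rank
  factor `m/rank` so that the largest p is never perturbed.
- Newick branch lengths place each leaf at depth `merge height / 2`,
  making the exported tree ultrametric and the patristic distance equal
  to half the cophenetic distance.

## Limitations

- The fragmentation rule and the CCSV definition are reconstructions of
  under-specified steps; both are stated contracts rather than claims
  about the original implementation.
- Document-level counting ignores mention multiplicity and proximity
  within a document.
- Edge weights are read and preserved but unused downstream (binary
  network); no confidence cutoff is applied.
- Enrichment results are only as meaningful as the chosen universe; the
  automatic default is a convenience, not a recommendation.
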