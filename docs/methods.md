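# Methods

## Scope and model

The package reconstructs, as composable library operations, the desk
analysis used to dissect expression divergence within a plant gene
family: tissue-level meta-expression summaries, Pearson co-expression
groups around bait genes, degenerate-consensus promoter scanning,
group-common/unique cis-element (CRE) set algebra, a distance-based
family phylogeny, and a hub-centred protein-interaction network with a
co-expression overlay. All randomness flows through explicit seeds; no
global RNG state is used anywhere.

## Expression and classification

The compendium is a genes × samples matrix of log2 intensities with a
sample → tissue map. Tissue profiles are arithmetic means per (gene,
tissue). The pattern classifier is deliberately simple and order-free:

* *suppressed* if the maximum tissue mean is below a floor
  (default 6 log2 units — just above the 5-unit lower bound of typical
  array colour scales, where signal is indistinguishable from
  background);
* *tissue-preferential* if `max − median(rest) ≥ δ` (default δ = 2 log2
  units, i.e. a ≥ 4-fold margin over the typical other tissue), with the
  argmax as the preferred tissue;
* *ubiquitous* otherwise.

Max-versus-median was chosen over max-versus-second-best because it is
robust to a single co-high tissue (e.g. root + embryo patterns) and over
mean-of-rest because one suppressed tissue should not inflate the score.
Missing values are disallowed in the matrix; a probe absent from a
platform is an absent row, never zeros.

Pearson correlation is computed by the centred product-moment formula
and raises on a zero-variance vector rather than returning 0 — silently
treating an undefined correlation as "uncorrelated" would corrupt
top-k rankings. Top-k ties break lexicographically on gene id so ranked
lists are reproducible. The qPCR helpers implement
`2^−ΔCt` and `2^−ΔΔCt` exactly as stated.

## Promoter scanning

Consensi use the 15-letter IUPAC alphabet. A consensus of length L is
compiled to a regular expression of per-position character classes
wrapped in a lookahead, so overlapping windows are all reported —
frequency ranking is ill-defined otherwise. Minus-strand matches are
windows whose reverse complement satisfies the consensus, reported at
forward coordinates. Both strands are scanned by default because short
plant CREs are generally treated as orientation-independent; the policy
is configurable. `N` in a *sequence* matches nothing, including the
consensus wildcard `N`: sequence-side `N` is missing data, not a
wildcard. Internally coordinates are 0-based half-open; reports can
translate to the 1-based negative ATG-relative convention (−1 = base
immediately upstream of the start codon).

The incidence matrix stores explicit zero counts with deterministic
row/column order (library order × input order), so set algebra
downstream never depends on dict iteration.

## CRE set algebra

"Common to a group" means present (≥ 1 hit on either strand) in every
member promoter; this is the only reading consistent with arithmetic of
the form |A| − |A∩B| = |unique(A)| across groups of unequal size. A
quorum mode (presence in ⌈q·n⌉ members) is provided for noisier data.
Unique sets are differences of common sets; comparisons are over motif
identities, not positions. For background-contamination analysis the
package provides an analytic joint-presence bound: with an i.i.d.
background at GC fraction g, a consensus with degeneracy D and length L
matches one window with probability ≤ D·p^L (p = max(g/2, (1−g)/2)); a
union bound over windows and strands bounds per-promoter presence, and
independence across promoters bounds joint presence in all n members.

## Phylogeny

Distances are p-distances under complete deletion: every column with a
gap in *any* row is removed before any pair is compared, so all pairs
share one retained-column set. Neighbor-joining follows Saitou–Nei with
the standard Q-criterion; ties break on the lexicographically smallest
taxon-id pair (internal nodes carry the smallest id among their
leaves), making degenerate inputs deterministic. Negative limb-length
estimates are clamped to zero with the deficit transferred to the
sibling limb, preserving the pair's joined path length. The final three
nodes are joined at a degree-3 node by the closed-form three-point
decomposition, so the unrooted tree is binary throughout. On additive
matrices the output path metric reproduces the input exactly (tested to
1e-9 against independently constructed random additive matrices, and
cross-checked topologically against an independent NJ implementation).

Bootstrap resamples alignment columns with replacement; replicate r
draws from an independently spawned seeded stream, so supports are
reproducible and independent of execution order. Support of a split is
the fraction of replicate trees containing that bipartition
(bipartitions canonicalised by smaller side, then lexicographically).

Subgroup assignment gives each taxon the label of the path-length
nearest exemplar and reports per-label monophyly (whether the label's
taxa form one side of a bipartition). Multiple sequence alignment
itself is out of scope: the module consumes pre-aligned FASTA, as
family analyses align with a dedicated external program. Pairwise
percent similarity uses a Needleman–Wunsch global alignment
(BLOSUM62, gap open −10, extend −0.5 by default); similarity counts
aligned columns with a positive substitution score, with gap columns in
the denominator.

## Interaction network

Interaction predictions are consumed as an edge table — re-deriving
interolog predictions is out of scope. The graph is undirected and
simple; duplicate rows collapse into one edge with recorded
multiplicity, self-edges are dropped with a warning. The co-expression
flag is strict (`PCC > 0.5`): an edge at exactly the threshold is not
flagged. Edges with an endpoint missing from the expression matrix (or
with a constant profile) carry `pcc = None` in memory and the explicit
token `NA` in exports — never 0, which would be a valid correlation.
Node functional classes come from a fixed 11-class vocabulary
(redox, amino-acid metabolism, cell cycle/lipid/photosynthesis/
development, DNA synthesis & repair, protein degradation/PTM,
RNA/transcription, signaling, abiotic stress, transport, unknown,
other); unknown labels are rejected with the vocabulary listed. The hub
summary reports both the distinct-partner union and the raw
interaction-row count, since databases quote either figure.

## Synthetic data

The generators define the package's reference study conditions and are
first-class, tested code.

* **Expression**: 6 tissues (leaf, shoot, root, flower, pollen, seed) ×
  3 replicate arrays, 200 genes, intensities clipped to [5, 15] log2
  units to mimic array saturation. Two planted blocks (5 and 6 genes)
  share a tissue-mean profile — seed-preferential and root-preferential
  respectively — plus independent N(0, 0.5²) per-sample noise; the
  planted boost is 4 log2 units. Background genes are ~20%
  tissue-preferential, ~60% ubiquitous, ~20% suppressed. The two block
  tissues are reserved: a background gene boosted in the same tissue
  would duplicate the block's profile shape and make block membership
  unidentifiable, which would turn recovery tests into coin flips for
  reasons unrelated to the method.
* **Promoters**: 2 kb of i.i.d. background. The GC default of 0.44 is a
  free parameter (no authoritative background statistics exist for the
  target promoters); 0.44 is typical of monocot promoter regions and
  makes short AT-rich consensi appear at realistic background rates.
  Group motifs (defaults: seed-associated consensi for group A,
  root/embryo-associated for group B) are inserted once per promoter at
  random non-overlapping positions as concrete realisations of their
  consensus. Accidental hits of the *other* group's motifs are removed
  by resampling only the offending background window — planted sites
  are never edited, preserving planting truth — and the promoter is
  rescanned until clean, so cross-group purity is exact and assertable,
  not merely probable.
* **Proteins**: 20 taxa in 4 clades on a known tree (within-clade
  branches 0.05 expected substitutions/site, clade stems 0.5), evolved
  by Poisson substitution counts per branch with uniform replacement
  over the other 19 amino acids. No indels and no empirical exchange
  matrix: topology-recovery tests need separation, not realism.
* **Interactions**: four hubs with degrees 60/16/3/3, disjoint partner
  sets by default (configurable overlap), classes drawn uniformly from
  the 11-class vocabulary, three partners flagged as functionally
  characterised. A companion expression generator gives the first
  12/3/0/2 partners of the hubs profiles tracking their hub (high PCC)
  and all others independent profiles redrawn until |PCC| < 0.3, so the
  count of >0.5 co-expression calls is exactly the configured one.

What the generators do *not* emulate: probe-level array artefacts and
normalisation, LD-like positional structure or CpG islands in
promoters, indel evolution, rate heterogeneity across protein sites,
and degree distributions of real interactomes. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
generative model, not performance on real compendia.

## Numerical and determinism choices

Identical config + seed gives byte-identical output files (asserted on
manifest checksums). Named RNG streams (`SeedSequence(seed, spawn_key=…)`)
isolate each generator, so adding draws to one artifact never perturbs
another. Pearson values are clipped to [−1, 1] against rounding spill.
The pipeline manifest records a SHA-256 per output so single-stage
re-runs can be verified bit-for-bit.

## Problem sizes used by the acceptance script

Planted-motif recovery uses 200 seeded promoter-set draws; scanner
equivalence uses 1,000 random 2 kb sequences against the 13-motif
library; NJ exactness uses 100 random additive matrices of 4–8 taxa;
subgroup recovery uses the 20-taxon family at 500 bootstrap
replicates; co-expression recovery uses 100 seeded compendia. These
sizes give stable percentages (binomial SE ≤ ~2 points) while keeping a
full run in tens of seconds on one CPU.

## Known limitations

* The common/unique arithmetic of any external motif catalogue is
  reproducible only as set algebra; absolute motif counts depend on the
  catalogue version used upstream and are not desk-reproducible.
* p-distance is not a metric (triangle violations permitted); NJ
  accepts it regardless, as is standard.
* The classifier's δ and floor are heuristics tuned to log2 array
  scales; RNA-seq TPMs would need different defaults.
* `assign_subgroups` assumes exemplars are correctly labelled; a
  misplaced exemplar silently relabels its neighbourhood.
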