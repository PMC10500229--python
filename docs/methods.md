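# Methods

## Model and procedure

The pipeline infers a ferroptosis-related ceRNA network from a
two-group (case vs control) design. Its core assumption is the ceRNA
hypothesis: a lncRNA that competitively binds a miRNA relieves the
repression of that miRNA's mRNA targets, so a functional
lncRNA–miRNA–mRNA axis should show the lncRNA and mRNA moving in the
same direction between conditions and the miRNA in the opposite one.
Candidate axes come purely from interaction-pair evidence plus this
direction rule; no expression-correlation filter is applied, and no
sequence-based target prediction is performed.

A consequence worth noting: because every retained axis pairs a lncRNA
of one direction with a miRNA of the other, the final network always
decomposes into (at least) an "up-lncRNA" and a "down-lncRNA" block —
no direction-consistent path can connect them. Centrality screening
therefore compares nodes across components, which is why harmonic
closeness (well-defined on disconnected graphs, larger for
better-connected hubs) is the default.

### Differential expression

The per-gene test is a pooled-variance two-sample *t*-test on log2
values. This is a deliberate stand-in for moderated-*t*/dispersion
machinery: the package's contribution is downstream of DE calling, and
the stand-in preserves the threshold semantics exactly. An optional
shrinkage of per-gene variances toward their mean (`prior_df` > 0,
default 0) gives a moderated flavour when sample sizes are small.
Count-scale miRNA input can be transformed to log2 counts-per-million
with pseudocount 0.5 (`log2_cpm`).

Class-specific calls (all strict inequalities): mRNA |log2FC| > 1 with
BH-FDR < 0.05; lncRNA |log2FC| > 1 with raw *P* < 0.05; miRNA
|log2FC| > 0.5 with raw *P* < 0.05. The raw-P/FDR asymmetry across
classes is preserved from the protocol this package operationalises,
not rationalised. Zero-variance genes never crash the test: equal
means give *P* = 1, unequal means the smallest positive float (the
difference is exact in the data).

### Network topology

Betweenness is unnormalised shortest-path betweenness on the
undirected, unweighted graph (each unordered pair counted once,
endpoints excluded, credit split among equally short paths); closeness
is harmonic by default with the classic per-component variant behind a
flag. These conventions were chosen because published pivotal-lncRNA
tables print betweenness ≫ 1 and closeness > 1, which the normalised
classic definitions cannot produce. Pivotal lncRNAs are the
intersection of the top-k (default 5) lncRNA sets under the three
metrics; every node tying the k-th value is included, making the
screen deterministic and order-independent.

The scale-free check is the pragmatic log–log regression: OLS of
log10 n(k) on log10 k over occupied degree bins k ≥ 1, reporting
a = 10^intercept, b = slope, and R². It needs at least two distinct
degrees and is not a rigorous maximum-likelihood power-law inference —
by design.

### Enrichment and activation

ORA uses the hypergeometric upper tail P(X ≥ k) with the universe
defaulting to all genes of the relevant DE input (configurable); gene
sets are intersected with the universe before counting, and the
significance flag uses raw *P* < 0.05 while both raw and BH-adjusted
values are reported. The activation score is the simple
direction-consistency form z = (consistent − inconsistent)/√total —
an open approximation to proprietary activation analytics; it is
reported absent (not zero) when no annotated gene overlaps the query.

### qPCR arithmetic

Replicate Ct values are averaged arithmetically (no outlier
rejection); ΔCt = Ct_target − Ct_reference; the calibrator is the
control-group mean ΔCt, so control fold changes have geometric mean 1
exactly, and all outputs are invariant to adding a constant to every
Ct. The group test defaults to Student's equal-variance *t* on the ΔCt
scale (the additive scale where Gaussian errors are natural); flags
switch to Welch and/or the fold-change scale. Amplification-efficiency
correction (Pfaffl) is out of scope.

## The synthetic-data generator

`simulate_dataset` emulates the structure of a mixed
microarray/sequencing study: per-class log2 expression matrices with a
two-group design, a ferroptosis list with roles, one lncRNA–miRNA pair
file and two miRNA-target databases. Expression is Gaussian on the
log2 scale — baseline N(8, 2) per gene, per-observation noise SD 0.5 —
with planted genes shifted by ±`effect_log2fc` in the case group; an
optional negative-binomial count mode (dispersion 0.1) emulates
sequencing-style miRNA input.

Defaults define the reference study conditions: 300 mRNAs / 150
lncRNAs / 100 miRNAs, 20 cases vs 18 controls (the cartilage mRNA
cohort design), effect 2.0 on log2, 30 planted triads, 3 hubs, 10
direction decoys, decoy pair density 0.01, target-database overlap
0.5, 20% of mRNAs ferroptosis-annotated. The gene-class sizes are
desk-scale (hundreds, not genome-wide) so the full pipeline runs in
about a second; the FRG fraction is correspondingly larger than a
genome-wide catalogue's so that the intersection stage stays
populated.

Planted geometry. Hub lncRNAs all share one miRNA pool of size q
(q ≥ 2, about 0.6·triads/hubs), one triad per (hub, miRNA) with a
fresh mRNA each: this mirrors real ceRNA crosstalk, where pivotal
lncRNAs sponge common miRNAs, and it gives the hubs a connected core
whose degree, betweenness and closeness all reflect the planted
multiplicity. Non-hub planted lncRNAs own exactly one private triad,
so hubs hold at least twice the planted triads of any other lncRNA.
Direction decoys are fully wired (pairs in the lncRNA–miRNA file and
in *both* target databases, all members differentially expressed) but
violate only the direction rule, making the direction filter's effect
observable in isolation. Random decoy pairs are added at density 0.01
of all possible pairs per file — the sparsity regime of curated
interaction databases — and the two target databases each contain an
`db_overlap` fraction of shared pairs, so
|db1 ∩ db2|/|db1 ∪ db2| = o/(2 − o).

Seeding: one master seed spawns independent named substreams
(structure, per-class expression, pairs, FRG fill) via
`numpy.random.SeedSequence`, so identical configs give byte-identical
output files.

What the generator does *not* emulate: probe/batch effects,
library-size biases, correlated co-expression modules, realistic
miRNA-target topology (planted miRNAs outside the hub core are
triad-private), or gene-symbol aliasing. Passing tests therefore show
that the pipeline's logic is correct under its stated model, not that
the thresholds are well-calibrated for any particular platform.

## Bundled reference tables

Two small tables from a published OA ferroptosis ceRNA study ship with
the package (`fercerna/data/`): the printed top-5 lncRNA centrality
columns, and the pivotal sub-network reconstructed from the printed
per-lncRNA partner lists. The publication names each pivotal lncRNA's
miRNA partners and target genes but not the individual miRNA→mRNA
assignments, so the bundled triad table is the bipartite completion of
those lists: node identities, per-class node counts (3/7/12) and
lncRNA degrees are exact, while edge and triad totals exceed the
published ones. The gene printed as "SLC38A" (an incomplete symbol) is
stored verbatim.

## Numerical and design choices

- Gene-id matching trims whitespace and case-folds; no alias
  resolution. Original ids are preserved in outputs.
- Target databases are combined by **intersection** by default
  (agreement of both sources); union is available and prominently
  flagged, since "combining" evidence is ambiguous in common usage.
- Axes are deduplicated across database provenance; provenance labels
  are kept for reporting.
- BH adjustment is a single implementation (statsmodels' step-up)
  reused by the DE and enrichment modules; inputs outside (0, 1]
  fail loudly.
- Disconnected graphs: shortest-path metrics are computed per
  component; unreachable pairs contribute nothing.
- The hypergeometric tail uses `sf(k−1)`, so k = 0 gives *P* = 1
  exactly; underflow is clamped into (0, 1].
- `direction` is "up" iff log2FC > 0; axes with any zero log2FC are
  dropped by the direction filter (sign undefined).
- The run manifest hashes analysis parameters only (not file paths),
  so identical inputs and settings give identical reports wherever
  the artifacts are written.

## Problem sizes

The default test and acceptance workloads use the desk-scale defaults
above: 50 seeded pipeline replicates for the hub-recovery property,
100 random graphs (≤ 12 nodes) for the brute-force centrality oracle,
exhaustive draw enumeration up to universe size 12 for ORA, and a
40 + 40-sample null run. Each full pipeline replicate takes well under
a second at these sizes.

## Known limitations

- The DE stand-in is an ordinary (optionally shrunken) *t*-test, not
  limma/edgeR; at very small n its *P*-values are conservative
  relative to moderated tests.
- The activation z is the simple published approximation, not a
  causal-network algorithm.
- Pivotal screening with tie inclusion can admit extra lncRNAs when
  many tie at rank 5 (common in sparse networks); consumers should
  read the centrality table, not just the set.
- The log–log histogram fit is descriptive; it cannot distinguish a
  true power law from other heavy-tailed forms on small networks.
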