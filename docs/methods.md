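# Methods

This note documents the models and procedures implemented in `gutatlas`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## The analysis

The package reconstructs a tissue expression atlas for an insect midgut
divided into four anterior-to-posterior compartments (M1–M4) plus the
remaining carcass. The input is a redundant, Trinity-style de-novo
protein catalog with per-replicate TPM expression; the outputs are a
filtered unigene set, per-compartment expression summaries, soft
expression clusters, term-enrichment tables and gene-family calls for
cytochrome P450s and nutrient transporters. The hindgut is not a
separate label: it is subsumed in M4, as it cannot be dissected apart.

## Unigene reduction

Three filters run in a fixed order:

1. **Longest isoform per gene.** Accessions are parsed with the Trinity
   scheme `DN<d>_c<d>_g<d>_i<d>`; the longest protein per gene is kept.
   Length ties break to the lexicographically smaller isoform id — the
   source tools are silent on ties, and determinism matters more than
   the choice itself. Unparseable accessions are rejected and reported,
   never silently dropped.
2. **Containment dedup.** A protein wholly contained in a longer one
   (exact substring, identity 1.0) is removed. Records are visited
   longest-first with id tie-breaks, so the surviving set is unique and
   independent of input order. No near-identity clustering is done: the
   upstream convention is an identity threshold of 1.0.
3. **Taxon filter.** Genes whose best annotation hit is bacterial or
   plant with e-value strictly below 1e-5 are removed. The removed
   bacterial-like set is returned separately because it is analysed
   (per-gene ANOVA along the gut) before being discarded.

Each filter is idempotent; the pipeline report accounts for every gene
(`genes_in = genes_out + genes_removed` at every stage).

## Expression atlas

* Per-tissue values are arithmetic means over replicates.
* **Presence** is mean TPM strictly greater than 1; a gene at exactly
  1 TPM is absent. Overlap partitions over M1–M4 are the 15 disjoint
  Venn cells; their sum equals the number of genes present anywhere.
* **Top-N groups** (default 500) take the most highly expressed genes
  per compartment, ties at the rank boundary resolving to smaller ids
  so the group at n nests inside the group at n+1.
* **PCA** treats the (tissue, replicate) columns as samples and genes
  as variables, centred and scaled to unit variance (zero-variance
  genes dropped) — the behaviour of the standard R PCA wrappers this
  analysis style comes from.
* **ANOVA** runs per gene across M1–M4 on log2(TPM+1); the log base and
  pseudocount are a design choice (the convention only says
  "log-transformed"), and a pseudocount of 1 handles zeros. The F
  statistic comes from the usual between/within decomposition; a gene
  that is constant everywhere reports F = 0, p = 1 rather than NaN.
  Significance is flagged at Benjamini–Hochberg 0.05 across the tested
  subset, for consistency with the enrichment stage.

## Fuzzy C-means clustering

Mean profiles over M1–M4 (carcass excluded by default — the clusters
describe patterns *along the midgut*; configurable) are z-scored per
gene (sample sd, ddof 1), which removes absolute expression level so
only the relative pattern matters. Genes with zero variance or with
mean TPM ≤ 1 in all selected compartments are excluded and reported.

The clusterer is the standard FCM alternating optimisation with
Euclidean distance: memberships u_ij ∝ (1/d_ij²)^(1/(m−1)) normalised
per gene, centroids the u^m-weighted means, objective
J = Σ u_ij^m d_ij². J is non-increasing across iterations by
construction; convergence is |ΔJ| < 1e-8 or 300 iterations. Distances
below 1e-60 are treated as exact centroid hits (membership 1, split on
ties), which also guards the power against overflow. Initial centroids
are sampled from the data rows; 20 seeded restarts are run and the best
objective kept.

Defaults: c = 8 clusters (the stated cluster count), fuzzifier
m = 1.25. The fuzzifier is not stated anywhere; a small m keeps
memberships decisive, which the α > 0.6 retention cut presumes — with
m near 2 on four-dimensional profiles, few genes would clear 0.6.
Cluster membership is strict: a gene joins a cluster only when
u > α = 0.6, so (α > 0.5) assignments are unique and a gene at exactly
0.6 stays unassigned.

## Term enrichment

For every (gene group, term) pair a contingency table is built by exact
set intersection over the unigene universe (duplicate annotation rows
count once). The over-representation p-value is the hypergeometric
upper tail P(X ≥ k), computed via `scipy.stats.hypergeom.sf` (log-space
internally; stable to ~1e-300) and verified in the test suite against
exact integer enumeration for every table with N ≤ 60.

Terms annotating fewer than 10 universe genes are excluded *before*
testing. The "minimum number of genes = 10" rule is read as a bound on
the term's universe count K (the smallest printed "in transcriptome"
count in the published table is 43, consistent with this reading); a
k-mode bounding the group overlap instead is available via
`min_genes_on="k"`. BH adjustment (statsmodels step-up) runs jointly
across all tests in the run, and rows with adjusted p < 0.001 are
reported, sorted by (group, fdr).

## Similarity search

A self-contained local aligner produces outfmt-6-style hit tables so
the family pipelines run without external binaries; externally produced
BLAST/HMMer tabular files are accepted interchangeably. Alignment is
Smith–Waterman with BLOSUM62 and affine gaps in the BLAST
existence/extension convention (gap of length L costs 11 + L),
executed through Biopython's `PairwiseAligner`; the test suite checks
the scores against an independent pure-DP oracle. Raw scores convert to
bits with fixed Karlin–Altschul constants λ = 0.267, K = 0.041 (the
standard BLOSUM62/11,1 values), and E = m·n·2^(−S′) where n is the
total subject-database length in a search (BLAST's convention) and the
single subject length for a lone pair. Percent identity is counted over
aligned columns; query coverage is the aligned query span over the
query length, applied strictly (> 40%).

For speed, the raw score is computed for every pair and the full
traceback only for pairs under the e-value cap.

## Transmembrane segments

TM helices are called with a Kyte–Doolittle sliding window (window 19,
threshold 1.6): maximal runs of above-threshold windows become
segments, and segments separated by fewer than 5 residues merge. This
caller is deterministic and in-repo; it is *not* claimed to reproduce
TMHMM's HMM output on real proteins, and the window/threshold are
configurable. Unknown residues score 0 with a warning.

## Family annotation

**P450-like:** a unigene is a candidate iff (a) a curated-panel query
hits it at e ≤ 1e-3 with query coverage > 40%, (b) the reciprocal
search of the unigene against the panel passes the same thresholds,
(c) its length is within [150, 650], and (d) it carries the P450
heme-ligand motif F-x-x-G-x-[RH]-x-C-x-G. The motif is an in-repo
stand-in for a Pfam PF00067 scan; an external per-gene domain table is
accepted and takes precedence when provided. Overlapping candidate
fragments are joined when a suffix of one equals a prefix of another
over ≥ 20 residues at 100% identity, repeating to a fixed point;
incompatible joins at the same fragment end are skipped and logged.
Fragment overlap is assessed at the protein level.

**Transporters (AAAP, APC, NSS, POT, SP, SSS, SWEET):** candidates are
classified by a reciprocal family vote over their back-hits against the
pooled two-species panels: (i) the top hit is in family F; (ii) at
least 4 of the top 5 hits are in F, or, when F has fewer than five
members, all of F's members appear in the top 5; (iii) the best percent
identity to an F member is ≥ 20%. "Similarity" is read as percent
identity (that is what tabular hit output carries); a BLOSUM-positive
reading is switchable. Hits order by e-value, ties by bit score then
subject id, so classification is deterministic. Accepted candidates
must then show ≥ 3 predicted TM segments and a length within
[panel min − sd, panel max + sd] (inclusive; sample sd over the pooled
panel, 0 for a single member).

Accepted candidates join the query set and the search iterates to a
fixed point (≤ 5 rounds); earlier calls are never revoked. The TM and
length filters are independent, so their application order does not
change the final call set.

**Expression summary:** per family × tissue, the mean member TPM plus
counts of members strictly above 5 and 50 TPM, after excluding genes
with TPM ≤ 1 in every midgut compartment.

## Synthetic data

The generator emulates the statistical shape the pipeline assumes, not
the biology of any real assembly:

* **Catalog:** Trinity-style ids; a configurable fraction of genes with
  a second, shorter isoform; a fraction emitted as exact substrings of
  earlier genes (to exercise dedup); a contaminant fraction (default
  0.09, a typical symbiont-derived share for such catalogs) whose
  taxon-annotation rows carry bacterial best hits with e < 1e-5.
  Contaminant expression mirrors a symbiont signal (mostly M4-peaked,
  some anterior-restricted) since that is the pattern the bacterial-gene
  ANOVA is meant to detect.
* **Expression:** each gene follows one of eight archetype mean
  profiles over (M1..M4, carcass) — four single-compartment peaks, a
  monotone increase and decrease, an anterior plateau, a mid-gut
  peak — or a flat background (default weights: 0.06 per archetype,
  0.52 flat). Single-compartment archetypes sit below the 1-TPM
  presence threshold outside their compartment, so the overlap
  partition reproduces the mixture of shared and section-specific
  expression seen in compartmentalised guts (roughly 70–80% of present
  genes shared across all four compartments at the defaults).
  Replicate values are the archetype mean times a gene-level lognormal
  amplitude times multiplicative lognormal noise with coefficient of
  variation `noise_cv`. Replicate-level variance is not pinned down by
  the atlas protocol; the default CV of 0.2 is a free choice of a
  plausible bulk-RNA-seq replicate spread and remains configurable.
* **Families:** each planted family descends from a single ancestor —
  either a random protein with a concrete heme-motif instance
  (P450-like) or a helix/linker architecture with k hydrophobic
  (L/I/V/F/A) 21-mers separated by hydrophilic linkers
  (transporter-like). Members are 10%-mutated copies (helix positions
  stay hydrophobic, the motif is conserved) with small C-terminal
  trims; reference-panel members are 22%-mutated, more heavily trimmed
  copies, one full-length member per species so the panel length range
  brackets the planted members. Decoys are i.i.d. draws from SwissProt-
  like background frequencies: unrelated to every ancestor, essentially
  never motif-positive, and far below the homology thresholds.
* **Terms:** each archetype has a planted Pfam-style signature term
  carried by 60% of its genes and 2% of others, plus uniform GO-style
  background terms — so archetype clusters are genuinely enriched and
  the planted (group, term) pairs are known.

What passing tests on this generator do **not** show: recovery under
assembly artefacts (chimeras, fragmented isoforms), realistic codon or
domain architecture, TMHMM-level TM accuracy on real membrane proteins,
or enrichment behaviour under correlated annotations. The generator's
role is to make every contract testable with known ground truth.

## Problem sizes and numerical choices

Stochastic suites run at sizes chosen to make their statistics
meaningful while keeping the whole test run quick: clustering recovery
at 2 000 genes; enrichment null calibration over 100 simulations of
2 000-gene universes (30 terms × 5 random groups); family recovery on
~70-decoy catalogs with 14 planted members across 10 seeds and 20
null-catalog seeds. The Fisher/enumeration and alignment/DP
equivalences are exhaustive at small instance sizes (all tables with
N ≤ 60; all pairs of ≤ 30-residue sequences from a 50-sequence
fixture).

Tolerances: FCM membership row sums to 1 within 1e-9; objective
monotonicity within 1e-10 relative; Fisher vs enumeration within 1e-12
relative. Ties everywhere break lexicographically; all strict-vs-
inclusive boundary decisions (presence > 1, α > 0.6, e < 1e-5,
e ≤ 1e-3, coverage > 40%, length window inclusive, TPM thresholds
strict) are asserted in the unit tests.

## Known limitations

* The aligner reports one best local alignment per pair; suboptimal
  secondary alignments (relevant for real multi-domain proteins) are
  not reported.
* E-values use fixed gapped constants; no composition-based or
  length-corrected adjustment, so absolute e-values on real data will
  differ from BLAST's (rankings agree far more closely).
* The hydropathy TM caller and the heme-motif domain check are
  deliberate stand-ins that favour determinism over sensitivity on
  real sequences; both accept external tool output as a replacement.
* Fuzzy clustering is run on mean profiles, not replicate-aware; the
  cluster count c is taken as given (no validation index is computed).
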