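# Methods

`cemag` classifies metagenome-assembled genomes (MAGs) from anaerobic,
medium-chain-fatty-acid (MCFA) producing bioreactor communities into four
functional groups — *Ferment to Intermediates*, *Intermediate Chain
Elongators*, *Carbohydrate Chain Elongators* and *uninvolved* — from the
presence of fermentation-pathway enzyme homologs detected by translated
homology search. This note documents the models, the numerical choices,
and what the synthetic benchmark does and does not demonstrate.

## Translated homology search

Each protein query is compared against all six reading frames of every
contig (offsets 0–2 on the forward strand and on the reverse complement,
translation table 11; codons containing non-ACGT bases become `X`, stop
codons are kept as `*` and score through the substitution matrix).

Alignment is affine-gap local alignment with BLOSUM62 and gap costs
11 (open) + 1 per residue, the classic gapped-BLAST parameterization.
The aligner is **exact**: a row-vectorized Gotoh dynamic program whose
horizontal-gap state is resolved with a prefix-max scan. The scan is exact
because merging two consecutive horizontal gaps into one is never worse
than re-opening (open cost ≥ 0), so only donors that did not themselves
arrive through a horizontal gap need to be considered. The optimum
therefore always equals the full Smith–Waterman score, which the test
suite verifies against an independent plain-Python dynamic program.

Searching a whole genome with an exact quadratic DP per (query, frame)
is needlessly slow, so frames are handled by size:

* frames where `query_len x frame_len` is at most `exhaustive_cell_limit`
  (300,000 cells by default) are aligned exhaustively;
* larger frames are screened BLAST-style: exact k-mer word seeding
  (word length 4), then for every seeded diagonal the best *ungapped*
  segment score (vectorized Kadane scan). Diagonals scoring at least
  `ungapped_prescreen` (60) are grouped into bands and extended with the
  exact aligner restricted to a padded diagonal window.

The prescreen threshold is chosen from the statistics of the reported
hits, not from the data: with the default filters an alignment must reach
a bit score of roughly `log2(m·n / evalue_max)` ≈ 57 bits, i.e. a raw
score near 137, to pass the E-value cutoff, so a 60-raw-score prescreen
cannot remove any reportable gapless hit. Like BLAST's two-hit/X-drop
heuristics, the screen can in principle miss a heavily gapped homolog
whose every gapless segment scores below the threshold; at the generous
detection thresholds used here this has no practical effect, and the
recovery-curve test measures sensitivity empirically.

Significance uses the Karlin–Altschul convention with the published
gapped BLOSUM62 constants λ = 0.267, K = 0.041 and an uncorrected `m·n`
search space (`n` = total translated length of all six frames).
Composition-based statistics, effective-length corrections and
low-complexity masking are deliberately not reproduced: downstream
analyses consume only presence/absence at generous thresholds
(E < 1e-10, pident > 25 %, qcovhsp > 70 %, all strict inequalities), which
is robust to these refinements. One hit — the highest bit score — is kept
per (query, genome) because features are binary detection.

Coordinates are reported 1-based inclusive on the forward strand with the
frame sign carrying the strand, one unambiguous convention for testing.
Score ties resolve to the first optimal cell in row-major order, with
diagonal moves preferred in traceback.

## Pathway profiles and rule-based classification

A genome's profile is, per pathway, the percentage of its enzyme roster
with at least one retained hit, plus per-enzyme presence bits. "Unique"
enzymes are those occurring in exactly one pathway roster; a separate
percentage over that subset is kept.

Hierarchical clustering of the pathway-percentage matrix uses Euclidean
distance and complete linkage (the defaults of the heatmap tooling this
mirrors); profiles cluster rows only, and the dendrogram is exported as
Newick. Clustering is descriptive; the functional assignment itself is a
per-genome rule with two thresholds, high = 60 % and low = 40 % of a
roster detected (the only quantitative anchors available for the
high/low bands), evaluated in order with first match winning:

1. *Ferment to Intermediates*: any carbohydrate-fermentation pathway
   (homolactic, phosphoketolase, bifid shunt) ≥ high, while lactic-acid
   utilization (LAU) and reverse β-oxidation (RBO) ≤ low.
2. *Intermediate Chain Elongators*: heterolactic pathways ≤ low,
   LAU ≥ high and RBO ≥ high.
3. *Carbohydrate Chain Elongators*: heterolactic pathways and LAU ≤ low,
   RBO ≥ high.
4. otherwise *uninvolved*.

Applying the rule per genome removes the manual cluster-labeling step
while matching the same criteria; the dendrogram remains available.
Ethanol-route chain elongation is not modeled as a separate class.

## Machine-learned classification

The ML route is a pluggable contract (fit / predict_proba / classes_).
The in-repo default is multinomial softmax regression with an L2 penalty
(1e-3), trained by full-batch gradient descent (learning rate 0.5, 500
iterations, features standardized, zero-initialized weights) — chosen to
be dependency-light and bit-deterministic. A LightGBM adapter satisfies
the same contract where that library is installed; the algorithm choice
is a plug-in exactly because gradient boosting was the winner of the
original model sweep on real genomes, which desk-scale synthetic data
cannot meaningfully re-run.

Features are the five pathway percentages plus per-enzyme presence bits.
Evaluation reports stratified cross-validated logloss (natural log,
probabilities clipped to [1e-15, 1-1e-15]), per-class average precision
and one-vs-rest ROC AUC, and the percent logloss improvement over the
class-frequency baseline predictor.

## Dereplication

Genome quality score: `completeness − 0.5·contamination + 5·log10(N50)`
(weights configurable; an optional genome-size term defaults to 0).
ANI is estimated Mash-style: bottom-5000 MinHash sketches of canonical
16-mers (splitmix64 hashing), merged-sketch Jaccard estimate j, and
`ANI = 1 + ln(2j/(1+j))/k`, clamped to [0, 1] with j = 0 reported as the
sentinel 0 ("unrelated"). Clustering is greedy best-first at a 99 % ANI
threshold: genomes sorted by score (ties by id), each joins the first
representative within the threshold or founds a cluster, so
representatives are the highest-scoring member by construction. This is
single-phase (no secondary ANI algorithm, no strain-heterogeneity term):
identical to full pairwise clustering when clusters are well separated,
as they are for near-clone duplicates, and a documented simplification
otherwise.

## Community analyses

Abundance tables are genomes × samples in percent with a per-sample
"unmapped" residual so columns total exactly 100. Presence means
abundance > 0 %; the high-abundance set is ≥ 1 % in at least one sample
anywhere. Per-experiment summaries report min/max/median of the summed
represented abundance.

NMDS minimizes Kruskal stress-1 by alternating isotonic regression of
disparities on configuration distances (disparities rescaled to the
configuration's sum of squares) with a Guttman transform; the first start
is classical metric scaling (PCoA) and the remaining restarts (default 8)
are seeded random configurations, best solution reported. Convergence is
a stress change below 1e-7 or 300 iterations.

PerMANOVA uses the standard pseudo-F from squared distances with
unrestricted label permutations and `p = (1 + #{F_perm ≥ F_obs})/(1 +
n_perm)`. Ordination distances default to Bray–Curtis while the global
and pairwise tests accept any distance matrix (both conventions used by
the original analyses are therefore available). Pairwise contrasts are
Benjamini–Hochberg adjusted (α = 0.05). Groups need at least two samples.

## EtfB function differentiation

EtfB (electron transfer flavoprotein β subunit) homologs partner either
with electron-confurcating lactate dehydrogenase (lactic acid
utilization) or with the electron-bifurcating acyl-CoA dehydrogenase
(chain elongation). Candidates are found by the translated search against
labeled references; overlapping hits at one locus merge (longest
alignment wins). Assignment is nearest-labeled-reference by end-gap-free
global-alignment identity distance (1 − identity, where identity counts
identical aligned pairs over the shorter sequence's length so that
unrelated pairs stay distant), accepting the label
only when the other label's best distance exceeds it by a margin
(default 0.10), otherwise "other" — a deliberately simple, testable
stand-in for a bootstrapped maximum-likelihood phylogeny that captures
the same three-way outcome. Summaries flag genomes carrying both
partnered homolog types.

## Synthetic data

The generator emulates the structure of a multi-bioreactor MAG study:

* **Catalog** — five pathways; LAU has exactly 3 enzymes (ecLDH, EtfA,
  EtfB) and RBO exactly 4 (including acetyl-CoA C-acetyltransferase and
  the electron-bifurcating acyl-CoA dehydrogenase), the biologically
  anchored counts; the three carbohydrate-fermentation rosters default to
  8/9/10 synthetic enzymes — only roster percentages matter downstream,
  so sizes are configurable. Queries are random proteins of 200–500 aa;
  an ACD-partnered EtfB companion protein is attached for the EtfB
  analysis.
* **Genomes** — 4 contigs of 50 kb by default. Assigned pathways embed
  ≥ 80 % of their roster as reverse-translated genes (uniform synonymous
  codons, table 11 — codon bias is irrelevant at amino-acid level),
  mutated by amino-acid substitutions re-encoded to codons so realized
  identity equals the sampled target (default levels 0.70–0.95, all above
  the detection floor) within rounding; unassigned pathways contribute at
  most one stray enzyme (probability 0.5). Placement is random strand and
  frame in i.i.d. random background. Completeness ~ U[75, 100] %,
  contamination ~ U[0, 7.5] %, matching the study's quality bounds.
  Intermediate chain elongators additionally carry the ACD-partnered
  EtfB companion gene, so they hold both EtfB types.
* **Clones** — i.i.d. per-site substitutions at a configured rate
  (nucleotide level, since that is what ANI measures); the dereplication
  fixture plants 23 near-clones (0.5 % divergence ≈ 99.5 % ANI) among 240
  genomes so the 99 % threshold must return exactly 217 representatives.
* **Abundances** — experiment-specific Dirichlet(1) base compositions;
  samples draw Dirichlet(60·base), making within-experiment Bray–Curtis
  dissimilarity smaller than between-experiment in expectation; default
  10 experiments × 8 samples. The unmapped residual is U(5 %, 35 %) per
  sample, spanning the represented fractions a real mapping typically
  leaves.

Everything is deterministic under the configured seed (byte-identical
files on re-run).

What passing these benchmarks shows — and does not. Embedded genes are
substitution-only mutants of the very queries searched for, in i.i.d.
background: detection is therefore easier than for real diverged protein
families with paralogs, low-complexity regions and indels, and the 100 %
rule recovery and ≥ 95 % ML accuracy measure internal consistency of the
pipeline, not expected field performance. Likewise the 240→217
dereplication count verifies the clustering logic on well-separated
clusters, not dRep-equivalence on real strain mixtures.

## Problem sizes and defaults

The pipeline's default end-to-end configuration is desk-scale (3 genomes
per group, 4 experiments × 4 samples) so a full run completes in well
under a minute; the benchmark suite uses the study-scale structures where
they matter (240-genome dereplication cohort, 800 genomes across 20 seeds
for rule recovery, 1000 null simulations × 999 permutations for PerMANOVA
calibration). Optional heatmap/ordination plotting is considered cosmetic
and is not implemented; all plottable tables (profile matrix, Newick
dendrogram, NMDS coordinates) are written as text.

## Known limitations

* Greedy best-first dereplication can differ from full average-linkage
  clustering when true ANI values straddle the threshold.
* The seeded search path inherits BLAST-like heuristic incompleteness
  for heavily gapped homologs (see above); the exhaustive path is exact.
* The EtfB margin rule collapses phylogenetic uncertainty into a single
  identity-distance margin; "other" calls are conservative, not a
  bootstrap support statement.
* PerMANOVA permutations are unrestricted; repeated-measure designs
  (time series within one reactor) would need restricted permutations.
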