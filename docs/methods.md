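# Methods

## Model and assumptions

The package treats a genome as an ordered grid of fixed-size,
non-overlapping windows (default 100 kb, 0-based half-open coordinates).
Each window carries a vector of ChIP-seq read densities (reads/kb, counted
only inside significantly enriched intervals), a mean replication timing
(MRT) value in [0, 1] where 0 is earliest, and derived annotations (genes,
sequence composition). The segmentation assumes that:

* the joint distribution of mark densities is a mixture of a small number
  of states, separable after a per-mark rank transform;
* state identity is meaningful at the window scale — sub-window chromatin
  heterogeneity is averaged away;
* window adjacency along a chromosome is approximately first-order Markov
  in the state labels, which makes block (run) lengths geometric.

## Pipeline stages and numerical choices

**Rank transform.** Ranks with ties assigned the maximum tied rank
(`scipy.stats.rankdata(method="max")`). All correlation analysis is the
Pearson correlation of rank columns; zero-variance columns produce NaN
entries which are reported and excluded pairwise. Mark ordering for display
uses average-linkage hierarchical clustering of the correlation distance
d = 1 − ρ. Any strictly decreasing transform of ρ would give the same
merge order under single linkage but not under average linkage; 1 − ρ is
the conventional choice and is the one implemented.

**PCA.** Columns centered and scaled to unit variance; full SVD; the first
3 components retained by default (configurable). A constant column is an
error naming the offending mark.

**CLARA/PAM.** PAM uses the standard greedy BUILD initializer followed by
best-single-swap SWAP iterations with a 1e-10 improvement threshold; ties
break on the lowest index, making the procedure deterministic given the
subsample. CLARA draws `n_samples = 20` random subsamples of
`sample_size = 500`, runs PAM on each, assigns all points to the nearest
medoids and keeps the lowest-cost solution. With `sample_size >= n` CLARA
reduces exactly to PAM on the full data (tested against brute-force medoid
enumeration on small sets). No internal re-standardization: features are
scaled upstream.

**Cluster-number diagnostics.** W_k is the pooled within-cluster sum of
squared distances to cluster means. The elbow is operationalized as the
argmax of the second difference of **log** W_k: the visual crossover from
fast to weak decrease is a change of relative slope, and on the raw scale
the second difference is dominated by the first split (k = 2) for any
data whose leading principal axis carries most of the between-state
variance. The gap statistic uses B = 50 uniform reference datasets drawn
over the per-dimension observed range (B = 10 in the replicate test suite,
a problem-size choice), clustered with the same CLARA procedure; k is
selected with the one-standard-error rule. On the default synthetic genome
both criteria select k = 4 in 20/20 seeded replicates.

**Silhouettes.** a(i) is the mean distance to the other members of i's
cluster, b(i) the smallest mean distance to another cluster,
s = (b−a)/max(a,b); singleton clusters get s = 0 by convention. Windows
with s < 0 are demoted to the unclassified label D. Computation is chunked
(O(chunk·n) memory) so 2×10^4 windows fit comfortably.

**Labeling.** C1 = cluster with the highest mean rank over the active-mark
set {H3K4me3, H3K27ac, H3K36me3, H3K79me2, RNAPII}; among the remainder C4
has the highest H3K9me3 rank, then C2 the highest H3K27me3 rank; C3 is the
residual cluster. Ties (to 1e-12) break on the lowest cluster index with a
warning. With k = 2 the naming degrades to an active/silent dichotomy.

**Blocks and transition matrix.** Blocks are maximal same-state runs; runs
never span chromosomes or grid gaps. Merged classes "1+2" and "3+4" bridge
exactly one interior D window (two or more break the block; leading and
trailing D windows are trimmed). The transition matrix counts each
adjacent window pair in both orientations (chromosome sense carries no
meaning), giving symmetric counts; rows are normalized by their adjacency
totals, which is row-stochastic by construction. The per-state window-count
denominator is available as an option (`denominator="windows"`) for
comparison with the literal N_ij/n_i estimator. M0/M1 predictions use the
geometric run-length moments mean = w/(1−r), σ = w√r/(1−r).

**U-domain profiles.** A window belongs to a domain if its midpoint lies
inside. Distance to the nearer border is measured from the window midpoint
and floored to 100 kb bins (both halves fold onto one axis). Coverage
fractions are averaged across the domains of a size class
(<0.8, 0.8–1.2, 1.2–1.8, 1.8–3.0 Mb; larger domains are excluded); the
error bar is the across-domain standard deviation divided by √(domains in
the bin). Block-length-vs-MRT profiles sort member windows by block length
and split them into 20 equal-count groups by default.

**Other characterization.** Pairwise MRT comparisons use the two-sided
Wilcoxon rank-sum test in its normal approximation with tie correction.
Genes merge when overlapping in the same orientation (coordinates and
exons union, transitively); the TSS is the start (+) or end − 1 (−) of the
merged gene, and genes are attached to the state of the TSS window.
RPKM = C / ((N/10^6)(L/10^3)) with C exonic reads, N library size, L exon
union length. The "expressed" threshold defaults to RPKM ≥ 1
(configurable); zero-RPKM genes are plotted at log10 RPKM = −3. CpG o/e is
computed after masking CpG islands as (N_CG/(L−l)) / ((N_C/L)(N_G/L)),
where L is the number of unmasked A/C/G/T nucleotides and l the number of
unmasked runs (masked-gap count + 1 for interior gaps), so L − l is the
number of dinucleotide sites; CG pairs spanning a mask boundary are not
counted. Term enrichment uses Fisher's exact test (two-sided,
point-probability method) with Benjamini–Hochberg control at FDR 20% and
the odds ratio for direction.

## The synthetic generator

`synthgenome.default_spec()` encodes the study conditions:

* **State sequence** — independent per-chromosome first-order Markov
  chains started from the stationary distribution, using the published
  K562 transition matrix with rows renormalized to sum exactly to 1
  (printed rows sum to 0.999–1.004). Default size 4 chromosomes × 5000
  windows of 100 kb.
* **Mark emissions** — log-normal per (state, mark):
  density = location · exp(scale·Z) with the location the median in
  reads/kb (background 0.5, log-sd 0.5). Signature marks are at 8×
  background (active set for C1, H3K27me3 for C2, H3K9me3 for C4) with
  secondary signatures at 2–4× (H2AZ/CTCF for C1, Sin3A/H4K20me1 for C2,
  CBX3/H3K9me1 for C4), and active marks *depleted* to 0.5× in the silent
  states; C3 is uniformly unmarked. The depletion matters: with signature
  elevation alone the third discriminating axis sits at the level of the
  noise principal components and the clustering cannot separate C2 from
  C3, unlike real data where 3 components carry ~76% of the variance.
  Densities are quantized to whole reads per window by default so written
  fixtures round-trip exactly (`quantize=False` restores the continuous
  law). Unclassified (D) windows draw a random pair of states and emit
  from the log-space convex combination (weight U(0.3, 0.7)) of their
  parameters, placing them between clusters.
* **MRT** — Beta per state with means 0.20/0.45/0.65/0.85 (C1..C4, D at
  0.55) and concentration 60. These means are configuration, not ground
  truth: they encode the observed early-to-late ordering.
* **U-domains** — alternating gap/domain placement covering 50% of each
  chromosome in expectation; log-normal lengths (median 1 Mb, log-sd 0.45)
  clipped to [0.3, 3] Mb; inside a domain states are laid out by distance
  to the nearer border (1 window of C1, then 2 of C2, 2 of C3, C4 beyond —
  the gradient truncates in small domains) and MRT rises parabolically
  from 0.15 at borders to 0.85 at the center with Gaussian noise 0.03.
* **Genes** — Poisson promoter counts per window at the published
  per-state densities (19.1/7.7/4.1/1.8 per Mb for C1..C4); log-normal
  lengths anchored at the published per-state medians; expressed fractions
  0.75/0.30/0.20/0.10; expressed RPKM ~ 10^N(1, 0.6), silent
  ~ 10^N(−1.5, 0.4). Exons alternate with introns inside the gene body,
  the first exon starting at the TSS.
* **Sequence** — per-window strings from a first-order dinucleotide model
  whose only perturbation is the C→G transition (scaled by the target
  CpG o/e, with compensating redistribution that keeps the stationary base
  composition exact), hitting the GC and CpG o/e targets in expectation
  (GC 0.458/0.455/0.380/0.367 for C1..C4 — the C4 value is the published
  one, the others follow the observed ordering). Sequences default to a
  10 kb representative subsequence per window: composition statistics are
  ratios, so the expectation targets are unaffected while generation stays
  fast.

Fixing the seed fixes every output byte (tested file-by-file).

### What the generator does not emulate

Read-length/fragment structure, mappability, copy-number or diploid
effects, distance-decay correlation of mark signal beyond the state
process, inter-mark correlation beyond state conditioning, isochore-scale
composition gradients, and realistic gene structure (UTRs, alternative
promoters). Passing tests therefore demonstrate the correctness and
internal consistency of the algorithms under the generating model — not
that four states is the right description of any particular real genome.

## Parameter-recovery metric

The end-to-end recovery test computes the adjusted Rand index between
recovered and generating states over windows whose true state is C1–C4.
Mixture (D) windows are excluded from the score because they have no
well-defined true cluster: by construction they interpolate between two
states, and whichever of the two the pipeline picks is not an error.
Including them caps the ARI near 0.87 regardless of algorithm quality;
excluding them the pipeline reaches ≈ 0.98 at the default scale.

## Known limitations

* Silhouette filtering removes only a small fraction of the mixture
  windows (~3% at the defaults): after the rank transform the margin
  between clusters collapses, so interpolated windows land at cluster
  edges with small positive silhouettes rather than between clusters.
  The filter is best understood as removing boundary allocations, not as
  a detector of mixed-state windows.
* The bidirectional adjacency estimator targets the reversibilized
  transition matrix; for a non-reversible generating chain its rows can
  differ from the forward transition probabilities (the default matrix is
  near-reversible, where the distinction is negligible).
* The elbow heuristic is a diagnostic, not an estimator; the log-scale
  second difference is reported together with the full W_k curve.
* Fisher's exact test treats genes as exchangeable; clustered gene
  families inflate enrichment significance.
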