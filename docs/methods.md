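# Methods

## The measurement model

Polysome profiling separates mRNAs on a sucrose gradient by the number of
bound ribosomes. The assay modeled here collects seven fractions — free
RNP, 40S/60S, 80S monosome, and four polysome pools — and sequences the 5ʹ
ends of capped transcripts in each, so that every TSS isoform leaves a
per-fraction tag count vector `C_i1..C_i7`. Each fraction carries an
average ribosome load `r = (0, 0, 1, 2.5, 4.5, 7.5, 12)`; translational
efficiency is ribosomes per mRNA per nt of ORF,

    T_i = Σ_j C_ij,   R_i = Σ_j r_j C_ij,   TE_i = R_i / l_i / T_i.

TE is invariant to uniform count scaling, and for two isoforms of one gene
the ORF length cancels, so a pair's divergence statistic
`log2(TE_A/TE_B)` equals the log2 ratio of their ribosomes-per-mRNA.

Counts from different fractions are made comparable with exogenous
spike-in RNA: clusters with more than 10 tags in every fraction of every
replicate define, per fraction, an upper-quartile normalization factor.
Factors are rescaled by their within-replicate geometric mean so
normalization preserves the overall count scale (TE ratios are scale-free
either way; the absolute scale is a convention).

## TSS discovery

Tags are pooled across the seven fractions per replicate. A position is
signal when its tag count strictly exceeds the local background — the
maximum of (i) the mean tag coverage in a 500-nt centered window and (ii)
the depth-scaled RNA-seq coverage in a strand-oriented [−500, +1500)
window. Strictly-greater comparison prevents calling on flat background
exactly at expectation. Above-background positions at most 20 nt apart
merge into one cluster; the summit is the argmax position, ties breaking
to the most 5ʹ position for determinism. Clusters longer than 100 nt are
refined by raising the background in 0.5·bg steps to at most 3·bg and
re-clustering; the parent summit is always retained in the candidate set
(otherwise a cluster sitting entirely below 1.5·bg would vanish), and
partitions still longer than 100 nt at 3·bg are emitted flagged.

Reproducibility across the two replicates is scored by an irreproducible
discovery rate: matched cluster pairs (≥ 1 nt strand-aware overlap, one
partner per cluster, largest overlap wins) are rank-transformed and fit
with a two-component Gaussian copula mixture by EM (reproducible
component: shared elevated mean, correlation ρ > 0; null: standard
normal; 100-iteration cap, 1e-6 relative log-likelihood tolerance). The
local IDR is the posterior probability of the null component; pairs with
IDR ≤ 0.05 are kept. With fewer than 10 matched pairs the mixture is
unidentifiable and the filter errors, pointing to the fallback mode
(matched in both replicates, combined count above a threshold). The
fallback is also the pipeline default on simulated data, where both
replicates share truth by construction and the mixture's null component is
nearly empty.

Cluster summits are classified against the annotation with precedence
annotated-5ʹUTR > up-1kb > CDS > intron > 3ʹUTR > intergenic, where the
annotated 5ʹUTR spans the most-5ʹ annotated TSS to the most-3ʹ annotated
start codon and up-1kb is the kilobase upstream of that TSS. Only the
first two classes (the gross 5ʹUTR) feed TE analysis. Assignment is by
summit, not span, so every cluster gets a single class.

## Divergence testing

Uncertainty in a pair's log2 TE fold change comes from finite tag counts.
Each bootstrap replicate resamples every fraction at its original depth;
for per-cluster counts this is exactly a multinomial draw over
{cluster A, cluster B, all other tags}, which is how it is implemented
(desk-scale fast, provably equivalent to read-level resampling for these
statistics). Spike normalization is re-applied inside each draw. Draws in
which a resampled isoform total (or ribosome sum) is zero carry no
information about the ratio and are excluded, with their count reported.
The B = 1,000 values are summarized into mean and sd; the p-value is the
two-sided normal tail of the Z-score mean/sd (sd = 0 degenerates to p = 0
or 1). BH adjustment is applied within replicate, across all pairs.

A pair is significant when adjusted p < 0.01 and |FC| > 1.5 hold in both
replicates with the same sign. The empirical FDR permutes the pairing
between replicate-1 and replicate-2 results 100 times, counting pseudo-
pairs that pass the full dual-replicate criterion; FDR is the mean
permuted count over the real count. Note a property of this null: when
most true effects share one direction (longer isoform lower), permuted
pairings frequently remain concordant, so the estimated FDR is
conservative (large) in high-signal-density simulations; it is most
informative when significant pairs are sparse, as in genome-scale data.

## 5ʹUTR reconstruction and features

A mature 5ʹUTR runs from the cluster summit to the main start codon
(exclusive). Splicing events overlapping the span are trichotomized by
percent-spliced-in, computed as retention-supporting over total
informative junction reads with annotation pseudo-reads added first: 10
splice-out reads for annotated-constitutive events, 5 + 5 for annotated-
alternative events, none for novel ones. PSI ≤ 0.1 (inclusive) removes
the region, PSI ≥ 0.9 retains it, and anything between marks the isoform
ambiguous and excludes it from sequence analyses. PSI is interpreted as
intron-retention PSI (splice-in = retention), which makes the pseudo-read
rules self-consistent; this convention choice affects only which column
is called splice-in.

Features of a mature UTR (DNA input is transcribed to the RNA alphabet):

* **uORF** — an upstream AUG with an in-frame stop codon fully inside the
  UTR. Each distinct AUG counts once; nested and overlapping uORFs count
  separately. AUGs whose ORF would run past the main start are uAUGs.
* **uAUG** — an upstream AUG without such a stop; in-frame with the main
  ORF iff its distance to the main AUG is divisible by 3.
* **5ʹ TOP** — cap-site C followed by at least four pyrimidines (no upper
  bound on the run is enforced).
* **Hexamers** — overlapping occurrence counts over the 3,841 hexamers
  that do not contain AUG (AUG-containing hexamers would proxy for
  uORFs/uAUGs).
* **Structure** — minimum free energy (and, with ViennaRNA, ensemble free
  energy) of the first 50 nt (cap window) and of 50-nt sliding windows
  beyond it, default step 1 nt. Stability flags use strict thresholds of
  −30 kcal/mol (cap) and −35 kcal/mol (downstream). These absolute
  thresholds are meaningful on the Turner-parameter scale, so the
  ViennaRNA engine (37 °C) is used when importable; the built-in
  stacking-energy dynamic program is a dependency-free fallback adequate
  for relative comparisons only.

For a pair, the divergent region is the 5ʹ segment of the longer mature
UTR when the shorter is its suffix; pairs whose mature UTRs do not share
their 3ʹ portion (splicing differs downstream) are excluded from
divergent-region analyses. Divergent-region uAUG frames are defined
relative to the main ORF of the full transcript.

## Association analyses

Because longer divergent regions carry more of every feature, every
two-group comparison first equalizes the pair groups' UTR
length-difference histograms (100-nt bins, random down-sampling to
per-bin minima, seeded). Group location differences use the two-sided
Mann–Whitney U test (exact null for groups ≤ 20 without ties); direction
enrichment uses Fisher's exact test on {feature present/absent} ×
{longer-isoform-lower / remaining}; the hexamer scan applies the matched
Mann–Whitney test per AUG-free hexamer (binary presence, ≥ 3 pairs on
each side) with BH correction across tested hexamers. TOP genes are
compared as log2(TE_TOP/TE_nonTOP) against control pairs whose
orientation is randomized, which recenters any global length bias at
zero.

## Quantitative models

The per-pair response is the replicate-mean log2 TE fold change; the
predictors are long-minus-short feature differences. Models are additive
multivariate adaptive regression splines: reflected hinge pairs
max(0, x−t)/max(0, t−x) with candidate knots at observed values, greedy
forward selection stopping at relative RSS improvement < 0.001 or
min(21, 2p+1) terms, then backward pruning to the minimum of
GCV = (RSS/n)/(1 − C/n)² with C = k + (k−1), i.e. penalty 2. Exhaustive
candidate search (no fast heuristics). Per-feature individual
contribution is the training variance explained by a single-feature
model; cumulative contributions add features in descending individual
order; deltas are successive gains. Held-out performance is repeated
10-fold cross-validation (default 100 repeats) with variance explained
pooled over folds against the overall response mean. Plain training R²
is reported; the GCV score accompanies every model.

## The synthetic-data generator

`simulate_dataset` emulates the study's data-generating process with full
ground truth:

* **Genes.** Default 100 genes on both strands; TSS count per gene 1/2/3
  with probabilities 0.58/0.32/0.10 (≈ 42% multi-TSS genes, matching the
  regime the pipeline presumes). Shared 5ʹUTR block 60–300 nt, each
  additional (divergent) block 80–400 nt, ORF 300–1,800 nt, 200-nt 3ʹUTR.
  The proximal isoform is the annotated transcript, so distal TSSs fall
  in the up-1kb class.
* **Loads and tags.** Per isoform a true mean ribosome load λ (gene base
  uniform on 0.5–9, multiplied by feature penalties); per mRNA copy a
  load K ~ min(Poisson(λ), 12) binned to fractions as K=0 → free/40S-60S
  (split evenly; both weight 0), 1 → 80S, {2,3} → first polysome
  fraction, {4,5}, {6..9}, ≥10 → heaviest. This map is the simulator's
  bridge to the downstream r weights and is configurable. Tag positions
  scatter geometrically downstream of the TSS (mean 2 nt). Isoform
  abundance is log-normal (median 300 copies), drawn independently per
  replicate around shared truth so the two replicates differ only by
  sampling noise.
* **Background and coverage.** Background tags are uniform within gene
  spans (0.01 /nt/fraction) — recapped degradation of expressed genes —
  matching the local-expectation background model the caller assumes.
  RNA-seq coverage is emitted in tag-equivalent units (default 5 /nt,
  `depth_norm` = 1) spanning each gene ± the expression-window extent, so
  the expression floor is flat across every in-gene window; real data
  would need an explicit depth-normalization ratio here.
* **Spike-ins.** Seven positive distortion factors per replicate multiply
  per-fraction counts before emission; 60 spike clusters (log-normal
  base abundance, Poisson counts) scale with the same factors, so the
  normalization stage can recover them; a fraction of clusters falls
  below the >10-tag filter by construction.
* **5ʹUTR sequences.** Background sequence is generated free of AUG *and*
  of stop trigrams in every frame, so planted features round-trip
  exactly: a planted bare AUG stays a uAUG instead of gaining an
  accidental in-frame stop, and a planted uORF's stop is the only stop in
  sight. Concatenated blocks always end in C, which no AUG/stop trigram
  can span, so block junctions are artifact-free. Planted features:
  uORFs (geometric dose), in/out-of-frame uAUGs (frame fixed against the
  actual downstream sequence; a uAUG whose every frame meets a downstream
  stop is dropped, since it would truly be a uORF), a TOP motif at the
  cap, a 14-bp GC hairpin inside the cap window, and an effect hexamer
  (AAUCCC). A TOP motif buried mid-UTR of a longer isoform is not a cap
  TOP and neither counts as a feature of, nor penalizes, that isoform.
* **Effect sizes.** Multiplicative penalties on λ: uORF 0.55 (per copy),
  out-of-frame uAUG 0.70, in-frame uAUG 1.0 (no effect), TOP 0.60,
  cap hairpin 0.65, effect hexamer 0.40. The hexamer penalty is set at
  the strong end (2.5-fold, within the range reporter assays show for
  validated repressive motifs) so that a single planted motif remains
  detectable in a ~200-pair desk-scale scan against the variance the
  other planted features contribute; weaker motif effects are only
  resolvable at genome scale.
* **Splicing.** 15% of genes carry one intron in the shared UTR block,
  constitutively removed / retained / ambiguous with true PSI 0.02 /
  0.97 / 0.5 and junction reads binomial at depth 40. Ambiguous events
  exclude their isoforms from sequence analyses, as in the pipeline.

What the generator does **not** emulate: read-level errors and alignment
artifacts, mappability, promoter shape heterogeneity (all isoform tags
scatter identically), internal degradation peaks with capped-like signal,
correlated feature co-occurrence, translational heterogeneity beyond a
single Poisson load per isoform, and cell-type effects. Passing tests
therefore demonstrate the correctness and statistical behavior of the
pipeline under its own assumptions, not robustness to every artifact of
real libraries.

## Problem sizes and numerical choices

The test suite runs the full chain at 30–500 genes; the end-to-end
association study uses 500 genes (≈ 350 analyzable pairs), B = 1,000
bootstrap replicates, folding-window step 10 nt, and 50 label shuffles —
sizes chosen to exercise every stage at meaningful power on a single CPU.
`cross_validate` defaults to 100 repeats but is exercised at 3–20 repeats
in tests. Ties in Mann–Whitney tests switch the exact null to the
tie-corrected normal approximation. Degenerate inputs error loudly
rather than silently: zero-total isoforms are dropped with a reason,
empty spike filters and degenerate Fisher margins raise, and the IDR
filter refuses unidentifiable fits.

## Known limitations

* The copula-mixture IDR is a from-scratch EM implementation; it matches
  the standard construction but is validated against simulated mixtures,
  not against an external package's output on real peak sets.
* The label-permutation FDR is conservative when significant pairs are
  dense and directionally aligned (see above).
* The built-in folding engine's energies are not on the kcal/mol scale;
  absolute stability thresholds require ViennaRNA.
* Hexamer association uses binary presence, not dose, and the scan's
  power at desk scale is limited by the number of pairs, not by depth.
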