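# isote

**Isoform-specific translational efficiency of alternative-TSS mRNAs from
polysome-fractionated 5ʹ end sequencing.**

Transcription initiated at alternative transcription start sites (TSSs)
produces mRNA isoforms that share a coding sequence but differ in their
5ʹUTRs, and therefore in the cis-elements — upstream ORFs, upstream AUGs,
5ʹ-terminal oligopyrimidine (TOP) tracts, cap-proximal RNA structure,
short sequence motifs — that control translation initiation. `isote`
implements the computational side of an assay that measures this directly:
mRNAs are separated on a sucrose gradient into seven fractions by ribosome
load, the 5ʹ ends of capped transcripts in each fraction are sequenced, and
each TSS isoform's translational efficiency is read off from how its tags
distribute across the gradient.

The package covers the full analysis chain:

1. **TSS discovery** — cluster 5ʹ tag positions against a local-tag and
   RNA-seq-expression background (20-nt merge rule, stepwise background
   refinement of wide clusters to ≤ 100 nt), filter for cross-replicate
   reproducibility (copula-mixture IDR or a count-threshold fallback), and
   assign clusters to gene regions; only clusters in the *gross 5ʹUTR*
   (annotated 5ʹUTR + 1 kb upstream of the annotated TSS) enter TE analysis.
2. **Quantification** — spike-in upper-quartile normalization across
   fractions, then per isoform *i*:
   `T_i = Σ_j C_ij`, `R_i = Σ_j r_j · C_ij`, `TE_i = R_i / l_i / T_i`,
   with fraction weights `r = (0, 0, 1, 2.5, 4.5, 7.5, 12)` ribosomes/mRNA
   and `l_i` the ORF length.
3. **Divergence testing** — per within-gene isoform pair, a per-fraction
   multinomial bootstrap (B = 1,000) of the log2 TE fold change; normal
   p-value from the Z-score of the bootstrap mean, Benjamini–Hochberg
   adjustment, significance requiring adjusted p < 0.01 and |FC| > 1.5 in
   *both* replicates with agreeing sign, and an empirical FDR from
   label permutation between replicates.
4. **5ʹUTR features** — mature UTR reconstruction under percent-spliced-in
   (PSI) rules with annotation pseudo-reads, then uORF/uAUG counting, TOP
   detection, AUG-free hexamer counting (3,841 motifs), and MFE/EFE folding
   of 50-nt windows (ViennaRNA or a built-in simplified engine).
5. **Association & modeling** — length-difference-matched Mann–Whitney
   comparisons, Fisher enrichment, a per-hexamer scan under BH correction,
   and additive MARS models (degree 1, GCV penalty 2) with per-feature
   variance decomposition and repeated 10-fold cross-validation.

A first-class synthetic-data generator (`isote.simulate`) emulates the
whole assay — truncated-Poisson ribosome loads binned into fractions,
geometric 5ʹ-end scatter, background tags, spike-in distortions, splice
junctions with known PSI, and 5ʹUTRs with planted features — so every stage
is testable against ground truth without any sequencing data.

## Worked example

```python
import numpy as np
from isote import isoform_te, bootstrap_pair, z_pvalue

heavy = np.array([0, 0, 0, 0, 0, 0, 100.0])   # tags all in the heaviest fraction
flat  = np.full(7, 100.0)
isoform_te(heavy, orf_length=900).ribosomes_per_mrna   # 12.0
isoform_te(flat, orf_length=900).ribosomes_per_mrna    # 3.929  (= 27.5/7)

counts_a = np.array([20, 10, 50, 100, 200, 400, 300.0])
counts_b = np.array([50, 40, 400, 200, 80, 30, 10.0])
s = bootstrap_pair(counts_a, counts_b, np.full(7, 10_000.0), n_boot=1000, rng=0)
(s.mean, s.sd, z_pvalue(s.mean, s.sd))
# (1.867, 0.055, 7.6e-249)
```

The bootstrap mean of 1.87 log2 units says isoform A carries about 3.6×
more ribosomes per mRNA than isoform B; the tiny p-value reflects the deep
counts. Running the full chain on a simulated study
(`examples/06_association.py`) prints:

```
isoform pairs with resolved divergent regions: 77
significant TE divergence: 50 pairs (label-permutation FDR = 0.68)
uORF in divergent region: median log2FC -1.66 vs -0.52 without (Mann-Whitney p = 4e-07)
uORF dose response (stratum: median log2FC): {'0': -0.51, '1': -1.58, '2': -1.78, '3+': -3.34}
```

i.e. isoform pairs whose longer 5ʹUTR gained uORFs show a strong, dose-
dependent TE decrease of the longer isoform — the planted ground truth.
Each script in `examples/` demonstrates one capability end to end.

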