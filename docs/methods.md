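# Methods

## Scientific question and overall design

Transcription factors (TFs) that drive tissue differentiation carry
bivalent or PRC2 (H3K27me3) chromatin marks at their promoters in
embryonic stem cells and become strongly expressed upon differentiation.
If blocks in differentiation contribute to carcinogenesis, these TFs
should be preferentially silenced in tumours of the corresponding tissue,
and the silencing should be attributable to an in-cis molecular event:
promoter hypermethylation, copy-number loss, or inactivating mutation.

The pipeline tests this in three stages:

1. **Upregulation relative to the stem-cell ground state.** Array-style
   expression for hESCs and normal tissues is quantile normalized; for
   each tissue a moderated-t table against the hESC samples is computed
   and bivalent/PRC2-marked TFs with BH-adjusted p < 0.05 and positive t
   are retained. Tissue-exclusive and common sets are derived by set
   algebra; the up/down skew of the TF set is compared against 1000
   randomly drawn genes with a one-tailed Fisher exact test.
2. **Preferential silencing in cancer.** RNA-seq counts of the matched
   tumour cohort are log2(count+1) regularized after removing all-zero
   and zero-variance genes, and a tumour-versus-normal moderated-t table
   is computed. Each tissue's upregulated TFs (restricted to those
   expressed above the cohort median in the normal-adjacent samples) are
   compared with a 1:1 expression-matched control set of non-TF,
   non-housekeeping genes via a one-tailed rank-sum test on the
   t-statistics. Silenced TFs are the upregulated TFs that are also
   significantly downregulated in the cancer (BH p < 0.05, t < 0).
3. **Per-tumour mechanism attribution.** Expression of each TF in each
   tumour is standardised against the normal-adjacent samples
   (Z = (X − μ)/σ, σ with n−1 denominator); Z < −2 calls
   underexpression. Among a TF's underexpressed tumours, three channels
   are scored: segment value < −0.35 (copy-number loss), promoter
   Δβ > 0.3 (hypermethylation; a relaxed Δβ > 0.1 regime is kept for
   exclusivity analyses), and any nonsense/missense/deletion mutation
   record (multiple hits in one gene and tumour count once). All four
   thresholds are strict inequalities: a value exactly at a threshold
   never produces a call.

Per-TF mechanism frequencies (computed only over that TF's underexpressed
tumours, channel-wise over non-missing data) feed four higher-level
analyses: a per-cancer rank-sum comparison of the silenced TFs against
all underexpressed genes per channel, combined across cancer types with
Fisher's method; a null-draw calibration of hypermethylation event counts
(TF-set observed count versus the 2.5–97.5 percentile interval of
repeated draws from the underexpressed pool); tertile and per-TF
mutual-exclusivity tests between hypermethylation and loss; and pairwise
cross-cancer concordance (squared Pearson correlation) of the frequency
vectors, with a paired one-tailed signed-rank test that the
hypermethylation R² exceeds the copy-number R².

## The moderated t-statistic

Differential expression and differential methylation both use an
empirical-Bayes moderated t. The hierarchical model treats each gene's
sample variance as s²_g | σ²_g ~ σ²_g χ²_d / d with residual degrees of
freedom d, and places a scaled inverse-chi-square prior on σ²_g with
prior degrees of freedom d₀ and prior variance s₀². The posterior
variance is the precision-weighted blend

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d)

and t̃_g = (mean_A − mean_B) / (s̃_g √(1/n_A + 1/n_B)) is referred to a t
distribution with d₀ + d degrees of freedom.

(d₀, s₀²) are estimated by the method of moments on z_g = log s²_g: with
e_g = z_g − ψ(d/2) + log(d/2), the model implies
Var(e_g) = ψ′(d/2) + ψ′(d₀/2) and
E(e_g) = log s₀² + log(d₀/2) − ψ(d₀/2), where ψ and ψ′ are the digamma
and trigamma functions. The trigamma equation is inverted by a monotone
Newton iteration with a bisection fallback (tolerance 1e-8). If the
observed dispersion of e_g does not exceed ψ′(d/2), the variances show no
excess heterogeneity, d₀ is set to infinity and s₀² to the mean variance
(complete shrinkage; the t reference becomes normal). With d₀ = 0 the
statistic reduces exactly to the classical pooled t — both limits are
tested, and the implementation is cross-checked against Bioconductor
limma on a shared fixture.

## Other statistical components

- **Rank-sum test**: exact by enumeration of all C(n, n_x) rank
  assignments of the pooled mid-ranks when the pooled size is ≤ 12
  (valid under ties); otherwise the normal approximation with tie and
  continuity corrections. Directions are always explicit parameters.
- **One-tailed Fisher exact test**: hypergeometric upper-tail probability
  of the enrichment cell.
- **Fisher's combined probability**: −2 Σ ln p against χ² with 2k df;
  p = 0 inputs are floored at the smallest positive float with a warning
  rather than propagated as −∞.
- **Multiple testing**: Benjamini–Hochberg step-up. The significance rule
  for "significantly differentially expressed" is BH-adjusted p < 0.05;
  the α is configurable.

## Promoter methylation assignment

Each gene receives one beta value per sample by the recursive promoter
model: the unweighted mean over TSS200 probes if any exist, else
first-exon probes, else TSS1500 probes; gene-body and 3'UTR probes are
never used. The region class is decided gene-wise from the manifest, not
per sample; a probe annotated to several region groups for one gene
counts once at its highest-priority group (prevents double counting).
Per-sample missing betas are averaged over the remaining probes of the
selected class; a cell is missing only when all probes are missing.
Equivalence with a brute-force per-gene enumeration oracle is asserted on
100 randomized manifests.

## Copy-number and mutation handling

SEG input is assumed 1-based inclusive (the common dialect) and converted
once, in the reader, to the package-wide 0-based half-open convention.
Genes take the value of the overlapping segment with the largest overlap;
ties go to the segment with the smaller start; genes without overlap are
missing and never produce calls. The MAF classification dictionary
(nonsense, missense, frameshift/in-frame deletion → inactivating;
everything else → Other) ships as a YAML config so other dialects can be
mapped without code changes.

## Mechanism classes

A silenced TF is classified from its frequencies: DNAm-dominant when
f_hyper ≥ 0.2 and f_loss < 0.1; CNV-dominant symmetrically; Both when
both reach 0.2; Neither otherwise. The 0.2/0.1 cutoffs are this package's
own operationalisation of the qualitative three-class description of
frequency scatterplots, and are exposed as parameters. Frequencies between
the two cutoffs fall to Neither by design (an ambiguous TF is not forced
into a dominant class).

## The synthetic cohort generator

The generator emulates the statistical structure every stage assumes, at
a scale that runs end to end in well under a minute on one CPU:

- **Scale** (defaults): 2000 genes (200 TFs, 150 housekeeping), 4
  tissues mapped to 6 cancer types (2+2+1+1, mirroring two lung-like and
  two kidney-like cohorts), 20 hESC + 4 compendium normals per tissue,
  20 normal-adjacent + 60 tumours per cancer cohort.
- **Expression**: gene baselines ~ N(7, 1.5²) on the log2 scale with
  sample noise sd 0.5. Developmental TFs (60% of TFs; each up in a given
  tissue with probability 0.55) gain +2 log2 units in their normal
  tissues relative to hESC — the regime in which most upregulated TFs
  show at least twofold changes. Housekeeping genes keep a constant mean
  everywhere. Compendium samples are synthesized directly on the log2
  scale; tumour cohorts are written as counts (round(2^x − 1)) so the
  log2-regularization path is exercised.
- **Silencing**: 55% of developmental TFs are silenced, in every cancer
  whose tissue they are up in, with a −1.5 log2 shift planted in 60% of
  tumours. Mechanism per TF: DNAm 50%, CNV 25%, Both 12.5%, Neither
  12.5% (Mutation available, default share 0) — i.e. the 20/10/5/5
  composition of a 40-TF silenced set. "Both" TFs plant hypermethylation
  and loss in disjoint tumour halves by default, emulating the observed
  mutual exclusivity.
- **Methylation**: normal promoter betas ~ Beta(4,16) (mean 0.2);
  DNAm-planted tumours gain Δβ = 0.4. Probe-level betas add truncated
  Gaussian noise (sd 0.05) and are distributed over region classes so
  that some genes lack TSS200 probes (exercising the recursive
  fallback); type-1/type-2 chemistry is not modelled and betas are
  generated pre-normalized.
- **Copy number**: per-tumour chromosome-spanning background segments
  with segval ~ N(0, 0.05); planted focal losses at −0.7 partition the
  background segment around the TF locus.
- **Background silenced genes**: 15% of non-TF genes per cancer are
  underexpressed with mechanism mix DNAm 5% / CNV 55% / Mutation 10% /
  Neither 30%, so copy-number loss and mutation are clearly at least as
  frequent among background underexpressed genes as among the TFs while
  hypermethylation is much rarer — the regime in which the epigenetic
  channel, and only that channel, distinguishes the TFs in the
  meta-analysis.
- **Cross-cancer consistency**: the per-(gene, cancer) fraction of
  silenced tumours that actually receive the planted event is drawn
  afresh per cancer — U(0.7, 1.0) for hypermethylation, U(0.3, 1.0) for
  loss — making copy-number frequencies deliberately less reproducible
  across cancer types than methylation frequencies, as focal genomic
  instability is cancer-type-specific while the epigenetic silencing
  program tracks the TF.

All randomness flows from a single integer seed; a fixed config is
byte-reproducible across processes. The ground truth (per-TF mechanism,
per-tumour planted events) is retained for recovery scoring
(sensitivity, FDR, and a mechanism confusion matrix in which planted
Mutation and Neither both map to the expected class Neither, since
neither leaves a DNAm/CNV footprint).

### What the generator does not emulate

Realistic chromosomal architecture, subclonality, tumour purity, age
effects, field defects in normal-adjacent tissue, probe chemistry biases,
and trans-acting silencing. Passing recovery tests therefore demonstrates
the correctness and calibration of the inference machinery under the
assumed generative structure, not performance on real cohorts, where
effect sizes are smaller, confounding is real, and the QC flag (below)
matters.

## Numerical and degenerate-input choices

- Quantile normalization maps each column onto the row-wise mean of the
  column-sorted matrix; tied entries receive the mean of the reference
  quantiles their positions span. This makes the procedure idempotent,
  but exact histogram equality across columns holds only for tie-free
  columns.
- log2 regularization uses offset +1 (keeps zeros at zero); the
  "no variation" filter is sample variance exactly 0 on the raw scale.
- The SVD QC computes right singular vectors of the row-centred matrix
  and flags the dataset when the top component's two-sided rank-sum
  association with phenotype has p > α (k = 5 components reported,
  α = 0.05) — the signature of dominant confounding variation.
- Z-scores drop genes with zero normal-sample variance (logged count);
  missing channel data excludes a gene from that channel only, never
  row-wise.
- Control matching is greedy 1:1 nearest-neighbour on mean
  normal-adjacent log2 expression, TFs processed in decreasing
  expression order, distance ties broken by lexicographic gene ID —
  fully deterministic. A pooled (non-1:1) matching mode was considered
  and rejected in favour of the simpler, audit-friendly 1:1 map.
- Tertile boundaries keep tied frequency values in the same tertile, so
  a tied value never straddles a boundary.
- Degenerate exclusivity inputs (an empty loss or no-loss group, fewer
  than 6 TFs, zero-variance frequency vectors) are skipped with log
  entries rather than forced.

## Known limitations

The moderated t covers only the two-group comparison (no general linear
models, array weights, or trend/robust variants). Promoter methylation
uses manifest region classes, not distances from raw coordinates.
Mechanism attribution is associative by construction: a hypermethylated,
underexpressed TF is not thereby shown to be silenced *by* methylation.
The Z < −2 rule is one-tailed by fiat of its definition; its nominal
two-tailed tail probability (~0.046) is not reinterpreted.
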