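# Methods

This note records the statistical model behind `msreseq`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Assay model

HpaII digests unmethylated CCGG; a methylated central CpG protects the
motif. Sequencing depth of intact fragments at a catalogued CCGG site is
therefore an increasing function of the site's methylation probability
θ. The package treats the scoring step abstractly: any per-site,
per-sample score on a roughly Gaussian log2 scale is accepted. The
built-in stand-in is

    score_ij = log2(CPM_ij + 0.5),  CPM_ij = depth_ij / Σ_i depth_ij × 10^6.

CPM normalisation makes scores invariant to library size (multiplying a
sample's depths by a constant leaves its column unchanged); the 0.5
pseudo-count keeps retained-but-shallow sites finite. The stand-in is
deliberately swappable (`ScoreMatrix.from_tsv`) because proprietary
scoring pipelines for this assay are not public. No model of partial
digestion or per-allele methylation is attempted: the score is a site
summary, not a genotype.

Sites are kept only if covered at `min_depth` (default 1) in **every**
sample of every condition, mirroring the common-site intersection such
studies report. The threshold is configurable because presence/absence
versus depth-threshold filtering is an assay-pipeline detail that
varies between platforms; the retained count is always reported.

## Per-site test

For one site with scores y over n samples in two groups, the working
model is Gaussian with a one-way contrast. With RSS0 the residual sum
of squares under a common mean and RSS1 under group means, the LRT
statistic is

    Λ = n · ln((RSS0 + ε) / (RSS1 + ε)),  ε = 10⁻⁸,

where ε is a variance floor so constant (zero-variance) sites return
Λ = 0 instead of 0/0. Λ is a monotone transform of the classical F
statistic, F = (n − 2)(e^{Λ/n} − 1), and two null distributions are
offered:

- `p_method="exact"` (default): `p = P(F(1, n−2) ≥ F)`, the exact
  finite-sample null of the working model. At n = 12 this is the
  calibrated choice: in the null simulation its p-values are uniform
  (KS distance ≈ 0.01 at 5,000 sites).
- `p_method="chi2"`: the asymptotic χ²(1) upper tail of Λ itself. At
  n = 12 the asymptotic tail is anti-conservative — its p-value
  distribution deviates from uniformity by up to ≈ 0.056, and a
  nominal p = 5×10⁻⁴ corresponds to a true level of ≈ 1.9×10⁻³ —
  so it is provided for asymptotic comparisons, not inference.

`logFC` is defined as the difference of group mean scores (CP −
control, log2 units); it is declared, not estimated from a count model.
Multiplicity uses Benjamini–Hochberg step-up FDR (the default of the
expression-style linear-model stacks this pipeline parallels);
significance is q < α with α = 0.05. No empirical-Bayes variance
moderation or covariate adjustment is attempted — with six samples per
group the unmoderated exact test is transparent and already calibrated,
and the cohort design carries no modelled covariates.

PCA for cohort visualisation uses sites with LRT p < 0.01, row-centred
but unscaled (all rows share one log2 scale), components over samples,
and per-group 90% covariance ellipses (χ²(2) scaling). Heatmap
selection takes the 200 sites with smallest q (ties: smaller p, then
catalogue order — deterministic) and orders rows by complete-linkage
Euclidean clustering.

## Regional layers

**Chromosome enrichment.** Per chromosome, a one-sided (greater)
Fisher exact test on [significant on/off chromosome × non-significant
on/off chromosome]. One-sided because enrichment is the question and
depleted chromosomes should report p ≈ 1; the universe is the tested
sites, not all genomic CCGGs, so the margins match the reported
significant-site totals.

**Megabase bins.** A site at 1-based position p belongs to bin
⌊(p−1)/10⁶⌋, anchored at coordinate 0 per chromosome; trailing partial
bins are kept, empty bins omitted. Bin value = mean logFC of member
sites (all tested sites, not only significant ones — regional load is a
property of the whole methylome). Bins are flagged hyper/hypo outside
μ ± 1.96σ of the genome-wide bin-value distribution. The "95% interval"
of a bin cloud could also be read as a percentile band or a
standard-error band; the SD band is the default because it matches the
flagging of individually extreme bins, and an empirical
[2.5%, 97.5%] percentile variant is available via
`flag_bins(..., method="percentile")`.

**Promoters.** Window = TSS ± 1000 bp **inclusive** (2001 positions;
symmetric, hence strand-independent). Windows with fewer than two
member CpGs are excluded; per gene one transcript is retained — the one
whose window contains the most member sites, ties broken by smaller TSS
then lexicographic transcript id (the inclusion rule and one-transcript
rule are standard for this design; the tie-break is this package's
deterministic choice). Window load = arithmetic mean of member-site
scores per sample; loads are tested exactly like single sites, with BH
across windows, separately per cell condition. Windows truncated at a
chromosome start are kept with a warning.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

- **Design**: 6 CP vs 6 control subjects, two paired cell conditions
  (MB, MT) sharing one ground truth with independent noise.
- **Sites**: positions sampled uniformly per chromosome at 0.75/kbp —
  the genome-wide HpaII-target density (≈2.3×10⁶ motifs over ≈3.1 Gbp).
  The default genome is 5 × 6 Mbp (~22,500 sites), big enough for 30
  megabase bins yet desk-scale.
- **Baseline methylation**: θ_i ~ Beta(2, 2) by default; validation
  scenarios that need a defined effect-to-logFC mapping use Beta(5, 15)
  (θ ≈ 0.25), where a +1.1 logit shift gives |logFC| ≈ 1–1.3, the
  centre of the reported effect-size range.
- **Planted effects**: an exact-count ⌊frac_dm·n⌋ subset (default 2%)
  receives a ±δ log-odds shift (default δ = 1.5), sign fair-coin per
  site; DM sites are allocated by weighted sampling without replacement
  so a designated chromosome carries a stated multiple (default 4×) of
  the genome-average DM density; 1-Mbp blocks and promoter windows add
  their effects on the logit scale to every member site. Exact-count
  allocation keeps recovery denominators deterministic. The truth table
  distinguishes the site-level subset (`planted_dm`) from block/promoter
  members so sensitivity is scored against the intended positives.
- **Coverage**: depth_ij ~ NegBin(mean = s_j · depth_mean · θ_i(group),
  dispersion φ), size factors s_j log-uniform on [0.7, 1.4] (bounded
  away from 0 so no sample is empty). The mean-linear link in θ is the
  simplest stand-in consistent with "coverage proportional to
  methylation probability"; true chemistry is closer to all-or-none per
  allele, and users can swap the link by supplying their own depths.
- **Noise level**: depth_mean = 300 at θ = 1 and φ = 0.005. These
  defaults are anchored to the reported tables, not tuned to tests: for
  the published effect sizes (|logFC| ≈ 0.7–2.4) to reach FDR < 0.05 in
  a 6v6 design over ~1.5×10⁶ sites, the per-site replicate SD must be
  ≈ 0.16–0.28 log2 units; the chosen defaults give ≈ 0.2 (at θ ≈ 0.25,
  var ≈ (1/75 + 0.005)/ln²2). Cultured near-clonal cell lines make a
  ~7% biological CV plausible.
- **Annotations**: non-overlapping gene models (one per equal-width
  slot), TSS placed midway between close site pairs where possible so a
  subset of promoters is guaranteed testable under the ≥2-CpG rule;
  ~30% of genes carry a second transcript to exercise deduplication;
  random enhancer intervals; a named "muscle" gene subset.

All randomness flows from a single integer seed through
`numpy.random.Generator`; identical configs give bit-identical outputs.

### What the synthetic validation shows — and does not

Passing recovery tests shows the pipeline's arithmetic and decision
rules are correct and calibrated **under the generator's assumptions**:
independent sites, Gaussian-ish log scores, NB coverage, uniform site
placement. Real MSRE-seq data add spatial autocorrelation of
methylation, CpG-island structure, batch effects, digestion-efficiency
variation and alignment artefacts, none of which are modelled. The
validation therefore certifies the software, not the biology of any
particular dataset.

## Validation scenarios and sizes

Chosen as the package's own desk-scale study conditions:

- **Null calibration**: δ = 0, one 7-Mbp chromosome (~5,250 sites),
  20 seeds; KS uniformity of site p-values and flagged fractions at
  FDR 0.05 for sites and promoter windows.
- **Recovery**: 5-chromosome genome (~22,500 sites), Beta(5, 15)
  baseline, δ = 1.1 at 2% of sites, chr3 enriched 4×, two ±0.3-logit
  1-Mbp blocks, five +1.1-logit promoters; 20 seeds. Measured:
  site sensitivity and empirical FDR, Fisher detection of chr3,
  signed recovery of the planted bins, promoter sensitivity.
- **Cross-condition stability**: MB and MT from one truth, bin-level
  Pearson r, 20 seeds.

`scripts/acceptance.py` reruns exactly these and writes the numbers;
the test suite asserts them at their stated thresholds.

## Numerical and degenerate-input conventions

- Interval containment is BED-style 0-based half-open; a 1-based site
  position p lies in [start, end) iff start ≤ p−1 < end.
- θ values are clipped to [10⁻⁶, 1−10⁻⁶] so logit shifts stay finite;
  planted-effect bookkeeping applies shifts only to affected sites so
  unaffected sites keep θ_CP ≡ θ_control exactly.
- Zero-variance score vectors return Λ = 0, p = 1 (ε floor).
- All-zero sample columns, empty genomes, malformed site ids, malformed
  intervals, groups with fewer than two samples, and zero retained
  sites raise errors naming the offending object.
- Site ids are `chrom.pos` with pos zero-padded to 10 digits; positions
  of 11+ digits are rejected.

## Known limitations

- The log2(CPM+0.5) scoring stand-in is one reasonable choice among
  several; absolute score values are not comparable across scoring
  schemes (rank-based quantities and group contrasts are).
- The LRT assumes equal group variances; no moderation is applied.
- Enhancer-to-promoter linkage, methylation–expression correlation,
  CpG-island detection and figure-perfect plotting are out of scope.
- The genome scanner is validated against an independent naive oracle
  at the megabase scale; full-genome catalogues (e.g. hg19's ≈2.29×10⁶
  CCGG motifs) require the external reference FASTA and are supported
  but not exercised in the test suite.
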