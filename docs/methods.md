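# Methods

This package implements the quantitative layer of an adverse-outcome-pathway
(AOP) guided in vitro neurotoxicity screen: concentration–response potency
estimation, a transcriptomic point of departure built on counts of
differentially expressed genes (DEGs), specificity and key-event (KE)
concordance classification, and respirometry arithmetic.  All statistics are
exercised end to end on synthetic data with retained ground truth; this note
records the models, the defaults and why, the numerical choices, and what the
synthetic data do and do not establish about real assays.

## Concentration–response model

Responses are percentages of vehicle control.  The model is the
four-parameter Hill curve with both asymptotes fixed,

    f(c) = 100 / (1 + (c / EC50)^h),

so only the midpoint EC50 (molar) and the slope h are free.  Fixing the
asymptotes reflects how screening data are normalized (untreated = 100%,
fully-effective positive control = 0%) and makes the fit robust to
stimulation artifacts above 100%, which are retained, not clipped.

Fitting minimizes least squares over (log10 EC50, log h) with
`scipy.optimize.least_squares`, EC50 bounded to [min tested conc/100,
max tested conc×100] and h to [0.2, 10].  Three starts at the geometric
quartiles of the tested range are tried; the lowest residual sum of squares
wins, ties resolved toward the smaller slope.  A solver that exhausts its
iteration budget inside a flat valley of a numerically perfect fit (gradient
below 1e-6 on the percent scale) is treated as converged.

**Flat curves.**  A series whose minimum mean response never drops below 75%
(no concentration reaches a 25% effect) is flagged flat: no EC50 is reported
and downstream consumers receive an explicit "no hit" rather than an
unconstrained extrapolation.  The DEG-response route lowers this threshold to
the 10% level it solves for.

**Effective concentrations.**  EC_x is solved analytically,
EC_x = EC50 · (x/(100−x))^(1/h), with an `extrapolated` flag when the
solution lies outside the tested range.  Concentrations are molar throughout;
the pEC = −log10(M) convention appears only in report columns.

**Benchmark concentrations.**  BMC at benchmark response b (default 10%) is
EC_b from the full-data fit; the confidence interval comes from
case-resampling replicates with replacement within each concentration,
refitting per resample (started from the full-data optimum), and taking the
2.5/97.5 percentiles.  Within-group resampling of n replicates understates
the group variance by (n−1)/n, so bootstrap deviations from the point
estimate are inflated by sqrt(n/(n−1)) on the log-concentration scale before
the percentiles are taken; without this correction, nominal 95% intervals
covered the true BMC in only ~83% of simulated three-replicate datasets,
with it ~91%.  The bootstrap is a documented stand-in for the original
benchmark-concentration web tool, whose internals are not specified.
Default 1000 resamples (tests and drivers use 200–300, which changes CI
endpoints by a few percent at most).

## Differential expression

The DEG caller is a deliberately transparent negative-binomial Wald test —
no fold-change shrinkage, no outlier filtering, no independent filtering —
because the downstream statistic consumes only DEG *counts* and needs
calibrated testing rather than optimal per-gene effect estimates.

1. **Prefilter.**  Samples with a raw total below 0.2 million reads are
   dropped, then genes with a mean raw count below 1.5.
2. **Normalization.**  Median-of-ratios size factors: reference genes are
   those with strictly positive counts in every sample; a sample's factor is
   the median ratio of its counts to the gene-wise geometric means.
3. **Test.**  Per contrast (one compound × concentration vs all vehicle
   samples), group means of normalized counts get a 0.5 pseudocount.  The
   per-gene NB dispersion α (Var = μ + αμ²) is estimated by pooled
   within-group method of moments (residual sums of squares pooled over both
   groups, df = n_t + n_c − 2) — within-group, so a true expression
   difference does not masquerade as overdispersion.  Raw estimates are
   moderated 50/50 toward a log-linear mean–dispersion trend.  The trend is
   fitted to *bin-averaged signed* raw estimates (20 quantile bins of log
   mean): averaging before taking logs avoids the severe downward bias of a
   direct log-scale regression on three-replicate moment estimates, and
   keeping negative raw values in the bin averages lets sampling noise
   cancel.  The blend is arithmetic, floored at 1e-8.  The Wald statistic is
   z = (ln μ_t − ln μ_c)/sqrt(v_t + v_c) with v = (1/n)(1/μ + α), compared
   to a standard normal; Benjamini–Hochberg adjustment spans all genes of
   the contrast.  Under a null simulation (2000 genes, n = 3, α = 0.05) the
   raw p < 0.05 fraction sits at 0.05–0.065.
4. **DEG rules.**  Two first-class options: `fdr_and_fc` (default for
   concentration–response work): |log2FC| > 0.59 (1.5-fold) and padj < 0.05;
   `fdr_only`: padj ≤ 0.05.

## Transcriptomic point of departure

Per concentration, the total DEG count n is summarized two ways:

* **Normalized response** = min(n / N_pos, 1) · 100, where N_pos is the DEG
  count of a designated positive-control condition (the published worked
  value is 325; N_pos is an explicit input, defaulted only in the run
  config).  An increasing Hill curve (0 → 100) is fitted and solved at 10%
  to give EC10(DEG).
* **DGH** (degree of gene-expression homeostasis) = max(0, 100 − n), a
  decreasing series fed to the benchmark-concentration machinery at a 10%
  benchmark response to give BMC10(DGH).

The two are different statistics — 10% of N_pos ≈ 33 DEGs versus a DGH drop
of 10 = 10 DEGs — and both are reported.  Note the DGH fit assumes the
series approaches 0 (i.e. ≥ 100 DEGs at the top concentration); a weaker
maximal response distorts the fixed-asymptote fit and BMC10(DGH) then leans
on extrapolation.

The **overlap signature** intersects the DEG sets at an anchor concentration
(e.g. the EC10 of viability) and a several-fold lower one (default 4×,
configurable), screening out regulation secondary to cytotoxicity.  The
**regulation matrix** reports signature-gene log2 fold changes across
conditions, masking cells with padj > 0.1 and distinguishing "masked" from
"absent".  The **PCA overview** ranks genes by variance of
log2(normalized count + 1) — the log scale matches the "most variable
genes" idiom for counts — and decomposes the 100 most variable, centered
per gene.

## Classification layers

* **Specificity.**  A compound is a specific neurotoxicant when
  EC25(viability)/EC25(neurite area) > 4 on the linear molar scale; < 4 (or
  exactly 4 — the rule is strict) is unspecific.  When viability never drops
  25% in the tested range, the ratio is right-censored at
  max tested conc / EC25(NA): a bound ≥ 2 yields "potential (lower bound)",
  anything else "not determinable".
* **Virtual screen.**  At a fixed 50 µM screen concentration a compound is a
  hit ("+") when the fitted curve shows ≥ 25% effect, otherwise "O"; the
  fitted curve, not the nearest tested point, is interpolated because tested
  grids differ between compounds.  Flat series covering 50 µM are immediate
  non-hits.
* **KE ratio matrix.**  Anchored on the KE4 (neurite) assay, each upstream
  KE assay contributes ratio = EC25(KE4)/EC25(upstream); categories are
  strong (> 100), marked (> 10), moderate (> 3), neutral [1/3, 3], inverse
  (< 1/3), with boundary values falling to the less extreme class and
  undefined ECs absorbed by "n.a.".

## Respirometry

Per well, with baseline = last pre-treatment OCR measurement, post = first
post-treatment measurement and nm = first measurement after the final
rotenone/antimycin injection (the non-mitochondrial residual):

    inhibition% = 100 · (baseline − post) / (baseline − nm).

The statistic is a ratio, hence invariant to per-well normalization (division
by the OCR at equilibration end) and uniform rescaling.  Values outside
[0, 100] are reported unclamped.  The negative-control noise band is
mean ± 2 SD of vehicle inhibition values (≥ 6 required); this definition is a
stand-in adopted here, as screening practice defers it to assay-specific
validation.  Wells aggregate as mean ± SEM.

## Synthetic data

The generators emulate the study conditions the pipeline was designed for:

* **Assay readouts**: Hill responses with Gaussian noise on the percent
  scale (default SD 5 percentage points, n = 3 replicates), clipped to
  [−10, 110] to admit the slight overshoot metabolic readouts show.
* **Counts**: a ~3000-gene targeted panel, 5 concentrations plus vehicle,
  n = 3; baseline means log-normal(meanlog 4, sdlog 1.5) to span a targeted
  panel's dynamic range (zeros arise naturally from NB sampling); per-sample
  size factors log-normal(0, 0.15); NB dispersion 0.05.  Planted DE genes
  (default 4% of the panel) follow a rising Hill in concentration saturating
  at a per-gene magnitude drawn from [1, 3] log2 units, signs random, with
  gene-level midpoints scattered 0.3 log10 around the compound's
  transcriptome EC50 so the DEG count rises gradually.
* **KE panels**: per mode-of-action class, upstream-KE EC50s are the KE4
  EC50 divided by a multiplier (defaults: complex-I-like 300/30/1 for
  KE1/KE2/KE3, complex-III-like 10/10/1, complex-II-like ≈ 1), reproducing
  the observed pattern that early key events trigger orders of magnitude
  below the adverse-outcome proxy.
* Concentration grids are log-spaced (half-log default; top concentration,
  dilution factor and point count are parameters, since real screening
  designs anchor ranges per compound).

One global seed expands into named, CRC-keyed substreams (responses per
compound × endpoint, baselines, DE parameters, size factors, counts per
sample), so adding a stream or regenerating one sample never perturbs the
rest, and identical seeds are bit-reproducible.

**What passing tests show — and don't.**  Recovery tests demonstrate
internal consistency: data generated by the assumed model are correctly
inverted at realistic noise, replicate counts and effect sizes.  They do not
establish robustness to features real data have and the generator lacks:
batch effects and plate-position artifacts, correlated genes, heavy-tailed
or asymmetric replicate noise, partial-asymptote endpoints (e.g. membrane
potential plateaus), compound precipitation, or dispersion that varies with
treatment.  The fixed-asymptote contract is kept for all endpoints; fits of
partially-inhibiting endpoints surface as high RSS rather than as a refit
with free asymptotes.

## Analysis sizes

The shipped drivers and tests use 5 synthetic compounds, 2000–3000 genes,
100–200 simulated curves and 200–300 bootstrap resamples — sizes chosen so
the whole analysis reruns from scratch in a few minutes on one core while
keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The Wald test's normal reference is approximate at n = 3; residual
  anticonservativeness (~1 point above nominal at the 5% level) remains
  after dispersion moderation.
* BMC10(DGH) inherits the fixed-asymptote assumption (see above).
* The specificity model consumes EC25 point estimates; it propagates no
  fit uncertainty into the 4-fold rule.
* No multi-factor designs, batch correction, biphasic curve families,
  model averaging, or in vitro–to–in vivo extrapolation.
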