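# Methods

## Scope and model

`crossmask` implements intensity-threshold masking of microarray probes
that target inter-species variable (ISV) regions in cross-species
hybridization (CSH) experiments, together with the preprocessing,
threshold-selection, and downstream analyses needed to use it end to end.
All statistics operate on probe-level intensity matrices (probes ×
samples, linear scale) with a sample design of (species, tissue,
replicate) triples and a chip layout mapping probe sets to ordered PM (and
optionally MM) probes.

### Masking rule

For a species hybridized on `Ts = R × S` arrays (S tissue types, R
replicates), a probe is retained at threshold `t` iff strictly more than
`t` in at least `R` samples; otherwise all `Ts` of its values are masked.
"Above" is strict (`intensity > t`), so "at or below" triggers masking —
the two phrasings partition all outcomes. The equivalent masking fraction
is `P = (Ts − R + 1)/Ts`, kept internally as an exact rational and rounded
to two decimals only for display (3 × 3 design: 7/9 → 0.78). The rationale
for `R`: if a probe's target region is conserved and the transcript is
expressed in at least one tissue, the probe should clear a modest
threshold in all `R` replicates of that tissue; fewer than `R` exceedances
mean the probe never responds convincingly anywhere.

Masks are built per threshold on background-corrected, quantile-normalized
intensities, and the same preprocessed matrix is then summarized with the
mask applied. A single preprocessing pass is used for both mask
construction and summarization; normalizing twice (once per purpose) would
apply the correction model to its own output, which has no statistical
justification.

### Preprocessing

*Background correction* uses the normal + exponential convolution model:
observed `X = B + S` with `B ~ N(mu, sigma²)` and `S ~ Exp(rate)`; the
corrected value is the posterior mean `E[S | X = x]`, evaluated in log
space so it remains stable deep in the background. Parameters are
estimated per sample column by method of moments around the column mode:
`mu` = histogram mode of the lower 75% of the column, `sigma` from the
mirrored second moment of values below the mode, and the exponential mean
from the mean exceedance above it. This estimator is deliberately simple
and fully specified so its behavior is testable; the posterior mean is
checked against direct numerical integration in the test suite. The
correction is strictly positive and monotone, hence rank-preserving within
a column.

*Quantile normalization* maps every column onto the per-rank mean of the
input columns; ties receive the mean of the reference values at their tied
ranks, which makes the map deterministic and idempotent.

*Summarization* fits the additive model
`log2(y) = mu + probe_effect + sample_effect` per probe set by Tukey
median polish over retained probes (row sweeps first, convergence when the
total absolute change of a sweep pair drops below 0.01, at most 10
iterations — a widely used convention). The expression value for sample
`s` is `mu + sample_effect_s`. One retained probe yields that probe's log2
values directly; zero retained probes remove the probe set from the
output.

*Detection calls* follow the MAS 5.0 convention: discrimination scores
`d_i = (PM_i − MM_i)/(PM_i + MM_i)` are tested against `tau = 0.015` by a
one-sided Wilcoxon signed-rank test; Present if `p < 0.04`, Marginal if
`p < 0.06`, Absent otherwise (vendor-default constants; the sources using
this pipeline do not print their values). The signed-rank test is exact by
enumeration over all `2^n` sign assignments for `n ≤ 12` pairs — 11-pair
probe sets are the hot path — with average ranks for ties and zero
differences dropped; above 12 a continuity-corrected normal approximation
with tie-corrected variance is used. Probe sets without MM probes get NA
calls rather than an error.

### Threshold sweep and selection

For each threshold the CSH species is masked and re-summarized while the
target species is summarized once unmasked. A gene is tissue-selected when
its replicate-averaged log2 expression differs by ≥ log2(min_fold)
(default 2-fold) between the two tissues; *commonly-selected genes* are
tissue-selected in both species, and the accuracy score is the Pearson
correlation of the two species' log2 ratios over that set (NA below 3
genes). Ratios correlate on the log2 scale; linear ratios would let a few
large values dominate. Fold-change selection uses tissue means of
replicates rather than per-replicate voting.

The default selection rule makes the published practice explicit:
maximize the correlation subject to retaining at least `min_fraction`
(default 0.95) of the probe sets, ties broken by the larger
commonly-selected count and then the smaller threshold. An alternative
`max_common` rule maximizes the commonly-selected count instead. Selection
only annotates the sweep table; nothing is applied silently.

### Downstream analyses

*Differential expression*: per probe set, one-way fixed-effects ANOVA of
log2 expression across tissues, Benjamini–Hochberg FDR across tested probe
sets, and a pairwise fold filter; a gene is significant when
`p < 1e-4`, `FDR < 0.0015`, and at least one tissue pair differs by ≥
2-fold. Probe sets tagged with pathogen-control organisms
(*Phytophthora sojae*, *Heterodera glycines*) are excluded before testing
and before the FDR is computed. Plain ANOVA is used — no variance
shrinkage — and documented as such.

*PCA*: samples are observations, probe sets variables; columns are
centered, not scaled; the decomposition is by SVD, so variance-explained
fractions sum to one; each component is oriented with its
largest-magnitude loading positive.

*Conservation classes*: from a mask's retained-probe counts per set,
`all_masked` (0), `hyper_variable` (1–2), `highly_conserved` (≥ 10 of 11),
`intermediate` otherwise. Fully masked sets are excluded from group
statistics because zero retention confounds sequence divergence with lack
of expression.

*Over-representation*: per annotation class, a two-sided Fisher exact test
of the 2 × 2 (class membership × selection membership) table over the
universe, Bonferroni correction over classes, and the signed transform
`z = Φ⁻¹(1 − p_adj/2)`, positive for over-representation (observed count
above expectation) and negative for under. Two-sided is chosen because the
readout flags both directions. z is reported uncapped; the conventional
−4..4 color scale is presentation only.

## Synthetic data generator

The generator emulates the structure the method assumes: two species on
one chip design, shared tissue expression programs, and planted ISV
attenuation in the CSH species only. Per gene `g` and tissue `t`, the
log2 mean is `mu_gt = b_g + shift_gt` with baseline `b_g ~ N(8, 2)` shared
between species; a fraction `frac_de` (default 0.15) of genes receives a
±`de_log2_effect` (default 2) shift in one random tissue. Probes carry an
affinity `a_p ~ N(0, 0.5)` and a response slope `s_p ~ N(1, 0.2)` (clipped
at 0.2), both properties of the physical probe and therefore shared
between species — probe-specific sensitivity differences of this size are
a standard feature of probe-level chip models and are what limits the
accuracy of expression values built from one or two probes. The PM signal
is `2^(s_p·mu_gt + a_p + eps)` with `eps ~ N(0, 0.3)` drawn independently
per species and cell.

Sequence divergence is gene-clustered: each gene draws an ISV probability
`v_g ~ Beta(shape, shape·(1−m)/m)` with mean `m = frac_isv_probes`
(default 0.3) and `shape = 1` (uniform), and each of its probes is ISV
with probability `v_g`. This produces the empirically observed continuum
from fully conserved to fully divergent probe sets — the basis of the
highly-conserved / hyper-variable classification — and it is what makes an
unmasked CSH analysis visibly pathological: when the majority of a gene's
probes are floored, the robust median-polish fit follows them and the
gene's fold change collapses. ISV probes are attenuated by a constant
per-probe factor `delta_p ~ Uniform(0.0001, 0.001)`: a 25-mer probe
overlapping genuinely variable sequence retains essentially no specific
hybridization, and its measured intensity is dominated by the additive
optical/non-specific background `~N(40, 10)` (linear scale, draws below 1
redrawn). MM intensities are background plus a 5% crosstalk of the PM
signal. All draws come from one seeded generator in a fixed documented
order, so outputs are bit-reproducible.

Evaluation against the planted truth restricts to probes of *expressed*
genes (true mean log2 across tissues ≥ 6 by default): probes of
unexpressed genes sit at the background floor whether or not their region
diverged, so no intensity rule can identify them, and counting them would
measure the expression distribution rather than the mask.

What the generator does **not** emulate: cross-hybridization between
paralogs, alternative splicing, partial (mild) attenuation continua,
species-specific expression programs, and array spatial artifacts.
Passing tests therefore show that the masking rule recovers strongly
attenuated probes and restores fold changes *under the model's
assumptions*; they do not bound its behavior on real chips, where
intensity-based masking is known to be biased toward abundant transcripts
and can over-mask.

## Problem sizes and numerical choices

The default synthetic chip is 2,000 probe sets × 11 probes (the full
pipeline including an 19-point threshold sweep runs in well under a minute);
the command-line pipeline test uses 5,000 probe sets. These sizes give
stable sweep curves and recovery estimates while keeping the suite quick to
iterate on. Tolerances: median polish 0.01 total absolute change; the
normexp posterior is validated to 1e-6 relative against quadrature; exact
signed-rank enumeration is used through n = 12. Degenerate inputs are
defined rather than erroneous where a convention exists (single retained
probe, probe set without MM, empty mask) and errors where none does
(zero-variance column, unbalanced design without explicit rule
parameters, thresholds out of order).

## Known limitations

* The masking-fraction closed form `(Ts − R + 1)/Ts` assumes one retention
  count `R` for all tissues; unbalanced designs must supply rule
  parameters explicitly.
* The threshold scale is data-dependent (it lives on the corrected,
  normalized intensity scale), so selected thresholds are not comparable
  across datasets with different background levels.
* The sweep's correlation score is nearly flat over a range of moderate
  thresholds when attenuation is strong; the retention constraint and
  tie-breaks then decide within that plateau.
* Present/absent calls implement only the detection p-value side of MAS5,
  not its Tukey-biweight signal estimate.
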