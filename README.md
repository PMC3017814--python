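# crossmask

Probe-level masking for **cross-species hybridization (CSH)** GeneChip
experiments: transcript profiling of a species that has no array of its own
by hybridizing its cRNA to a close relative's chip.

## The problem

Short-oligo arrays interrogate each transcript with a probe set of ~11
25-mer perfect-match (PM) probes. When RNA from a *non-target* species is
hybridized, probes that overlap **inter-species variable (ISV)** regions —
stretches where the two species' sequences diverge — bind poorly. Their
signals sit at the background floor regardless of transcript abundance,
which (1) reduces the number of expressed genes detected and (2)
compresses measured fold changes. Because a probe set needs only one probe
to yield an expression value, biased probes can be masked electronically
and summarization restricted to the informative remainder.

## The method

For one species hybridized in `S` tissue types with `R` replicates each
(`Ts = R × S` arrays total), a probe is **retained** at signal-intensity
threshold `t` iff its background-corrected, quantile-normalized intensity
exceeds `t` in at least `R` of the `Ts` samples; otherwise all of its
values are masked. Equivalently, masking triggers when at least a fraction

```
P = (Ts − R + 1) / Ts
```

of the samples are at or below `t` (for the canonical 3 × 3 design,
P = 7/9 ≈ 0.78). One mask is built per candidate threshold; probe sets are
then summarized by masked RMA (median polish of log2 intensities over
retained probes).

The operating threshold is chosen by sweeping a grid of thresholds and
scoring each against the target species analyzed in parallel:

* **sensitivity** — the number of *commonly-selected genes*: probe sets
  with ≥ 2-fold expression difference between two tissues in **both** the
  target species (unmasked) and the CSH species (masked at `t`);
* **accuracy** — the Pearson correlation of the two species' log2 tissue
  ratios over the commonly-selected genes.

The default rule takes the threshold maximizing the correlation subject to
retaining ≥ 95% of probe sets. Downstream modules provide MAS5-style
present/absent detection calls, one-way ANOVA differential expression with
BH-FDR and pairwise fold filters, PCA overviews, conservation classes from
retained-probe counts (highly-conserved = 10–11 retained, hyper-variable =
1–2), and Fisher-exact class over-representation with Bonferroni
correction and a signed z transform.

## Worked example

A synthetic two-species dataset (3 tissues × 3 replicates per species,
11-probe sets, a planted subset of ISV probes attenuated in the CSH
species) pushed through the sweep:

```python
import crossmask as cm

params = cm.SimParams(n_probesets=500, seed=0)
data = cm.generate_dataset(params)
csh = cm.quantile_normalize(cm.background_correct(data.csh))
target = cm.quantile_normalize(cm.background_correct(data.target))
sweep = cm.run_sweep(csh, target, data.layout,
                     [0, 10, 20, 40, 80, 160, 640], "nodule", "leaf",
                     preprocessed=True)
threshold = cm.select_threshold(sweep)
print(sweep.table.round(3).to_string(index=False))
print(f"selected threshold: {threshold:g}")

mask = sweep.masks[[m.threshold for m in sweep.masks].index(threshold)]
rec = cm.evaluate_mask_recovery(mask, data.truth, data.layout)
print(f"ISV probe recovery: sensitivity={rec.sensitivity:.3f} "
      f"specificity={rec.specificity:.3f} precision={rec.precision:.3f}")
```

Output:

```
 threshold  n_probes_retained  n_probesets_retained  n_common  pearson_r  selected
       0.0               5500                   500        30      0.988     False
      10.0               4684                   500        42      0.986     False
      20.0               3730                   491        47      0.992      True
      40.0               3386                   485        47      0.987     False
      80.0               2915                   465        46      0.986     False
     160.0               2329                   437        44      0.983     False
     640.0               1193                   321        35      0.993     False
selected threshold: 20
ISV probe recovery: sensitivity=0.979 specificity=0.989 precision=0.974
```

Reading the table: masking removes probes rapidly but probe sets only
gradually (a set survives until its last probe is masked). The
commonly-selected gene count rises from 30 (no masking) to 47 at the
selected threshold — masking recovers differential genes whose fold
changes were compressed by floored ISV probes — and falls again at extreme
thresholds as whole probe sets disappear. The selected mask flags 97.9% of
the planted ISV probes among expressed genes while keeping 98.9% of the
conserved ones.

The same pipeline is available from the shell:

```sh
crossmask simulate --seed 1 --out-dir sim/
crossmask mask --intensities sim/Pv_intensities.tsv --layout sim/layout.tsv \
    --design sim/design.tsv --species Pv --threshold 80 --out Pv80.mask
crossmask sweep --csh sim/Pv_intensities.tsv --target sim/Gm_intensities.tsv \
    --layout sim/layout.tsv --design sim/design.tsv --csh-species Pv \
    --target-species Gm --tissues nodule,leaf --out sweep.tsv
crossmask summarize --intensities sim/Pv_intensities.tsv --layout sim/layout.tsv \
    --design sim/design.tsv --species Pv --mask Pv80.mask --out Pv_expr.tsv
crossmask de --expr Pv_expr.tsv --design sim/design.tsv --layout sim/layout.tsv \
    --out de.tsv
```

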