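"""Threshold-sweep optimization.

Each candidate masking threshold is scored on two axes against the target
species analyzed in parallel:

* sensitivity — the number of "commonly-selected" genes, i.e. probe sets
  showing at least a ``min_fold`` expression difference between two tissues
  in *both* the target species (unmasked) and the cross-hybridized species
  (masked at that threshold);
* accuracy — the Pearson correlation, over the commonly-selected genes, of
  the two species' log2 tissue ratios.

The default selection rule takes the threshold maximizing the correlation
subject to retaining at least ``min_fraction`` of the probe sets, breaking
ties by the larger common-gene count and then the smaller threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, InputError, ParameterError, SelectionError
from .io import ChipLayout, ExpressionMatrix, IntensityMatrix, ProbeMask
from .masking import MaskRuleParams, mask_series, retained_counts
from .preprocess import background_correct, quantile_normalize, summarize_rma

__all__ = [
    "fold_change_genes",
    "commonly_selected",
    "SweepResult",
    "run_sweep",
    "select_threshold",
    "plot_sweep",
]


def _tissue_means(expr: ExpressionMatrix, tissue: str) -> pd.Series:
    samples = expr.design.samples_for(tissue=tissue)
    if not samples:
        raise DesignError(f"tissue {tissue!r} absent from design")
    return expr.values.loc[:, samples].mean(axis=1)


def fold_change_genes(
    expr: ExpressionMatrix, tissue_a: str, tissue_b: str, min_fold: float = 2.0
) -> set[str]:
    """Probe sets with >= min_fold mean expression ratio between two tissues.

    Replicates are averaged per tissue on the log2 scale first; a gene is
    selected when |mean_log2(a) - mean_log2(b)| >= log2(min_fold).
    """
    diff = _tissue_means(expr, tissue_a) - _tissue_means(expr, tissue_b)
    cut = np.log2(min_fold)
    return set(diff.index[diff.abs() >= cut])


def log2_ratio(expr: ExpressionMatrix, tissue_a: str, tissue_b: str) -> pd.Series:
    """Per-gene log2(tissue_a / tissue_b) of replicate-averaged expression."""
    return _tissue_means(expr, tissue_a) - _tissue_means(expr, tissue_b)


def commonly_selected(
    expr_target: ExpressionMatrix,
    expr_csh: ExpressionMatrix,
    tissue_a: str,
    tissue_b: str,
    min_fold: float = 2.0,
) -> tuple[set[str], float]:
    """Commonly-selected genes and the cross-species ratio correlation.

    Returns the intersection of each species' fold-change gene sets and the
    Pearson correlation of the two species' per-gene log2(a/b) ratios over
    that set (NaN when fewer than 3 genes are common).
    """
    shared = set(expr_target.probeset_ids) & set(expr_csh.probeset_ids)
    if not shared:
        raise InputError("the two expression matrices share no probe-set IDs")
    genes_t = fold_change_genes(expr_target, tissue_a, tissue_b, min_fold)
    genes_c = fold_change_genes(expr_csh, tissue_a, tissue_b, min_fold)
    common = genes_t & genes_c & shared
    if len(common) < 3:
        return common, float("nan")
    idx = sorted(common)
    rt = log2_ratio(expr_target, tissue_a, tissue_b).loc[idx]
    rc = log2_ratio(expr_csh, tissue_a, tissue_b).loc[idx]
    r = float(np.corrcoef(rt.to_numpy(), rc.to_numpy())[0, 1])
    return common, r


@dataclass
class SweepResult:
    """Per-threshold metrics of the masking sweep.

    ``table`` has one row per threshold with columns threshold,
    n_probes_retained, n_probesets_retained, n_common, pearson_r, selected.
    ``n_probesets_total`` is the unmasked probe-set count used by the
    retention constraint of :func:`select_threshold`.
    """

    table: pd.DataFrame
    n_probesets_total: int
    masks: list[ProbeMask] = field(default_factory=list, repr=False)

    @property
    def selected_threshold(self) -> float | None:
        sel = self.table.loc[self.table["selected"]]
        return float(sel["threshold"].iloc[0]) if len(sel) else None


def run_sweep(
    matrix_csh: IntensityMatrix,
    matrix_target: IntensityMatrix,
    layout: ChipLayout,
    thresholds: list[float],
    tissue_a: str,
    tissue_b: str,
    min_fold: float = 2.0,
    preprocessed: bool = False,
) -> SweepResult:
    """Evaluate every masking threshold against the parallel target data.

    The target species is background-corrected, quantile-normalized, and
    summarized once without a mask; the cross-hybridized (CSH) species is
    preprocessed once, then masked and re-summarized per threshold. Set
    ``preprocessed`` when both matrices are already on the corrected,
    normalized scale.
    """
    if not preprocessed:
        matrix_csh = quantile_normalize(background_correct(matrix_csh))
        matrix_target = quantile_normalize(background_correct(matrix_target))
    expr_target = summarize_rma(matrix_target, layout, mask=None)
    masks = mask_series(matrix_csh, layout, thresholds)
    rows = []
    for mask in masks:
        counts = retained_counts(mask, layout)
        expr_csh = summarize_rma(matrix_csh, layout, mask=mask)
        if expr_csh.values.empty:
            common, r = set(), float("nan")
        else:
            common, r = commonly_selected(
                expr_target, expr_csh, tissue_a, tissue_b, min_fold
            )
        rows.append(
            {
                "threshold": mask.threshold,
                "n_probes_retained": counts.n_probes_retained,
                "n_probesets_retained": counts.n_probesets_retained,
                "n_common": len(common),
                "pearson_r": r,
                "selected": False,
            }
        )
    table = pd.DataFrame(rows)
    return SweepResult(table=table, n_probesets_total=layout.n_probesets, masks=masks)


def select_threshold(
    sweep: SweepResult,
    rule: str = "max_correlation",
    min_fraction: float = 0.95,
) -> float:
    """Pick the operating threshold from a sweep table.

    ``max_correlation`` (default): maximize pearson_r among thresholds
    retaining at least ``min_fraction`` of the unmasked probe-set count;
    ties broken by larger n_common, then smaller threshold.
    ``max_common``: maximize n_common under the same constraint, ties by
    larger pearson_r, then smaller threshold. The chosen row is flagged in
    ``sweep.table['selected']``; nothing is applied silently.
    """
    t = sweep.table
    if t.empty:
        raise SelectionError("empty sweep table")
    eligible = t[t["n_probesets_retained"] >= min_fraction * sweep.n_probesets_total]
    if rule == "max_correlation":
        eligible = eligible.dropna(subset=["pearson_r"])
        keys = ["pearson_r", "n_common"]
    elif rule == "max_common":
        keys = ["n_common", "pearson_r"]
    else:
        raise ParameterError(f"unknown selection rule {rule!r}")
    if eligible.empty:
        raise SelectionError(
            "no threshold satisfies the probe-set retention constraint "
            f"(min_fraction={min_fraction}); consider relaxing min_fraction"
        )
    ranked = eligible.sort_values(
        keys + ["threshold"], ascending=[False, False, True], kind="stable"
    )
    best = ranked.index[0]
    sweep.table["selected"] = False
    sweep.table.loc[best, "selected"] = True
    return float(sweep.table.loc[best, "threshold"])


def plot_sweep(sweep: SweepResult, path: str, retained: bool = True) -> None:
    """Two-panel sweep plot: retention curves and the optimization curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = sweep.table
    nrows = 2 if retained else 1
    fig, axes = plt.subplots(nrows, 1, figsize=(7, 4 * nrows), squeeze=False)
    if retained:
        ax = axes[0][0]
        ax.plot(t["threshold"], t["n_probes_retained"], "^-", label="probes retained")
        ax.plot(t["threshold"], t["n_probesets_retained"], "o-", label="probe sets retained")
        ax.set_xscale("symlog")
        ax.set_xlabel("signal intensity threshold")
        ax.set_ylabel("count")
        ax.legend()
    ax = axes[-1][0]
    ax.plot(t["threshold"], t["n_common"], "o-", color="tab:blue", label="commonly-selected genes")
    ax.set_xscale("symlog")
    ax.set_xlabel("signal intensity threshold")
    ax.set_ylabel("commonly-selected genes", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(t["threshold"], t["pearson_r"], "^-", color="tab:red", label="Pearson r")
    ax2.set_ylabel("Pearson r of log2 tissue ratios", color="tab:red")
    sel = t.loc[t["selected"]]
    if len(sel):
        ax.axvline(float(sel["threshold"].iloc[0]), color="k", ls="--", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
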