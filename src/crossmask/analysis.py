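"""Downstream expression analyses.

* one-way ANOVA across tissues with Benjamini-Hochberg FDR and a pairwise
  fold-ratio filter, excluding pathogen-control probe sets;
* PCA overview of samples (probe sets as variables, columns centered);
* conservation-class assignment from retained-probe counts;
* Fisher-exact over/under-representation of annotation classes with
  Bonferroni correction and an inverse-normal z transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, EstimationError, InputError, ParameterError
from .io import ChipLayout, ExpressionMatrix, ProbeMask
from .masking import retained_counts

__all__ = [
    "DEFAULT_EXCLUDED_ORGANISMS",
    "anova_de",
    "PCAResult",
    "pca_overview",
    "classify_conservation",
    "fisher_overrep",
]

# Pathogen-control probe sets excluded from differential-expression testing.
DEFAULT_EXCLUDED_ORGANISMS: tuple[str, ...] = (
    "Phytophthora sojae",
    "Heterodera glycines",
)


def _pair_col(a: str, b: str) -> str:
    return f"log2_{a}_vs_{b}"


def anova_de(
    expr: ExpressionMatrix,
    p_cut: float = 1e-4,
    fold_cut: float = 2.0,
    fdr_cut: float = 0.0015,
    exclude_organisms: Iterable[str] = DEFAULT_EXCLUDED_ORGANISMS,
    layout: ChipLayout | None = None,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across tissues, per probe set.

    ``expr`` must cover a single species with >= 2 tissues and >= 2
    replicates per tissue. Probe sets whose layout organism tag is in
    ``exclude_organisms`` are dropped before testing (and before the BH FDR
    is computed). A probe set is ``significant`` when p < p_cut, BH FDR <
    fdr_cut, and at least one tissue pair differs by >= fold_cut (i.e.
    |log2 ratio| >= log2(fold_cut)).

    Returns a DataFrame indexed by probeset_id with columns f_statistic,
    p_value, fdr, one ``log2_<a>_vs_<b>`` column per tissue pair,
    max_abs_log2_ratio, and significant.
    """
    design = expr.design
    if len(design.species) > 1:
        raise DesignError("expression matrix spans several species; subset first")
    tissues = design.tissues()
    if len(tissues) < 2:
        raise DesignError(f"need >= 2 tissues, found {tissues}")
    groups = []
    for t in tissues:
        samples = design.samples_for(tissue=t)
        if len(samples) < 2:
            raise DesignError(f"tissue {t!r} has {len(samples)} replicate(s); need >= 2")
        groups.append(expr.values.loc[:, samples].to_numpy())

    keep = pd.Series(True, index=expr.values.index)
    excluded = set(exclude_organisms)
    if layout is not None and excluded:
        keep = pd.Series(
            [layout.organism_of(ps) not in excluded for ps in expr.values.index],
            index=expr.values.index,
        )
    groups = [g[keep.to_numpy()] for g in groups]
    index = expr.values.index[keep.to_numpy()]

    ns = np.array([g.shape[1] for g in groups])
    n_total = int(ns.sum())
    k = len(groups)
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = np.concatenate(groups, axis=1).mean(axis=1)
    ss_between = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.zeros(len(index))
    for j, g in enumerate(groups):
        ss_within += ((g - means[:, [j]]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    msb = ss_between / df_b
    msw = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(msw == 0, np.where(msb == 0, 0.0, np.inf), f)
    p = stats.f.sf(f, df_b, df_w)
    p = np.where(np.isinf(f), 0.0, p)

    out = pd.DataFrame({"f_statistic": f, "p_value": p}, index=index)
    out["fdr"] = multipletests(p, method="fdr_bh")[1] if len(p) else []
    pair_cols = []
    for a, b in combinations(range(k), 2):
        col = _pair_col(tissues[a], tissues[b])
        out[col] = means[:, a] - means[:, b]
        pair_cols.append(col)
    out["max_abs_log2_ratio"] = out[pair_cols].abs().max(axis=1)
    out["significant"] = (
        (out["p_value"] < p_cut)
        & (out["fdr"] < fdr_cut)
        & (out["max_abs_log2_ratio"] >= np.log2(fold_cut))
    )
    return out


@dataclass
class PCAResult:
    """Sample scores and per-component variance-explained fractions."""

    scores: pd.DataFrame  # samples x components, columns 'PC1', 'PC2', ...
    explained: np.ndarray  # fractions over all components, sums to 1
    loadings: pd.DataFrame  # probe sets x components


def pca_overview(expr: ExpressionMatrix, n_components: int = 2) -> PCAResult:
    """PCA with samples as observations and probe sets as variables.

    Variables (probe-set columns of the samples x genes matrix) are
    centered but not scaled; the decomposition uses singular values, so
    variance-explained fractions over all components sum to one. Each
    component is oriented so its largest-magnitude loading is positive.
    """
    x = expr.values.to_numpy().T  # samples x genes
    n_samples = x.shape[0]
    if n_samples < 2:
        raise DesignError(f"PCA needs >= 2 samples, got {n_samples}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise EstimationError("expression matrix is constant; zero total variance")
    explained = s**2 / total
    # sign convention: largest-magnitude loading positive per component
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    n_components = min(n_components, len(s))
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores[:, :n_components], index=expr.values.columns, columns=cols),
        explained=explained,
        loadings=pd.DataFrame(vt[:n_components].T, index=expr.values.index, columns=cols),
    )


def classify_conservation(
    mask: ProbeMask,
    layout: ChipLayout,
    hi_min: int = 10,
    hyper_max: int = 2,
) -> pd.DataFrame:
    """Assign each probe set a conservation class from its retained count.

    ``all_masked`` (0 probes retained, excluded from group statistics),
    ``hyper_variable`` (1..hyper_max), ``highly_conserved`` (>= hi_min),
    ``intermediate`` otherwise. Retained-probe counts come from the mask;
    the class is a proxy for sequence divergence of the probe set's target
    region between the two species.
    """
    if hi_min <= hyper_max:
        raise ParameterError(f"need hi_min > hyper_max, got {hi_min} <= {hyper_max}")
    counts = retained_counts(mask, layout).per_set
    rows = []
    for ps, kept in counts.items():
        if kept == 0:
            group = "all_masked"
        elif kept <= hyper_max:
            group = "hyper_variable"
        elif kept >= hi_min:
            group = "highly_conserved"
        else:
            group = "intermediate"
        rows.append({"probeset_id": ps, "retained": kept, "group": group})
    return pd.DataFrame(rows).set_index("probeset_id")


def _normalize_class_map(
    class_map: Mapping[str, Iterable[str]] | pd.DataFrame,
) -> dict[str, set[str]]:
    """Accept probeset->classes mappings or (probeset_id, class_id) tables."""
    classes: dict[str, set[str]] = {}
    if isinstance(class_map, pd.DataFrame):
        for col in ("probeset_id", "class_id"):
            if col not in class_map.columns:
                raise InputError(f"class table missing column {col!r}")
        for ps, cls in zip(class_map["probeset_id"], class_map["class_id"]):
            classes.setdefault(str(cls), set()).add(str(ps))
    else:
        for ps, labels in class_map.items():
            for cls in labels:
                classes.setdefault(str(cls), set()).add(str(ps))
    return classes


def fisher_overrep(
    selection: set[str],
    class_map: Mapping[str, Iterable[str]] | pd.DataFrame,
    universe: set[str],
    z_cut: float = 1.0,
) -> pd.DataFrame:
    """Fisher-exact over/under-representation of classes in a gene selection.

    For each class, a two-sided Fisher exact test on the 2x2 table
    (in/out of class) x (in/out of selection) over ``universe``; p-values
    are Bonferroni-corrected over the classes tested and transformed to a
    signed z value z = Phi^-1(1 - bonferroni_p / 2), positive when the
    class is over-represented (observed count above expectation) and
    negative when under-represented. Classes with |z| >= z_cut are flagged.
    z is reported uncapped; any color-scale capping (e.g. at 4) is
    presentation-only.
    """
    universe = {str(g) for g in universe}
    selection = {str(g) for g in selection}
    if not universe:
        raise InputError("empty universe")
    if not selection <= universe:
        raise InputError("selection must be a subset of the universe")
    classes = {
        cls: members & universe
        for cls, members in _normalize_class_map(class_map).items()
    }
    classes = {cls: m for cls, m in classes.items() if m}
    n_classes = len(classes)
    n_sel = len(selection)
    rows = []
    for cls, members in sorted(classes.items()):
        a = len(members & selection)
        b = n_sel - a
        c = len(members) - a
        d = len(universe) - n_sel - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        bonf = min(1.0, p * n_classes)
        expected = n_sel * len(members) / len(universe)
        direction = "over" if a > expected else "under"
        z = float(stats.norm.isf(bonf / 2.0))
        if direction == "under":
            z = -z
        rows.append(
            {
                "class_id": cls,
                "count_in_selection": a,
                "count_in_universe": len(members),
                "expected_in_selection": expected,
                "fisher_p": p,
                "bonferroni_p": bonf,
                "z_value": z,
                "direction": direction,
                "flagged": abs(z) >= z_cut,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "class_id", "count_in_selection", "count_in_universe",
            "expected_in_selection", "fisher_p", "bonferroni_p",
            "z_value", "direction", "flagged",
        ],
    ).set_index("class_id")
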