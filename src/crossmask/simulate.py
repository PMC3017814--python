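"""Synthetic two-species probe-level data with planted ground truth.

The generator emulates the structure the masking method assumes: two
species hybridized to one chip design (S tissues x R replicates each),
shared tissue expression programs, per-probe affinities, and a planted
subset of probes attenuated in the cross-hybridized (CSH) species because
their target regions are inter-species variable (ISV).

Generative model (log2 scale unless noted):

* gene baseline  b_g ~ Normal(8, 2), shared by both species and tissues;
* a fraction ``frac_de`` of genes is differentially expressed: each gets a
  +/- ``de_log2_effect`` shift in one randomly chosen tissue;
* sequence divergence is gene-clustered: gene g draws an ISV probability
  v_g ~ Beta(isv_gene_shape, isv_gene_shape * (1 - m) / m) with mean
  m = ``frac_isv_probes``; each of its probes is ISV with probability v_g.
  The U-shaped Beta puts most genes near fully-conserved and a tail near
  fully-divergent, which is what produces distinct highly-conserved and
  hyper-variable probe-set classes — and what makes an unmasked analysis
  compress fold changes (for a divergent gene the majority of probes sit
  at the background floor, so the robust probe-set fit follows them);
* probe affinity  a_p ~ Normal(0, affinity_sd) and probe response slope
  s_p ~ Normal(1, probe_slope_sd) (clipped to >= 0.2), both properties of
  the physical probe and therefore shared between species: probes differ
  in how strongly and how steeply they respond to their target's abundance;
* per-cell noise  eps ~ Normal(0, noise_sd_log2), independent per species;
* PM signal (linear) = 2**(s_p * mu_gt + a_p + eps); in the CSH species
  the signal of an ISV probe is additionally multiplied by a constant
  attenuation delta_p ~ Uniform(attenuation_range) — sequence divergence is
  a property of the probe, not the sample. The default attenuation is
  near-total: a probe overlapping a genuinely variable region retains
  essentially no specific hybridization, and its measured intensity is
  dominated by the additive non-specific background;
* optical background ~ Normal(background_mean, background_sd), added on the
  linear scale (draws below 1 are redrawn so intensities stay positive);
* MM intensity = background + mm_crosstalk * PM signal.

All draws come from one seeded generator in the fixed order above, so the
output is bit-reproducible for a given parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .io import ChipLayout, IntensityMatrix, ProbeMask, SampleDesign

__all__ = [
    "SimParams",
    "SimTruth",
    "SimDataset",
    "generate_dataset",
    "MaskRecovery",
    "evaluate_mask_recovery",
    "DEImprovement",
    "evaluate_de_improvement",
]

_TISSUE_NAMES = ("nodule", "leaf", "root")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic two-species dataset.

    Defaults emulate the canonical design of 2 species x 3 tissues x 3
    replicates on an 11-probe-per-set chip, with attenuation strong enough
    that an unmasked analysis of the CSH species visibly loses detection
    sensitivity and compresses fold changes.
    """

    n_probesets: int = 2000
    probes_per_set: int = 11
    tissues: int = 3
    replicates: int = 3
    frac_de: float = 0.15
    de_log2_effect: float = 2.0
    frac_isv_probes: float = 0.3
    isv_gene_shape: float = 1.0
    attenuation_range: tuple[float, float] = (0.0001, 0.001)
    affinity_sd: float = 0.5
    probe_slope_sd: float = 0.2
    noise_sd_log2: float = 0.3
    background_mean: float = 40.0
    background_sd: float = 10.0
    mm_crosstalk: float = 0.05
    target_species: str = "Gm"
    csh_species: str = "Pv"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.attenuation_range
        if not (0.0 < lo < hi < 1.0):
            raise ParameterError(
                f"attenuation_range must satisfy 0 < low < high < 1, got {self.attenuation_range}"
            )
        for name in ("frac_de", "frac_isv_probes", "mm_crosstalk"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_probesets", "probes_per_set", "tissues", "replicates"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        for name in ("isv_gene_shape", "affinity_sd", "probe_slope_sd",
                     "noise_sd_log2", "background_mean", "background_sd"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")

    @property
    def tissue_names(self) -> list[str]:
        if self.tissues <= len(_TISSUE_NAMES):
            return list(_TISSUE_NAMES[: self.tissues])
        extra = [f"tissue{i + 1}" for i in range(len(_TISSUE_NAMES), self.tissues)]
        return list(_TISSUE_NAMES) + extra


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth accompanying a synthetic dataset."""

    isv_probes: frozenset[str]
    de_genes: dict[tuple[str, str], frozenset[str]]  # per (tissue_a, tissue_b)
    true_expression: pd.DataFrame  # genes x tissues, log2 means (shared program)

    @property
    def all_de_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.de_genes.values():
            out |= genes
        return frozenset(out)

    def expressed_genes(self, floor: float = 6.0) -> frozenset[str]:
        """Genes whose true mean log2 expression across tissues >= floor."""
        means = self.true_expression.mean(axis=1)
        return frozenset(means.index[means >= floor])


@dataclass
class SimDataset:
    target: IntensityMatrix
    csh: IntensityMatrix
    layout: ChipLayout
    design: SampleDesign
    truth: SimTruth
    params: SimParams


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: tuple[int, ...], low: float = 1.0) -> np.ndarray:
    """Normal draws with values below ``low`` redrawn (keeps intensities > 0)."""
    out = rng.normal(mean, sd, size=size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < low
    return out


def generate_dataset(params: SimParams = SimParams()) -> SimDataset:
    """Generate paired target/CSH intensity matrices plus layout and truth.

    Deterministic given ``params.seed``; both species' PM and MM rows are
    emitted in one matrix per species so detection calls and masking can
    run on the same files.
    """
    rng = np.random.default_rng(params.seed)
    n_genes = params.n_probesets
    k = params.probes_per_set
    n_probes = n_genes * k
    tissues = params.tissue_names
    width = len(str(n_genes))
    genes = [f"PS{str(i + 1).zfill(width)}" for i in range(n_genes)]
    pm_ids = [f"{g}:{j + 1:02d}" for g in genes for j in range(k)]
    mm_ids = [f"{g}:{j + 1:02d}m" for g in genes for j in range(k)]
    layout = ChipLayout(
        pm_probes={g: pm_ids[i * k : (i + 1) * k] for i, g in enumerate(genes)},
        mm_probes={g: mm_ids[i * k : (i + 1) * k] for i, g in enumerate(genes)},
        organism={g: params.target_species for g in genes},
    )

    # 1. gene baselines, shared across species and tissues
    baseline = rng.normal(8.0, 2.0, size=n_genes)
    # 2. DE assignment: gene subset, one tissue each, sign
    n_de = int(round(params.frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_tissue = rng.integers(0, params.tissues, size=n_de)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    mu = np.tile(baseline[:, None], (1, params.tissues))
    mu[de_idx, de_tissue] += de_sign * params.de_log2_effect
    true_expression = pd.DataFrame(mu, index=genes, columns=tissues)
    de_genes: dict[tuple[str, str], frozenset[str]] = {}
    for a, b in combinations(range(params.tissues), 2):
        hit = np.abs(mu[:, a] - mu[:, b]) > 0
        de_genes[(tissues[a], tissues[b])] = frozenset(np.asarray(genes)[hit])

    # 3. probe affinities and response slopes
    affinity = rng.normal(0.0, params.affinity_sd, size=n_probes)
    slope = np.maximum(rng.normal(1.0, params.probe_slope_sd, size=n_probes), 0.2)
    # 4. gene-clustered ISV probes and their attenuations
    m = params.frac_isv_probes
    if m == 0.0:
        isv_flag = np.zeros(n_probes, dtype=bool)
    elif m == 1.0:
        isv_flag = np.ones(n_probes, dtype=bool)
    else:
        shape = params.isv_gene_shape
        v_gene = rng.beta(shape, shape * (1.0 - m) / m, size=n_genes)
        isv_flag = rng.random(n_probes) < np.repeat(v_gene, k)
    isv_idx = np.flatnonzero(isv_flag)
    lo, hi = params.attenuation_range
    delta = np.ones(n_probes)
    delta[isv_idx] = rng.uniform(lo, hi, size=isv_idx.size)
    isv_probes = frozenset(np.asarray(pm_ids)[isv_idx])

    # sample sheet: species x tissue x replicate, design-file order
    rows = []
    for sp in (params.target_species, params.csh_species):
        for t in tissues:
            for r in range(1, params.replicates + 1):
                rows.append(
                    {"sample_id": f"{sp}_{t}_{r}", "species": sp, "tissue": t, "replicate": r}
                )
    design = SampleDesign(pd.DataFrame(rows))

    n_samples = params.tissues * params.replicates
    # per-probe per-sample true log2 mean: gene mean of the sample's tissue
    gene_of_probe = np.repeat(np.arange(n_genes), k)
    tissue_of_sample = np.repeat(np.arange(params.tissues), params.replicates)
    mu_probe_sample = (
        slope[:, None] * mu[gene_of_probe][:, tissue_of_sample] + affinity[:, None]
    )

    def species_matrix(attenuate: bool, species: str) -> pd.DataFrame:
        # 5/6. per-cell noise (target first, then CSH: call order fixes this)
        eps = rng.normal(0.0, params.noise_sd_log2, size=(n_probes, n_samples))
        signal = 2.0 ** (mu_probe_sample + eps)
        if attenuate:
            signal = signal * delta[:, None]
        # 7. backgrounds: PM then MM per species
        bg_pm = _truncated_normal(rng, params.background_mean, params.background_sd,
                                  (n_probes, n_samples))
        bg_mm = _truncated_normal(rng, params.background_mean, params.background_sd,
                                  (n_probes, n_samples))
        pm = signal + bg_pm
        mm = bg_mm + params.mm_crosstalk * signal
        sub = design.subset(species)
        return pd.DataFrame(
            np.vstack([pm, mm]), index=pm_ids + mm_ids, columns=sub.sample_ids
        )

    target_vals = species_matrix(False, params.target_species)
    csh_vals = species_matrix(True, params.csh_species)
    target = IntensityMatrix(target_vals, design.subset(params.target_species))
    csh = IntensityMatrix(csh_vals, design.subset(params.csh_species))
    truth = SimTruth(isv_probes=isv_probes, de_genes=de_genes, true_expression=true_expression)
    return SimDataset(target=target, csh=csh, layout=layout, design=design,
                      truth=truth, params=params)


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskRecovery:
    """Confusion-matrix summary of a mask against the planted ISV probes."""

    sensitivity: float  # masked ISV probes / all ISV probes
    specificity: float  # retained conserved probes / all conserved probes
    precision: float  # masked ISV probes / all masked probes
    n_isv: int
    n_conserved: int


def evaluate_mask_recovery(
    mask: ProbeMask,
    truth: SimTruth,
    layout: ChipLayout,
    expressed_only: bool = True,
    expression_floor: float = 6.0,
) -> MaskRecovery:
    """Score a mask as a classifier of planted ISV probes.

    When ``expressed_only`` the evaluation is restricted to probes of genes
    whose true mean log2 expression is at least ``expression_floor``:
    probes of unexpressed genes are unidentifiable by any intensity rule
    (their signals sit in the background whether or not the target region
    diverged). NaN metrics signal an empty denominator.
    """
    probes: set[str] = set()
    if expressed_only:
        expressed = truth.expressed_genes(expression_floor)
        for g in expressed:
            if g in layout.pm_probes:
                probes.update(layout.pm_probes[g])
    else:
        probes = set(layout.all_pm_probes)
    isv = truth.isv_probes & probes
    conserved = probes - truth.isv_probes
    masked = mask.masked_probes & probes
    sens = len(masked & isv) / len(isv) if isv else float("nan")
    spec = len(conserved - masked) / len(conserved) if conserved else float("nan")
    prec = len(masked & isv) / len(masked) if masked else float("nan")
    return MaskRecovery(sensitivity=sens, specificity=spec, precision=prec,
                        n_isv=len(isv), n_conserved=len(conserved))


@dataclass(frozen=True)
class DEImprovement:
    """Detection sensitivity and fold-change compression, before vs after."""

    sensitivity_before: float
    sensitivity_after: float
    mean_abs_log2ratio_before: float
    mean_abs_log2ratio_after: float
    n_true_de: int


def evaluate_de_improvement(
    de_before: pd.DataFrame,
    de_after: pd.DataFrame,
    truth: SimTruth,
) -> DEImprovement:
    """Compare two differential-expression tables against planted truth.

    Both tables must come from :func:`crossmask.analysis.anova_de` over the
    same probe-set universe (reindex the masked table over the full
    universe, with ``significant=False`` for absent probe sets, before
    calling). Sensitivity is the fraction of true DE genes flagged
    significant; the mean |log2 ratio| is taken over (gene, tissue pair)
    combinations that are truly differential, so an attenuation-induced
    compression shows up as a smaller value before masking.
    """
    if set(de_before.index) != set(de_after.index):
        raise InputError("the two DE tables cover different probe-set universes")
    universe = set(de_before.index)
    true_de = truth.all_de_genes & universe
    if not true_de:
        return DEImprovement(float("nan"), float("nan"), float("nan"), float("nan"), 0)

    def sensitivity(de: pd.DataFrame) -> float:
        return float(de.loc[sorted(true_de), "significant"].mean())

    def mean_abs_ratio(de: pd.DataFrame) -> float:
        vals = []
        for (a, b), genes in truth.de_genes.items():
            col = f"log2_{a}_vs_{b}"
            if col not in de.columns:
                col = f"log2_{b}_vs_{a}"
                if col not in de.columns:
                    raise InputError(f"DE table lacks a pairwise column for ({a}, {b})")
            g = sorted(genes & universe)
            if g:
                vals.append(de.loc[g, col].abs())
        return float(pd.concat(vals).mean()) if vals else float("nan")

    return DEImprovement(
        sensitivity_before=sensitivity(de_before),
        sensitivity_after=sensitivity(de_after),
        mean_abs_log2ratio_before=mean_abs_ratio(de_before),
        mean_abs_log2ratio_after=mean_abs_ratio(de_after),
        n_true_de=len(true_de),
    )
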