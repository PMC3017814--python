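"""Intensity-threshold masking of probes targeting inter-species variable regions.

A probe interrogates the same transcript in Ts = R x S hybridizations of
the non-target (cross-hybridized) species: S tissue types with R replicates
each. If the probe's target region is conserved, its signal should clear a
modest intensity threshold in at least the R samples of the tissue where
the transcript is expressed. The rule is therefore:

    retain the probe  iff  at least R of the Ts samples exceed the threshold;
    otherwise mask all Ts of its values.

Equivalently, a probe is masked when at least a fraction
P = (Ts - R + 1) / Ts of the samples are at or below the threshold; for the
canonical 3-tissue x 3-replicate design P = 7/9, displayed as 0.78.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import DesignError, ParameterError
from .io import ChipLayout, IntensityMatrix, ProbeMask, SampleDesign

__all__ = [
    "mask_fraction",
    "MaskRuleParams",
    "build_mask",
    "mask_series",
    "RetainedCounts",
    "retained_counts",
    "DEFAULT_THRESHOLDS",
]

# Default sweep grid of linear-scale signal intensity thresholds.
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    5, 7, 8, 10, 13, 15, 20, 30, 40, 60, 80, 100, 120, 160, 320, 640, 1280, 2560,
)


def mask_fraction(Ts: int, R: int, S: int) -> Fraction:
    """Masking fraction P = (Ts - R + 1) / Ts.

    The smallest fraction of a species' samples that, when at or below the
    intensity threshold, forces the probe to be masked — the complement of
    the retain-iff-at-least-R-above rule. Returned as an exact
    :class:`fractions.Fraction`; round to two decimals for display
    (e.g. Ts=9, R=3 -> 7/9 -> 0.78).
    """
    if Ts < 1 or R < 1 or S < 1:
        raise ParameterError(f"Ts, R, S must be positive, got {Ts}, {R}, {S}")
    if R > Ts:
        raise ParameterError(f"replicate count R={R} exceeds total samples Ts={Ts}")
    return Fraction(Ts - R + 1, Ts)


@dataclass(frozen=True)
class MaskRuleParams:
    """Parameters of the masking rule for one species.

    Ts: total sample files for the species; R: replicates per tissue;
    S: number of tissue types; threshold: linear-scale intensity cutoff
    applied to background-corrected, quantile-normalized intensities.
    """

    Ts: int
    R: int
    S: int
    threshold: float

    def __post_init__(self) -> None:
        mask_fraction(self.Ts, self.R, self.S)  # validates Ts, R, S
        if self.threshold < 0:
            raise ParameterError(f"threshold must be non-negative, got {self.threshold}")

    @property
    def p_fraction(self) -> Fraction:
        return mask_fraction(self.Ts, self.R, self.S)

    @classmethod
    def from_design(
        cls, design: SampleDesign, species: str, threshold: float
    ) -> "MaskRuleParams":
        ts, r, s, balanced = design.balance(species)
        if not balanced:
            raise DesignError(
                f"species {species!r} has an unbalanced design; pass Ts/R/S explicitly"
            )
        return cls(Ts=ts, R=r, S=s, threshold=threshold)


def build_mask(
    matrix: IntensityMatrix,
    layout: ChipLayout,
    params: MaskRuleParams,
    species: str | None = None,
    created_from: str = "",
) -> ProbeMask:
    """Build the probe mask for one threshold from one species' samples.

    ``matrix`` must hold exactly the Ts samples of the species, already
    background-corrected and quantile-normalized (the scale on which
    thresholds are defined). A probe is masked iff fewer than R of its
    intensities are strictly above the threshold. Only PM probes known to
    the layout participate; MM probes ride along with their PM partner's
    probe set and are never masked themselves.
    """
    if matrix.n_samples != params.Ts:
        raise DesignError(
            f"matrix has {matrix.n_samples} samples but the rule expects Ts={params.Ts}"
        )
    if species is None:
        species_in = matrix.design.species
        species = species_in[0] if len(species_in) == 1 else ""
    pm_probes = layout.all_pm_probes
    probe_ids = np.asarray(matrix.values.index)
    in_layout = np.fromiter((p in pm_probes for p in probe_ids), bool, len(probe_ids))
    above = (matrix.values.to_numpy() > params.threshold).sum(axis=1)
    masked = probe_ids[in_layout & (above < params.R)]
    return ProbeMask(
        masked_probes=frozenset(masked),
        threshold=float(params.threshold),
        species=species,
        p_fraction=float(params.p_fraction),
        created_from=created_from,
    )


def mask_series(
    matrix: IntensityMatrix,
    layout: ChipLayout,
    thresholds: list[float],
    params: MaskRuleParams | None = None,
    species: str | None = None,
) -> list[ProbeMask]:
    """One mask per threshold; masks are nested along increasing thresholds.

    ``thresholds`` must be strictly increasing. If ``params`` is omitted the
    rule is derived from the matrix's (single-species, balanced) design.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ParameterError(f"thresholds must be strictly increasing: {thresholds}")
    if params is None:
        species_in = matrix.design.species
        if len(species_in) != 1:
            raise DesignError("matrix spans several species; pass params explicitly")
        base = MaskRuleParams.from_design(matrix.design, species_in[0], 0.0)
    else:
        base = params
    return [
        build_mask(
            matrix,
            layout,
            MaskRuleParams(Ts=base.Ts, R=base.R, S=base.S, threshold=t),
            species=species,
        )
        for t in thresholds
    ]


@dataclass(frozen=True)
class RetainedCounts:
    """Probe- and probe-set-level retention totals for one mask."""

    n_probes_retained: int
    n_probesets_retained: int
    per_set: dict[str, int]  # probeset_id -> retained-probe count (0..k)


def retained_counts(mask: ProbeMask, layout: ChipLayout) -> RetainedCounts:
    """Count retained PM probes per probe set and overall.

    A probe set counts as retained iff at least one of its PM probes is
    retained (the minimum needed to produce an expression value).
    """
    unknown = mask.masked_probes - layout.all_probes
    if unknown:
        raise DesignError(f"mask references probes absent from layout: {sorted(unknown)[:5]}")
    per_set: dict[str, int] = {}
    total = 0
    for ps, probes in layout.pm_probes.items():
        kept = sum(1 for p in probes if p not in mask.masked_probes)
        per_set[ps] = kept
        total += kept
    n_sets = sum(1 for k in per_set.values() if k >= 1)
    return RetainedCounts(
        n_probes_retained=total, n_probesets_retained=n_sets, per_set=per_set
    )
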