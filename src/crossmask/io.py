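"""Interchange formats and in-memory containers for probe-level chip data.

All files are plain tab-separated UTF-8 text with a '.' decimal separator.
Intensities are stored on the linear scale; log2 happens only inside
summarization. Probe IDs are free-form strings; when a source table lacks
globally unique probe names the convention ``<probeset_id>:<probe_index>``
guarantees that every probe belongs to exactly one probe set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, LayoutReferenceError

__all__ = [
    "ChipLayout",
    "SampleDesign",
    "IntensityMatrix",
    "ProbeMask",
    "ExpressionMatrix",
    "read_design",
    "write_design",
    "read_intensities",
    "write_intensities",
    "read_layout",
    "write_layout",
    "read_mask_file",
    "write_mask_file",
    "read_expression",
    "write_expression",
]


# ---------------------------------------------------------------------------
# Chip layout
# ---------------------------------------------------------------------------

@dataclass
class ChipLayout:
    """Maps probe-set IDs to their ordered perfect-match (PM) probes.

    Parameters
    ----------
    pm_probes
        ``probeset_id -> ordered list of PM probe IDs`` (order is the
        probe_index order and is stable across reads/writes).
    mm_probes
        Optional ``probeset_id -> ordered list of mismatch (MM) probe IDs``,
        parallel to ``pm_probes`` for every probe set present.
    organism
        Optional ``probeset_id -> organism tag`` used e.g. to exclude
        pathogen control probe sets from differential-expression testing.
    """

    pm_probes: dict[str, list[str]]
    mm_probes: dict[str, list[str]] = field(default_factory=dict)
    organism: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ps, probes in self.pm_probes.items():
            if not probes:
                raise FormatError(f"probe set {ps!r} has no PM probes")
            for p in probes:
                if p in seen:
                    raise FormatError(
                        f"probe {p!r} assigned to both probe sets "
                        f"{seen[p]!r} and {ps!r}"
                    )
                seen[p] = ps
        for ps, probes in self.mm_probes.items():
            if ps not in self.pm_probes:
                raise FormatError(f"MM probes for unknown probe set {ps!r}")
            if len(probes) != len(self.pm_probes[ps]):
                raise FormatError(
                    f"probe set {ps!r}: {len(probes)} MM probes for "
                    f"{len(self.pm_probes[ps])} PM probes"
                )
            for p in probes:
                if p in seen:
                    raise FormatError(
                        f"probe {p!r} assigned to both probe sets "
                        f"{seen[p]!r} and {ps!r}"
                    )
                seen[p] = ps
        self._probe_to_set = seen
        self._all_pm = frozenset(p for probes in self.pm_probes.values() for p in probes)
        self._all = frozenset(seen)

    # -- derived views ------------------------------------------------------

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.pm_probes)

    @property
    def n_probesets(self) -> int:
        return len(self.pm_probes)

    @property
    def all_pm_probes(self) -> frozenset[str]:
        return self._all_pm

    @property
    def all_probes(self) -> frozenset[str]:
        return self._all

    def probeset_of(self, probe_id: str) -> str:
        try:
            return self._probe_to_set[probe_id]
        except KeyError:
            raise LayoutReferenceError(f"unknown probe ID {probe_id!r}") from None

    def organism_of(self, probeset_id: str) -> str:
        return self.organism.get(probeset_id, "")


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Sample sheet: one row per hybridization (species, tissue, replicate)."""

    table: pd.DataFrame  # columns: sample_id, species, tissue, replicate

    REQUIRED = ("sample_id", "species", "tissue", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing columns {missing}")
        t = self.table.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        t["sample_id"] = t["sample_id"].astype(str)
        t["species"] = t["species"].astype(str)
        t["tissue"] = t["tissue"].astype(str)
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] < 1).any():
            raise FormatError("replicate numbers must be positive integers")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample ID {dup!r} in design")
        trip = t[["species", "tissue", "replicate"]]
        if trip.duplicated().any():
            raise FormatError("duplicate (species, tissue, replicate) triple in design")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.table["species"]))

    def tissues(self, species: str | None = None) -> list[str]:
        t = self.table if species is None else self.table[self.table["species"] == species]
        return list(dict.fromkeys(t["tissue"]))

    def subset(self, species: str) -> "SampleDesign":
        sub = self.table[self.table["species"] == species]
        if sub.empty:
            raise DesignError(f"no samples for species {species!r}")
        return SampleDesign(sub.reset_index(drop=True))

    def restrict(self, sample_ids: Iterable[str]) -> "SampleDesign":
        """Narrow to the given samples, keeping design row order."""
        wanted = set(sample_ids)
        sub = self.table[self.table["sample_id"].isin(wanted)]
        if sub.empty:
            raise DesignError("no design rows match the requested samples")
        return SampleDesign(sub.reset_index(drop=True))

    def samples_for(self, species: str | None = None, tissue: str | None = None) -> list[str]:
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return t["sample_id"].tolist()

    def balance(self, species: str) -> tuple[int, int, int, bool]:
        """Return (Ts, R, S, balanced) for one species.

        Ts is the total number of sample files for the species, S the number
        of tissue types, and R the per-tissue replicate count. ``balanced``
        is True iff every tissue has the same replicate count, in which case
        Ts == R * S.
        """
        sub = self.table[self.table["species"] == species]
        if sub.empty:
            raise DesignError(f"no samples for species {species!r}")
        counts = sub.groupby("tissue", sort=False)["sample_id"].count()
        ts = int(len(sub))
        s = int(len(counts))
        balanced = counts.nunique() == 1
        r = int(counts.iloc[0]) if balanced else int(counts.min())
        return ts, r, s, balanced


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Probe x sample grid of strictly positive linear-scale intensities."""

    values: pd.DataFrame  # index: probe IDs, columns: sample IDs
    design: SampleDesign

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate probe ID {dup!r} in intensity matrix")
        matrix_samples = list(v.columns)
        design_samples = self.design.sample_ids
        extra = set(matrix_samples) - set(design_samples)
        if extra:
            raise DesignError(
                f"samples {sorted(extra)} in matrix are absent from the design"
            )
        missing = set(design_samples) - set(matrix_samples)
        if missing:
            raise DesignError(
                f"design samples {sorted(missing)} are absent from the matrix"
            )
        # column order follows the design
        v = v.loc[:, design_samples].astype(float)
        arr = v.to_numpy()
        bad = ~np.isfinite(arr) | (arr <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive or missing intensity at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}: {arr[i, j]!r}"
            )
        self.values = v

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, species: str) -> "IntensityMatrix":
        sub = self.design.subset(species)
        return IntensityMatrix(self.values.loc[:, sub.sample_ids].copy(), sub)

    def with_values(self, values: pd.DataFrame) -> "IntensityMatrix":
        return IntensityMatrix(values, self.design)


# ---------------------------------------------------------------------------
# Probe mask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeMask:
    """Set of probes excluded from summarization at one intensity threshold."""

    masked_probes: frozenset[str]
    threshold: float
    species: str
    p_fraction: float
    created_from: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "masked_probes", frozenset(self.masked_probes))
        if not (0.0 < self.p_fraction <= 1.0):
            raise ValueError(f"p_fraction must be in (0, 1], got {self.p_fraction}")
        if self.threshold < 0:
            raise ValueError(f"threshold must be non-negative, got {self.threshold}")

    def __len__(self) -> int:
        return len(self.masked_probes)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.masked_probes

    @classmethod
    def empty(cls, species: str = "", threshold: float = 0.0,
              p_fraction: float = 1.0, created_from: str = "") -> "ProbeMask":
        return cls(frozenset(), threshold, species, p_fraction, created_from)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe-set x sample grid of log2 expression after summarization."""

    values: pd.DataFrame  # index: probeset IDs, columns: sample IDs
    design: SampleDesign
    probes_used: pd.Series  # per-probe-set count of retained probes

    def __post_init__(self) -> None:
        design_samples = self.design.sample_ids
        if set(self.values.columns) != set(design_samples):
            raise DesignError("expression columns do not match the design sample set")
        self.values = self.values.loc[:, design_samples].astype(float)
        self.probes_used = (
            self.probes_used.reindex(self.values.index).astype(int).rename("probes_used")
        )
        if (self.probes_used < 1).any():
            bad = self.probes_used.index[self.probes_used < 1][0]
            raise ValueError(
                f"probe set {bad!r} present with probes_used < 1; probe sets "
                "with zero retained probes must be absent from the matrix"
            )

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, species: str) -> "ExpressionMatrix":
        sub = self.design.subset(species)
        return ExpressionMatrix(
            self.values.loc[:, sub.sample_ids].copy(), sub, self.probes_used.copy()
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design TSV (sample_id, species, tissue, replicate)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate" in table.columns:
        try:
            table["replicate"] = table["replicate"].astype(int)
        except ValueError as exc:
            raise FormatError(f"non-integer replicate in {path}: {exc}") from None
    return SampleDesign(table)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_intensities(path: str | Path, design_path: str | Path | SampleDesign) -> IntensityMatrix:
    """Read a probe x sample intensity TSV plus its sample design.

    The TSV has a header row of sample IDs and probe IDs in the first
    column. Sample (column) order in the returned matrix follows the design
    file order, not the matrix file order. A design covering more samples
    than the matrix (e.g. both species of a two-species design against a
    one-species intensity file) is narrowed to the matrix's samples; a
    matrix sample missing from the design is an error.
    """
    design = design_path if isinstance(design_path, SampleDesign) else read_design(design_path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    if set(values.columns) < set(design.sample_ids):
        design = design.restrict(values.columns)
    values.index = values.index.astype(str)
    values.index.name = None
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"duplicate probe ID {dup!r} in {path}")
    return IntensityMatrix(values, design)


def write_intensities(matrix: IntensityMatrix, path: str | Path) -> None:
    matrix.values.rename_axis(index="probe_id").to_csv(path, sep="\t")


def read_layout(path: str | Path) -> ChipLayout:
    """Read a chip layout TSV.

    Columns: probeset_id, probe_id, probe_index, optional mm_probe_id,
    optional organism. Probe order within a probe set follows probe_index,
    which must be contiguous from 1; input row order is not semantic.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probeset_id", "probe_id", "probe_index"):
        if col not in table.columns:
            raise FormatError(f"layout file {path} missing column {col!r}")
    try:
        table["probe_index"] = table["probe_index"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer probe_index in {path}: {exc}") from None

    pm: dict[str, list[str]] = {}
    mm: dict[str, list[str]] = {}
    organism: dict[str, str] = {}
    has_mm = "mm_probe_id" in table.columns
    has_org = "organism" in table.columns
    for ps, grp in table.groupby("probeset_id", sort=False):
        grp = grp.sort_values("probe_index")
        idx = grp["probe_index"].to_numpy()
        if idx[0] != 1 or not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise FormatError(
                f"probe set {ps!r}: probe_index must run 1..{len(idx)} "
                f"without gaps, got {idx.tolist()}"
            )
        pm[ps] = grp["probe_id"].tolist()
        if has_mm:
            mms = grp["mm_probe_id"].tolist()
            if not any(pd.isna(m) for m in mms):
                mm[ps] = [str(m) for m in mms]
        if has_org:
            tags = set(grp["organism"].dropna())
            if len(tags) > 1:
                raise FormatError(f"probe set {ps!r} carries multiple organism tags")
            if tags:
                organism[ps] = tags.pop()
    return ChipLayout(pm, mm, organism)


def write_layout(layout: ChipLayout, path: str | Path) -> None:
    rows = []
    for ps, probes in layout.pm_probes.items():
        mms = layout.mm_probes.get(ps)
        org = layout.organism.get(ps, "")
        for i, p in enumerate(probes):
            rows.append(
                {
                    "probeset_id": ps,
                    "probe_id": p,
                    "probe_index": i + 1,
                    "mm_probe_id": mms[i] if mms else "",
                    "organism": org,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_MASK_META_KEYS = ("threshold", "species", "p_fraction", "created_from")


def write_mask_file(mask: ProbeMask, path: str | Path, layout: ChipLayout) -> None:
    """Write a mask file: '#key=value' header lines then sorted probe rows.

    Each data row is ``probeset_id <TAB> probe_id``; rows are sorted
    lexicographically so write -> read -> write is byte-identical. The
    layout is needed to resolve each probe's probe set.
    """
    lines = [
        f"#threshold={mask.threshold!r}",
        f"#species={mask.species}",
        f"#p_fraction={mask.p_fraction!r}",
        f"#created_from={mask.created_from}",
    ]
    rows = sorted((layout.probeset_of(p), p) for p in mask.masked_probes)
    lines += [f"{ps}\t{p}" for ps, p in rows]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_mask_file(path: str | Path, layout: ChipLayout | None = None) -> ProbeMask:
    """Read a mask file; validates probe IDs against ``layout`` if given."""
    meta: dict[str, str] = {}
    probes: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key] = value
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"malformed mask line {line!r} in {path}")
        ps, probe = parts
        if layout is not None:
            if probe not in layout.all_probes:
                raise LayoutReferenceError(f"unknown probe ID {probe!r} in {path}")
            if layout.probeset_of(probe) != ps:
                raise LayoutReferenceError(
                    f"probe {probe!r} listed under {ps!r} but belongs to "
                    f"{layout.probeset_of(probe)!r}"
                )
        probes.append(probe)
    for key in ("threshold", "species", "p_fraction"):
        if key not in meta:
            raise FormatError(f"mask file {path} missing '#{key}=' header")
    return ProbeMask(
        masked_probes=frozenset(probes),
        threshold=float(meta["threshold"]),
        species=meta["species"],
        p_fraction=float(meta["p_fraction"]),
        created_from=meta.get("created_from", ""),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression TSV plus a '<path>.probes_used' companion file."""
    expr.values.rename_axis(index="probeset_id").to_csv(path, sep="\t")
    expr.probes_used.rename_axis(index="probeset_id").to_frame("probes_used").to_csv(
        f"{path}.probes_used", sep="\t"
    )


def read_expression(path: str | Path, design: str | Path | SampleDesign) -> ExpressionMatrix:
    design = design if isinstance(design, SampleDesign) else read_design(design)
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    used = pd.read_csv(f"{path}.probes_used", sep="\t", index_col=0)["probes_used"]
    used.index = used.index.astype(str)
    used.index.name = None
    return ExpressionMatrix(values, design, used)
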