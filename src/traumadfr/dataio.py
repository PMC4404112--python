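"""Domain types and I/O for expression matrices, sample metadata, cytokine panels
and clinical count tables.

All expression values are assumed to be normalized log2-scale intensities;
normalization itself is upstream of this package. Fold-change computations
convert to the linear scale explicitly (see :mod:`traumadfr.selection`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("traumadfr")

AGE_GROUPS = ("aged", "young", "control")
OUTCOME_CLASSES = ("complicated", "intermediate", "uncomplicated", "control")
#: default post-injury sampling grid, days
TIMEPOINT_GRID_DAYS = (0.5, 1.0, 4.0, 7.0, 14.0, 21.0, 28.0)
#: cytokine sampling grid, hours
CYTOKINE_GRID_HOURS = (12, 24, 96, 185, 336, 504, 672)
DEFAULT_ANALYTES = ("IL-6", "IL-8", "IL-10", "IL-1b", "IP-10", "MCP-1", "TNF-a")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, missing sentinels, bad shape)."""


class ParseError(ValueError):
    """A cell could not be parsed; message names the offending row/column."""


class InsufficientDataError(ValueError):
    """Too few samples/observations for the requested operation."""


class DegenerateReferenceError(ValueError):
    """Every control probe has zero variance; no reference can be built."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe-set × sample matrix of normalized log2 expression values."""

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_probes, n_samples), float64

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} ids present")
        if not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None
        return self.values[:, j]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.probe_ids, tuple(sample_ids), self.values[:, idx])

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in pos]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        idx = [pos[p] for p in probe_ids]
        return ExpressionMatrix(tuple(probe_ids), self.sample_ids, self.values[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.probe_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class SampleMeta:
    """Clinical annotation of one expression sample.

    ``timepoint_days`` is days post-injury; healthy controls carry ``None``.
    ``ais`` is the per-body-region abbreviated injury score vector.
    """

    sample_id: str
    patient_id: str
    age_group: str
    outcome_class: str
    timepoint_days: float | None = None
    gender: str | None = None
    ais: tuple[int, ...] = ()
    survived_28d: bool | None = None

    def __post_init__(self):
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age_group {self.age_group!r}")
        if self.outcome_class not in OUTCOME_CLASSES:
            raise ValueError(f"unknown outcome_class {self.outcome_class!r}")
        if self.age_group == "control":
            if self.outcome_class != "control" or self.timepoint_days is not None:
                raise ValueError("controls must have outcome_class=control and no timepoint")
        elif self.timepoint_days is not None and self.timepoint_days < 0:
            raise ValueError("timepoint_days must be non-negative")


def check_metadata(metadata: Sequence[SampleMeta],
                   timepoint_grid: Iterable[float] = TIMEPOINT_GRID_DAYS) -> None:
    """Validate a metadata set: unique sample ids, timepoints on the grid."""
    ids = [m.sample_id for m in metadata]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_id in metadata")
    grid = set(float(t) for t in timepoint_grid)
    for m in metadata:
        if m.timepoint_days is not None and float(m.timepoint_days) not in grid:
            raise ValueError(
                f"sample {m.sample_id}: timepoint {m.timepoint_days} not on grid {sorted(grid)}"
            )


@dataclass(frozen=True)
class ReferenceStats:
    """Per-probe healthy-control mean ``M_i`` and variance ``V_i``.

    Variances below ``variance_floor`` were raised to the floor so the
    standardized deviations that feed the distance-from-reference score stay
    bounded for probes with near-degenerate control spread.
    """

    probe_ids: tuple[str, ...]
    means: np.ndarray
    variances: np.ndarray
    variance_floor: float
    n_controls: int

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "variances", np.asarray(self.variances, dtype=float))
        if self.means.shape != (len(self.probe_ids),) or \
                self.variances.shape != (len(self.probe_ids),):
            raise FormatError("reference stats shape mismatch")
        if self.n_controls < 2:
            raise InsufficientDataError("reference requires >=2 controls")
        if not np.all(self.variances > 0):
            raise DegenerateReferenceError("non-positive variance after flooring")


@dataclass(frozen=True)
class CytokineRecord:
    patient_id: str
    age_group: str
    analyte: str
    timepoint_hours: float
    concentration: float  # pg/mL

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class CytokinePanel:
    """Long-format longitudinal cytokine concentrations (pg/mL).

    Missing patient × timepoint cells are simply absent rows (dropout).
    """

    records: list[CytokineRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.patient_id, r.age_group, r.analyte, r.timepoint_hours, r.concentration)
             for r in self.records],
            columns=["patient_id", "age_group", "analyte", "timepoint_hours",
                     "concentration"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CytokinePanel":
        recs = [CytokineRecord(str(r.patient_id), str(r.age_group), str(r.analyte),
                               float(r.timepoint_hours), float(r.concentration))
                for r in df.itertuples(index=False)]
        return cls(recs)


@dataclass(frozen=True)
class ClinicalCountTable:
    """2-group × K-category clinical count table (e.g. discharge dispositions)."""

    row_labels: tuple[str, ...]
    group_labels: tuple[str, str]
    counts: np.ndarray  # shape (K, 2), non-negative ints
    group_totals: tuple[int, int]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), 2):
            raise FormatError("count table shape mismatch")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if any(t <= 0 for t in self.group_totals):
            raise ValueError("group totals must be positive")
        for j in range(2):
            if counts[:, j].sum() > self.group_totals[j]:
                raise ValueError(
                    f"column {self.group_labels[j]!r} counts exceed its group total"
                )


# ---------------------------------------------------------------------------
# Readers / writers.  One canonical dialect: tab-delimited UTF-8, header row of
# sample ids, first column probe ids.


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited probe × sample expression matrix.

    Raises :class:`FormatError` on duplicate ids and :class:`ParseError`
    (naming the offending row and column) on non-numeric cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe_ids = tuple(str(p) for p in df.index)
    sample_ids = tuple(str(s) for s in df.columns)
    if len(set(probe_ids)) != len(probe_ids):
        raise FormatError(f"{path.name}: duplicate probe ids")
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path.name}: duplicate sample ids")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{path.name}: non-numeric value at probe {bad[0]!r}, sample {col!r}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path.name}: missing value at probe {probe_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    m = ExpressionMatrix(probe_ids, sample_ids, values)
    logger.info("read expression matrix %s: %d probes x %d samples",
                path.name, m.n_probes, m.n_samples)
    return m


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(Path(path), sep="\t", index_label="probe_id",
                             float_format="%.10g")


_META_COLS = ["sample_id", "patient_id", "age_group", "outcome_class",
              "timepoint_days", "gender", "ais", "survived_28d"]


def write_sample_metadata(metadata: Sequence[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metadata:
        rows.append({
            "sample_id": m.sample_id,
            "patient_id": m.patient_id,
            "age_group": m.age_group,
            "outcome_class": m.outcome_class,
            "timepoint_days": "" if m.timepoint_days is None else m.timepoint_days,
            "gender": m.gender or "",
            "ais": ";".join(str(a) for a in m.ais),
            "survived_28d": "" if m.survived_28d is None else int(m.survived_28d),
        })
    pd.DataFrame(rows, columns=_META_COLS).to_csv(Path(path), sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str).fillna("")
    out = []
    for r in df.itertuples(index=False):
        out.append(SampleMeta(
            sample_id=r.sample_id,
            patient_id=r.patient_id,
            age_group=r.age_group,
            outcome_class=r.outcome_class,
            timepoint_days=None if r.timepoint_days == "" else float(r.timepoint_days),
            gender=r.gender or None,
            ais=tuple(int(x) for x in r.ais.split(";")) if r.ais else (),
            survived_28d=None if r.survived_28d == "" else bool(int(float(r.survived_28d))),
        ))
    check_metadata(out)
    return out


def write_cytokine_panel(panel: CytokinePanel, path: str | Path) -> None:
    panel.to_frame().to_csv(Path(path), sep="\t", index=False)


def read_cytokine_panel(path: str | Path) -> CytokinePanel:
    return CytokinePanel.from_frame(pd.read_csv(Path(path), sep="\t"))


def read_geo_series_matrix(path: str | Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Parse a GEO series-matrix text file (optional convenience reader).

    Returns the expression matrix plus a DataFrame of whatever ``!Sample_*``
    annotation lines the file carries (one row per annotation key, quoted
    values stripped). Requires the ``!series_matrix_table_begin``/``_end``
    sentinels.
    """
    path = Path(path)
    meta_rows: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table, saw_begin = True, True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table, saw_end = False, True
            continue
        if in_table:
            if line.strip():
                table_lines.append(line)
        elif line.startswith("!Sample_"):
            parts = [p.strip().strip('"') for p in line.split("\t")]
            key = parts[0][len("!Sample_"):]
            if key in meta_rows:  # repeated keys (characteristics_ch1) get suffixes
                n = sum(1 for k in meta_rows if k == key or k.startswith(key + "."))
                key = f"{key}.{n}"
            meta_rows[key] = parts[1:]
    if not (saw_begin and saw_end):
        raise FormatError(f"{path.name}: missing series-matrix table sentinels")
    if not table_lines:
        raise FormatError(f"{path.name}: empty series-matrix table")
    header = [h.strip().strip('"') for h in table_lines[0].split("\t")]
    sample_ids, probe_ids, rows = tuple(header[1:]), [], []
    for line in table_lines[1:]:
        parts = line.split("\t")
        probe_ids.append(parts[0].strip().strip('"'))
        rows.append([float(x) for x in parts[1:]])
    matrix = ExpressionMatrix(tuple(probe_ids), sample_ids, np.array(rows))
    annotations = pd.DataFrame(meta_rows, index=list(sample_ids)).T
    return matrix, annotations


# ---------------------------------------------------------------------------


def build_reference(matrix: ExpressionMatrix,
                    control_sample_ids: Sequence[str],
                    floor_quantile: float = 0.10) -> ReferenceStats:
    """Per-probe control mean and (n−1)-denominator variance, with flooring.

    Variances below the ``floor_quantile``-th quantile of all *positive*
    per-probe variances are raised to that floor; this keeps standardized
    deviations finite for probes whose control spread is degenerate.
    """
    if len(control_sample_ids) < 2:
        raise InsufficientDataError("build_reference needs >=2 control samples")
    sub = matrix.subset_samples(list(control_sample_ids))
    means = sub.values.mean(axis=1)
    variances = sub.values.var(axis=1, ddof=1)
    positive = variances[variances > 0]
    if positive.size == 0:
        raise DegenerateReferenceError("all control variances are zero")
    floor = float(np.quantile(positive, floor_quantile)) if floor_quantile > 0 else 0.0
    n_floored = int(np.sum(variances < floor)) if floor > 0 else 0
    if floor > 0:
        variances = np.maximum(variances, floor)
    elif np.any(variances <= 0):
        raise DegenerateReferenceError(
            "zero-variance probes present and floor_quantile=0; "
            "raise floor_quantile or drop the probes"
        )
    logger.info("reference: %d controls, variance floor %.4g (%d probes floored)",
                len(control_sample_ids), floor, n_floored)
    return ReferenceStats(matrix.probe_ids, means, variances,
                          variance_floor=floor, n_controls=len(control_sample_ids))
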