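"""The distance-from-reference (DFR) genomic perturbation score.

For a patient sample with expression ``e_i`` and healthy-control reference
mean ``M_i`` and variance ``V_i`` over a probe universe ``S``::

    DFR = sum_{i in S} (e_i - M_i)**2 / V_i

One scalar per patient-timepoint summarizes the total transcriptomic
deviation from baseline, up- and downregulation alike. The score may be
natural-log transformed (log of the sum); reported values here follow the
no-log convention, with a ×10³ display divisor applied only at formatting
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataio import ExpressionMatrix, ReferenceStats, SampleMeta

__all__ = ["DFRScore", "TrajectorySummary", "dfr_score", "dfr_scores",
           "dfr_trajectories", "dfr_null_expectation_per_probe"]


class EmptySubsetError(ValueError):
    """The requested probe subset is empty."""


class AlignmentError(ValueError):
    """Probe subset not covered by both matrix and reference."""


@dataclass(frozen=True)
class DFRScore:
    sample_id: str
    patient_id: str
    timepoint_days: float | None
    score: float
    n_probes_used: int
    natural_log_applied: bool = False
    display_scale: float = 1e3

    @property
    def display_value(self) -> float:
        """Score on the reporting scale (raw sum ÷ display_scale)."""
        return self.score / self.display_scale

    def __str__(self) -> str:  # e.g. "DFR (x10^3): 116.2"
        return f"DFR (x10^{int(np.log10(self.display_scale))}): {self.display_value:.3g}"


@dataclass(frozen=True)
class TrajectorySummary:
    cohort: str
    timepoint_days: float
    mean_score: float
    sd_score: float
    n_patients: int
    display_scale: float = 1e3

    def display(self) -> str:
        return (f"{self.cohort} day {self.timepoint_days:g}: "
                f"{self.mean_score / self.display_scale:.3g} ± "
                f"{self.sd_score / self.display_scale:.3g} (SD), n={self.n_patients}")


def _resolve_subset(reference: ReferenceStats,
                    matrix_probes: Sequence[str],
                    probe_subset: Sequence[str] | None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the working probes in (matrix, reference) order-aligned."""
    ref_pos = {p: i for i, p in enumerate(reference.probe_ids)}
    mat_pos = {p: i for i, p in enumerate(matrix_probes)}
    if probe_subset is None:
        probe_subset = [p for p in matrix_probes if p in ref_pos]
    probes = list(probe_subset)
    if not probes:
        raise EmptySubsetError("probe subset is empty")
    missing = [p for p in probes if p not in ref_pos or p not in mat_pos]
    if missing:
        raise AlignmentError(f"probes absent from matrix or reference: {missing[:5]}")
    return (np.asarray([mat_pos[p] for p in probes]),
            np.asarray([ref_pos[p] for p in probes]))


def dfr_score(expr_column: np.ndarray,
              reference: ReferenceStats,
              probe_ids: Sequence[str],
              probe_subset: Sequence[str] | None = None,
              natural_log: bool = False,
              sample_id: str = "",
              patient_id: str = "",
              timepoint_days: float | None = None,
              display_scale: float = 1e3) -> DFRScore:
    """DFR of a single expression column against the control reference.

    ``probe_ids`` names the rows of ``expr_column``; ``probe_subset`` (default:
    all probes shared with the reference) restricts the sum. With
    ``natural_log`` the natural log of the sum — not the sum of logs — is
    returned.
    """
    expr = np.asarray(expr_column, dtype=float)
    mat_idx, ref_idx = _resolve_subset(reference, probe_ids, probe_subset)
    dev = expr[mat_idx] - reference.means[ref_idx]
    total = float(np.sum(dev * dev / reference.variances[ref_idx]))
    score = float(np.log(total)) if natural_log else total
    return DFRScore(sample_id, patient_id, timepoint_days, score,
                    n_probes_used=mat_idx.size, natural_log_applied=natural_log,
                    display_scale=display_scale)


def dfr_scores(matrix: ExpressionMatrix,
               metadata: Sequence[SampleMeta],
               reference: ReferenceStats,
               probe_subset: Sequence[str] | None = None,
               natural_log: bool = False,
               include_controls: bool = False) -> list[DFRScore]:
    """Score every (by default non-control) sample of a matrix."""
    meta = {m.sample_id: m for m in metadata}
    out = []
    for sid in matrix.sample_ids:
        m = meta.get(sid)
        if m is None or (not include_controls and m.age_group == "control"):
            continue
        out.append(dfr_score(matrix.column(sid), reference, matrix.probe_ids,
                             probe_subset, natural_log, sample_id=sid,
                             patient_id=m.patient_id,
                             timepoint_days=m.timepoint_days))
    return out


def dfr_trajectories(scores: Sequence[DFRScore],
                     metadata: Sequence[SampleMeta],
                     group_by: str = "age_group") -> list[TrajectorySummary]:
    """Per (cohort × timepoint) mean, SD (n−1) and n of DFR scores.

    Patients missing a timepoint are simply absent from that cell; cells with
    a single patient report SD 0.
    """
    meta = {m.sample_id: m for m in metadata}
    cells: dict[tuple[str, float], list[float]] = {}
    for s in scores:
        m = meta.get(s.sample_id)
        if m is None or s.timepoint_days is None:
            continue
        key = (getattr(m, group_by), float(s.timepoint_days))
        cells.setdefault(key, []).append(s.score)
    out = []
    for (cohort, t), vals in sorted(cells.items()):
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append(TrajectorySummary(cohort, t, float(arr.mean()), sd, arr.size))
    return out


def dfr_null_expectation_per_probe(n_controls: int) -> float:
    """Expected per-probe DFR term for a sample drawn from the reference
    distribution when M and V are *estimated* from ``n`` controls.

    With x, controls iid Normal(μ, σ²): E[(x − M̄)²] = σ²(1 + 1/n) and
    E[σ²/V] = (n−1)/(n−3), giving (n−1)/(n−3)·(1 + 1/n) per probe
    (requires n > 3; exactly 1 in the population-reference limit).
    """
    n = n_controls
    if n <= 3:
        raise ValueError("expectation finite only for n_controls > 3")
    return (n - 1) / (n - 3) * (1 + 1 / n)
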