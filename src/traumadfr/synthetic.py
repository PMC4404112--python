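"""Synthetic cohorts emulating the age-dependent post-trauma "genomic storm".

The generator produces a healthy-control expression baseline, trauma cohorts
whose responsive probes are shifted by an age-group- and time-dependent
amplitude (young > aged in the first day, crossing over by day 4), monotone
longitudinal dropout, log-normal cytokine trajectories with age and time
effects, and multinomial clinical count tables. Every draw is governed by a
single integer seed; identical parameters and seed reproduce outputs
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .dataio import (
    CYTOKINE_GRID_HOURS,
    DEFAULT_ANALYTES,
    ClinicalCountTable,
    CytokinePanel,
    CytokineRecord,
    ExpressionMatrix,
    SampleMeta,
)

__all__ = [
    "SimulationParams",
    "CohortTruth",
    "simulate_cohort",
    "simulate_cytokines",
    "simulate_clinical_table",
]


def _default_amplitude() -> dict[str, dict[float, float]]:
    # Mean |shift| of responsive probes in control-SD units.  Orderings encode
    # the study signature: young more perturbed at days 0.5 and 1, aged more
    # perturbed by day 4 (delayed recovery); young recovering toward baseline.
    return {
        "young": {0.5: 2.0, 1.0: 1.7, 4.0: 0.8, 7.0: 0.4},
        "aged": {0.5: 1.2, 1.0: 1.1, 4.0: 1.4, 7.0: 1.1},
    }


def _default_outcome_scale() -> dict[str, float]:
    # Uncomplicated patients perturb less and resolve faster than complicated.
    return {"complicated": 1.0, "intermediate": 0.7, "uncomplicated": 0.45}


@dataclass
class SimulationParams:
    """Knobs of the synthetic-cohort generator.

    ``amplitude[age_group][timepoint]`` is the mean absolute shift of
    responsive probes in control-SD units; timepoints beyond the keyed grid
    decay exponentially at ``recovery_rate[age_group]`` (per day) from the
    last keyed value. Defaults encode the qualitative study structure:
    young > aged early, aged > young at day 4.
    """

    n_probes: int = 500
    n_controls: int = 17
    n_patients_per_cell: int = 17
    timepoints_days: tuple[float, ...] = (0.5, 1.0, 4.0, 7.0)
    fraction_responsive: float = 0.75
    amplitude: dict[str, dict[float, float]] = field(default_factory=_default_amplitude)
    outcome_scale: dict[str, float] = field(default_factory=_default_outcome_scale)
    recovery_rate: dict[str, float] = field(
        default_factory=lambda: {"young": 0.25, "aged": 0.08})
    dropout_hazard: float = 0.10
    noise_sd: float = 1.0
    age_groups: tuple[str, ...] = ("aged", "young")
    outcome_classes: tuple[str, ...] = ("complicated",)
    # control-baseline hyperpriors (log2 units); standardized out by the DFR
    control_mean_loc: float = 8.0
    control_mean_scale: float = 2.0
    control_var_mean: float = 0.25
    control_var_df: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fraction_responsive <= 1):
            raise ValueError("fraction_responsive must be in (0, 1]")
        if self.n_patients_per_cell < 1 or self.n_controls < 2 or self.n_probes < 1:
            raise ValueError("cell sizes must be >=1 (controls >=2)")
        if not (0 <= self.dropout_hazard <= 1):
            raise ValueError("dropout_hazard must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g, byt in self.amplitude.items():
            if any(a < 0 for a in byt.values()):
                raise ValueError(f"negative amplitude for {g}")

    def amplitude_at(self, age_group: str, timepoint: float) -> float:
        byt = self.amplitude[age_group]
        if timepoint in byt:
            return byt[timepoint]
        keyed = sorted(byt)
        last = max(t for t in keyed if t <= timepoint) if any(
            t <= timepoint for t in keyed) else keyed[0]
        rate = self.recovery_rate.get(age_group, 0.0)
        return byt[last] * float(np.exp(-rate * (timepoint - last)))


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort, for parameter-recovery tests."""

    seed: int
    responsive_probes: tuple[str, ...]
    shift_signs: dict[str, int]  # probe -> ±1, fixed per probe
    control_means: np.ndarray
    control_variances: np.ndarray
    #: expected DFR against the *population* reference per (age, outcome, day)
    expected_dfr: dict[tuple[str, str, float], float]
    params: dict = field(default_factory=dict)


def simulate_cohort(params: SimulationParams
                    ) -> tuple[ExpressionMatrix, list[SampleMeta], CohortTruth]:
    """Draw controls and longitudinal trauma cohorts.

    Controls: ``x_ij ~ Normal(M_i, V_i)`` with ``M_i ~ Normal(loc, scale²)``
    and ``V_i`` scaled-inverse-chi-square with the configured mean. Each
    responsive probe carries a per-probe random sign; a patient sample at
    timepoint ``t`` in cohort ``(g, c)`` is shifted by
    ``sign_i · amplitude[g][t] · outcome_scale[c] · sqrt(V_i)`` plus
    ``Normal(0, noise_sd²·V_i)`` residual noise. Dropout is monotone in time.
    """
    rng = np.random.default_rng(params.seed)
    p = params.n_probes
    probe_ids = tuple(f"P{i:05d}" for i in range(p))

    M = rng.normal(params.control_mean_loc, params.control_mean_scale, size=p)
    df = params.control_var_df
    tau2 = params.control_var_mean * (df - 2.0) / df  # mean of df*tau²/chi2_df
    V = df * tau2 / rng.chisquare(df, size=p)
    sd = np.sqrt(V)

    n_resp = int(round(params.fraction_responsive * p))
    responsive_idx = rng.choice(p, size=n_resp, replace=False)
    responsive_idx.sort()
    signs = np.zeros(p, dtype=int)
    signs[responsive_idx] = rng.choice([-1, 1], size=n_resp)

    columns: list[np.ndarray] = []
    metadata: list[SampleMeta] = []

    for j in range(params.n_controls):
        sid = f"CTRL{j:03d}"
        columns.append(rng.normal(M, sd))
        metadata.append(SampleMeta(sid, sid, "control", "control",
                                   gender="male" if j % 2 else "female",
                                   ais=(), survived_28d=True))

    expected_dfr: dict[tuple[str, str, float], float] = {}
    noise2 = params.noise_sd ** 2
    for g in params.age_groups:
        for c in params.outcome_classes:
            scale_c = params.outcome_scale[c]
            for t in params.timepoints_days:
                amp = params.amplitude_at(g, t) * scale_c
                # E Σ (e−M)²/V with population reference: noise²·p + amp²·n_resp
                expected_dfr[(g, c, t)] = noise2 * p + amp * amp * n_resp
            for k in range(params.n_patients_per_cell):
                pid = f"{g[:1].upper()}{c[:1].upper()}{k:03d}"
                gender = "male" if rng.random() < 0.65 else "female"
                ais = tuple(int(a) for a in rng.integers(0, 6, size=6))
                survived = bool(rng.random() > (0.25 if c == "complicated" else 0.05))
                # monotone dropout: first missing timepoint censors the rest
                n_obs = len(params.timepoints_days)
                for ti in range(1, n_obs + 1):
                    if rng.random() < params.dropout_hazard:
                        n_obs = ti
                        break
                for t in params.timepoints_days[:n_obs]:
                    amp = params.amplitude_at(g, t) * scale_c
                    shift = signs * amp * sd
                    col = rng.normal(M + shift, params.noise_sd * sd)
                    sid = f"{pid}_d{t:g}"
                    columns.append(col)
                    metadata.append(SampleMeta(sid, pid, g, c, timepoint_days=t,
                                               gender=gender, ais=ais,
                                               survived_28d=survived))

    matrix = ExpressionMatrix(probe_ids, tuple(m.sample_id for m in metadata),
                              np.column_stack(columns))
    truth = CohortTruth(
        seed=params.seed,
        responsive_probes=tuple(probe_ids[i] for i in responsive_idx),
        shift_signs={probe_ids[i]: int(signs[i]) for i in responsive_idx},
        control_means=M,
        control_variances=V,
        expected_dfr=expected_dfr,
        params=asdict(params),
    )
    return matrix, metadata, truth


def _default_cytokine_baseline() -> dict[str, float]:
    # log pg/mL at first draw; rough magnitudes of acute-phase plasma levels
    return {"IL-6": 5.5, "IL-8": 4.0, "IL-10": 3.5, "IL-1b": 1.5,
            "IP-10": 5.0, "MCP-1": 5.5, "TNF-a": 2.0}


def simulate_cytokines(
    delta_age: Mapping[str, float] | None = None,
    time_profile: Mapping[float, float] | None = None,
    dispersion: float = 0.5,
    n_per_cohort: int = 17,
    analytes: Sequence[str] = DEFAULT_ANALYTES,
    timepoints_hours: Sequence[float] = CYTOKINE_GRID_HOURS,
    dropout_hazard: float = 0.10,
    seed: int = 0,
) -> tuple[CytokinePanel, dict]:
    """Log-normal cytokine trajectories with additive age and time effects.

    ``log concentration = baseline[analyte] + time_profile[t] + δ_age·1[aged]
    + Normal(0, dispersion²)``. Default ``δ_age`` is negative for every
    analyte (aged mount lower circulating levels); the default time profile
    decays from the acute peak toward discharge.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if delta_age is None:
        delta_age = {a: -0.6 for a in analytes}
    if time_profile is None:
        ts = list(timepoints_hours)
        time_profile = {t: -1.2 * (i / max(len(ts) - 1, 1)) for i, t in enumerate(ts)}
    baseline = _default_cytokine_baseline()
    rng = np.random.default_rng(seed)
    records: list[CytokineRecord] = []
    for g in ("aged", "young"):
        for k in range(n_per_cohort):
            pid = f"{g[:1].upper()}CYT{k:03d}"
            n_obs = len(timepoints_hours)
            for ti in range(1, n_obs + 1):
                if rng.random() < dropout_hazard:
                    n_obs = ti
                    break
            for t in list(timepoints_hours)[:n_obs]:
                for a in analytes:
                    mu = (baseline.get(a, 3.0) + time_profile.get(t, 0.0)
                          + (delta_age.get(a, 0.0) if g == "aged" else 0.0))
                    conc = float(np.exp(rng.normal(mu, dispersion)))
                    records.append(CytokineRecord(pid, g, a, float(t), conc))
    truth = {"delta_age": dict(delta_age), "time_profile": dict(time_profile),
             "dispersion": dispersion, "seed": seed}
    return CytokinePanel(records), truth


def simulate_clinical_table(
    true_proportions: Mapping[str, Sequence[float]],
    group_totals: Sequence[int],
    row_labels: Sequence[str],
    seed: int = 0,
) -> ClinicalCountTable:
    """Multinomial draws of a 2-group clinical count table.

    ``true_proportions[group]`` gives per-category probabilities summing to
    at most 1 (remainder = uncounted); group totals are preserved exactly.
    """
    groups = tuple(true_proportions)
    if len(groups) != 2 or len(group_totals) != 2:
        raise ValueError("exactly two groups required")
    rng = np.random.default_rng(seed)
    cols = []
    for g, total in zip(groups, group_totals):
        probs = np.asarray(true_proportions[g], dtype=float)
        if len(probs) != len(row_labels):
            raise ValueError("proportions length must match row_labels")
        if np.any(probs < 0) or probs.sum() > 1 + 1e-12:
            raise ValueError("proportions must be in [0,1] and sum to <=1")
        rest = max(0.0, 1.0 - probs.sum())
        draw = rng.multinomial(int(total), np.append(probs, rest))
        cols.append(draw[:-1])
    return ClinicalCountTable(tuple(row_labels), groups,
                              np.column_stack(cols), tuple(int(t) for t in group_totals))
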