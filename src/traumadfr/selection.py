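"""Trauma-responsive probe selection.

Per-probe one-way F-tests across cohorts, Benjamini–Hochberg false-discovery
adjustment, signed linear-scale fold changes versus the healthy-control
baseline, and restriction to a user-supplied gene panel through a
probe→gene table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix, InsufficientDataError

logger = logging.getLogger("traumadfr")

__all__ = [
    "SelectionResult",
    "ftest_per_probe",
    "adjust_fdr_bh",
    "signed_fold_change",
    "select_trauma_responsive",
    "restrict_gene_set",
]


@dataclass(frozen=True)
class SelectionResult:
    """Per-probe F statistics, raw and BH-adjusted p-values, signed fold
    changes per non-control group, and the boolean selection mask."""

    probe_ids: tuple[str, ...]
    f_statistics: np.ndarray
    p_values: np.ndarray
    adjusted_p: np.ndarray
    fold_changes: dict[str, np.ndarray]  # group -> per-probe signed fold vs control
    selected: np.ndarray  # boolean mask
    alpha: float
    min_fold: float
    use_adjusted: bool

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def selected_probes(self) -> tuple[str, ...]:
        return tuple(p for p, s in zip(self.probe_ids, self.selected) if s)


def _group_indices(sample_ids: Sequence[str],
                   group_labels: Mapping[str, str]) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(sample_ids):
        if s in group_labels:
            groups.setdefault(group_labels[s], []).append(j)
    return {g: np.asarray(idx) for g, idx in sorted(groups.items())}


def ftest_per_probe(matrix: ExpressionMatrix,
                    group_labels: Mapping[str, str],
                    floor_quantile: float = 0.10,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Classical one-way ANOVA F and upper-tail p for every probe.

    ``group_labels`` maps sample_id -> group. Probes whose pooled
    within-group mean square is degenerate are floored at the
    ``floor_quantile``-th quantile of positive within mean squares, so a
    probe identical in every sample yields F=0, p=1 rather than 0/0.
    """
    groups = _group_indices(matrix.sample_ids, group_labels)
    if len(groups) < 2:
        raise InsufficientDataError("F-test needs >=2 groups")
    for g, idx in groups.items():
        if idx.size < 2:
            raise InsufficientDataError(f"group {g!r} has <2 samples")

    X = matrix.values
    n_total = sum(idx.size for idx in groups.values())
    k = len(groups)
    grand = sum(X[:, idx].sum(axis=1) for idx in groups.values()) / n_total

    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for idx in groups.values():
        sub = X[:, idx]
        gm = sub.mean(axis=1)
        ss_between += idx.size * (gm - grand) ** 2
        ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)

    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    positive = ms_within[ms_within > 0]
    if positive.size:
        floor = np.quantile(positive, floor_quantile) if floor_quantile > 0 else 0.0
        ms_within = np.maximum(ms_within, floor)
    degenerate = ms_within <= 0
    f = np.zeros_like(ms_between)
    np.divide(ms_between, ms_within, out=f, where=~degenerate)
    p = stats.f.sf(f, df_between, df_within)
    p[degenerate & (ms_between <= 0)] = 1.0
    return f, p


def adjust_fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(group_mean_log2, reference_mean_log2):
    """Signed linear fold change between log2-scale means.

    Returns the linear ratio ``r = 2**(group − reference)`` when ``r >= 1``
    and ``−1/r`` otherwise, so −3.1 reads "3.1-fold down"; the magnitude is
    always >= 1. Accepts scalars or arrays.
    """
    diff = np.asarray(group_mean_log2, dtype=float) - np.asarray(
        reference_mean_log2, dtype=float)
    r = np.exp2(diff)
    out = np.where(r >= 1.0, r, -1.0 / r)
    if out.ndim == 0:
        return float(out)
    return out


def select_trauma_responsive(matrix: ExpressionMatrix,
                             group_labels: Mapping[str, str],
                             control_group: str = "control",
                             alpha: float = 0.001,
                             min_fold: float = 2.0,
                             use_adjusted: bool = True,
                             probe_gene_table: Mapping[str, str] | None = None,
                             ) -> SelectionResult:
    """Select probes by F-test significance AND a minimum fold change.

    A probe is selected when its (adjusted, by default) p-value is <= alpha
    and |signed fold change vs the control group| >= min_fold in at least one
    non-control group. Fold changes compare log2 group means (ratios of
    geometric means on the linear scale). Selected probe and — when a
    probe→gene table is supplied — distinct gene counts are logged.
    """
    f, p = ftest_per_probe(matrix, group_labels)
    adj = adjust_fdr_bh(p)
    groups = _group_indices(matrix.sample_ids, group_labels)
    if control_group not in groups:
        raise InsufficientDataError(f"control group {control_group!r} absent")
    ref_mean = matrix.values[:, groups[control_group]].mean(axis=1)
    fold_changes = {
        g: signed_fold_change(matrix.values[:, idx].mean(axis=1), ref_mean)
        for g, idx in groups.items() if g != control_group
    }
    chosen_p = adj if use_adjusted else p
    if fold_changes and np.isfinite(min_fold):
        fold_ok = np.any(
            np.vstack([np.abs(fc) >= min_fold for fc in fold_changes.values()]),
            axis=0)
    else:
        fold_ok = np.zeros(matrix.n_probes, dtype=bool) if np.isinf(min_fold) \
            else np.ones(matrix.n_probes, dtype=bool)
    selected = (chosen_p <= alpha) & fold_ok

    n_sel = int(selected.sum())
    msg = f"selected {n_sel} probe sets"
    if probe_gene_table is not None:
        genes = {probe_gene_table[pid] for pid, s in zip(matrix.probe_ids, selected)
                 if s and pid in probe_gene_table}
        msg += f" ({len(genes)} genes)"
    logger.info("%s at %s alpha=%g, min_fold=%g", msg,
                "adjusted" if use_adjusted else "raw", alpha, min_fold)
    return SelectionResult(matrix.probe_ids, f, p, adj, fold_changes,
                           selected, alpha, min_fold, use_adjusted)


def restrict_gene_set(selection: SelectionResult,
                      panel: Sequence[str],
                      probe_gene_table: Mapping[str, str],
                      ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Probes mapping to panel genes AND passing selection.

    Returns ``(probe_ids, surviving_genes)``. An empty intersection is a
    warning, not an error — mirroring panel restriction where only a subset
    of a previously published gene list remains significantly expressed.
    """
    panel_set = set(panel)
    probes = tuple(
        pid for pid, sel in zip(selection.probe_ids, selection.selected)
        if sel and probe_gene_table.get(pid) in panel_set
    )
    genes = tuple(sorted({probe_gene_table[p] for p in probes}))
    if not probes:
        logger.warning("gene panel restriction produced an empty probe subset")
    else:
        logger.info("panel restriction: %d of %d panel genes survive selection "
                    "(%d probes)", len(genes), len(panel_set), len(probes))
    return probes, genes
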