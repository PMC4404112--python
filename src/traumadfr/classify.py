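"""Leave-one-out cross-validated class prediction with a Monte Carlo
permutation null for the misclassification rate.

The default classifier is nearest centroid on the working probe set; probe
selection is re-run inside every fold by default so the reported rate is free
of selection bias. The permutation null shuffles sample labels (class sizes
preserved), re-runs the full LOOCV pipeline per permutation, and reports the
add-one-smoothed p-value P = (1 + #{permuted rate <= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np

from .dataio import ExpressionMatrix, InsufficientDataError
from .selection import select_trauma_responsive

__all__ = [
    "NearestCentroid",
    "LoocvResult",
    "PermutationNull",
    "loocv_misclassification",
    "monte_carlo_label_permutation",
]


@dataclass(frozen=True)
class NearestCentroid:
    """Per-class centroids (per-probe means); prediction minimizes Euclidean
    distance, ties broken by lexicographically smaller class label."""

    classes: tuple[str, ...]
    centroids: np.ndarray  # shape (n_classes, n_probes)

    @classmethod
    def fit(cls, X: np.ndarray, labels: Sequence[str]) -> "NearestCentroid":
        """X: samples × probes."""
        labels = list(labels)
        classes = tuple(sorted(set(labels)))
        if len(classes) < 2:
            raise InsufficientDataError("need >=2 classes")
        cents = []
        for c in classes:
            idx = [i for i, l in enumerate(labels) if l == c]
            if not idx:
                raise InsufficientDataError(f"empty class {c!r}")
            cents.append(np.asarray(X)[idx].mean(axis=0))
        return cls(classes, np.vstack(cents))

    def predict(self, x: np.ndarray) -> str:
        d = np.linalg.norm(self.centroids - np.asarray(x)[None, :], axis=1)
        # classes are sorted, argmin returns the first minimum -> lexicographic tie-break
        return self.classes[int(np.argmin(d))]


@dataclass(frozen=True)
class LoocvResult:
    n_samples: int
    n_misclassified: int
    predictions: tuple[str, ...]
    true_labels: tuple[str, ...]
    selection_inside_fold: bool
    classifier: str = "nearest_centroid"

    @property
    def misclassification_rate(self) -> float:
        return self.n_misclassified / self.n_samples

    @property
    def rate_exact(self) -> Fraction:
        return Fraction(self.n_misclassified, self.n_samples)


@dataclass(frozen=True)
class PermutationNull:
    observed_rate: float
    permuted_rates: np.ndarray
    n_perm: int
    seed: int

    @property
    def p_value(self) -> float:
        return (1 + int(np.sum(self.permuted_rates <= self.observed_rate + 1e-12))) \
            / (1 + self.n_perm)


def _fold_probe_subset(matrix: ExpressionMatrix,
                       fold_labels: Mapping[str, str],
                       alpha: float, min_fold: float, use_adjusted: bool,
                       control_group: str) -> tuple[str, ...]:
    labels = dict(fold_labels)
    sel = select_trauma_responsive(
        matrix.subset_samples(list(labels)), labels, control_group=control_group,
        alpha=alpha, min_fold=min_fold, use_adjusted=use_adjusted)
    probes = sel.selected_probes()
    # an empty fold selection would leave the classifier with no features;
    # fall back to the full probe universe for that fold
    return probes if probes else matrix.probe_ids


def loocv_misclassification(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    alpha: float = 0.001,
    min_fold: float = 2.0,
    use_adjusted: bool = True,
    selection_inside_fold: bool = True,
    control_group: str | None = None,
    classifier_fit: Callable = NearestCentroid.fit,
) -> LoocvResult:
    """Leave-one-out misclassification rate.

    ``labels`` maps sample_id -> class over the samples to classify. When
    ``selection_inside_fold`` (default) and a ``control_group`` is given,
    trauma-responsive probe selection is recomputed on each fold's training
    samples only; with ``control_group=None`` no selection is done and all
    probes are used. Deterministic given inputs.
    """
    sample_ids = [s for s in matrix.sample_ids if s in labels]
    classes = sorted({labels[s] for s in sample_ids})
    if len(classes) < 2:
        raise InsufficientDataError("LOOCV needs >=2 classes")
    counts = {c: sum(1 for s in sample_ids if labels[s] == c) for c in classes}
    min_per_class = 3 if (control_group is not None and selection_inside_fold) else 2
    if min(counts.values()) < min_per_class:
        raise InsufficientDataError(
            f"every class needs >={min_per_class} samples; got {counts}")

    work = matrix.subset_samples(sample_ids)
    probe_pos = {p: i for i, p in enumerate(work.probe_ids)}

    # selection outside the folds (the biased variant), computed once
    if control_group is not None and not selection_inside_fold:
        global_subset = _fold_probe_subset(work, labels, alpha, min_fold,
                                           use_adjusted, control_group)
    else:
        global_subset = work.probe_ids

    preds, truth = [], []
    for j, held in enumerate(sample_ids):
        train_ids = [s for s in sample_ids if s != held]
        train_labels = {s: labels[s] for s in train_ids}
        if len({*train_labels.values()}) < len(classes):
            raise InsufficientDataError(f"class collapse in fold holding out {held!r}")
        if control_group is not None and selection_inside_fold:
            subset = _fold_probe_subset(work.subset_samples(train_ids), train_labels,
                                        alpha, min_fold, use_adjusted, control_group)
        else:
            subset = global_subset
        rows = np.asarray([probe_pos[p] for p in subset])
        cols = np.asarray([sample_ids.index(s) for s in train_ids])
        model = classifier_fit(work.values[np.ix_(rows, cols)].T,
                               [train_labels[s] for s in train_ids])
        preds.append(model.predict(work.values[rows, j]))
        truth.append(labels[held])

    n_mis = sum(p != t for p, t in zip(preds, truth))
    return LoocvResult(len(sample_ids), n_mis, tuple(preds), tuple(truth),
                       selection_inside_fold)


def monte_carlo_label_permutation(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    **loocv_kwargs,
) -> PermutationNull:
    """Permutation null for the LOOCV misclassification rate.

    Labels are permuted uniformly over samples (class sizes preserved) and
    the full LOOCV pipeline — including any in-fold probe selection — is
    re-run per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >=1")
    observed = loocv_misclassification(matrix, labels, **loocv_kwargs)
    sample_ids = [s for s in matrix.sample_ids if s in labels]
    values = [labels[s] for s in sample_ids]
    rng = np.random.default_rng(seed)
    rates = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(values))
        perm_labels = {s: values[perm[i]] for i, s in enumerate(sample_ids)}
        rates[b] = loocv_misclassification(matrix, perm_labels,
                                           **loocv_kwargs).misclassification_rate
    return PermutationNull(observed.misclassification_rate, rates, n_perm, seed)
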