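"""End-to-end orchestration: simulate or load → control reference → probe
selection → DFR trajectories → LOOCV + permutation null → group statistics,
all from one declarative config with seeded reproducibility and a run
manifest recording every threshold, seed and stage count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dataio import (
    ExpressionMatrix, SampleMeta, build_reference,
    read_expression_matrix, read_sample_metadata,
    write_expression_matrix, write_sample_metadata,
)
from .dfr import dfr_scores, dfr_trajectories
from .selection import select_trauma_responsive
from .classify import loocv_misclassification, monte_carlo_label_permutation
from .cohort_stats import anova_newman_keuls, kruskal_wallis
from .synthetic import SimulationParams, simulate_cohort

logger = logging.getLogger("traumadfr")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run; round-trips through YAML."""

    # input: either simulate (params) or load (paths)
    simulate: dict | None = None
    expression_path: str | None = None
    metadata_path: str | None = None
    # thresholds
    alpha: float = 0.001
    min_fold: float = 2.0
    use_adjusted: bool = True
    floor_quantile: float = 0.10
    # DFR
    dfr_subset: str = "all"  # "all" | "selected"
    natural_log: bool = False
    dfr_timepoints: tuple[float, ...] = (0.5, 1.0, 4.0)
    # classification
    classify_timepoint: float = 0.5
    n_perm: int = 99
    selection_inside_fold: bool = True
    # stats
    stats_alpha: float = 0.05
    pairwise_method: str = "newman-keuls"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dfr_timepoints" in raw:
            raw["dfr_timepoints"] = tuple(raw["dfr_timepoints"])
        sim = raw.get("simulate")
        if sim:  # YAML has no tuples; restore the sequence-typed params
            for key in ("timepoints_days", "age_groups", "outcome_classes"):
                if key in sim:
                    sim[key] = tuple(sim[key])
        return cls(**raw)


def _load_inputs(config: PipelineConfig
                 ) -> tuple[ExpressionMatrix, list[SampleMeta]]:
    if config.simulate is not None:
        params = SimulationParams(**{**config.simulate, "seed": config.seed})
        matrix, metadata, _ = simulate_cohort(params)
        return matrix, metadata
    if not (config.expression_path and config.metadata_path):
        raise ValueError("config needs either 'simulate' params or input paths")
    return (read_expression_matrix(config.expression_path),
            read_sample_metadata(config.metadata_path))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write per-stage TSV/JSON artifacts plus a manifest.

    Identical config (and seed) produces byte-identical numeric artifacts.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, metadata = _load_inputs(config)
    meta_by_sid = {m.sample_id: m for m in metadata}
    control_ids = [m.sample_id for m in metadata if m.age_group == "control"]

    write_expression_matrix(matrix, out / "expression.tsv")
    write_sample_metadata(metadata, out / "metadata.tsv")

    reference = build_reference(matrix, control_ids, config.floor_quantile)

    # selection at the earliest timepoint (acute response), controls included
    sel_labels = {
        m.sample_id: m.age_group for m in metadata
        if m.age_group == "control" or m.timepoint_days == config.classify_timepoint
    }
    selection = select_trauma_responsive(
        matrix.subset_samples(list(sel_labels)), sel_labels,
        alpha=config.alpha, min_fold=config.min_fold,
        use_adjusted=config.use_adjusted)
    sel_summary = {
        "n_probes_tested": len(selection.probe_ids),
        "n_selected": selection.n_selected,
        "alpha": config.alpha, "min_fold": config.min_fold,
        "use_adjusted": config.use_adjusted,
    }
    (out / "selection.json").write_text(json.dumps(sel_summary, indent=2))

    subset = selection.selected_probes() if config.dfr_subset == "selected" else None
    scores = dfr_scores(matrix, metadata, reference, probe_subset=subset,
                        natural_log=config.natural_log)
    with open(out / "dfr_scores.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpatient_id\ttimepoint_days\tscore\tn_probes\n")
        for s in scores:
            fh.write(f"{s.sample_id}\t{s.patient_id}\t{s.timepoint_days:g}"
                     f"\t{s.score:.10g}\t{s.n_probes_used}\n")
    trajectories = dfr_trajectories(scores, metadata)
    with open(out / "dfr_trajectories.tsv", "w", encoding="utf-8") as fh:
        fh.write("cohort\ttimepoint_days\tmean\tsd\tn\n")
        for t in trajectories:
            fh.write(f"{t.cohort}\t{t.timepoint_days:g}\t{t.mean_score:.10g}"
                     f"\t{t.sd_score:.10g}\t{t.n_patients}\n")

    # group comparisons of DFR at each timepoint
    comparisons = {}
    for tp in config.dfr_timepoints:
        groups: dict[str, list[float]] = {}
        for s in scores:
            m = meta_by_sid[s.sample_id]
            if s.timepoint_days == tp:
                groups.setdefault(m.age_group, []).append(s.score)
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        if config.pairwise_method == "kruskal-wallis":
            cmp_res = kruskal_wallis(groups)
        else:
            cmp_res = anova_newman_keuls(groups, alpha=config.stats_alpha)
        comparisons[f"day_{tp:g}"] = {
            "method": cmp_res.method,
            "omnibus_statistic": cmp_res.omnibus_statistic,
            "omnibus_p": cmp_res.omnibus_p,
            "pairwise": [
                {"pair": [p.group_a, p.group_b], "statistic": p.statistic,
                 "reject": p.reject} for p in cmp_res.pairwise],
            "group_means": {g: float(np.mean(v)) for g, v in sorted(groups.items())},
        }
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))

    # LOOCV on the acute timepoint, aged vs young, permutation null
    cls_labels = {m.sample_id: m.age_group for m in metadata
                  if m.timepoint_days == config.classify_timepoint
                  and m.age_group in ("aged", "young")}
    classification = None
    counts = {g: sum(1 for v in cls_labels.values() if v == g)
              for g in set(cls_labels.values())}
    if len(counts) == 2 and min(counts.values()) >= 3:
        loo = loocv_misclassification(
            matrix, cls_labels, alpha=config.alpha, min_fold=config.min_fold,
            use_adjusted=config.use_adjusted,
            selection_inside_fold=config.selection_inside_fold,
            control_group=None)
        null = monte_carlo_label_permutation(
            matrix, cls_labels, n_perm=config.n_perm, seed=config.seed,
            alpha=config.alpha, min_fold=config.min_fold,
            use_adjusted=config.use_adjusted,
            selection_inside_fold=config.selection_inside_fold,
            control_group=None)
        classification = {
            "n_samples": loo.n_samples,
            "n_misclassified": loo.n_misclassified,
            "misclassification_rate": loo.misclassification_rate,
            "permutation_p": null.p_value,
            "n_perm": null.n_perm,
        }
        (out / "classification.json").write_text(json.dumps(classification, indent=2))

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "n_probes": matrix.n_probes,
        "n_samples": matrix.n_samples,
        "n_controls": len(control_ids),
        "variance_floor": reference.variance_floor,
        "selection": sel_summary,
        "n_dfr_scores": len(scores),
        "comparisons": sorted(comparisons),
        "classification": classification,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline run complete: %s", out)
    return manifest
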