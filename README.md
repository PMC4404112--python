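# traumadfr

Trajectory analysis of the peripheral-neutrophil transcriptome after severe
blunt trauma with hemorrhagic shock, centred on the **distance-from-reference
(DFR)** genomic score and the age-dependent "genomic storm".

Severe trauma perturbs a large fraction of the circulating-leukocyte
transcriptome. Young patients with complicated outcomes mount a massive acute
response (days 0.5–1 post-injury) and then trend back toward the
healthy-control baseline, while aged patients (≥55 years) mount a blunted
acute response that *fails to resolve*, crossing over to become the more
aberrant cohort by day 4. `traumadfr` provides the quantitative machinery for
studying this signature, for bioinformaticians and trauma-immunology groups
working with probe-level expression matrices and longitudinal clinical data.

## The score

For a patient sample with expression $e_i$ on probe set $i$, and
healthy-control mean $M_i$ and variance $V_i$:

$$\mathrm{DFR} = \sum_{i \in S} \frac{(e_i - M_i)^2}{V_i}$$

summed over a probe universe $S$ (the whole array, the trauma-responsive
selection, or a gene panel). One scalar per patient-timepoint captures total
transcriptomic deviation from baseline, up- and downregulation alike. Scores
are reported without the optional natural-log transform (available via
`natural_log=True`, applied to the sum) and displayed on a ×10³ scale.

Around the score, the package implements:

- **Probe selection** — per-probe one-way F-tests across cohorts,
  Benjamini–Hochberg adjustment (selection at adjusted *p* ≤ 0.001 by
  default), and a two-fold signed fold-change filter versus controls;
  restriction to user-supplied gene panels via a probe→gene table.
- **Classification** — leave-one-out cross-validated nearest-centroid
  prediction with optional in-fold probe re-selection, and a Monte Carlo
  label-permutation null for the misclassification rate,
  $p = (1 + \#\{r_{perm} \le r_{obs}\})/(1 + B)$.
- **Cohort statistics** — greedy matched-pair construction (gender, 28-day
  survival and sampling-timepoint equality as hard criteria, minimal summed
  |ΔAIS|), one-way ANOVA with Student–Newman–Keuls post hoc comparisons,
  Kruskal–Wallis, Holm–Šidák, Fisher's exact and Wilcoxon rank-sum tests,
  and the longitudinal cytokine age×time linear model (type-II F tests on
  log concentrations).
- **Synthetic cohorts** — a seeded generator producing control baselines,
  age- and time-structured trauma responses (young > aged acutely, crossover
  by day 4), monotone dropout, log-normal cytokine trajectories and clinical
  count tables, together with the ground truth needed for parameter-recovery
  testing.

## Worked example

```sh
python examples/dfr_trajectories.py
```

```
cohort trajectories, DFR (x10^3), mean ± SD:
  aged day 0.5: 1.15 ± 0.0522 (SD), n=17
  aged day 4: 1.34 ± 0.0523 (SD), n=11
  young day 0.5: 2.16 ± 0.0881 (SD), n=17
  young day 4: 0.83 ± 0.0513 (SD), n=14
  ...

Newman-Keuls aged-vs-young comparison per day:
  day 0.5: young > aged  (q = 57.9, *)
  day   1: young > aged  (q = 29.1, *)
  day   4: aged > young  (q = 34.9, *)
```

On a simulated 17-vs-17 matched cohort, the young mean DFR (×10³) of 2.16 at
day 0.5 dwarfs the aged 1.15 — the blunted acute response of
immuno-senescence — while by day 4 the aged cohort (1.34) has overtaken the
recovering young (0.83); all three differences are significant by
Newman–Keuls at α = 0.05. The other scripts in `examples/` each demonstrate
one capability (simulation truth records, probe selection and panel
restriction, LOOCV with its permutation null, the cytokine GLM, clinical
tables and matched pairs).

A thin CLI mirrors the library (`traumadfr simulate|select|dfr|classify|stats|run`);
`traumadfr run --seed 1 --out bundle/` executes the full pipeline from a
YAML config and writes per-stage TSV/JSON artifacts plus a manifest.

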