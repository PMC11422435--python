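# rocftrace

Scoring and diagnostic analysis of **Rey–Osterrieth complex figure (ROCF)
tracing tasks** for detecting **unilateral spatial neglect (USN)**.

Left-sided spatial neglect after right-hemisphere stroke is routinely
screened with cancellation, line-bisection and copying tests, but these
miss patients whose deficit only emerges when spatial working memory is
loaded. Tracing the ROCF *without leaving visible marks on the sample*
creates exactly that load: patients cannot see where they have already
traced, so left-sided omissions and repeated re-tracing ("overlaps")
surface. This package implements the quantitative side of that task for
clinicians and methods researchers:

- **Figure scoring** — the conventional 18-unit / 36-point ROCF rubric,
  lateralised left (max 12) and right (max 16) scores, and the
  **Laterality Index**

  ```
  LI = (left score / 12) / (right score / 16)
  ```

  LI < 1 means the right-sided structures were reproduced proportionally
  better than the left-sided ones — the left-neglect direction.
- **Overlapping scores** — 1 point per complete re-trace of a unit, 0.5
  per incomplete re-trace, summed per side and in total; a marker of
  spatial working-memory failure.
- **Screening classification** — the four-test battery (line
  cancellation, star cancellation, line bisection, landscape copying);
  a patient flagging on *any* test is USN+.
- **Group statistics** — Shapiro–Wilk gate, Kruskal–Wallis, pairwise
  Mann–Whitney with Holm correction, effect size *r*, Spearman
  correlation screen with a |ρ| > 0.8 meaningfulness bar, demographics
  tables with Fisher's exact test.
- **ROC analysis** — AUC via the Mann–Whitney kernel, DeLong 95%
  confidence intervals, cutoff nearest the top-left corner,
  sensitivity/specificity and percent of patients beyond the cutoff.
- **Synthetic cohorts** — a generator calibrated so the derived-measure
  medians of its three groups (healthy n=40, USN− n=10, USN+ n=10)
  match the published study's group summaries, since the original
  per-subject data are available only on request.

## Worked example

Score a single tracing performance. The patient reproduced the
right-sided structures well (13/16) but lost points on the left (7/12),
and re-traced three units (one complete overlap on a left unit, one
complete plus one incomplete on right units):

```python
from rocftrace import UnitScore, summarize_task

units = [UnitScore(1, 2.0), UnitScore(2, 2.0), UnitScore(3, 1.0),
         UnitScore(4, 1.0), UnitScore(5, 0.0),
         UnitScore(6, 2.0, complete_overlaps=1), UnitScore(7, 1.0),
         UnitScore(8, 1.0), UnitScore(9, 2.0), UnitScore(10, 2.0),
         UnitScore(11, 2.0), UnitScore(12, 2.0, incomplete_overlaps=1),
         UnitScore(13, 2.0, complete_overlaps=1), UnitScore(14, 1.5),
         UnitScore(15, 1.0), UnitScore(16, 0.5), UnitScore(17, 1.0),
         UnitScore(18, 0.0)]
summary = summarize_task(units, task="tracing")
for key, value in summary.as_dict().items():
    print(f"{key}: {value}")
```

prints

```
task: tracing
total_score: 24.0
left_score: 7.0
right_score: 13.0
laterality_index: 0.717948717948718
left_overlap: 1.0
right_overlap: 1.5
total_overlap: 2.5
```

A total of 24/36 would look merely "below average"; the LI of 0.72
(well under 1) localises the loss to the left side, and the 2.5
overlap points quantify the re-tracing behaviour. A healthy tracing
performance typically has LI ≈ 1 and few overlaps.

## Full analysis

The numbered scripts under `analysis/` run the complete study analysis
on a synthetic cohort — `01` generates the calibrated cohort,
`02`–`06` score it, classify the patients, compare the groups,
screen correlations and build the ROC table — writing all tables under
`results/`. The same chain is available as a CLI:

```sh
rocftrace simulate --seed 11 --out results/data
rocftrace run-all --units results/data/units.csv \
    --screening results/data/screening.csv \
    --subjects results/data/subjects.csv \
    --out results/report --seed 11
```

## Layout

```
src/rocftrace/     scoring, screening, stats, roc, simulate, io, pipeline, cli
analysis/          numbered drivers reproducing the study analysis chain
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    models, conventions, calibration and limitations
```
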