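"""Score every figure performance: totals, lateral scores, LI, overlaps.

Reads results/data/units.csv, writes results/task_summaries.csv and
prints the per-group tracing-task medians.
"""

from pathlib import Path

import pandas as pd

from rocftrace.io import read_subjects, read_unit_scores, summarize_subjects

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    units = read_unit_scores(ROOT / "data" / "units.csv")
    summaries = summarize_subjects(units)
    summaries.to_csv(ROOT / "task_summaries.csv", index=False)
    print(f"wrote {ROOT / 'task_summaries.csv'} ({len(summaries)} performances)")

    subjects = read_subjects(ROOT / "data" / "subjects.csv")
    merged = summaries.merge(subjects[["subject_id", "group"]], on="subject_id")
    tracing = merged[merged["task"] == "tracing"]
    table = tracing.groupby("group")[["total_score", "laterality_index", "total_overlap"]].median()
    print("\ntracing-task group medians:")
    print(table.round(3).to_string())


if __name__ == "__main__":
    main()
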