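"""Compare figure measures across the three groups.

Kruskal-Wallis omnibus plus Holm-corrected Mann-Whitney pairs for each
task measure; the tracing-task laterality index is the primary outcome
and the tracing-task total overlapping score the secondary one.
Writes results/group_comparisons.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from rocftrace.io import read_subjects
from rocftrace.stats import compare_groups

ROOT = Path(__file__).resolve().parents[1] / "results"
GROUPS = ("healthy", "usn_minus", "usn_plus")
MEASURES = [
    ("copying", "total_score"),
    ("copying", "laterality_index"),
    ("tracing", "total_score"),
    ("tracing", "laterality_index"),
    ("tracing", "right_overlap"),
    ("tracing", "left_overlap"),
    ("tracing", "total_overlap"),
]


def main() -> None:
    summaries = pd.read_csv(ROOT / "task_summaries.csv")
    subjects = read_subjects(ROOT / "data" / "subjects.csv")
    merged = summaries.merge(subjects[["subject_id", "group"]], on="subject_id")

    rows = []
    for task, measure in MEASURES:
        sub = merged[merged["task"] == task]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = compare_groups(
                {g: sub.loc[sub["group"] == g, measure] for g in GROUPS},
                measure_name=f"{task}_{measure}",
            )
        row = {"measure": comp.measure_name, "omnibus_p": round(comp.omnibus_p, 4)}
        for g in GROUPS:
            m, q1, q3 = comp.summaries[g]
            row[g] = f"{m:.2f} ({q1:.2f}-{q3:.2f})"
        for p in comp.pairwise:
            row[f"p_{p.pair[0][0]}v{p.pair[1][0]}"] = round(p.p_holm, 4)
            row[f"r_{p.pair[0][0]}v{p.pair[1][0]}"] = round(p.effect_size_r, 2)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "group_comparisons.csv", index=False)
    print(table.to_string(index=False))
    primary = table[table["measure"] == "tracing_laterality_index"].iloc[0]
    print(
        f"\nprimary outcome (tracing LI): omnibus p = {primary['omnibus_p']}, "
        f"healthy vs USN+ Holm p = {primary['p_hvu']}"
        if "p_hvu" in primary
        else f"\nprimary outcome (tracing LI): omnibus p = {primary['omnibus_p']}"
    )


if __name__ == "__main__":
    main()
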