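"""ROC analysis: how well does each measure detect USN among patients?

Evaluates the nine candidate measures (conventional screening scores,
figure scores/LIs and tracing overlapping scores) against the USN+/-
classification: AUC with DeLong 95% CI, corner-nearest cutoff,
sensitivity/specificity and percent of patients beyond the cutoff.
Writes results/roc_table.csv.
"""

from pathlib import Path

import pandas as pd

from rocftrace.io import read_screening, read_subjects
from rocftrace.roc import HIGHER_INDICATES_USN, LOWER_INDICATES_USN, evaluate_measure

ROOT = Path(__file__).resolve().parents[1] / "results"
ORIENTATIONS = {
    "star_cancellation": LOWER_INDICATES_USN,
    "line_bisection": HIGHER_INDICATES_USN,
    "copying_score": LOWER_INDICATES_USN,
    "copying_li": LOWER_INDICATES_USN,
    "tracing_score": LOWER_INDICATES_USN,
    "tracing_li": LOWER_INDICATES_USN,
    "right_overlap": HIGHER_INDICATES_USN,
    "left_overlap": HIGHER_INDICATES_USN,
    "total_overlap": HIGHER_INDICATES_USN,
}


def main() -> None:
    summaries = pd.read_csv(ROOT / "task_summaries.csv")
    subjects = read_subjects(ROOT / "data" / "subjects.csv")
    screening = read_screening(ROOT / "data" / "screening.csv")
    classification = pd.read_csv(ROOT / "screening_classification.csv")

    labels = classification.set_index("subject_id")["label"].eq("usn_plus").astype(int)
    wide = summaries[summaries["subject_id"].isin(labels.index)].pivot(
        index="subject_id", columns="task"
    )
    scr = screening.set_index("subject_id").loc[labels.index]
    measures = pd.DataFrame(
        {
            "star_cancellation": scr["star_cancel_score"].astype(float),
            "line_bisection": scr["line_bisection_deviation"],
            "copying_score": wide[("total_score", "copying")],
            "copying_li": wide[("laterality_index", "copying")],
            "tracing_score": wide[("total_score", "tracing")],
            "tracing_li": wide[("laterality_index", "tracing")],
            "right_overlap": wide[("right_overlap", "tracing")],
            "left_overlap": wide[("left_overlap", "tracing")],
            "total_overlap": wide[("total_overlap", "tracing")],
        }
    ).loc[labels.index]

    rows = [
        evaluate_measure(name, measures[name], labels, ORIENTATIONS[name]).as_dict()
        for name in measures.columns
    ]
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "roc_table.csv", index=False)
    show = table[
        ["measure", "inequality", "cutoff", "pct_beyond_cutoff", "sensitivity",
         "specificity", "auc", "auc_ci_low", "auc_ci_high", "accuracy_band"]
    ].round(2)
    print(show.to_string(index=False))
    best = table.loc[table["auc"].idxmax()]
    print(
        f"\nhighest AUC: {best['measure']} "
        f"(AUC {best['auc']:.2f}, {best['accuracy_band']})"
    )


if __name__ == "__main__":
    main()
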