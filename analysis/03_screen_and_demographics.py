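"""Classify patients as USN+/USN- and compare group demographics.

Writes results/screening_classification.csv and results/demographics.csv.
"""

from pathlib import Path

import pandas as pd

from rocftrace.io import read_screening, read_subjects, screening_result_from_row
from rocftrace.screening import classify_usn
from rocftrace.stats import demographics_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    screening = read_screening(ROOT / "data" / "screening.csv")
    subjects = read_subjects(ROOT / "data" / "subjects.csv")
    patients = set(subjects.loc[subjects["group"] != "healthy", "subject_id"])

    rows = []
    for _, row in screening.iterrows():
        if row["subject_id"] not in patients:
            continue
        cls = classify_usn(screening_result_from_row(row))
        rows.append({"subject_id": row["subject_id"], "label": cls.label, **cls.flags})
    classification = pd.DataFrame(rows)
    classification.to_csv(ROOT / "screening_classification.csv", index=False)
    counts = classification["label"].value_counts().to_dict()
    print(f"patients classified: {counts}")

    demo = demographics_table(
        subjects,
        continuous=["age", "education_years", "mmse", "weeks_since_onset"],
        categorical=["sex", "diagnosis"],
    )
    demo.to_csv(ROOT / "demographics.csv", index=False)
    print("\ndemographics (no variable should separate the groups):")
    print(demo.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
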