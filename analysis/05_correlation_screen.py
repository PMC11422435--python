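"""Spearman screen: tracing-task measures vs conventional screening tests.

Within the 20 right-brain-damaged patients, correlates the tracing
score, LI and overlapping scores with the star-cancellation score,
line-bisection deviation and copying score/LI.  With n = 20, a
correlation is only considered clinically meaningful above |rho| = 0.8.
Writes results/correlation_screen.csv.
"""

from pathlib import Path

import pandas as pd

from rocftrace.io import read_screening, read_subjects
from rocftrace.stats import correlation_screen

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summaries = pd.read_csv(ROOT / "task_summaries.csv")
    subjects = read_subjects(ROOT / "data" / "subjects.csv")
    screening = read_screening(ROOT / "data" / "screening.csv")
    patients = subjects.loc[subjects["group"] != "healthy", "subject_id"]

    wide = summaries[summaries["subject_id"].isin(patients)].pivot(
        index="subject_id", columns="task"
    )
    scr = screening.set_index("subject_id").loc[wide.index]
    tracing = pd.DataFrame(
        {
            "tracing_score": wide[("total_score", "tracing")],
            "tracing_li": wide[("laterality_index", "tracing")],
            "right_overlap": wide[("right_overlap", "tracing")],
            "left_overlap": wide[("left_overlap", "tracing")],
            "total_overlap": wide[("total_overlap", "tracing")],
        }
    )
    conventional = pd.DataFrame(
        {
            "star_cancellation": scr["star_cancel_score"],
            "line_bisection": scr["line_bisection_deviation"],
            "copying_score": wide[("total_score", "copying")],
            "copying_li": wide[("laterality_index", "copying")],
        }
    )
    screen = correlation_screen(tracing, conventional)
    screen.rho.T.round(3).to_csv(ROOT / "correlation_screen.csv")
    print("Spearman rho (conventional tests x tracing measures):")
    print(screen.rho.T.round(2).to_string())
    n_meaningful = int(screen.meaningful.sum().sum())
    print(
        f"\n{n_meaningful} correlation(s) exceed the |rho| > "
        f"{screen.meaningful_threshold} meaningfulness bar"
    )


if __name__ == "__main__":
    main()
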