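"""Run the full analysis pipeline over the simulated study.

For each configured crowd (first-r per arm plus the low-feedback top-5),
assembles the crowd per image, fuses demarcations by plurality vote,
scores the consensus against ground truth on the withheld affected
evaluation set, and writes all study tables (scores, crowd summaries,
rater reliability, per-photo view spread, variability regression,
learning curves) under results/study.

Run after 01:  python analysis/02_run_study.py
"""

from pathlib import Path

import pandas as pd

from skincrowd.io import read_dataset, run_study

DATA = Path("scratch/dataset")
OUT = Path("results/study")


def main() -> None:
    data = read_dataset(DATA)
    OUT.parent.mkdir(exist_ok=True)
    run_study(data, OUT, seed=42)
    summary = pd.read_csv(OUT / "summary.csv")
    print("crowd performance over the evaluation set:")
    cols = ["crowd_name", "n_images", "median_dice", "median_sae",
            "mean_dice", "mean_sae"]
    print(summary[cols].round(3).to_string(index=False))
    print(f"\nall tables written to {OUT}")


if __name__ == "__main__":
    main()
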