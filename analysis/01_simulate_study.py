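"""Simulate the desk-scale crowd study and write it to disk.

Generates the two-split / two-arm study layout (ground-truth-provided
photos at 7 viewing angles, withheld photos at 9; high-feedback arm at a
1/4 feedback rate, low-feedback arm at 1/14) with heterogeneous-skill
raters, and writes the dataset (masks, images.csv, raters.csv,
demarcations.csv, exposure_log.csv) under scratch/dataset.

Run from the repository root:  python analysis/01_simulate_study.py
"""

from pathlib import Path

from skincrowd import RunConfig, simulate_study
from skincrowd.io import write_dataset

SEED = 42
OUT = Path("scratch/dataset")


def main() -> None:
    cfg = RunConfig.desk_scale()
    data = simulate_study(cfg, seed=SEED)
    OUT.parent.mkdir(exist_ok=True)
    write_dataset(data, OUT)
    n_eval = len(data.evaluation_images())
    print(f"study seed {SEED}: {len(data.images)} 2D images "
          f"({n_eval} withheld affected = evaluation set), "
          f"{len(data.raters)} raters, {len(data.demarcations)} demarcations")
    print(f"dataset written to {OUT}")


if __name__ == "__main__":
    main()
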