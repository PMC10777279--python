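"""Compare crowd definitions with Mann-Whitney U tests.

Tests whether the per-image surface-area-error distributions of each
pair of crowds differ, mirroring the study-level question of whether a
leaner but better-curated crowd (top-5 by reliability) matches the
crowd that received more expert feedback. Writes
results/crowd_comparison.csv.

Run after 02:  python analysis/03_compare_crowds.py
"""

from itertools import combinations
from pathlib import Path

import pandas as pd

from skincrowd.analysis import compare_crowds

SCORES = Path("results/study/scores.csv")
OUT = Path("results/crowd_comparison.csv")


def main() -> None:
    scores = pd.read_csv(SCORES)
    rows = []
    for a, b in combinations(sorted(scores["crowd_name"].unique()), 2):
        ea = scores.loc[scores["crowd_name"] == a, "surface_area_error"]
        eb = scores.loc[scores["crowd_name"] == b, "surface_area_error"]
        u, p = compare_crowds(ea, eb)
        rows.append({"crowd_a": a, "crowd_b": b, "n_a": len(ea), "n_b": len(eb),
                     "median_sae_a": ea.median(), "median_sae_b": eb.median(),
                     "U": u, "p_two_sided": p})
    out = pd.DataFrame(rows)
    out.to_csv(OUT, index=False)
    print(out.round(4).to_string(index=False))
    print(f"\nwritten to {OUT}")


if __name__ == "__main__":
    main()
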