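"""Reliability analyses: view-to-view spread and disagreement-vs-error.

Reports (a) the spread of consensus surface-area error across the
multiple viewing angles of each photo — the same skin under slightly
different geometry can score very differently — and (b) the regression
of per-photo consensus error on the SD of individual raters' area
estimates, asking whether crowd disagreement predicts consensus
inaccuracy.

Run after 02:  python analysis/04_variability_and_spread.py
"""

from pathlib import Path

import pandas as pd

STUDY = Path("results/study")


def main() -> None:
    spread = pd.read_csv(STUDY / "photo_spread.csv")
    reg = pd.read_csv(STUDY / "regression.csv")

    print("per-photo spread of consensus error across viewing angles")
    for crowd, grp in spread.groupby("crowd_name"):
        widths = grp["max_error"] - grp["min_error"]
        print(f"  {crowd}: median view-range {widths.median():.2f} pp, "
              f"worst photo range {widths.max():.2f} pp "
              f"(over {len(grp)} photos)")

    print("\nconsensus error vs rater-SD regression (per crowd):")
    print(reg.round(4).to_string(index=False))
    print(
        "\nnote: at desk scale the regression pools only "
        f"{int(reg['n_points'].iloc[0])} photos whose lesion sizes vary, and "
        "lesion size inflates both axes of this plot (both are absolute "
        "percentages of skin), so a high R^2 here reflects that shared scale, "
        "not disagreement predicting inaccuracy. The controlled null "
        "experiment — an identical-skill crowd over 40 size-matched photos — "
        "shows R^2 < 0.1 in ~95% of replicates (see the acceptance suite)."
    )


if __name__ == "__main__":
    main()
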