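# skincrowd

Simulation and analysis of crowdsourced skin demarcations: can a crowd
of untrained raters outline disease-affected skin in photographs well
enough to replace scarce expert annotation?

The package targets the study design used for cutaneous chronic
graft-versus-host disease (cGVHD): multi-angle 2D views of patient
photos, a split into feedback ("ground truth provided") and evaluation
("ground truth withheld") sets, two rater arms with different expert
feedback rates (1/4 vs 1/14), and several crowd definitions — the first
r raters per image, a larger crowd, and the top-5 most reliable raters.
Since patient photos are not public, a first-class synthetic-data
module generates studies with the same structure, so every stage is
testable end to end.

## Core model

For one image and an assembled crowd of n raters with binary masks
D₁…Dₙ, the consensus is the plurality vote

    C(p) = 1   iff   #{i : Dᵢ(p) = 1} / n ≥ 0.5

(pixels marked by at least half the crowd, ties included). Agreement
with the expert mask G inside the skin mask S uses two metrics:

- **Dice coefficient** `2|C∩G| / (|C|+|G|)` — spatial overlap, 0 to 1;
- **surface area error** `| 100·|C|/|S| − 100·|G|/|S| |` — the absolute
  difference in percent of skin marked, the quantity clinical surface
  scoring cares about. (A mask can have perfect area and poor overlap,
  hence both.)

Rater reliability is the mean Dice of a rater's demarcations on the
ground-truth-provided set; per-image top-k crowds take the k available
raters with the best reliability. Study-level analyses: crowd summaries
(median/IQR/mean), Mann-Whitney U comparison between crowds (exact by
enumeration for small n, normal approximation with tie correction
otherwise), per-photo error spread across viewing angles, the
regression of consensus error on the SD of individual raters' area
estimates, and per-rater learning curves in 20-image bins.

## Worked example

```bash
python analysis/01_simulate_study.py
python analysis/02_run_study.py
```

prints, for the bundled desk-scale study (142 images, 44 raters,
2840 demarcations, seed 42):

```
crowd performance over the evaluation set:
crowd_name  n_images  median_dice  median_sae  mean_dice  mean_sae
   high_r8        54        0.878       2.289      0.826     3.866
   low_r12        54        0.836       3.169      0.748     4.567
    low_r8        54        0.829       2.624      0.752     4.369
  low_top5        54        0.837       2.234      0.792     3.968
```

Reading: each row is one crowd definition scored on the 54 withheld
images with affected skin. The high-feedback crowd (r=8 here) beats the
low-feedback crowd of the same size on surface-area error (median 2.3
vs 2.6 percentage points of skin); enlarging the low-feedback crowd
(r=12) does not close the gap; selecting the 5 most reliable
low-feedback raters per image does (median SAE 2.2, and
`analysis/03_compare_crowds.py` reports the high-vs-top5 Mann-Whitney
p = 0.97 — statistically indistinguishable). The remaining drivers
report the per-photo spread of error across viewing angles
(`04_variability_and_spread.py`) and the flat learning curves
(`05_learning_curves.py`).

The same pipeline is scriptable from the shell:

```bash
skincrowd simulate --out data/ --seed 42          # desk-scale default config
skincrowd run-study --data data/ --out results/
skincrowd report --results results/ --out figures/
```

`simulate --config my_study.json` accepts a full study configuration
(photo counts per split, viewing angles, arm sizes, feedback rates,
skill distributions, crowd definitions); `RunConfig.full_scale()` in
`skincrowd.config` materializes the full 3000-image layout.

## Layout

```
src/skincrowd/       library: synthetic data, consensus, metrics,
                     reliability, analyses, IO, CLI
analysis/            numbered drivers reproducing the study analyses
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      model assumptions, parameters, design decisions
```
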