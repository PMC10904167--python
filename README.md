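# qflap

Quantitative indocyanine-green fluorescence angiography (Q-ICGFA) of
mastectomy-flap perfusion.

After a nipple-sparing mastectomy, the surgeon must decide whether the skin
flap is perfused well enough for immediate breast reconstruction.
Intraoperative ICG fluorescence angiography films the flap with a
near-infrared camera while an intravenous ICG bolus washes in; visual
interpretation of these videos is subjective, and single-frame intensity
readings discard the inflow dynamics. `qflap` turns the full angiogram video
into numbers: per-region time–intensity curve milestones, perfusion
heatmaps, cohort statistics, and a classifier for perfusion-related
complications (PRC — the composite of necrosis, wound dehiscence, infection
and implant loss). It is written for surgical-imaging researchers analysing
flap ICGFA cohorts, and ships a synthetic angiogram generator so the entire
pipeline runs and is tested without any clinical data.

## The quantification model

The flap is annotated as a single ROI and partitioned into 14×14-pixel
boxes. Each box's mean intensity over time (8-bit grey units, "g.u.";
nominally 30 frames/s over 90 s) is a fluorescence inflow curve, summarised
by the standard milestones, extracted from the raw curve (prefix *n*) and
after Savitzky–Golay smoothing:

- **latency** — time from recording start to inflow initiation (onset =
  first sustained rise above baseline median + max(3·MAD, 2 g.u.));
- **F<sub>max</sub> / nF<sub>max</sub>** — peak brightness (g.u.);
- **T<sub>max</sub> / nT<sub>max</sub>** — time from end of latency to peak;
  **peak time** = latency + T<sub>max</sub>;
- **upslope** = (F<sub>max</sub> − onset value)/T<sub>max</sub> (g.u./s);
- **T50, F50, upslope50** — time to half-maximal rise, the intensity there,
  and the gradient up to it;
- the intraoperative decision rule: proceed only if the absolute intensity
  at 90 s is ≥ 14 g.u.

Boxes are aggregated over three regional schemes — quadrants (UIQ/UOQ/
LIQ/LOQ, laterality-aware), concentric halves and concentric thirds (the
normalised radius bisected or divided in three) — plus the whole breast.
Group comparisons use Mann–Whitney U / Wilcoxon signed-rank (exact null for
small samples) and Fisher's exact test, at p < 0.05. For PRC prediction,
features (metric × region) are ranked by −log₁₀ p of a Kruskal–Wallis test,
the cohort is re-balanced (all PRC cases plus an equal-size seeded sample of
the rest), and a Gaussian naïve Bayes model is evaluated by stratified
cross-validation with pooled out-of-fold confusion/ROC reporting over 30
seeded repetitions.

## Worked example

Render one synthetic angiogram, extract per-box curves, and tabulate
regional milestones:

```python
from qflap import CohortSpec, Geometry, generate_case, build_box_grid, extract_box_series
from qflap.metrics import milestones_for_boxes
from qflap.regions import assign_all, aggregate_region_metrics

geom = Geometry(width=256, height=192, frame_rate=10, duration_s=90)
spec = CohortSpec("demo", n_cases=1,
                  metrics={"Fmax": (79.1, 37.5), "latency": (16.6, 8.5),
                           "Tmax": (29.3, 14.0)})
case = generate_case(spec, 0, seed=7, geometry=geom)
grid = build_box_grid(case.roi, 14)
series = extract_box_series(case.stack, grid, case.roi)
mil = milestones_for_boxes(series, geom.frame_rate)
reg = aggregate_region_metrics(mil, assign_all(grid, case.roi))
print(reg[["latency", "F_max", "T_max", "upslope", "n_boxes"]].round(2))
```

```
              latency  F_max  T_max  upslope  n_boxes
region
whole_breast    31.21  55.68  23.87     2.15      138
LOQ             30.40  53.63  23.41     2.15       35
LIQ             30.39  54.31  23.84     2.13       30
UOQ             33.39  55.57  23.81     2.07       38
UIQ             30.34  59.04  24.42     2.26       35
inner_half      31.23  59.02  23.92     2.28       36
outer_half      31.20  54.51  23.85     2.11      102
inner_third     32.89  57.70  23.07     2.24       16
middle_third    28.50  58.82  26.14     2.23       46
outer_third     32.49  53.36  22.67     2.09       76
```

This flap drew a dim case (ground-truth whole-flap peak 53.4 g.u., well
below the 79.1 g.u. group mean): latencies are long (~31 s), peaks are low
(~56 g.u.), and the centre-brighter gradient shows as inner regions
outperforming outer ones. Each row is the unweighted mean over that region's
valid boxes; `n_boxes` is how many boxes contributed.

The same flow is available from the shell:

```sh
qflap run --config run.yaml --out results/ --seed 7
qflap heatmap --stack case.tif --mask case_mask.png --metric nF_max \
      --resolution pixel --out map.png
```

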