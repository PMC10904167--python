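# Methods

## Signal model

An angiogram recording is a stack of 8-bit grayscale frames (grey units,
0–255) at a fixed frame rate. The synthetic generator models each analysis
box's fluorescence inflow as a smoothstep ramp with linear washout:

```
F(t) = b                                   t <  L
F(t) = b + (P − b)·S((t − L)/R)            L ≤ t ≤ L + R,  S(u) = u²(3 − 2u)
F(t) = P − w·(t − L − R)                   t >  L + R
```

with baseline `b` (g.u.), latency `L` (s), rise time `R` (s), peak `P`
(g.u.) and washout rate `w` (g.u./s), clipped to [0, 255]. Real ICG bolus
kinetics are often described by gamma-variate or compartment models; the
smoothstep was chosen deliberately because every milestone of the
extraction rules then has a closed form, so the extractor can be tested
against analytic oracles. `R` maps one-to-one onto the Tmax milestone and
`P` onto Fmax, which lets cohort targets be stated directly in milestone
units. Additive components: a sinusoidal drift (respiratory artifact,
default amplitude 1 g.u., period 4 s), white sensor noise (default
SD 2 g.u.) and 8-bit quantisation with clipping at 255 — the saturation
failure mode real datasets are screened for.

## Synthetic cohorts

A cohort group is described by (mean, SD) targets for whole-flap Fmax,
latency and Tmax; the shipped presets carry the published whole-breast
group summaries for reconstructions with vs without perfusion-related
complications (PRC), and for immediate vs delayed reconstruction at the
index procedure (e.g. Fmax 79.10 ± 37.47 vs 59.38 ± 25.47 g.u. for
no-PRC vs PRC). Per-case parameters are truncated-normal draws from these
targets; per-box parameters modulate the case draw with (i) a
centre-brighter radial gradient (default centre/periphery ratio 1.3,
normalised to preserve the flap mean) reflecting the better-perfused flap
centre, and (ii) a spatially correlated fractional field (Gaussian
smoothing over ~2 boxes, CV 10%). Box curves are rendered into frames with
shared per-box noise plus independent pixel noise and quantised. Artifacts
are injected per-case with configurable probabilities: saturation (central
boxes pushed beyond the ceiling), missed inflow (zero latency — recording
started after the bolus), and hand-held camera wobble (sinusoidal frame
translation). Outcome flags are drawn so the composite-PRC label matches
the group, with component frequencies in the published proportions.

What the generator does **not** emulate: tissue texture, camera pose and
perspective, instrument/hand intrusion, bleeding, inter-metric clinical
correlations beyond those induced by the curve model, or ICG
pharmacokinetics. Passing tests therefore demonstrate the correctness of
the quantification machinery under the stated signal model, not clinical
performance on real angiograms.

Default geometry is the clinical acquisition (1024×768 px, 30 fps, 90 s).
Test and example runs use reduced geometries (e.g. 160×120–256×192 px at
2–10 fps); the analysis is resolution-agnostic, and all geometry is
configurable.

## Gridding and regions

The ROI bounding box is tiled with 14×14-px boxes; a box is kept iff the
mask covers its central 2×2 pixel block (single centre pixel for odd box
sizes). An even-sized box has no centre pixel, and the symmetric central
block makes membership exactly invariant under left–right mirroring.
Column tiling is anchored at the anatomically *lateral* edge of the
bounding box (image-left for a right breast viewed from the front), so
flipping the image and toggling laterality maps boxes onto boxes exactly —
a property the test suite checks on random flap outlines. Row tiling is
anchored at the top.

Quadrants split at the mask centroid; "inner" (medial) is the
larger-column side for a right breast and mirrored for a left breast.
Concentric schemes use the normalised radial position
`u = |centre − centroid| / (distance from centroid to the ROI boundary
along that ray)`, with the boundary found by sub-pixel ray marching
(step 0.25 px, midpoint of the last-inside/first-outside pair); halves
split at u = 1/2, thirds at 1/3 and 2/3. Boundary ties go to the
inner/upper/medial label. A flap whose centroid falls outside the mask is
rejected for concentric schemes with a diagnostic. Region metrics are
unweighted means over member boxes' milestones (box-level averaging keeps
the per-box distribution that the statistics operate on); regions with no
valid boxes report missing values, never zero.

## Milestone extraction

Smoothing is Savitzky–Golay, window ≈ 1 s (rounded to an odd frame count),
polynomial order 3: long enough to suppress sensor noise and fine
hand-held motion, short enough to preserve respiration-scale structure.
Onset ("inflow initiation") has no published operational rule, so the
package defines one: baseline = median of the first 2 s of the smoothed
series; onset = first sample exceeding baseline + max(3·MAD, 2 g.u.) that
stays above threshold for ≥ 1 s. If the series is already rising across
the baseline window (no observable baseline), latency is 0. Latency is
measured from recording start; recordings begin at first detected
fluorescence, so the injection-to-onset offset is unidentifiable and is
not estimated. T50 is measured from the end of latency (parallel to
Tmax); the half-maximal level is referenced to the onset value, not to
absolute zero, so a nonzero baseline does not bias T50. Upslope is the
chord gradient (Fmax − onset)/Tmax, not a fitted slope. Times are reported
at frame resolution (no sub-frame interpolation). Degenerate inputs —
no detectable onset, no rise above onset, instant peak — flag the curve
invalid with missing milestones rather than zeros.

Two numerical consequences are worth knowing. First, the threshold rule
fires where the curve crosses baseline + 2 g.u., which for a slow
smoothstep foot is up to a couple of seconds after the true ramp start;
recovered latency is therefore the closed-form crossing time of the rule,
not `L` itself, and the tests assert exactly that. Second, the smoothstep
has zero slope at its peak, so the smoothed-series argmax (peak time,
Tmax) can sit anywhere within about half a smoothing window of the
continuous curve's corner; the tests pin those milestones against an
independent re-implementation of the smoother (explicit per-window
least-squares fits) and bound the corner deviation structurally.

## Quality control

Three published exclusion criteria are operationalised (flagging, not
auto-exclusion — exclusion is a pipeline configuration choice):
saturation — more than 1% of ROI pixels at ≥ 254 g.u. in any frame (the
threshold tolerates isolated specular pixels); missed inflow — the
ROI-mean series reaches 90% of its maximum within the first second;
excessive motion — the intensity-weighted ROI centroid, restricted to
frames with ROI mean ≥ 10 g.u. (darker frames carry no localisable
signal) and smoothed over ~1 s to suppress noise jitter, drifts faster
than 2 px/s on average. Instrument intrusion and bleeding are visual
criteria with no published operational definition and are out of scope.

## Statistics

Independent comparisons use the two-sided Mann–Whitney U test, paired
comparisons the Wilcoxon signed-rank test. Exact null distributions are
used for small samples (MWU: combined n ≤ 25 without ties; Wilcoxon: ≤ 12
non-zero differences, via full sign-pattern enumeration with midranks,
which also handles tied magnitudes); otherwise the tie-corrected normal
approximation. Shapiro–Wilk normality is computed as a diagnostic only —
the nonparametric p value is always the one reported. Frequency tables use
the two-sided Fisher exact test; a zero margin returns p = 1 with a
warning. Significance is p < 0.05 with **no** multiplicity correction
across the many metric×region rows (the rendered report states this), and
each breast is treated as one record.

## Complication classifier

Features are metric × region milestone means per breast. Ranking uses the
Kruskal–Wallis test, scored as −log₁₀ p (χ² approximation, df = 1), ties
broken by feature name; constant features score 0. Because PRC cohorts are
heavily imbalanced, training uses a balanced subset: all minority-class
cases plus an equal-size seeded uniform sample of the majority class.
The model is Gaussian naïve Bayes (continuous milestone features;
scikit-learn's default variance smoothing of 1e-9 of the largest feature
variance); k-NN and decision-tree comparators are available behind a flag
but never headline. Evaluation is stratified cross-validation with as many
folds as the minority class — on a balanced 13+13 subset this is
leave-one-per-class-out, so every training fold stays balanced. Plain
leave-one-out is available as a config option but is not the default: on
balanced two-class data its pooled out-of-fold scores are structurally
pessimistic (the held-out case depletes its own class in training), which
drives the permutation-null AUC well below 0.5 (≈ 0.32 measured on this
problem) and would misstate chance performance. Pooled out-of-fold class-1
probabilities give the confusion matrix (threshold 0.5), the derived
sensitivity/specificity/PPV/NPV/accuracy (undefined ratios reported as
missing), and the ROC/AUC by the rank method with tie handling. Model
"refinement" is 30 seeded repetitions of balance → cross-validate,
summarised by the mean and dispersion of every metric — the dispersion
shows how sensitive headline numbers are to the majority-class subsample.

## Heatmaps

Any milestone renders as a colour map at box resolution or at pixel
resolution (the batch extractor run on every ROI pixel's own series,
chunked to bound memory; smoothing defaults unchanged). Brightness-like
metrics map larger values to the bright colormap end; time-like metrics
use the reversed colormap so *faster* is also "better". Colour limits
default to each map's own data range, with an explicit annotated range in
the figure; a fixed-scale mode supports cross-case comparison, since
per-image ranges make visually similar maps incomparable. Invalid cells
render in a dedicated no-data grey. The value matrix is written as an
unrounded CSV sidecar, so the image is pure presentation. No clinical
decision thresholds are attached to heatmap display.

## Pipeline

Stages (simulate → QC/extract → milestones → regions → stats → train →
heatmap) hand data over as plain files (TIFF/PNG/CSV/JSON) for
inspectability. Every run writes a manifest with the configuration hash,
seed, package version and QC exclusions with reasons; identical
configuration and seed reproduce all numeric outputs byte-for-byte. All
randomness flows from `numpy` SeedSequences spawned per case/repetition.

## Known limitations

- The curve model is phenomenological; no pharmacokinetic interpretation
  of its parameters is intended.
- Synthetic inter-metric correlations arise only implicitly from the curve
  model; clinical correlation structure is unknown from group summaries
  alone.
- Milestones are frame-resolution; sub-frame accuracy would require
  interpolation that the noise level does not justify.
- The onset rule, saturation fraction, motion threshold and smoothing
  window are package conventions where no published operational values
  exist; all are configurable.
- Classifier results on synthetic cohorts characterise the pipeline, not
  expected clinical performance.
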