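# cropheight

Automatic crop-height measurement from daily field-camera images of a
striped reference marker bar.

## The problem

Crop height is one of the most direct indicators of growth state and yield
potential, but surveying a paddy by hand is expensive and happens at most a
couple of times per season. An in-field sensor station ("field server")
with a fixed RGB camera can photograph the crop every day; if a marker bar
of known length is staked in the camera's view, the crop's height can be
read off each frame indirectly: the taller the crop, the less of the bar
remains visible. This package implements that measurement pipeline for
agronomists and phenotyping engineers running such stations — from raw
frame to a corrected, evaluated daily height series — plus a synthetic
scene generator so the whole pipeline is testable without field data.

## The method

Four image-processing stages per frame:

1. **Band selection.** The bar carries alternating red and white stripes
   (easy for a human to count, hard to segment). In the excess-green index

   `ExG = 2G − R − B`

   both stripe colours score at or below zero while vegetation scores
   high, so the striped bar becomes one homogeneous dark object; ExG also
   cancels channel-common illumination shifts. The raw red band (where
   both stripe colours are bright) is supported for comparison.

2. **Filtering.** A square zero-row-sum kernel sized to the bar: for a bar
   `w` px wide the kernel is `(2w+1) × (2w+1)`, its central `w` columns one
   negative constant and the flanking columns one positive constant, each
   column constant top to bottom. Dark bar under the negative centre plus
   bright canopy under the positive flanks drive the response up exactly
   along the bar (w = 5 → 11×11; w = 3 → 7×7; w = 7 → 15×15). Classical
   Laplacian and directional kernels are included as baselines.

3. **Thresholding.** A single clip level (strictly greater → 1) turns the
   response into a binary mask; the level is either the shipped default
   (2000) or learned as the midpoint of the gap between labelled marker
   and background samples.

4. **Height measurement.** The bar is the longest vertical run of mask
   pixels. With `I` / `L` the initial visible bar in pixels / cm and `R`
   the initial crop height, a detection of `M` pixels gives

   `H = ((I − M) / I) · L + R`  (cm).

At the series level, the station's rain gauge flags frames taken during
rainfall (blur truncates the segmented bar; with the red band, darkness
days < 400 W/m² are flagged too) and flagged estimates are replaced by
interpolation from reliable neighbouring days. Accuracy is scored as
relative error `|est − ref| / ref × 100`, and features are compared with
Welch's t-test on their error columns.

## Worked example

Render a synthetic 48-day season shaped like a real one (growth from 77 to
119 cm easing to 100 cm, five weather conditions), calibrate on the first
frame, and measure the season:

```python
import dataclasses, os, tempfile
import cropheight as ch

# 1. Synthetic season with ground truth
workdir = tempfile.mkdtemp()
heights, conditions = ch.reference_season()
ch.generate_series(ch.SceneSpec(seed=3), heights, conditions, out_dir=workdir)

# 2. Calibrate on the first frame (77 cm crop hides 77 of the 230
#    above-ground cm, so 153 cm of bar are visible)
marker = ch.MarkerReference(initial_px=1, initial_cm=153.0, initial_crop_cm=77.0,
                            above_ground_cm=230.0, stripe_cm=10.0, marker_width_px=5)
config = ch.PipelineConfig(marker=marker)
frame = ch.read_rgb(os.path.join(workdir, "2012-07-01.png"))
response = ch.response_plane(frame, config)
run = ch.longest_vertical_runs(ch.apply_threshold(response, ch.DEFAULT_THRESHOLD))[0]
print(f"initial bar: {run.length} px for 153 cm visible")

config = ch.PipelineConfig(
    marker=dataclasses.replace(marker, initial_px=run.length),
    sensor_csv=os.path.join(workdir, "truth.csv"),
    reference_csv=os.path.join(workdir, "truth.csv"),
)

# 3. Measure the season: estimate, flag rain, hybrid-correct, evaluate
series, report = ch.run_series(workdir, config)
rain = next(r for r in series if r.condition == "rainfall")
print(f"rain day {rain.date}: estimated {rain.estimated_cm:.1f} cm, "
      f"corrected to {rain.corrected_cm:.1f} cm (true 117.0 cm)")
print(f"season relative error: mean {report['mean_error_pct']:.2f}% "
      f"sd {report['sd_error_pct']:.2f}% over {report['n_frames']} days")
```

Output:

```
initial bar: 160 px for 153 cm visible
rain day 2012-07-25: estimated 160.2 cm, corrected to 115.2 cm (true 117.0 cm)
season relative error: mean 3.17% sd 1.56% over 48 days
```

The rain frame is blurred, so segmentation keeps only part of the bar and
the raw estimate overshoots (160.2 cm vs 117 true); the rain gauge flags
the day and linear interpolation from its neighbours repairs it. The
season-wide mean error of ~3% on synthetic frames sits right where the
method's published field accuracy lies.

The same flow is available from a shell:

```bash
cropheight simulate --out frames/ --seed 3
cropheight estimate frames/2012-07-01.png -c config.yaml
cropheight series frames/ -c config.yaml
cropheight learn-threshold frames/2012-07-01.png -c config.yaml \
    --marker-roi 360,220,1,200 --background-roi 10,10,200,400
cropheight evaluate heights.csv --reference truth.csv
```

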