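# orgcompete

Quantification of cell competition in 3D images of mixed organoids and
microtissues.

When intestinal cancer cells and wild-type liver cells are grown
together in a single 3D culture, the cancer population progressively
outcompetes the liver cells: the wild-type cells compact, arrest their
cell cycle, lose the progenitor state and are eventually eliminated.
Measuring this requires counting and phenotyping thousands of nuclei in
multi-channel confocal stacks.  `orgcompete` is a reusable pipeline for
exactly that analysis, aimed at groups doing organoid co-culture /
competition experiments:

- **Per-channel processing** of DAPI, membrane (mTmG, Dendra2),
  nuclear-label (H2B), pulse (EdU, pH3) and transcription-factor (SOX9)
  channels: data-driven kernel-size estimation, adapted top-hat
  background subtraction, below-mean thresholding, Li minimum
  cross-entropy thresholding and two-round watershed splitting.
- **3D nucleus detection** by a distance-transform-seeded watershed
  with physical (µm) seed spacing, plus per-nucleus volume, ellipsoid
  semi-axes and elongation.
- **Classification** via the volume ratio α = marker volume / nuclear
  volume (α ≥ 0.1 for mTmG/EdU/pH3, α ≥ 0.25 for H2B), per-experiment
  normalised SOX9 percentile classes (low < P25 < mid < P75 < high),
  FUCCI2 cell-cycle phases (mCherry⁺/mVenus⁻ = G1, mCherry⁻/mVenus⁺ =
  S-G2-M, double-negative = G0-like) and EdU/pH3 cycle states.
- **Competition metrics**: population fractions, expansion ratios
  N(t)/N(0), doubling times from log-linear fits (T_d = t / log₂ F for
  a fold change F over time t), mean 5-nearest-neighbour inter-nuclear
  distance, simple linear regression (slope, R², p), per-population
  microtissue volumes and Cleaved-Caspase3 counts in standard
  250 × 250 × 50 µm crops.
- **A synthetic 3D image generator** with exact ground truth — two
  intermingled or patch-structured nuclear populations, exponential
  growth with population-specific doubling times, competition-coupled
  cell-cycle arrest, geometric compaction, per-channel intensity models
  and imaging noise — used to validate every stage of the pipeline.

The scientific background, model assumptions and numerical choices are
documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a mixed organoid (55% wild-type seeding, wild-type doubling
time 33 h, cancer 15 h, competition-coupled arrest), image the first
frame, and run the full analysis:

```python
import numpy as np
from orgcompete import (KernelSpec, assign_population_df,
                        default_marker_models, detect_nuclei_3d,
                        estimate_kernel_radius, fit_doubling_time,
                        generate_nucleus_field, internuclear_distance,
                        mixed_organoid_params, population_fractions,
                        process_dapi, process_population_channels,
                        quantify_marker, render_stack, simulate_timelapse)

params = mixed_organoid_params(
    n_nuclei_initial=150, duration_h=60.0, frame_interval_h=5.0,
    geometry="solid", min_separation_um=9.0, seed=1,
    marker_models=default_marker_models(("DAPI", "mTmG", "Dendra2")))
truth = simulate_timelapse(generate_nucleus_field(params), params)

# image analysis on the first frame
stack = render_stack(truth, params, frame=0)
dapi = stack.get_channel("DAPI").astype(float)
kernel = KernelSpec(estimate_kernel_radius(dapi))
masked, _ = process_dapi(dapi, kernel)
records, labels = detect_nuclei_3d(masked, kernel, params.voxel_size)
wt_mask, _ = process_population_channels(
    stack.get_channel("mTmG").astype(float),
    stack.get_channel("Dendra2").astype(float), kernel)
records = quantify_marker(records, labels, wt_mask, "mTmG")
records["population"] = np.where(
    assign_population_df(records, "mTmG"), "WT", "cancer")

fractions = population_fractions(records["population"])
print(f"kernel radius: {kernel.radius_px:.2f} px")
print(f"nuclei detected: {len(records)} (truth: {(truth['frame'] == 0).sum()})")
print(f"WT fraction at t=0: {fractions['WT']:.1f}%")

counts = truth.groupby(["frame", "population"]).size().unstack(fill_value=0)
times = counts.index.to_numpy() * params.frame_interval_h
for pop in ("WT", "cancer"):
    td = fit_doubling_time(counts[pop].to_numpy(), times)
    expansion = counts[pop].iloc[-1] / counts[pop].iloc[0]
    print(f"{pop}: {expansion:.1f}x over 60 h, doubling time {td:.1f} h")

wt0 = truth[(truth["frame"] == 0) & (truth["population"] == "WT")]
_, knn = internuclear_distance(wt0[["z_um", "y_um", "x_um"]].to_numpy())
print(f"WT 5-NN distance at t=0: {knn:.2f} um")
```

Output:

```
kernel radius: 5.05 px
nuclei detected: 147 (truth: 150)
WT fraction at t=0: 51.7%
WT: 1.9x over 60 h, doubling time 61.1 h
cancer: 14.7x over 60 h, doubling time 15.2 h
WT 5-NN distance at t=0: 21.00 um
```

The kernel radius (~5 px ≈ 4 µm at 0.83 µm/px) is recovered from the
image itself; 147 of 150 ground-truth nuclei are detected and assigned
a population by their mTmG volume ratio.  In the time-lapse the cancer
population expands 14.7× in 60 h while the wild-type population only
doubles: its *effective* doubling time (61 h) is much longer than its
intrinsic 33 h cycle because a growing fraction of wild-type divisions
produce arrested, G0-like daughters — the signature of competition.
The 5-NN distance is the compaction readout: compacted wild-type
coordinates shrink this value by exactly the imposed factor.

## Command line

A thin CLI wraps the library for shell use:

```bash
orgcompete fixtures out/fixtures --seed 1     # synthetic test suite
orgcompete crop stack.ome.tif rois.csv out/   # per-organoid crops
orgcompete preprocess stack.ome.tif dapi.ome.tif --channel-role dapi --kernel auto
orgcompete segment dapi.ome.tif nuclei.csv --kernel 5 --voxel-size 2.5 0.83 0.83
orgcompete classify nuclei.csv                # appends class columns
orgcompete metrics nuclei.csv summary.csv     # per-organoid summary
```

`preprocess` writes a JSON sidecar recording the kernel radius and
thresholds used, so every run is reproducible.

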