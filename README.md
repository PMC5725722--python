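# megconsist

How robust are MEG source-space connectivity and network estimates to errors
in the assumed head anatomy? Atlas-based MEG analyses co-register the sensor
data with an anatomical image before beamforming; when a subject's own MRI is
unavailable, a population template is substituted, which displaces the assumed
source positions by millimeters to centimeters. `megconsist` implements, on
fully synthetic data, the complete analysis chain needed to quantify what such
displacements do to the derived measures — and the agreement statistics used
to report it.

The package is aimed at methods researchers in electrophysiological
connectomics who want a tested, reproducible sandbox for co-registration
robustness questions: every stage is a pure function of configuration and
seed, and the whole experiment runs on one CPU in minutes.

## The pipeline

1. **Synthetic recording.** Narrowband cortical sources with configurable
   constant-phase-lag coupling in the classical frequency bands (delta
   0.5–4 Hz … gamma 30–48 Hz) are placed in ROI patches inside a spherical
   volume conductor and forward-projected (Sarvas closed form) onto a
   151-channel-style hemispheric sensor array at 625 Hz, plus white sensor
   noise.
2. **Two anatomies.** The true ("native") source geometry, and a displaced
   ("template") copy in which every voxel is moved by a configurable
   magnitude — the stand-in for template-MRI co-registration error.
3. **Beamforming.** Per band, a scalar LCMV/SAM virtual electrode per voxel,

   `VE = (LᵀC⁻¹L)⁻¹ LᵀC⁻¹B = WᵀB`,

   with the power-maximizing dipole orientation and unit gain `WᵀL = 1`. Each
   ROI is summarized by its pseudo-Z peak voxel or by its geometric centroid.
4. **Measures.** Relative band power per ROI; phase lag index (PLI)
   connectivity `|⟨sign sin Δφ(t)⟩|` per epoch; weighted clustering, Dijkstra
   path length on 1/PLI, Newman modularity by seeded simulated annealing
   (averaged over runs), and the Kruskal minimum spanning tree with degree,
   leaf fraction and diameter.
5. **Consistency.** Template vs native compared as two fixed raters:
   ICC(3,1) = (MS_rows − MS_err)/(MS_rows + MS_err) with McGraw–Wong 95% CIs
   and conventional ratings, Bland–Altman limits (mean ± 1.96 SD of the
   differences), and the Pearson correlation between per-ROI voxel
   displacement and per-ROI power ICC.

## Worked example

```python
from megconsist import desk_scale_config, run_experiment
from megconsist.pipeline import mean_global_icc_by_displacement

result = run_experiment(desk_scale_config(seed=1))
print(mean_global_icc_by_displacement(result))
```

prints

```
displacement_mm
0.0     1.000000
5.0     0.521140
15.0    0.292726
30.0    0.109928
Name: icc, dtype: float64
```

With identical anatomies every global measure agrees exactly (ICC 1). As the
template geometry is displaced by 5, 15 and 30 mm, the mean subject-level
ICC across the eight global measures (mean power, mean PLI, clustering, path
length, modularity Q, module count, MST leaf fraction, MST diameter) decays
monotonically — reconstruction error propagates into every downstream
network statistic. `result.regional_icc`, `result.distances` and
`result.distance_power_corr` hold the per-ROI tables; larger representative-
voxel displacements go with lower power consistency (negative Pearson r when
pooled across displacement levels).

The same experiment is available from a shell:

```sh
megconsist run -c config.yaml -o out/        # full experiment, CSV + manifest
megconsist simulate -c config.yaml -o sim/   # one subject's synthetic recording
megconsist report -d out/                    # JSON summary of global ICCs
```

An empty config reproduces the default acquisition geometry (151 channels,
625 Hz, 4096-sample epochs — 6.554 s each — 78 ROIs, six bands, 17 subjects).

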