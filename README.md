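# surftrack

Label-free live-cell analysis of bacterial surface colonization under flow.

When rod-shaped bacteria (*E. coli*) bind to the floor of a microfluidic
channel and adapt to surface life, a brightfield time-lapse contains far
more than a cell count: every bound cell's length trace reports its
metabolic state, the colonization curve mixes division with detachment,
and the small wiggle of each cell about its median axis reveals *how* it
is attached.  `surftrack` is a pipeline for extracting all of this from
label-free movies — built for researchers screening antibacterial surface
coatings (e.g. covalently grafted antimicrobial peptides) who need
mechanistic readouts, not just end-point counts.  Because raw footage of
this kind is rarely shareable, the package includes a first-class
synthetic-scene generator with exact ground truth, used to validate every
estimator end to end.

## What it computes

**Segmentation and tracking** (brightfield, 2 fps): 20-frame block
averaging suppresses moving unbound cells; illumination is flattened by a
robust polynomial fit; the cell mask is built by constant-offset
subtraction, two median-filter passes, a marker-controlled watershed
seeded from the distance transform, and area/aspect/solidity gates that
exclude round confounders.  Observations are stitched into trajectories
when footprints overlap and length changes by <25%, with 1-min gap
bridging and division detection (one footprint → two, lengths summing to
the mother's), giving full lineages.

**Growth kinetics.** The momentaneous growth rate GR(*t*) of a cell is the
OLS slope of its length trace over ±5 min.  Per-cell rates are pooled in
20-min bins; the binned medians of GR(*t*) and length *L*(*t*) are fitted
with a Gompertz sigmoid

    y(t) = y0 + (A − y0)·exp(−exp(−k·(t − t_i)))

whose inflection *t*<sub>i</sub> is the **transition time** from the
post-binding adaptation lag to the biofilm growth phase.  The duplication
time is  T₂(t) = (2/3)·L(t_end)/GR(t).

**Binding kinetics.** The count of bound cells follows
N(t) = N₀·exp(∫<sub>t₀</sub><sup>t</sup> [ln2/T₂(s) − ln2/T₁/₂] ds)
in the exponential phase; with T₂ known from the growth analysis, fitting
this curve yields the mean surface-residence half-life **T₁/₂**.

**Binding mode.** Over 2-min full-frame-rate windows, each cell's axis
angle θ to the flow gives (θ_M, STD(θ)); the standard deviation of the
lateral separation of each position *l* along the axis from the median
axis is V-shaped with its vertex at the rotation pivot.  A central pivot
with a symmetric profile ("rocking") indicates distributed,
fimbriae-mediated binding; an off-centre pivot ("twisting") indicates a
single adhesive patch.

## Worked example

```python
from surftrack import RunConfig, SceneConfig, SegmentationParams, run_pipeline

scene = SceneConfig(                   # a wild-type-like colonization movie
    duration_min=110, frame_rate_fps=1/30, image_shape=(480, 480),
    injection_window_min=20, arrival_rate_per_min=0.7,
    min_spacing_um=6.5, initial_length_um=(2.6, 0.3),
    detach_halflife_min=60.0, daughter_detach_prob=0.0,
    noise_sd=0.02, illumination_coeffs=[[1.0, 0.08], [0.12, 0.0]], seed=42)
bundle = run_pipeline(RunConfig(
    scene=scene, segmentation=SegmentationParams(averaging_block=1),
    motion_windows_min=(30.0, 100.0), motion_window_duration_min=5.0))
print(bundle["summary"])
```

prints (seed 42; values rounded here for display):

```
{'name': 'run', 'condition': 'control',
 'n_trajectories': 116, 'n_growth_trajectories': 68,
 'initial_gr_um_per_min': 0.0467, 'final_gr_um_per_min': 0.0872,
 'transition_time_min': 42.4, 'T2_end_min': 24.9,
 'T_half_min': 58.0, 'N0': 14.8,
 'mode_fractions': {'rocking@30min': 1.0,
                    'rocking@100min': 0.914, 'twisting@100min': 0.086}}
```

Read: the population grew at 0.047 µm/min during the adaptation lag and
0.087 µm/min afterwards, with the transition at ≈42 min; near the end a
cell duplicated every ≈25 min while leaving the surface with a half-life
of ≈58 min (the scene was configured with 60 min); almost all cells rock
about their centres, the signature of fimbriae-mediated binding.  The
generating scene used growth 0.045 → 0.09 µm/min with *t*<sub>i</sub> = 45
min, so every number above is a round-trip estimate, not an input.

The same chain is available from the shell:

```bash
surftrack simulate --config scene.toml --out movie.tif --truth truth.csv
surftrack segment  --in movie.tif --out observations.csv
surftrack track    --in observations.csv --out trajectories.csv
surftrack analyze-growth  --in trajectories.csv --out results/
surftrack analyze-binding --obs observations.csv --growth results/gompertz_fits.json --out binding.json
surftrack analyze-motion  --in trajectories.csv --windows 30,160 --out motion/
surftrack run-all  --config scene.toml --out results/     # everything at once
surftrack report   --config scene.toml --out figures/     # standard figure set
```

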