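# axodyn

Single-particle tracking of quantum-dot-labelled cargo moving along
neuronal axons: a complete, reproducible pipeline from raw EMCCD movies
(or simulated ones with known ground truth) to region-stratified transport
kinetics.

## Who this is for

Labs that track discrete, blinking fluorescent labels — typically
quantum-dot-conjugated neurotrophins internalized into signaling
endosomes — as they undergo retrograde transport along sensory-neuron
axons grown in compartmentalized microfluidic devices. The pipeline
recovers, for every tracked cargo, the standard trajectory statistics and
an active/pause decomposition of motor-driven transport, and compares
kinetics between distal axons (microchannels), proximal axons (cell-body
compartment) and somata.

## The analysis chain

1. **Camera calibration** (`axodyn.calibration`): ADU → photons with the
   mean-variance (photon-transfer) method; flat-field correction for
   fixed-cell imaging.
2. **Detection** (`axodyn.detection`): difference-of-Gaussians bandpass,
   strict local maxima, then maximum-likelihood fitting of a
   pixel-integrated Gaussian PSF under the Poisson photon model.  Each
   localization carries a Cramér–Rao-bound precision and a Poisson
   deviance fit-quality score used for filtering.
3. **Linking** (`axodyn.linking`): frame-to-frame linear assignment with
   birth/death costs derived from the quantum-dot blinking model
   (−log of the per-frame off/on probabilities), plus gap closing across
   dark periods.
4. **Trajectory metrics** (`axodyn.metrics`): for a track
   {p_i, t_i}, i = 1…N —

   | statistic | definition |
   |---|---|
   | net displacement | d_net = ‖p_N − p_1‖ |
   | max displacement | d_max = max_{i,j} ‖p_i − p_j‖ |
   | net speed | s_net = d_net / (t_N − t_1) |
   | mean curvilinear speed | s̄ = mean_i ‖p_{i+1} − p_i‖ / (t_{i+1} − t_i) |
   | linearity of forward progression | r_lin = s_net / s̄ |
   | diffusion constant | MLE of D with per-localization precision, increments d_i ~ N(0, 2DΔt_i + σ_i² + σ_{i+1}²) |

   plus a sliding-window (7 localizations) linear-fit instantaneous
   velocity.
5. **Segmentation** (`axodyn.segmentation`): motion taxonomy (stationary /
   confined back-and-forth / active transport) and two-threshold
   hysteresis segmentation of active transport into alternating active
   and paused phases, with changepoint-refined boundaries.
6. **Regional analysis** (`axodyn.regional`): region labels from the
   chamber geometry, 200-µm transport-distance histograms, the regional
   kinetics grid (active speed, active duration, paused duration ×
   region), coordinated-pair detection (< 2 µm criterion), and Welch/ANOVA
   group comparisons.

A synthetic-data generator (`axodyn.motion`, `axodyn.render`,
`axodyn.presets`) emulates the study conditions — blinking emitters at
17 frames/s, 127-nm pixels, EMCCD noise, motor-driven runs ≈ 1.5 µm/s
interspersed with pauses — so every stage is testable against ground
truth.

## Worked example

Simulate five distal-axon transport trajectories, run the pipeline, and
print the regional summary:

```bash
axodyn simulate --preset distal --seed 1 --out runs/distal
axodyn report runs/distal
```

which prints (abridged):

```
Regional kinetics (mean +/- SEM, n):
  microchannel:
    active_speed_um_s    1.500 +/- 0.069 (n=42)
    active_duration_s    7.251 +/- 0.990 (n=42)
    paused_duration_s    4.362 +/- 0.976 (n=41)
    paused_disp_um       0.095 +/- 0.008 (n=41)
    s_net_um_s           0.821 +/- 0.109 (n=5)
    r_lin                0.539 +/- 0.065 (n=5)
```

Read: the five tracks live in the microchannel (distal axon); their
interior active phases average ≈ 1.5 µm/s for ≈ 7.3 s between pauses of
≈ 4.4 s (the pause SEM is wide — pause durations are heavy-tailed), the
pause displacement ≈ 0.1 µm confirms the cargo stays on the track, and
whole-trajectory net speed ≈ 0.82 µm/s — the run/pause alternation, not
the motor speed, sets the net transport rate
(s_net ≈ s_a·T_a/(T_a+T_p) ≈ 0.88 µm/s at these kinetics). With five
tracks the SEMs are wide; the self-consistency suite below uses 53 per
region.

The same stages run on real data:

```bash
axodyn detect movie.tif --out locs.csv      # needs movie.tif.meta.txt
axodyn link locs.csv --out tracks.csv
axodyn metrics tracks.csv --out stats.csv
axodyn segment tracks.csv --out phases.csv
axodyn analyze tracks.csv --out analysis/
```

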