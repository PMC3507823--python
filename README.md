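# loomkit

Analysis toolkit for looming-stimulus experiments on flying insects:

- **`loomkit.geometry`** — looming-disc geometry with optional wing bars:
  angular subtense and expansion-rate time courses, approach trajectories,
  projected-collision bookkeeping, and per-frame CRT display schedules.
- **`loomkit.kinematics`** — predator speed estimation from digitized video
  tracks with pixel calibration, hierarchical segment → attack → individual
  averaging (anti-pseudoreplication), closing-speed geometry, and
  predator-thorax `l/|v|` (half-size over speed) range estimation.
- **`loomkit.spikes`** — looming-detector spike-train statistics: a windowed
  rate computed at each spike event (25 ms half-wingbeat window, anchoring
  spike included), peak extraction, binned PSTHs with
  presentation → individual → group aggregation, and 150 Hz
  threshold-crossing times.
- **`loomkit.glides`** — glide detection from wingbeat sensor events (pause
  > 1.25× the mean of the preceding 10 intervals), onset timing relative to
  projected collision, and occurrence / before-collision proportions.
- **`loomkit.synth`** — synthetic data generators: a multiplicative
  looming-response rate model (peak rate rising as `l/|v|` falls, peak time
  linear in `l/|v|`), inhomogeneous-Poisson spike trains by thinning,
  rhythmic wingbeat trains with rate-gated glide injection, noisy straight
  attack tracks, and a full battery generator (individuals × stimuli ×
  presentations) with deterministic seed fan-out.
- **`loomkit.io` / `loomkit.cli`** — CSV schemas with validating readers,
  run configuration with manifest output, and the umbrella CLI.

All event times are stored in milliseconds relative to the projected time of
collision (negative = before collision); `t_to_collision` in the geometry
layer is in seconds and positive before collision.

## Command-line usage

```sh
# Per-frame display schedule for a winged looming disc
loomkit stim --half-size 0.04 --speed 15 --wing-span 0.36 --refresh 200 \
    --out schedule.csv

# Hierarchical speed summary from a track table
loomkit kinematics --tracks tracks.csv --cal-px 69.5 --cal-m 0.56 \
    --fps 25 --trim-s 1.25 --out out/

# Predator-thorax l/|v| range from speed statistics
loomkit lov-range --predator-mean 10.76 --predator-sd 1.42 \
    --prey-mean 4.6 --prey-sd 0.65 --wingspan 1.36 --fraction 0.10

# Windowed spike rates and threshold crossings
loomkit spikes --in spikes.csv --window 25 --threshold 150 --out rates.csv

# Glide detection
loomkit glides --in wingbeats.csv --k 1.25 --history 10 --out glides.csv

# Generate a synthetic battery, then run the full pipeline on it
loomkit synth --config sim.yaml --out-dir data/ --seed 1
loomkit run --config run.yaml
```

`loomkit run` reads a flat YAML mapping (input paths, window/threshold/glide
parameters, output directory), writes summary CSVs and a `manifest.json`
echoing every parameter and seed, and rejects unknown configuration keys.

### CSV schemas

| file | columns |
| --- | --- |
| stimuli | `stim_id, half_size_m, speed_m_s, start_m, end_m, wing_span_m, wing_height_m, wing_offset_m` (empty wing columns = no wing) |
| spikes | `individual_id, stim_id, presentation, t_ms` |
| wingbeats | `individual_id, stim_id, presentation, t_ms, valid_flight` |
| tracks | `kite_id, attack_id, segment_id, frame, x_px, y_px` |

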