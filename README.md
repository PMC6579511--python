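# tastekit

A tested, reusable pipeline for quantifying taste-evoked calcium imaging
responses and proboscis extension response (PER) behavior:

- **`tastekit.synthetic`** — generates imaging movies (GCaMP-like transients,
  rigid x-y drift, photon + read noise) and behavioral datasets (two-trial PER
  tests with a state-dependent dose response, directional-PER trials), each
  carrying a ground-truth manifest so every downstream stage can be verified
  by parameter recovery.
- **`tastekit.registration`** — sub-pixel rigid registration within and across
  trials by DFT-upsampled cross-correlation, with periodic Fourier resampling.
- **`tastekit.quantify`** — ROI traces, ΔF/F₀ (F₀ = mean of the 20 pre-stimulus
  frames), peak responses (mean of the two highest consecutive in-window
  frames), integrated responses, per-fly trial averages, and responder calls
  (θ = 0.15 absolute ΔF/F₀ by default, with 0.10 / 0.20 alternatives).
- **`tastekit.behavior`** — PER test scoring (positive ⇔ PER on ≥1 of 2
  trials), fly-level QC policies, group percent-PER summaries (groups of
  15–20 flies are the statistical unit), and directional-PER tallies.
- **`tastekit.stats`** — from-scratch one-way repeated-measures and two-way
  mixed (between × within) ANOVA with Bonferroni post-tests and Monte-Carlo
  Dunnett many-to-one comparisons, plus type-I/power simulation audits.
- **`tastekit.io` / `tastekit.cli`** — TIFF movies, YAML session manifests,
  CSV tables, JSON summaries, and the command-line pipeline.

## CLI

```sh
tastekit simulate --out scratch/sim --seed 1 --stimuli "water:0,stim:0.5"
tastekit register --in scratch/sim/manifest.yaml --upsample 20 --out scratch/reg
tastekit quantify --in scratch/reg --theta 0.15 --out scratch/tables
tastekit per-summarize --in per.csv --policy compare_groups --out groups.csv
tastekit per-stats --in groups.csv --design two-way-rm --between state --within dose --out stats
tastekit per-directional --in directional.csv
tastekit run-all --manifest scratch/sim/manifest.yaml --out scratch/full
```

## Conventions

Pixel indices are 0-based `(row, col)`; shifts are `(dx, dy)` with `dx`
along columns; frame indices are 0-based and stimulus windows include both
onset and offset frames. ΔF/F₀ is dimensionless (0.15 = 15 percentage
points). All randomness flows from one seed through named substreams, so
identical parameters and seed give bit-identical outputs.
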