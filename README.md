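# svtrack

Single-particle tracking and mobility analysis for synaptic vesicles in
presynaptic terminals — with a fully ground-truthed synthetic-data
generator, so every stage of the pipeline is testable without microscopy
data.

## Who this is for

Labs doing live-cell imaging of labeled synaptic vesicles (quantum dots,
pH-sensitive dyes) in nerve terminals — in particular giant calyx-type
terminals, whose swellings (~2 µm bulbs) connected by thin finger-like
processes host a mixture of tethered, diffusing, and motor-driven
vesicles. The package covers the full analysis chain: simulating
calibrated time-lapse movies, detecting ~150 nm spots, linking them into
trajectories, and turning trajectories into the mobility statistics such
studies report.

## What it computes

- **Spot detection** — median-filter + band-pass candidate detection at
  the 150 nm scale, sub-pixel 2D Gaussian refinement.
- **Trajectory linking** — optimal frame-to-frame assignment under a
  hard gate (0.8 µm per frame, no gap closing), with two motion models:
  *Brownian* (nearest-neighbour cost) and *autoregressive*
  (constant-velocity prediction `x̂ₜ₊₁ = xₜ + w·v̂ₜ` with exponentially
  smoothed velocity). The autoregressive cost keeps hold of long
  directional runs that the Brownian cost loses to nearby distractors.
- **Diffusion from MSD** — ensemble or per-track mean squared
  displacement; in *d* dimensions `MSD(τ) = 2d·D·τ + 2d·σ_loc²`, so the
  weighted short-lag line fit returns D from the slope and the static
  localization error from the intercept.
- **Trajectory classification** — cumulative path length into S/M/L
  classes (cuts at 2 and 4 µm, the swelling scale), and displacement
  modality from the anomalous exponent α in `MSD ∝ τ^α` (diffusive for
  α ∈ [0.7, 1.3]; facilitated above; impeded below).
- **FRAP** — single-exponential recovery fit
  `I(t) = I₀ + A(1 − e^(−kt))` giving the mobile fraction and
  `T½ = ln2/k`, and the disk-bleach diffusion estimate
  `D = 0.224·ω²/T½`.
- **Region statistics** — swelling/finger/active-zone assignment by
  majority occupancy, displacement-direction cones relative to the
  synaptic cleft, Pearson pixel colocalization of two channels.
- **Group comparisons** — fold and percent changes, Q10 temperature
  coefficients, two-tailed unpaired t-tests, class-proportion tables.

The simulator (`svtrack.simulate`) generates calyx-like geometries,
three-state vesicle motion (tethered / diffusive / directed runs along
fingers), photon-realistic movies (integrated Gaussian PSF, Poisson +
read noise), and particle-wise FRAP experiments, all bit-reproducible
from a seed and all with ground truth attached.

## Worked example

```python
import svtrack as sv

geom = sv.build_terminal_geometry(n_swellings=3, mean_diameter=2.1, seed=7)
truth = sv.simulate_tracks(geom, sv.MotionModel(), n_vesicles=300,
                           frames=30, dt=1.0, seed=7)

summ = sv.summarize_tracks(truth.to_dataframe(), dt=1.0)
tab = sv.proportion_table(summ)
msd = sv.compute_msd(truth.to_dataframe(), dt=1.0, min_track_length=5)
fit = sv.estimate_d(msd, fit_lags=4)
print(f"ensemble D = {fit.d_coef:.4f} um^2/s")
print(f"S/M/L shares: {tab['length_pct']['S']:.1f} / "
      f"{tab['length_pct']['M']:.1f} / {tab['length_pct']['L']:.1f} %")
print(f"active share: {tab['modality_pct']['active']:.1f} %")
print(f"speed-length Pearson r = {sv.speed_length_correlation(summ):.2f}")

from svtrack.experiments import linker_contrast
out = linker_contrast(seed=7, n_terminals=4)
print(f"AR/Brownian ensemble-D ratio with 20% runs: {out['ratio_runs']:.1f}")
print(f"AR/Brownian ensemble-D ratio without runs:  {out['ratio_norun']:.2f}")
```

prints

```
ensemble D = 0.0166 um^2/s
S/M/L shares: 61.7 / 9.7 / 28.7 %
active share: 27.3 %
speed-length Pearson r = 0.78
AR/Brownian ensemble-D ratio with 20% runs: 2.1
AR/Brownian ensemble-D ratio without runs:  1.06
```

Reading these numbers: most simulated vesicles stay tethered inside one
swelling (61.7% short trajectories), a ~20% minority executes directed
runs along fingers, which couples trajectory length to maximum speed
(r = 0.78). Linking the same noisy detections with the two cost models
shows the headline methodological effect: when directed runs are
present, the Brownian linker loses them to nearby spots and the
autoregressive linker's ensemble D comes out twice as high, while the
two agree when no runs exist.

There is also a thin CLI (`svtrack simulate / detect / track / analyze /
frap / compare`) over the same functions:

```sh
svtrack simulate --n-vesicles 60 --frames 30 --seed 1 --out movie.tif
svtrack detect movie.tif --snr 5 --out spots.csv
svtrack track spots.csv --linker autoregressive --out tracks.csv
svtrack analyze tracks.csv --out summary.csv
```

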