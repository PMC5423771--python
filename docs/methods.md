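# Methods

This note documents the models behind `svtrack`, the defaults and why
they were chosen, the numerical decisions that matter, and what the
synthetic data can and cannot establish about real recordings.

## Terminal geometry

A terminal is a union of disk-shaped swellings and capsule-shaped
fingers (`TerminalGeometry`). `build_terminal_geometry` places
`n_swellings` on a jittered horizontal chain and connects consecutive
centers with fingers, giving a path graph with `n_swellings − 1` edges.
Swelling diameters are normal around `mean_diameter` (default 2.1 µm,
the typical size of large presynaptic swellings; CV 0.12, clipped to
[0.4, 2]× the mean radius). Finger half-width defaults to 0.25 µm.
Membership tests are geometric (resolution-independent); `mask()`
rasterizes onto the pixel grid for rendering and colocalization.
Optional active zones are small disks (radius 0.3 µm) placed on the
swelling rim facing the synaptic cleft (+y by convention).

## Motion model

Vesicle motion is a three-state continuous-time Markov chain sampled at
the frame interval:

| state     | displacement per frame                           | default parameter |
|-----------|--------------------------------------------------|-------------------|
| tethered  | Gaussian, per-axis variance 2·D_teth·dt          | D_teth = 3·10⁻⁴ µm²/s |
| diffusive | Gaussian, per-axis variance 2·D_free·dt          | D_free = 0.05 µm²/s |
| directed  | v_run·dt along a persistent finger-aligned direction | v_run = 0.5 µm/s |

`switch_rates` are per-second exit rates converted to per-frame
probabilities as `1 − exp(−rate·dt)`, so the simulated process is
invariant to the sampling interval — halving dt and doubling frames
samples the same physics. Defaults (T→D 0.005, D→T 0.05, D→R 0.15,
R→D 0.10 s⁻¹) make runs last ~10 s (~5 µm, with observed run lengths up
to ~6 µm) and keep the population tether-dominated.

Only an `active_fraction` (default 0.2) of vesicles can enter the run
state; run-capable vesicles start in the diffusive or directed state,
run-incapable ones start 80% tethered. With these defaults ~18% of
30-frame tracks contain a run, ~60% of trajectories are shorter than
2 µm, and trajectory length correlates with maximum speed (r ≈ 0.8) —
the qualitative population structure of vesicles in giant calyceal
terminals, which is what the generator is meant to emulate.

Boundary handling is Metropolis-style rejection: a step that would leave
the mask is discarded and the vesicle stays put for that frame (directed
runs also reverse direction). Rejection keeps the uniform stationary
density exact on an arbitrary mask; step *inversion* was tried first and
measurably skews density at curved boundaries (~20% central enrichment
over 100 frames in a disk), which corrupts FRAP equilibria. The cost is
a slightly sticky boundary layer one step wide.

3D simulation (`ndim=3`) adds an independently diffusing z coordinate
confined to a slab (half-depth 0.75 µm by default, an optical-section
scale); directed runs stay in-plane.

## Optics and rendering

Defaults: 0.1 µm pixels, PSF sigma 0.13 µm (a ~150 nm Gaussian-fitted
spot), 1 s frame interval, 30-frame sequences, 2000 photons/spot,
background 20 counts/px, read noise SD 2 counts. Emitters are rendered
as erf-integrated 2D Gaussians over pixel areas; pixel values are
Poisson(signal + background) plus Gaussian read noise, clipped at zero.
Pixel *i* spans [i, i+1)·pixel_size, so pixel centers sit at
(i + 0.5)·pixel_size; detection converts back with the same convention.

For image-free experiments, `GroundTruth.to_spots` adds per-axis
Gaussian localization noise (σ_loc, default 0.03 µm; 0.045 µm reproduces
the fixed-specimen apparent-mobility floor of ~0.008 µm²/s via the MSD
plateau 4σ²) and shuffles rows within each frame so linkers cannot
exploit ordering.

## Detection

Per frame: 3×3 median filter, difference-of-Gaussians band-pass at the
spot scale, threshold at `snr_threshold` robust SDs (1.4826·MAD) above
the band-passed median, local maxima at a minimum separation of one spot
diameter, then a 2D Gaussian least-squares fit in a window of side
2×spot_diameter (centroid fallback if the fit fails or leaves the
window). The intensity threshold is exposed because published pipelines
rarely state theirs. Overlapping emitters closer than the PSF are
deliberately treated as one spot (no multi-emitter fitting).

## Linking

Both linkers run the same per-frame-pair optimal assignment
(`scipy.optimize.linear_sum_assignment` on a matrix augmented with
birth/death entries at cost gate²; a link is forbidden when the *actual*
displacement exceeds the gate, 0.8 µm by default — the distance a
kinesin-carried vesicle can cover in one 1 s frame). No frame gaps, no
merging or splitting. Ties cannot occur for generic float positions;
the solver is deterministic.

The Brownian cost is squared distance from the track head. The
autoregressive cost is squared distance from the prediction
`x + w·v̂` (memory weight w = 0.9), where `v̂` is the per-track velocity
smoothed with a fixed constant 0.6 — fast enough to lock onto a run in
2–3 frames, while averaging a diffusive track's zero-mean steps toward
zero. Two design details matter in crowded fields:

- **Velocity deadband** (`min_speed`, default 0.28 µm/frame ≈ gate/3):
  smoothed speeds below it are treated as zero when predicting. Without
  it, localization and diffusion jitter entering `v̂` seeds
  self-exciting "momentum chains" — the predictor prefers whichever spot
  continues the previous (noise) direction, and the resulting spurious
  directional tracks inflate the AR-linked ensemble D by 30–75% even
  when no directed motion exists. With the deadband the two linkers
  agree within a few percent on run-free populations while runs
  (~0.5 µm/frame) are far above the threshold.
- With `w = 0` the prediction is the head position and the
  autoregressive linker reduces bit-identically to the Brownian one
  (tested).

`evaluate_linking` matches output localizations to ground truth per
frame (optimal assignment within `match_radius`), then scores the
fraction of output links whose two endpoints belong to the same true
vesicle, localization-weighted track purity, and fragmentation (extra
output tracks per true vesicle).

## MSD, diffusion, classification

MSD uses all ordered pairs per lag (not just independent pairs);
ensemble curves pool pair counts across tracks. `estimate_d` fits
`MSD = slope·τ + b` over the first `fit_lags` lags (default 4 — the
standard compromise for 30-frame tracks: fewer lags are noisy, more lags
mix in confinement and run curvature), weighting lags by √(pair count);
D = slope/(2d) with negative slopes clamped to zero and flagged. The
intercept estimates the static-noise offset 2d·σ_loc². Tracks shorter
than `min_track_length` (default 5 frames) are excluded everywhere —
shorter tracks give unusable MSD fits.

`apparent_d_floor` quotes the first-lag MSD divided by its lag time —
deliberately without the 2d divisor — because that is the scale on which
immobile-specimen "mobility" is conventionally quoted: for static spots
it equals the noise plateau 4σ_loc² per second (0.0081 µm²/s at
σ_loc = 45 nm).

Trajectory length is *cumulative path length* (consistent with observed
lengths up to 6 µm exceeding any swelling diameter), classed S/M/L on
half-open intervals [0,2), [2,4), [4,∞) µm — the half-open convention
resolves the otherwise-unassigned boundary values upward. Note that
cumulative path length is noise-inflated: 30 frames of σ_loc = 0.03 µm
noise alone contribute ~1.5 µm, so S/M/L tables computed on noisy linked
tracks shift toward M relative to ground-truth tables.

Displacement modality fits `log MSD = log C + α·log τ` over the first
lags (capped at a quarter of the track length); α ∈ [0.7, 1.3] is
diffusive, above is active-facilitated, below active-impeded, and
"active" is their union. The thresholds are configurable; the
classifier's measured error matters: on genuinely Brownian 30-frame
tracks the per-track α estimate has SD ≈ 0.3, so ~15% of diffusive
tracks are misclassified (mostly as impeded). Per-track modality shares
at 30 frames should therefore be read with that error in mind; at 100
frames the error falls to a few percent.

## FRAP

`simulate_frap` is particle-wise: fluorophores are uniform in the
terminal, a `mobile_fraction` of them diffuse (others immobile), and at
the bleach frame everything inside a circular ROI (radius ω) at the
first swelling center is switched off permanently. The reported trace is
double-normalized — ROI count over total remaining fluorescence,
referenced to the pre-bleach mean — the standard correction for the
finite share of the pool destroyed by the bleach pulse; without it the
recovered mobile fraction is depressed by exactly that share in any
finite geometry. There is no photobleaching outside the pulse and no
reaction–diffusion chemistry.

`fit_recovery` fits the single exponential `I₀ + A(1 − e^(−kt))` to the
post-bleach trace; mobile fraction = A/(I_pre − I₀) (clipped to [0,1]),
T½ = ln2/k, and D = 0.224·ω²/T½ (uniform-disk approximation). Two known
biases of this standard estimator, quantified on simulations: the
exponential underestimates the plateau of a diffusive recovery (its
tail is slower than exponential), costing ~0.03–0.05 of mobile fraction
when the reservoir is large; and the fitted k depends mildly on the
window length. The round-trip experiment (`experiments.frap_roundtrip`)
therefore uses a finite pool (swelling radius 2.1ω, 180 s window), where
exchange is close to exponential: across seeds it returns the generating
mobile fraction within ±0.05 and D within ~×1.3.

ω is always an explicit argument — "ROI half-width" is ambiguous in the
literature, and the same printed T½ values map to different D depending
on whether ω means 1.5 or ~1.31 µm; nothing in the package hard-codes
either reading.

Destaining traces are fitted with the Boltzmann sigmoid
`A2 + (A1−A2)/(1+e^((t−t0)/s))`; percent destaining = (A1−A2)/A1·100.

## Regions and directions

Tracks get one region label by majority occupancy of their localizations
(swelling beats finger where a finger cap overlaps a swelling disk);
active-zone membership is an orthogonal in/out label at 50% occupancy.
Direction classification uses the net displacement vector against the
cleft normal with 45° half-angle cones (outward/inward/lateral cover
25/25/50% of angle in 2D, which the isotropic-input test checks);
tracks with net displacement below 0.2 µm (the noise scale for 30-frame
tracks) are excluded as unclassifiable. Pearson colocalization is plain
pixel-intensity correlation over a mask.

## Reporting conventions

Folds are quoted to one decimal (half-up) or as whole numbers where a
verbal fold is natural; percent change is (a−b)/b·100. Q10 is
(D₁/D₂)^(10/(T₁−T₂)). The default t-test is the classical equal-variance
Student test (Welch behind `equal_var=False`); no multiple-testing
correction is applied. Its type-I error at α = 0.05 calibrates to
0.046–0.053 over 10,000 null replicates at n = 10 per group.

## Problem sizes used in validation

Chosen as the smallest sizes at which the measured quantities are stable
across seeds: diffusion recovery 300 tracks × 30 frames per D*; noise
floor 300 spots × 30 frames; linker contrast 12 terminals × 100 vesicles
× 40 frames (a crowded-terminal regime; at low spot density both linkers
trivially agree and the contrast vanishes); FRAP round-trip 80,000
particles × 180 frames; t-test calibration 10,000 replicates;
rate robustness 300 tracks at dt = 0.5 s vs the same paths decimated to
dt = 1 s.

## What the synthetic data does not capture

No blinking or photobleaching outside the FRAP pulse, no pH-dependent
intensity fluctuations, no 3D PSF (3D exists only at track level), no
motion blur within a frame, no vesicle–vesicle exclusion, no gradual
tethering maturation, and geometries are idealized disk-and-capsule
unions rather than segmented terminal shapes. Passing tests therefore
establish that the *analysis* is correct under the stated motion and
noise models — not that those models exhaust real terminals. In
particular, absolute class proportions on real data depend on the
localization noise level through the path-length inflation noted above.

## Known limitations

- The autoregressive linker is one defensible reconstruction of
  velocity-predictive tracking (smoothed constant-velocity prediction,
  optimal per-frame assignment); commercial implementations are
  unpublished and may weight intensity or use multi-frame hypotheses.
- Modality classification by a single per-track α cannot segment
  within-track state switches; a vesicle that runs briefly inside a long
  tethered track usually stays "diffusive" or "impeded".
- The 0.224 disk prefactor ties FRAP D to a specific bleach geometry;
  for strongly finger-limited exchange the formula can be off by far
  more than the ×1.5 envelope validated here.
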