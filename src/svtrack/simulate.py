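"""Synthetic presynaptic-terminal movies with ground-truth vesicle trajectories.

This module fabricates everything the downstream analysis consumes: a
calyx-like terminal geometry (bulbous swellings connected by thin
finger-like processes), vesicle trajectories driven by a three-state
motion model (tethered / diffusive / directed run), diffraction-limited
fluorescence movies with Poisson + read noise, and particle-wise FRAP
(fluorescence recovery after photobleaching) experiments.

All randomness is routed through :class:`numpy.random.Generator` seeded
explicitly, so identical inputs give bit-identical outputs.

Units throughout: positions in µm, time in s, diffusion coefficients in
µm²/s, intensities in photon counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frap import FRAPRecord

__all__ = [
    "TerminalGeometry",
    "MotionModel",
    "OpticsConfig",
    "GroundTruth",
    "MovieStack",
    "build_terminal_geometry",
    "simulate_tracks",
    "render_movie",
    "simulate_frap",
]

# Motion-state codes used in GroundTruth.states
STATE_TETHERED = 0
STATE_DIFFUSIVE = 1
STATE_DIRECTED = 2
STATE_NAMES = {STATE_TETHERED: "tethered", STATE_DIFFUSIVE: "diffusive", STATE_DIRECTED: "directed"}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminalGeometry:
    """Calyx-like terminal: disk-shaped swellings joined by capsule fingers.

    Parameters are stored geometrically (centers, radii, segment endpoints)
    so point-membership tests are resolution independent; :meth:`mask`
    rasterizes onto the pixel grid for rendering and region overlays.
    """

    swellings: tuple[tuple[tuple[float, float], float], ...]  # ((cx, cy), radius)
    fingers: tuple[tuple[tuple[float, float], tuple[float, float], float], ...]  # (p0, p1, half_width)
    fov: tuple[float, float]  # (width_um, height_um)
    pixel_size: float = 0.1
    az_regions: tuple[tuple[tuple[float, float], float], ...] = ()
    cleft_normal: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for (_, r) in self.swellings:
            if r <= 0:
                raise ValueError(f"swelling radius must be > 0, got {r}")
        for (_, _, hw) in self.fingers:
            if hw <= 0:
                raise ValueError(f"finger half-width must be > 0, got {hw}")

    # -- membership ---------------------------------------------------------

    def _in_swelling(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pts), dtype=bool)
        for (c, r) in self.swellings:
            out |= np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= r
        return out

    def _in_finger(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pts), dtype=bool)
        for (p0, p1, hw) in self.fingers:
            p0a, p1a = np.asarray(p0, float), np.asarray(p1, float)
            seg = p1a - p0a
            L2 = float(seg @ seg)
            rel = pts[:, :2] - p0a
            t = np.clip(rel @ seg / L2, 0.0, 1.0) if L2 > 0 else 0.0
            proj = p0a + np.outer(np.atleast_1d(t), seg)
            out |= np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1]) <= hw
        return out

    def _in_az(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pts), dtype=bool)
        for (c, r) in self.az_regions:
            out |= np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= r
        return out

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (n, 2+) µm coordinates in the terminal."""
        pts = np.atleast_2d(np.asarray(points, float))
        return self._in_swelling(pts) | self._in_finger(pts)

    def classify_points(self, points: np.ndarray) -> np.ndarray:
        """Per-point region label: 'swelling', 'finger' or 'outside'.

        Swellings take precedence where a finger cap overlaps a swelling.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        lab = np.full(len(pts), "outside", dtype=object)
        lab[self._in_finger(pts)] = "finger"
        lab[self._in_swelling(pts)] = "swelling"
        return lab

    def in_active_zone(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return self._in_az(pts)

    # -- rasterization ------------------------------------------------------

    def _pixel_centers(self) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
        w_px = int(np.ceil(self.fov[0] / self.pixel_size))
        h_px = int(np.ceil(self.fov[1] / self.pixel_size))
        xs = (np.arange(w_px) + 0.5) * self.pixel_size
        ys = (np.arange(h_px) + 0.5) * self.pixel_size
        return xs, ys, (h_px, w_px)

    def mask(self) -> np.ndarray:
        """Binary (H, W) rasterization of the terminal on the pixel grid."""
        xs, ys, shape = self._pixel_centers()
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        return self.contains(pts).reshape(shape)

    def az_mask(self) -> np.ndarray:
        """Binary (H, W) rasterization of the active-zone sub-regions."""
        xs, ys, shape = self._pixel_centers()
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        return self._in_az(pts).reshape(shape)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside the terminal (rejection sampling)."""
        out = np.empty((0, 2))
        w, h = self.fov
        while len(out) < n:
            cand = rng.random((max(4 * n, 256), 2)) * (w, h)
            out = np.vstack([out, cand[self.contains(cand)]])
        return out[:n]


def build_terminal_geometry(
    n_swellings: int,
    mean_diameter: float = 2.1,
    layout: str = "chain",
    seed: int = 0,
    pixel_size: float = 0.1,
    finger_halfwidth: float = 0.25,
    diameter_cv: float = 0.12,
    center_spacing: float | None = None,
    n_az: int = 0,
    az_radius: float = 0.3,
    margin: float = 1.0,
) -> TerminalGeometry:
    """Build a calyx-like terminal of swellings chained by finger processes.

    ``layout='chain'`` places ``n_swellings`` centers on a gently jittered
    horizontal line and connects consecutive centers with fingers (a path
    graph: ``n_swellings - 1`` fingers). Swelling diameters are drawn from a
    normal distribution around ``mean_diameter`` (coefficient of variation
    ``diameter_cv``), mimicking the ~2 µm bulbous sub-compartments of giant
    terminals. ``n_az`` small active-zone disks are placed on swelling
    perimeters facing the synaptic cleft (``cleft_normal`` points toward
    the postsynaptic side, +y by convention).
    """
    if n_swellings < 1:
        raise ValueError("n_swellings must be >= 1")
    if mean_diameter <= 0:
        raise ValueError("mean_diameter must be > 0")
    if layout != "chain":
        raise ValueError(f"unknown layout {layout!r}; only 'chain' is supported")

    rng = np.random.default_rng(seed)
    radii = np.clip(
        rng.normal(mean_diameter / 2.0, diameter_cv * mean_diameter / 2.0, n_swellings),
        0.2 * mean_diameter, 1.0 * mean_diameter,
    )
    spacing = center_spacing if center_spacing is not None else 1.9 * mean_diameter
    cx = margin + radii[0] + np.arange(n_swellings) * spacing
    cy = np.full(n_swellings, margin + float(radii.max()))
    cy += rng.normal(0.0, 0.1 * mean_diameter, n_swellings)  # slight meander

    fov = (float(cx[-1] + radii[-1] + margin), float(2 * (margin + radii.max())))
    if not (0 < cx[0] < fov[0]):
        raise ValueError("layout places no swelling inside the field of view")

    swellings = tuple(((float(x), float(y)), float(r)) for x, y, r in zip(cx, cy, radii))
    fingers = tuple(
        ((float(cx[i]), float(cy[i])), (float(cx[i + 1]), float(cy[i + 1])), finger_halfwidth)
        for i in range(n_swellings - 1)
    )

    cleft_normal = (0.0, 1.0)
    az: list[tuple[tuple[float, float], float]] = []
    for k in range(n_az):
        (c, r) = swellings[k % n_swellings]
        # AZ disk centered just inside the swelling rim, on the cleft side
        az.append(((c[0], c[1] + (r - az_radius)), az_radius))

    return TerminalGeometry(
        swellings=swellings, fingers=fingers, fov=fov, pixel_size=pixel_size,
        az_regions=tuple(az), cleft_normal=cleft_normal,
    )


# ---------------------------------------------------------------------------
# motion model and track simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionModel:
    """Three-state Markov motion: tethered, diffusive, directed run.

    Tethered vesicles wobble with ``d_tethered``; diffusive vesicles take
    Gaussian steps of per-axis variance ``2 * d_free * dt``; directed
    vesicles translocate at ``v_run`` along a persistent run direction
    (finger-aligned when a geometry is supplied). Only an ``active_fraction``
    of vesicles can ever enter the run state, which sets the share of tracks
    containing active transport (~20% by default, the share seen for
    vesicles in giant calyceal terminals).

    ``switch_rates`` are continuous-time exit rates (per second), keyed
    ``(from_state, to_state)``; per-frame probabilities are
    ``1 - exp(-rate * dt)`` so the underlying process does not depend on the
    sampling interval. ``p_init_active`` / ``p_init_passive`` are initial
    state distributions over (tethered, diffusive, directed) for run-capable
    and run-incapable vesicles.
    """

    d_free: float = 0.05
    d_tethered: float = 0.0003
    v_run: float = 0.5
    active_fraction: float = 0.2
    switch_rates: tuple[tuple[int, int, float], ...] = (
        (STATE_TETHERED, STATE_DIFFUSIVE, 0.005),
        (STATE_DIFFUSIVE, STATE_TETHERED, 0.05),
        (STATE_DIFFUSIVE, STATE_DIRECTED, 0.15),
        (STATE_DIRECTED, STATE_DIFFUSIVE, 0.10),
    )
    p_init_passive: tuple[float, float, float] = (0.80, 0.20, 0.0)
    p_init_active: tuple[float, float, float] = (0.0, 0.50, 0.50)

    def __post_init__(self) -> None:
        if self.d_free < 0 or self.d_tethered < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.v_run < 0:
            raise ValueError("v_run must be >= 0")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        for (_, _, rate) in self.switch_rates:
            if rate < 0:
                raise ValueError("switch rates must be >= 0")
        for p in (self.p_init_passive, self.p_init_active):
            if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError("initial state probabilities must be a distribution")

    def transition_matrix(self, dt: float, runs_enabled: bool) -> np.ndarray:
        """Row-stochastic per-frame transition matrix for time step dt."""
        p = np.zeros((3, 3))
        for (i, j, rate) in self.switch_rates:
            if not runs_enabled and j == STATE_DIRECTED:
                continue
            p[i, j] = 1.0 - np.exp(-rate * dt)
        np.fill_diagonal(p, 0.0)
        np.fill_diagonal(p, 1.0 - p.sum(axis=1))
        if np.any(np.diag(p) < 0):
            raise ValueError("switch rates too large for this dt (per-frame probs exceed 1)")
        return p


@dataclass(frozen=True)
class OpticsConfig:
    """Confocal acquisition settings emulated by the renderer.

    Defaults reproduce the study regime: 0.1 µm pixels, a ~130 nm PSF sigma
    (150 nm Gaussian-fitted spots), 1 frame/s, 30-frame sequences.
    """

    psf_sigma: float = 0.13
    pixel_size: float = 0.1
    frame_interval: float = 1.0
    photons_per_spot: float = 2000.0
    background: float = 20.0
    read_noise_sd: float = 2.0
    frames: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size, frame_interval and psf_sigma must be > 0")


@dataclass
class GroundTruth:
    """True vesicle positions and motion states from the simulator.

    ``positions`` has shape (n_vesicles, n_frames, ndim) in µm;
    ``states`` has shape (n_vesicles, n_frames) with codes 0/1/2
    (tethered / diffusive / directed).
    """

    positions: np.ndarray
    states: np.ndarray
    dt: float
    seed: int

    @property
    def n_vesicles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def ndim(self) -> int:
        return self.positions.shape[2]

    def to_dataframe(self) -> pd.DataFrame:
        n, t, d = self.positions.shape
        df = pd.DataFrame({
            "track_id": np.repeat(np.arange(n), t),
            "frame": np.tile(np.arange(t), n),
            "x_um": self.positions[:, :, 0].ravel(),
            "y_um": self.positions[:, :, 1].ravel(),
            "z_um": self.positions[:, :, 2].ravel() if d > 2 else 0.0,
            "state": self.states.ravel(),
        })
        return df

    def decimate(self, step: int) -> "GroundTruth":
        """Keep every ``step``-th frame (coarser acquisition of the same paths)."""
        return GroundTruth(self.positions[:, ::step], self.states[:, ::step],
                           self.dt * step, self.seed)

    def to_spots(self, sigma_loc: float = 0.03, seed: int = 0,
                 intensity: float = 1000.0) -> pd.DataFrame:
        """Anonymized detections: add localization noise, shuffle per frame.

        Mimics what spot detection would produce (no identities), for
        image-free linking experiments. ``sigma_loc`` is the per-axis
        localization error SD in µm.
        """
        rng = np.random.default_rng(seed)
        df = self.to_dataframe()
        noisy = df[["x_um", "y_um", "z_um"]].to_numpy()
        noisy = noisy + rng.normal(0.0, sigma_loc, noisy.shape)
        if self.ndim == 2:
            noisy[:, 2] = 0.0
        df = df.assign(x_um=noisy[:, 0], y_um=noisy[:, 1], z_um=noisy[:, 2],
                       intensity=intensity, width_um=0.15)
        df = df.drop(columns=["track_id", "state"])
        df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).sort_values(
            "frame", kind="stable").reset_index(drop=True)
        return df


@dataclass
class MovieStack:
    """Calibrated time-lapse stack: (T, H, W) counts plus acquisition metadata."""

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _finger_direction(geometry: TerminalGeometry | None, pos: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit run direction: along the nearest finger axis if any, else random."""
    if geometry is not None and geometry.fingers:
        best, best_d = None, np.inf
        for (p0, p1, _) in geometry.fingers:
            mid = (np.asarray(p0) + np.asarray(p1)) / 2.0
            d = np.hypot(pos[0] - mid[0], pos[1] - mid[1])
            if d < best_d:
                best_d, best = d, (np.asarray(p1, float) - np.asarray(p0, float))
        u = best / np.linalg.norm(best)
    else:
        theta = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
    return u * rng.choice([-1.0, 1.0])


def simulate_tracks(
    geometry: TerminalGeometry | None,
    model: MotionModel,
    n_vesicles: int,
    frames: int,
    dt: float,
    seed: int = 0,
    ndim: int = 2,
    z_halfdepth: float = 0.75,
    az_attraction: float = 0.0,
) -> GroundTruth:
    """Simulate ground-truth vesicle trajectories inside a terminal.

    Each vesicle carries a hidden motion state evolving as a Markov chain
    (see :class:`MotionModel`); steps are Brownian (tethered / diffusive) or
    ballistic (directed, along a persistent finger-aligned direction).
    Steps that would exit the terminal are rejected (the vesicle stays put
    that frame), which keeps the uniform stationary density exact on any
    mask shape; directed runs flip their direction on boundary contact.
    With ``geometry=None`` the motion is unconfined (used for diffusion
    calibration).

    ``ndim=3`` adds an independent z coordinate diffusing within a slab of
    half-depth ``z_halfdepth`` (an optical-section thickness); runs stay
    in-plane.

    ``az_attraction`` (µm/s) adds a drift toward the nearest active-zone
    center for non-running vesicles, emulating recruitment of vesicles to
    release sites (e.g. under sustained stimulation); 0 disables it.
    """
    if n_vesicles < 1:
        raise ValueError("n_vesicles must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if ndim not in (2, 3):
        raise ValueError("ndim must be 2 or 3")

    rng = np.random.default_rng(seed)
    runs_enabled = model.active_fraction > 0 and model.v_run >= 0
    trans = model.transition_matrix(dt, runs_enabled=True)
    trans_norun = model.transition_matrix(dt, runs_enabled=False)

    capable = rng.random(n_vesicles) < model.active_fraction
    p0 = np.where(capable[:, None], model.p_init_active, model.p_init_passive)

    if geometry is not None:
        xy = geometry.sample_points(n_vesicles, rng)
    else:
        xy = rng.random((n_vesicles, 2)) * 10.0

    pos = np.zeros((n_vesicles, frames, 3))
    states = np.zeros((n_vesicles, frames), dtype=np.int8)
    pos[:, 0, :2] = xy
    if ndim == 3:
        pos[:, 0, 2] = rng.uniform(-z_halfdepth, z_halfdepth, n_vesicles)

    for i in range(n_vesicles):
        s = rng.choice(3, p=p0[i])
        states[i, 0] = s
        run_dir = _finger_direction(geometry, pos[i, 0, :2], rng)
        P = trans if capable[i] else trans_norun
        for t in range(1, frames):
            s = rng.choice(3, p=P[s])
            if s == STATE_DIRECTED and states[i, t - 1] != STATE_DIRECTED:
                run_dir = _finger_direction(geometry, pos[i, t - 1, :2], rng)
            states[i, t] = s
            prev = pos[i, t - 1]
            if s == STATE_DIRECTED:
                step_xy = model.v_run * dt * run_dir
                step_z = 0.0
            else:
                d = model.d_free if s == STATE_DIFFUSIVE else model.d_tethered
                sd = np.sqrt(2.0 * d * dt)
                step_xy = rng.normal(0.0, sd, 2)
                step_z = rng.normal(0.0, sd) if ndim == 3 else 0.0
                if az_attraction > 0 and geometry is not None and geometry.az_regions:
                    az_centers = np.array([c for (c, _) in geometry.az_regions])
                    to_az = az_centers - prev[:2]
                    nearest = to_az[np.argmin(np.linalg.norm(to_az, axis=1))]
                    dist = np.linalg.norm(nearest)
                    if dist > 1e-9:
                        step_xy = step_xy + az_attraction * dt * nearest / dist
            new_xy = prev[:2] + step_xy
            if geometry is not None and not geometry.contains(new_xy[None, :])[0]:
                # Metropolis-style rejection: stay put this frame. Unlike
                # step inversion, rejection keeps the uniform density exact
                # on an arbitrarily shaped mask. Runs turn around.
                new_xy = prev[:2]
                if s == STATE_DIRECTED:
                    run_dir = -run_dir
            new_z = prev[2] + step_z
            if ndim == 3 and abs(new_z) > z_halfdepth:
                new_z = prev[2]
            pos[i, t] = (*new_xy, new_z)

    return GroundTruth(positions=pos[:, :, :ndim] if ndim == 3 else pos[:, :, :3],
                       states=states, dt=dt, seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _integrated_gaussian(shape: tuple[int, int], centers_px: np.ndarray,
                         photons: float, sigma_px: float) -> np.ndarray:
    """Expected photon image: each emitter's flux integrated over pixels.

    Pixel ``i`` spans [i, i+1) in pixel coordinates; a position ``x_um``
    maps to pixel coordinate ``x_um / pixel_size`` (so the center of pixel
    i sits at i + 0.5).
    """
    from scipy.special import erf

    h, w = shape
    img = np.zeros((h, w))
    half = int(np.ceil(5 * sigma_px)) + 1
    s = sigma_px * np.sqrt(2.0)
    for (cx, cy) in centers_px:
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        ex = 0.5 * (erf((np.arange(x0, x1) + 1 - cx) / s) - erf((np.arange(x0, x1) - cx) / s))
        ey = 0.5 * (erf((np.arange(y0, y1) + 1 - cy) / s) - erf((np.arange(y0, y1) - cy) / s))
        img[y0:y1, x0:x1] += photons * np.outer(ey, ex)
    return img


def render_movie(truth: GroundTruth, geometry: TerminalGeometry | None,
                 optics: OpticsConfig, seed: int = 0) -> MovieStack:
    """Render ground-truth positions into a noisy fluorescence movie.

    Each vesicle becomes an integrated 2D Gaussian of width ``psf_sigma``;
    pixel values are Poisson(signal + background) plus Gaussian read noise.
    The field of view is taken from ``geometry`` when given, else from the
    bounding box of the trajectories.
    """
    if optics.photons_per_spot <= 0:
        raise ValueError("photons_per_spot must be > 0")
    rng = np.random.default_rng(seed)
    ps = optics.pixel_size
    if geometry is not None:
        shape = (int(np.ceil(geometry.fov[1] / ps)), int(np.ceil(geometry.fov[0] / ps)))
    else:
        extent = truth.positions[:, :, :2].reshape(-1, 2) if truth.n_vesicles else np.zeros((1, 2))
        shape = (int(np.ceil((extent[:, 1].max() + 1.0) / ps)),
                 int(np.ceil((extent[:, 0].max() + 1.0) / ps)))

    movie = np.zeros((truth.n_frames, *shape))
    sigma_px = optics.psf_sigma / ps
    for t in range(truth.n_frames):
        centers = truth.positions[:, t, :2] / ps
        signal = _integrated_gaussian(shape, centers, optics.photons_per_spot, sigma_px)
        lam = signal + optics.background
        frame = rng.poisson(lam).astype(float)
        if optics.read_noise_sd > 0:
            frame += rng.normal(0.0, optics.read_noise_sd, shape)
        movie[t] = np.maximum(frame, 0.0)
    return MovieStack(frames=movie, pixel_size=ps, frame_interval=optics.frame_interval)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def simulate_frap(
    geometry: TerminalGeometry,
    d: float,
    mobile_fraction: float,
    roi_halfwidth: float,
    bleach_frame: int,
    frames: int,
    dt: float,
    seed: int = 0,
    n_particles: int = 6000,
    region_type: str = "swelling",
) -> FRAPRecord:
    """Particle-wise FRAP: bleach a circular ROI and watch diffusive refill.

    ``n_particles`` fluorophores start uniformly in the terminal; a
    ``mobile_fraction`` of them diffuse with coefficient ``d`` (boundary
    steps rejected), the rest are immobile. At ``bleach_frame`` every
    fluorophore inside the ROI (disk of radius ``roi_halfwidth`` at the
    first swelling center) is switched off permanently. The reported trace
    is double-normalized, as in standard FRAP analysis: the ROI count is
    divided by the total remaining fluorescence before normalizing to the
    pre-bleach mean, which corrects for the finite share of the pool
    destroyed by the bleach pulse. Recovery comes only from mobile
    fluorophores wandering in from outside; the immobile share never
    recovers.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if roi_halfwidth <= 0:
        raise ValueError("roi_halfwidth must be > 0")
    if not 0 <= bleach_frame < frames:
        raise IndexError(f"bleach_frame {bleach_frame} outside [0, {frames})")
    if d < 0:
        raise ValueError("d must be >= 0")

    rng = np.random.default_rng(seed)
    pos = geometry.sample_points(n_particles, rng)
    mobile = rng.random(n_particles) < mobile_fraction
    lit = np.ones(n_particles, dtype=bool)
    center = np.asarray(geometry.swellings[0][0])

    def in_roi(p: np.ndarray) -> np.ndarray:
        return np.hypot(p[:, 0] - center[0], p[:, 1] - center[1]) <= roi_halfwidth

    sd = np.sqrt(2.0 * d * dt)
    counts = np.empty(frames)
    for t in range(frames):
        if t > 0 and sd > 0:
            step = rng.normal(0.0, sd, (int(mobile.sum()), 2))
            cand = pos[mobile] + step
            bad = ~geometry.contains(cand)  # rejected steps stay put
            cand[bad] = pos[mobile][bad]
            pos[mobile] = cand
        if t == bleach_frame:
            lit &= ~in_roi(pos)
        total = max(np.count_nonzero(lit), 1)
        counts[t] = np.count_nonzero(lit & in_roi(pos)) / total

    pre = counts[:bleach_frame].mean() if bleach_frame > 0 else counts[0]
    intensity = counts / max(pre, 1e-12)
    return FRAPRecord(
        times=np.arange(frames) * dt,
        intensity=intensity,
        bleach_index=bleach_frame,
        omega=roi_halfwidth,
        region_type=region_type,
    )
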