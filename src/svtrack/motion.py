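"""Per-track and ensemble motion statistics.

Core quantities for each trajectory: cumulative path length, maximum
frame-to-frame speed, the mean squared displacement (MSD) curve over time
lags, the diffusion coefficient D from the short-lag MSD slope
(MSD = 2 d D τ + offset in d spatial dimensions; the offset absorbs
localization noise, 2 d σ_loc²), the anomalous-diffusion exponent α from
a log-log MSD fit, and two classifications used throughout the analysis:

* trajectory-length class S / M / L with cut points at 2 and 4 µm, chosen
  relative to the ~2.1 µm swelling size (S: intra-swelling, M:
  intermediate, L: inter-swelling traffic);
* displacement modality — diffusive (α near 1), active facilitated
  (superdiffusive, α high) or active impeded (subdiffusive/confined,
  α low); "active" is the union of the last two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .link import iter_tracks

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "path_length",
    "max_speed",
    "compute_msd",
    "compute_msd_per_track",
    "estimate_d",
    "apparent_d_floor",
    "classify_length",
    "classify_modality",
    "summarize_tracks",
    "speed_length_correlation",
]

LENGTH_CLASS_EDGES = (2.0, 4.0)  # µm; [0,2) S, [2,4) M, [4,inf) L
ALPHA_LO = 0.7
ALPHA_HI = 1.3


@dataclass
class MSDCurve:
    """Lag-time MSD with pair counts; ``d`` is the spatial dimensionality."""

    lags: np.ndarray      # s, starting at 0
    msd: np.ndarray       # µm²
    n_pairs: np.ndarray   # ordered pairs contributing per lag
    d: int = 2

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.msd = np.asarray(self.msd, float)
        self.n_pairs = np.asarray(self.n_pairs, int)


@dataclass(frozen=True)
class DiffusionFit:
    """Weighted linear MSD fit: D = slope / (2 d), intercept = noise offset."""

    d_coef: float         # µm²/s, clamped at 0
    intercept: float      # µm²
    slope: float          # µm²/s, raw fitted slope
    clamped: bool
    n_lags: int


def _positions(track) -> np.ndarray:
    """Accept a DataFrame track or raw (n, k) array; return (n, 3) float."""
    if isinstance(track, pd.DataFrame):
        pos = track[["x_um", "y_um", "z_um"]].to_numpy(float) if "z_um" in track \
            else track[["x_um", "y_um"]].to_numpy(float)
    else:
        pos = np.asarray(track, float)
    if pos.ndim != 2:
        raise ValueError("track positions must be a 2D array")
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(len(pos))])
    return pos


def path_length(track) -> float:
    """Cumulative trajectory length: sum of consecutive displacements, µm."""
    pos = _positions(track)
    if len(pos) < 2:
        raise ValueError("path length undefined for a 1-point track")
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def max_speed(track, dt: float) -> float:
    """Maximum frame-to-frame speed, µm/s."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    pos = _positions(track)
    if len(pos) < 2:
        raise ValueError("speed undefined for a 1-point track")
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).max() / dt)


def _msd_sums(pos: np.ndarray, max_lag_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared displacements and pair counts for lags 0..max_lag_frames."""
    n = len(pos)
    k_max = min(max_lag_frames, n - 1)
    sums = np.zeros(max_lag_frames + 1)
    counts = np.zeros(max_lag_frames + 1, dtype=int)
    counts[0] = n
    for k in range(1, k_max + 1):
        diff = pos[k:] - pos[:-k]
        sums[k] = np.einsum("ij,ij->", diff, diff)
        counts[k] = n - k
    return sums, counts


def compute_msd(tracks, dt: float, max_lag: float | None = None,
                min_track_length: int = 2, d: int = 2) -> MSDCurve:
    """Ensemble MSD: pool squared displacements over all tracks per lag.

    ``tracks`` is a track DataFrame (or anything :func:`iter_tracks`
    accepts); pooling weights each track by its pair count at every lag.
    A ``max_lag`` longer than the longest track is truncated (with the
    pair counts going to zero at the missing lags dropped).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    track_list = [pos for (_, pos, _) in iter_tracks(tracks, min_track_length)] \
        if isinstance(tracks, pd.DataFrame) else [_positions(t) for t in tracks]
    if not track_list:
        raise ValueError("no eligible tracks for MSD")
    longest = max(len(p) for p in track_list) - 1
    k_req = longest if max_lag is None else int(round(max_lag / dt))
    k_max = min(k_req, longest)
    if d == 2:
        track_list = [p[:, :2] for p in track_list]

    sums = np.zeros(k_max + 1)
    counts = np.zeros(k_max + 1, dtype=int)
    for pos in track_list:
        s, c = _msd_sums(pos, k_max)
        sums += s
        counts += c
    keep = counts > 0
    msd = np.zeros(k_max + 1)
    msd[keep] = sums[keep] / counts[keep]
    return MSDCurve(lags=np.arange(k_max + 1)[keep] * dt, msd=msd[keep],
                    n_pairs=counts[keep], d=d)


def compute_msd_per_track(tracks, dt: float, max_lag: float | None = None,
                          min_track_length: int = 2, d: int = 2) -> dict[int, MSDCurve]:
    """Per-track MSD curves keyed by track id."""
    out: dict[int, MSDCurve] = {}
    for tid, pos, _ in iter_tracks(tracks, min_track_length):
        if d == 2:
            pos = pos[:, :2]
        k_max = len(pos) - 1 if max_lag is None else min(int(round(max_lag / dt)), len(pos) - 1)
        s, c = _msd_sums(pos, k_max)
        out[tid] = MSDCurve(lags=np.arange(k_max + 1) * dt, msd=np.where(c > 0, s / np.maximum(c, 1), 0.0),
                            n_pairs=c, d=d)
    return out


def estimate_d(msd: MSDCurve, fit_lags: int = 4) -> DiffusionFit:
    """Diffusion coefficient from a weighted line fit of the short-lag MSD.

    Fits ``msd = slope * τ + intercept`` over the first ``fit_lags``
    nonzero lags, weighting each lag by its pair count; D = slope / (2 d).
    A negative slope is clamped to D = 0 and flagged. The intercept
    estimates the static localization-noise offset 2 d σ_loc².
    """
    pos_lags = msd.lags > 0
    lags = msd.lags[pos_lags][:fit_lags]
    y = msd.msd[pos_lags][:fit_lags]
    w = msd.n_pairs[pos_lags][:fit_lags].astype(float)
    if len(lags) < 2:
        raise ValueError(f"need at least 2 nonzero lags to fit, have {len(lags)}")
    slope, intercept = np.polyfit(lags, y, 1, w=np.sqrt(w))
    clamped = slope < 0
    d_coef = max(float(slope), 0.0) / (2 * msd.d)
    return DiffusionFit(d_coef=d_coef, intercept=float(intercept),
                        slope=float(slope), clamped=bool(clamped), n_lags=len(lags))


def apparent_d_floor(msd: MSDCurve) -> float:
    """Uncorrected single-lag mobility floor: MSD(τ₁) / τ₁, µm²/s.

    For immobile particles the short-lag MSD plateaus at the localization
    noise offset 2 d σ_loc² (4 σ_loc² in 2D); dividing the first-lag MSD by
    its lag time quotes that plateau as an apparent per-second mobility —
    the number a tracking pipeline reports for fixed specimens or surface
    beads, setting the measurement noise floor.
    """
    pos_lags = msd.lags > 0
    if not np.any(pos_lags):
        raise ValueError("MSD curve has no nonzero lag")
    return float(msd.msd[pos_lags][0] / msd.lags[pos_lags][0])


def classify_length(length_um: float) -> str:
    """S / M / L class from cumulative trajectory length (cuts at 2 and 4 µm)."""
    if length_um < 0:
        raise ValueError("length must be >= 0")
    if length_um < LENGTH_CLASS_EDGES[0]:
        return "S"
    if length_um < LENGTH_CLASS_EDGES[1]:
        return "M"
    return "L"


def classify_modality(track, dt: float, fit_lags: int = 4,
                      alpha_lo: float = ALPHA_LO, alpha_hi: float = ALPHA_HI,
                      d: int = 2) -> tuple[str, float]:
    """Displacement modality from the anomalous exponent α.

    Fits ``log MSD = log C + α log τ`` over the first ``fit_lags`` lags of
    the per-track MSD (capped at a quarter of the track duration, min 2).
    α near 1 is free diffusion; α above ``alpha_hi`` marks facilitated
    (directed) transport, α below ``alpha_lo`` impeded/confined motion.
    A degenerate zero-MSD track is classed impeded.
    Returns (label, α).
    """
    pos = _positions(track)
    if d == 2:
        pos = pos[:, :2]
    n = len(pos)
    if n < 3:
        raise ValueError("modality needs at least 3 localizations")
    k = min(max(2, min(fit_lags, (n - 1) // 4)), n - 1)
    s, c = _msd_sums(pos, k)
    msd = s[1:] / c[1:]
    if np.any(msd <= 0):
        return "active_impeded", float("nan")
    tau = np.arange(1, k + 1) * dt
    alpha = float(np.polyfit(np.log(tau), np.log(msd), 1)[0])
    if alpha > alpha_hi:
        return "active_facilitated", alpha
    if alpha < alpha_lo:
        return "active_impeded", alpha
    return "diffusive", alpha


def summarize_tracks(tracks: pd.DataFrame, dt: float, fit_lags: int = 4,
                     min_track_length: int = 5, d: int = 2) -> pd.DataFrame:
    """Per-track motion summary table.

    Columns: track_id, n_frames, path_length, max_speed, length_class,
    modality, alpha, d_coef (per-track MSD fit). Tracks shorter than
    ``min_track_length`` frames are excluded (short tracks give unstable
    MSD fits).
    """
    rows = []
    for tid, pos, _ in iter_tracks(tracks, min_track_length):
        p = pos[:, :2] if d == 2 else pos
        plen = path_length(p)
        speed = max_speed(p, dt)
        modality, alpha = classify_modality(p, dt, fit_lags=fit_lags, d=d)
        k = min(fit_lags, len(p) - 1)
        s, c = _msd_sums(p, k)
        curve = MSDCurve(np.arange(k + 1) * dt, np.where(c > 0, s / np.maximum(c, 1), 0.0), c, d=d)
        try:
            dc = estimate_d(curve, fit_lags=fit_lags).d_coef
        except ValueError:
            dc = float("nan")
        rows.append((tid, len(p), plen, speed, classify_length(plen), modality, alpha, dc))
    return pd.DataFrame(rows, columns=[
        "track_id", "n_frames", "path_length", "max_speed",
        "length_class", "modality", "alpha", "d_coef",
    ])


def speed_length_correlation(summaries: pd.DataFrame) -> float:
    """Pearson r between trajectory length and maximum speed across tracks."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 tracks")
    x = summaries["path_length"].to_numpy(float)
    y = summaries["max_speed"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)
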