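"""Morphological region statistics: swelling vs. finger assignment,
displacement directionality relative to the synaptic cleft, pixel-level
Pearson colocalization, and active-zone recruitment.

A track gets one region label — the region holding the majority of its
localizations — matching how per-region diffusion coefficients are
reported (one value per trajectory). Active-zone (AZ) membership is an
orthogonal in/out label against a set of AZ sub-regions or a binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TerminalGeometry

__all__ = [
    "assign_tracks",
    "direction_proportions",
    "DirectionSummary",
    "pearson_colocalization",
    "az_recruitment",
]


def assign_tracks(tracks: pd.DataFrame, geometry: TerminalGeometry) -> pd.DataFrame:
    """Label each track by the region holding most of its localizations.

    Returns one row per track: ``region`` (swelling | finger | outside),
    per-region occupancy fractions (summing to 1), and — when the geometry
    defines active zones — ``az_label`` (az_in | az_out) with the AZ
    occupancy fraction. A track lying wholly outside the terminal keeps
    the label 'outside'.
    """
    rows = []
    has_az = len(geometry.az_regions) > 0
    for tid, g in tracks.groupby("track_id", sort=True):
        pts = g[["x_um", "y_um"]].to_numpy(float)
        labels = geometry.classify_points(pts)
        n = len(labels)
        occ = {r: float(np.mean(labels == r)) for r in ("swelling", "finger", "outside")}
        region = max(occ, key=lambda r: (occ[r], r != "outside"))
        row = {"track_id": tid, "region": region, "n_points": n, **{f"occ_{k}": v for k, v in occ.items()}}
        if has_az:
            az_frac = float(np.mean(geometry.in_active_zone(pts)))
            row["occ_az"] = az_frac
            row["az_label"] = "az_in" if az_frac > 0.5 else "az_out"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DirectionSummary:
    """Percent of classified tracks moving toward / away from / along the cleft."""

    outward_pct: float
    inward_pct: float
    lateral_pct: float
    n_classified: int
    n_excluded: int


def direction_proportions(
    tracks: pd.DataFrame,
    cleft_normal: tuple[float, float],
    cone_halfangle: float = 45.0,
    min_net_displacement: float = 0.2,
) -> DirectionSummary:
    """Classify net displacement vectors relative to the cleft normal.

    A track is *outward* when its net displacement lies within
    ``cone_halfangle`` degrees of ``cleft_normal`` (toward the
    postsynaptic surface), *inward* within the same cone of the opposite
    direction, *lateral* otherwise. Tracks whose net displacement is below
    ``min_net_displacement`` µm are excluded from the percentages.
    """
    normal = np.asarray(cleft_normal, float)
    nrm = np.linalg.norm(normal)
    if nrm == 0:
        raise ValueError("cleft_normal must be a nonzero direction")
    normal = normal / nrm
    cos_cone = np.cos(np.deg2rad(cone_halfangle))

    counts = {"outward": 0, "inward": 0, "lateral": 0}
    excluded = 0
    for _, g in tracks.groupby("track_id", sort=True):
        pts = g[["x_um", "y_um"]].to_numpy(float)
        net = pts[-1] - pts[0]
        mag = np.linalg.norm(net)
        if mag < min_net_displacement:
            excluded += 1
            continue
        c = float(net @ normal) / mag
        if c >= cos_cone:
            counts["outward"] += 1
        elif c <= -cos_cone:
            counts["inward"] += 1
        else:
            counts["lateral"] += 1
    n = sum(counts.values())
    pct = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
    return DirectionSummary(pct["outward"], pct["inward"], pct["lateral"], n, excluded)


def pearson_colocalization(channel_a: np.ndarray, channel_b: np.ndarray,
                           mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two channels' pixel intensities over a mask.

    Symmetric in its arguments and invariant to affine rescaling of
    either channel; raises on zero variance.
    """
    a = np.asarray(channel_a, float)
    b = np.asarray(channel_b, float)
    if a.shape != b.shape:
        raise ValueError("channels must have the same shape")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != a.shape:
            raise ValueError("mask must match the image shape")
        if not mask.any():
            raise ValueError("mask is empty")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("colocalization undefined: a channel has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def az_recruitment(tracks_pre: pd.DataFrame, tracks_stim: pd.DataFrame,
                   geometry: TerminalGeometry) -> dict:
    """Share of trajectories whose majority occupancy is inside active zones,
    before vs. during stimulation, and the fold change between them.
    """
    if len(geometry.az_regions) == 0:
        raise ValueError("geometry defines no active zones")

    def frac_inside(tracks: pd.DataFrame) -> float:
        assign = assign_tracks(tracks, geometry)
        return float((assign["az_label"] == "az_in").mean()) if len(assign) else 0.0

    f_pre = frac_inside(tracks_pre)
    f_stim = frac_inside(tracks_stim)
    fold = f_stim / f_pre if f_pre > 0 else float("inf")
    return {"fraction_in_pre": f_pre, "fraction_in_stim": f_stim, "fold_change": fold}
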