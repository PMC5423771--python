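"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own algorithms: the MSD oracle is
a literal double loop over pairs, and the linking oracle enumerates every
injective partial matching per frame pair instead of solving an
assignment problem.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_force_msd(pos: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """MSD by explicit double loop: mean over all ordered pairs per lag."""
    n = len(pos)
    msd = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    counts[0] = n
    for k in range(1, max_lag + 1):
        acc = 0.0
        c = 0
        for i in range(n - k):
            diff = pos[i + k] - pos[i]
            acc += float(np.dot(diff, diff))
            c += 1
        if c:
            msd[k] = acc / c
        counts[k] = c
    return msd, counts


def enumerate_optimal_matching(costs: np.ndarray, allowed: np.ndarray,
                               gate: float) -> tuple[float, frozenset]:
    """Exhaustively optimal partial matching of heads to spots.

    Objective: sum of ``costs`` over matched pairs plus ``gate**2`` per
    unmatched head and per unmatched spot; pairs with ``allowed`` False
    cannot be matched. Returns (optimal cost, matched pair set). Feasible
    only for small instances (≤ ~5 per side).
    """
    n, m = costs.shape
    best = (np.inf, frozenset())
    spots = list(range(m)) + [None] * n  # None = unmatched slot
    seen = set()
    for perm in permutations(spots, n):
        real = [s for s in perm if s is not None]
        if len(set(real)) != len(real):
            continue
        key = tuple(perm)
        if key in seen:
            continue
        seen.add(key)
        total = 0.0
        pairs = []
        ok = True
        for i, s in enumerate(perm):
            if s is None:
                total += gate**2
            else:
                if not allowed[i, s]:
                    ok = False
                    break
                total += costs[i, s]
                pairs.append((i, s))
        if not ok:
            continue
        total += gate**2 * (m - len(pairs))
        if total < best[0] - 1e-12:
            best = (total, frozenset(pairs))
    return best


def sequential_oracle_link(spots_by_frame: list[np.ndarray], gate: float,
                           w: float, min_speed: float = 0.28,
                           vel_smooth: float = 0.6) -> list[list[tuple[int, int]]]:
    """Frame-sequential linking with exhaustively optimal per-frame matching.

    Follows the linker contract (prediction x + w*v with exponentially
    smoothed velocity, speed deadband, gate on actual distance, gate²
    birth/death penalty) but finds each frame's matching by enumeration.
    Returns tracks as lists of (frame, spot_index) pairs.
    """
    tracks: list[list[tuple[int, int]]] = []
    active: list[int] = []   # indices into tracks
    pos: dict[int, np.ndarray] = {}
    vel: dict[int, np.ndarray] = {}

    for f, pts in enumerate(spots_by_frame):
        if f == 0 or not active:
            matches = frozenset()
        else:
            heads = np.array([pos[i] for i in active])
            vels = np.array([vel[i] for i in active])
            vels[np.linalg.norm(vels, axis=1) < min_speed] = 0.0
            preds = heads + w * vels
            d_act = np.linalg.norm(heads[:, None, :] - pts[None, :, :], axis=2)
            d_pred2 = np.sum((preds[:, None, :] - pts[None, :, :]) ** 2, axis=2)
            _, matches = enumerate_optimal_matching(d_pred2, d_act <= gate, gate)
        matched_spots = {s for (_, s) in matches}
        new_active = []
        for (hi, sj) in matches:
            ti = active[hi]
            v_inst = pts[sj] - pos[ti]
            vel[ti] = (1 - vel_smooth) * vel[ti] + vel_smooth * v_inst
            pos[ti] = pts[sj]
            tracks[ti].append((f, sj))
            new_active.append(ti)
        for sj in range(len(pts)):
            if sj not in matched_spots:
                ti = len(tracks)
                tracks.append([(f, sj)])
                pos[ti] = pts[sj]
                vel[ti] = np.zeros(pts.shape[1])
                new_active.append(ti)
        active = new_active
    return tracks
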