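"""File round-trips: TIFF movies with a YAML calibration sidecar, and CSV
tables for spots, tracks and FRAP traces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frap import FRAPRecord
from .simulate import GroundTruth, MovieStack

__all__ = [
    "save_movie", "load_movie",
    "save_tracks_csv", "load_tracks_csv",
    "save_ground_truth_csv",
    "save_frap_csv", "load_frap_csv",
]


def save_movie(path: str | Path, movie: MovieStack) -> None:
    """Write a multi-page TIFF plus a ``<name>.yaml`` calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), photometric="minisblack")
    sidecar = {"pixel_size_um": float(movie.pixel_size),
               "frame_interval_s": float(movie.frame_interval)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def load_movie(path: str | Path) -> MovieStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return MovieStack(frames=np.asarray(frames, float),
                      pixel_size=float(meta["pixel_size_um"]),
                      frame_interval=float(meta["frame_interval_s"]))


def save_tracks_csv(path: str | Path, tracks: pd.DataFrame) -> None:
    tracks.to_csv(path, index=False)


def load_tracks_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_ground_truth_csv(path: str | Path, truth: GroundTruth) -> None:
    truth.to_dataframe().to_csv(path, index=False)


def save_frap_csv(path: str | Path, record: FRAPRecord) -> None:
    df = pd.DataFrame({"time_s": record.times, "intensity_norm": record.intensity})
    df.attrs = {}
    header = (f"# bleach_index={record.bleach_index} omega_um={record.omega} "
              f"region={record.region_type}\n")
    Path(path).write_text(header + df.to_csv(index=False))


def load_frap_csv(path: str | Path) -> FRAPRecord:
    text = Path(path).read_text().splitlines()
    meta = dict(kv.split("=") for kv in text[0].lstrip("# ").split())
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(text[1:])))
    return FRAPRecord(times=df["time_s"].to_numpy(),
                      intensity=df["intensity_norm"].to_numpy(),
                      bleach_index=int(meta["bleach_index"]),
                      omega=float(meta["omega_um"]),
                      region_type=meta.get("region", "swelling"))
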