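"""Read and validate particle-track files into :class:`TrackSet`.

Supports the TrackMate "spots statistics" CSV dialect (including the
three-row unit header of recent TrackMate versions) and a Model/AllSpots/
AllTracks subset of TrackMate XML. Positions are kept in TrackMate's
convention: origin at image top-left, x rightward, y downward, um units.
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .models import TrackSet, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["load_tracks", "filter_min_length", "TrackFormatError"]

REQUIRED_COLUMNS = ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y")


class TrackFormatError(ValueError):
    """Raised when a track file does not match a known dialect."""


def load_tracks(
    path: str | Path,
    dt: float,
    fmt: str = "auto",
    pixel_size: float | None = None,
) -> TrackSet:
    """Load a TrackMate CSV or XML export.

    Parameters
    ----------
    dt : frame interval in seconds (TrackMate exports do not carry it
        reliably).
    pixel_size : if given, positions are assumed to be in pixels and are
        converted to um by multiplication.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if fmt == "auto":
        fmt = "xml" if path.suffix.lower() == ".xml" else "csv"
    if fmt == "csv":
        df = _read_csv(path)
    elif fmt == "xml":
        df = _read_xml(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if df.empty:
        warnings.warn(f"{path}: no spots found, returning empty TrackSet", stacklevel=2)
        return TrackSet(trajectories=[], dt=dt, pixel_size=pixel_size, source=str(path))

    scale = pixel_size if pixel_size is not None else 1.0
    df = df.sort_values(["TRACK_ID", "FRAME"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(subset=["TRACK_ID", "FRAME"]).any():
        raise ValueError(f"{path}: duplicate spots within a frame for one track")

    trajectories = []
    for tid, grp in df.groupby("TRACK_ID", sort=True):
        frames = grp["FRAME"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"{path}: non-monotone frames in track {tid}")
        trajectories.append(
            Trajectory(
                track_id=int(tid),
                frames=frames,
                x=grp["POSITION_X"].to_numpy(dtype=float) * scale,
                y=grp["POSITION_Y"].to_numpy(dtype=float) * scale,
                dt=dt,
            )
        )
    return TrackSet(trajectories=trajectories, dt=dt, pixel_size=pixel_size, source=str(path))


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    # TrackMate >= 7 inserts up to three non-numeric unit/header rows below
    # the header; drop any row whose FRAME does not parse as a number.
    frame_num = pd.to_numeric(df["FRAME"], errors="coerce")
    df = df[frame_num.notna()].copy()
    for col in REQUIRED_COLUMNS:
        df[col] = pd.to_numeric(df[col])
    return df[list(REQUIRED_COLUMNS)]


def _read_xml(path: Path) -> pd.DataFrame:
    root = ET.parse(path).getroot()
    model = root.find("Model")
    if model is None:
        raise TrackFormatError(f"{path}: no <Model> element")
    spots: dict[int, tuple[int, float, float]] = {}
    allspots = model.find("AllSpots")
    if allspots is not None:
        for spot in allspots.iter("Spot"):
            sid = int(spot.attrib["ID"])
            spots[sid] = (
                int(float(spot.attrib["FRAME"])),
                float(spot.attrib["POSITION_X"]),
                float(spot.attrib["POSITION_Y"]),
            )
    rows = []
    alltracks = model.find("AllTracks")
    if alltracks is not None:
        for track in alltracks.iter("Track"):
            tid = int(track.attrib["TRACK_ID"])
            ids: set[int] = set()
            for edge in track.iter("Edge"):
                ids.add(int(edge.attrib["SPOT_SOURCE_ID"]))
                ids.add(int(edge.attrib["SPOT_TARGET_ID"]))
            for sid in ids:
                f, x, y = spots[sid]
                rows.append((tid, f, x, y))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def filter_min_length(ts: TrackSet, min_frames: int = 6) -> TrackSet:
    """Keep trajectories spanning at least ``min_frames`` frames.

    The default 6 implements the "more than five frames" rule read
    strictly; span counts first-to-last frame inclusive, so interior gaps
    do not reduce it. Idempotent.
    """
    kept = [t for t in ts.trajectories if t.span >= min_frames]
    removed = len(ts.trajectories) - len(kept)
    if removed:
        logger.info("filter_min_length: removed %d of %d tracks", removed, len(ts.trajectories))
    return TrackSet(trajectories=kept, dt=ts.dt, pixel_size=ts.pixel_size, source=ts.source)
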