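"""Ground-truth generators for trajectories, image stacks and localizations.

Every downstream stage of the pipeline (track ingestion, motion
classification, iMSD correlation, SMLM cluster sizing) is exercised against
data produced here, where the motion mode of every frame and the membership
of every localization are known exactly.

Motion is generated by Euler steps at the frame interval ``dt``:

* ``brownian``  -- dx, dy ~ Normal(0, 2 D dt) per axis,
* ``drifted``   -- v dt (cos h, sin h) plus the Brownian term,
* ``confined``  -- Brownian step reflected at radius R_conf about the
  segment anchor,
* ``immobile``  -- the anchor position.

Localization noise (SD ``sigma_loc`` per axis) is added independently per
frame after the true path is built, which is the standard additive
static-error model of SPT.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .models import (
    KIND_TO_CLASS,
    AcquisitionConfig,
    MotionModel,
    SwitchingSchedule,
    Trajectory,
)

__all__ = [
    "simulate_trajectory",
    "simulate_mixture",
    "with_gaps",
    "render_stack",
    "write_stack",
    "export_tracks",
    "export_tracks_xml",
    "simulate_localizations",
]


def _as_schedule(model: MotionModel | SwitchingSchedule, n_frames: int) -> SwitchingSchedule:
    if isinstance(model, SwitchingSchedule):
        return model
    return SwitchingSchedule(segments=((model, n_frames),))


def simulate_trajectory(
    model: MotionModel | SwitchingSchedule,
    acq: AcquisitionConfig,
    rng: np.random.Generator | int | None = None,
    *,
    track_id: int = 0,
    start: tuple[float, float] | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Simulate one trajectory; returns (trajectory, per-frame truth labels).

    A plain :class:`MotionModel` runs for ``acq.n_frames`` frames; a
    :class:`SwitchingSchedule` runs each of its segments in order, the next
    segment starting from the current position (anchors for immobile and
    confined segments re-anchor at the segment start).
    """
    rng = np.random.default_rng(rng if rng is not None else acq.seed)
    schedule = _as_schedule(model, acq.n_frames)
    n = schedule.n_frames

    if start is None:
        fov_y, fov_x = acq.fov_um
        # keep well inside the field so rendered spots do not clip
        pos0 = np.array(
            [rng.uniform(0.15 * fov_x, 0.85 * fov_x), rng.uniform(0.15 * fov_y, 0.85 * fov_y)]
        )
    else:
        pos0 = np.asarray(start, dtype=float)

    true = np.empty((n, 2))
    labels = np.empty(n, dtype=object)
    noise_sd = np.empty(n)
    cur = pos0.copy()
    i = 0
    for seg_model, seg_n in schedule.segments:
        anchor = cur.copy()
        for k in range(seg_n):
            if k == 0 and i == 0:
                # first frame of the track sits at the starting position
                pass
            elif seg_model.kind == "immobile":
                cur = anchor.copy()
            else:
                step = rng.normal(0.0, np.sqrt(2.0 * seg_model.D * acq.dt), size=2)
                if seg_model.kind == "drifted":
                    step += seg_model.v * acq.dt * np.array(
                        [np.cos(seg_model.heading), np.sin(seg_model.heading)]
                    )
                cur = cur + step
                if seg_model.kind == "confined":
                    cur = _reflect_disc(cur, anchor, seg_model.R_conf)
            true[i] = cur
            labels[i] = KIND_TO_CLASS[seg_model.kind]
            noise_sd[i] = seg_model.sigma_loc
            i += 1

    obs = true + rng.normal(0.0, 1.0, size=true.shape) * noise_sd[:, None]
    traj = Trajectory(
        track_id=track_id,
        frames=np.arange(n, dtype=np.int64),
        x=obs[:, 0],
        y=obs[:, 1],
        dt=acq.dt,
    )
    return traj, labels


def _reflect_disc(pos: np.ndarray, anchor: np.ndarray, radius: float) -> np.ndarray:
    """Fold a position back inside a disc of given radius about ``anchor``."""
    d = np.linalg.norm(pos - anchor)
    if d <= radius:
        return pos
    # reflect the radial overshoot; clamp to the rim for pathological steps
    new_d = 2.0 * radius - d
    if new_d < 0:
        new_d = radius
    return anchor + (pos - anchor) * (new_d / d)


def simulate_mixture(
    models: list[MotionModel | SwitchingSchedule],
    counts: list[int],
    acq: AcquisitionConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[Trajectory], list[np.ndarray]]:
    """Simulate ``counts[k]`` trajectories from ``models[k]``, ids sequential."""
    rng = np.random.default_rng(rng if rng is not None else acq.seed)
    trajectories: list[Trajectory] = []
    all_labels: list[np.ndarray] = []
    tid = 0
    for model, count in zip(models, counts):
        for _ in range(count):
            traj, labels = simulate_trajectory(model, acq, rng, track_id=tid)
            trajectories.append(traj)
            all_labels.append(labels)
            tid += 1
    return trajectories, all_labels


def with_gaps(
    traj: Trajectory,
    rng: np.random.Generator | int | None = None,
    gap_rate: float = 0.05,
    max_gap: int = 3,
) -> Trajectory:
    """Delete random interior spots, never more than ``max_gap`` in a row.

    Emulates missed detections bridged by gap-closing tracking (maximum
    frame gap 3); first and last spots are always kept so the span is
    unchanged.
    """
    rng = np.random.default_rng(rng)
    n = traj.n_spots
    if n <= 2:
        return traj
    keep = np.ones(n, dtype=bool)
    run = 0
    for i in range(1, n - 1):
        if run < max_gap and rng.random() < gap_rate:
            keep[i] = False
            run += 1
        else:
            run = 0
    return Trajectory(
        track_id=traj.track_id,
        frames=traj.frames[keep],
        x=traj.x[keep],
        y=traj.y[keep],
        dt=traj.dt,
    )


# ---------------------------------------------------------------------------
# image-stack rendering


def render_stack(
    trajectories: list[Trajectory],
    acq: AcquisitionConfig,
    rng: np.random.Generator | int | None = None,
    *,
    out_of_field: str = "warn",
    wrap: bool = False,
) -> np.ndarray:
    """Render trajectories into a Poisson-noise image stack (uint16).

    Each particle is an isotropic 2-D Gaussian of SD
    ``sqrt(psf_sigma^2 + (particle_diameter/4)^2)`` (a uniform disc of
    diameter d has per-axis second moment (d/4)^2) integrating to
    ``photons_per_spot`` counts; Poisson noise is applied to signal plus
    ``background`` counts/px.

    With ``wrap=True`` positions are folded modulo the field of view
    (periodic boundaries). Combined with uniform seeding over the full
    field this keeps the ensemble density stationary and uniform, the
    regime the circular spatiotemporal correlation assumes; without it, a
    static density profile adds a broad correlation pedestal.
    """
    if out_of_field not in ("warn", "error"):
        raise ValueError("out_of_field must be 'warn' or 'error'")
    rng = np.random.default_rng(rng if rng is not None else acq.seed)
    ny, nx = acq.image_shape
    sigma_um = float(np.hypot(acq.psf_sigma, acq.particle_diameter / 4.0))
    sigma_px = sigma_um / acq.pixel_size
    half = max(2, int(np.ceil(4.0 * sigma_px)))

    expected = np.full((acq.n_frames, ny, nx), float(acq.background))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    for traj in trajectories:
        for f, x_um, y_um in zip(traj.frames, traj.x, traj.y):
            if f < 0 or f >= acq.n_frames:
                continue
            if wrap:
                fov_y, fov_x = acq.fov_um
                x_um = x_um % fov_x
                y_um = y_um % fov_y
            cx = x_um / acq.pixel_size
            cy = y_um / acq.pixel_size
            if not (0 <= cx < nx and 0 <= cy < ny):
                msg = f"track {traj.track_id} frame {f} out of field; clipped"
                if out_of_field == "error":
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)
                cx = min(max(cx, 0.0), nx - 1.0)
                cy = min(max(cy, 0.0), ny - 1.0)
            ix, iy = int(round(cx)), int(round(cy))
            g = np.exp(-(((xx + ix - cx) ** 2) + ((yy + iy - cy) ** 2)) / (2 * sigma_px**2))
            g *= acq.photons_per_spot / (2 * np.pi * sigma_px**2)
            if wrap:
                # fold the PSF tail around the periodic field
                gy = (np.arange(iy - half, iy + half + 1)) % ny
                gx = (np.arange(ix - half, ix + half + 1)) % nx
                expected[f][np.ix_(gy, gx)] += g
            else:
                x0, x1 = max(0, ix - half), min(nx, ix + half + 1)
                y0, y1 = max(0, iy - half), min(ny, iy + half + 1)
                expected[f, y0:y1, x0:x1] += g[
                    (y0 - iy + half) : (y1 - iy + half), (x0 - ix + half) : (x1 - ix + half)
                ]
    stack = rng.poisson(expected).astype(np.uint16)
    return stack


def write_stack(path: str | Path, stack: np.ndarray, acq: AcquisitionConfig) -> None:
    """Write a multipage TIFF plus a JSON sidecar with dt and pixel size."""
    path = Path(path)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"dt": acq.dt, "pixel_size": acq.pixel_size, "n_frames": int(stack.shape[0])})
    )


def render_particle_field(
    model: MotionModel,
    acq: AcquisitionConfig,
    n_particles: int,
    rng: np.random.Generator | int | None = None,
    *,
    tracks: list[Trajectory] | None = None,
) -> tuple[np.ndarray, list[Trajectory]]:
    """Render a stationary uniform field of moving particles.

    Particles are seeded uniformly over the whole field and rendered with
    periodic wrapping, keeping the ensemble density flat — the regime the
    spatiotemporal correlation analysis assumes. Pass ``tracks`` to reuse
    previously simulated trajectories (e.g. to vary only the rendered
    particle size); only the Poisson noise is then redrawn.
    """
    rng = np.random.default_rng(rng if rng is not None else acq.seed)
    if tracks is None:
        fov_y, fov_x = acq.fov_um
        tracks = [
            simulate_trajectory(
                model, acq, rng, track_id=i, start=(rng.uniform(0, fov_x), rng.uniform(0, fov_y))
            )[0]
            for i in range(n_particles)
        ]
    stack = render_stack(tracks, acq, rng, wrap=True)
    return stack, tracks


# ---------------------------------------------------------------------------
# track export (TrackMate spots-statistics dialect)


def export_tracks(trajectories: list[Trajectory], path: str | Path) -> None:
    """Write a TrackMate-style spots-statistics CSV.

    Columns TRACK_ID, FRAME, POSITION_X, POSITION_Y (um). Gap frames are
    simply absent (no interpolation). Duplicate (track_id, frame) pairs are
    rejected.
    """
    rows = []
    for traj in trajectories:
        for f, x, y in zip(traj.frames, traj.x, traj.y):
            rows.append((traj.track_id, int(f), x, y))
    df = pd.DataFrame(rows, columns=["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"])
    if df.duplicated(subset=["TRACK_ID", "FRAME"]).any():
        raise ValueError("duplicate (track_id, frame) pairs in export")
    df.to_csv(path, index=False, float_format="%.6f")


def export_tracks_xml(trajectories: list[Trajectory], path: str | Path, dt: float) -> None:
    """Write a minimal TrackMate XML (Model/AllSpots/AllTracks subset)."""
    root = ET.Element("TrackMate", version="7")
    model = ET.SubElement(root, "Model", spatialunits="micron", timeunits="frame")
    allspots = ET.SubElement(model, "AllSpots")
    alltracks = ET.SubElement(model, "AllTracks")

    spot_id = 0
    frames_seen: dict[int, ET.Element] = {}
    for traj in trajectories:
        track_el = ET.SubElement(alltracks, "Track", TRACK_ID=str(traj.track_id))
        prev_id = None
        for f, x, y in zip(traj.frames, traj.x, traj.y):
            f = int(f)
            if f not in frames_seen:
                frames_seen[f] = ET.SubElement(allspots, "SpotsInFrame", frame=str(f))
            ET.SubElement(
                frames_seen[f],
                "Spot",
                ID=str(spot_id),
                FRAME=str(f),
                POSITION_X=f"{x:.6f}",
                POSITION_Y=f"{y:.6f}",
                POSITION_T=f"{f * dt:.6f}",
            )
            if prev_id is not None:
                ET.SubElement(
                    track_el,
                    "Edge",
                    SPOT_SOURCE_ID=str(prev_id),
                    SPOT_TARGET_ID=str(spot_id),
                )
            prev_id = spot_id
            spot_id += 1
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# SMLM localization tables


def simulate_localizations(
    n_clusters: int,
    diameter_nm: float = 150.0,
    locs_per_cluster: int = 200,
    noise_locs: int = 0,
    field_nm: float = 10_000.0,
    seed: np.random.Generator | int | None = None,
    frame_range: tuple[int, int] = (501, 20_000),
) -> pd.DataFrame:
    """Disc-shaped localization clusters plus uniform background noise.

    Cluster members are uniform on a disc of ``diameter_nm``; the returned
    table carries ThunderSTORM-style columns (frame, x, y, sigma,
    uncertainty, all nm) plus a ground-truth ``cluster_id`` (-1 for noise).
    Sigma and uncertainty are drawn inside the standard quality filters
    (sigma <= 130 nm, uncertainty <= 40 nm) so filtering keeps them.
    """
    if diameter_nm <= 0:
        raise ValueError("diameter_nm must be positive")
    rng = np.random.default_rng(seed)
    radius = diameter_nm / 2.0

    centers = rng.uniform(1.5 * radius, field_nm - 1.5 * radius, size=(n_clusters, 2))
    if n_clusters > 1:
        from scipy.spatial.distance import pdist

        if pdist(centers).min() < 2.0 * diameter_nm:
            warnings.warn(
                "cluster centers closer than 2x diameter: ground truth ambiguous",
                stacklevel=2,
            )

    xs, ys, ids = [], [], []
    for k in range(n_clusters):
        r = radius * np.sqrt(rng.uniform(size=locs_per_cluster))
        th = rng.uniform(0, 2 * np.pi, size=locs_per_cluster)
        xs.append(centers[k, 0] + r * np.cos(th))
        ys.append(centers[k, 1] + r * np.sin(th))
        ids.append(np.full(locs_per_cluster, k))
    if noise_locs:
        xs.append(rng.uniform(0, field_nm, size=noise_locs))
        ys.append(rng.uniform(0, field_nm, size=noise_locs))
        ids.append(np.full(noise_locs, -1))

    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    cid = np.concatenate(ids).astype(int) if ids else np.empty(0, dtype=int)
    n = len(x)
    df = pd.DataFrame(
        {
            "frame": rng.integers(frame_range[0], frame_range[1] + 1, size=n),
            "x": x,
            "y": y,
            "sigma": np.clip(rng.normal(110.0, 10.0, size=n), 60.0, 130.0),
            "uncertainty": np.clip(rng.normal(20.0, 5.0, size=n), 5.0, 40.0),
            "cluster_id": cid,
        }
    )
    return df


def export_localizations(df: pd.DataFrame, path: str | Path) -> None:
    """Write a ThunderSTORM-dialect CSV (quoted headers with nm units)."""
    out = pd.DataFrame(
        {
            "frame": df["frame"].astype(int),
            "x [nm]": df["x"],
            "y [nm]": df["y"],
            "sigma [nm]": df["sigma"],
            "uncertainty [nm]": df["uncertainty"],
        }
    )
    out.to_csv(path, index=False, float_format="%.2f")
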