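"""Shared domain types for the granule-mobility pipeline.

Units follow the imaging conventions of the field throughout: positions in
micrometers (SPT, iMSD) or nanometers (SMLM), time in seconds, diffusion
coefficients in um^2/s, speeds in um/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

MotionKind = Literal["immobile", "confined", "brownian", "drifted"]
MotionClass = Literal["blocked", "diffusive", "drifted"]
SubLabel = Literal["immobile", "slow", "fast", "drifted_step1", "drifted_step2"]

#: ground-truth mapping from generative motion kind to observed class
KIND_TO_CLASS: dict[str, str] = {
    "immobile": "blocked",
    "confined": "diffusive",
    "brownian": "diffusive",
    "drifted": "drifted",
}

SUBLABEL_TO_LABEL: dict[str, str] = {
    "immobile": "blocked",
    "slow": "diffusive",
    "fast": "diffusive",
    "drifted_step1": "drifted",
    "drifted_step2": "drifted",
}


@dataclass(frozen=True)
class MotionModel:
    """One generative motion mode for a (sub)trajectory.

    Parameters
    ----------
    kind : {"immobile", "confined", "brownian", "drifted"}
    D : diffusion coefficient, um^2/s.
    v : drift speed, um/s; required (and only allowed) for ``drifted``.
    heading : drift direction, radians; used for ``drifted`` only.
    R_conf : confinement radius, um; required for ``confined``.
    sigma_loc : localization-noise SD added per frame and axis, um.
    """

    kind: MotionKind
    D: float = 0.0
    v: float = 0.0
    heading: float = 0.0
    R_conf: float = 0.0
    sigma_loc: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KIND_TO_CLASS:
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if (self.v > 0) != (self.kind == "drifted"):
            raise ValueError("v > 0 required iff kind == 'drifted'")
        if (self.R_conf > 0) != (self.kind == "confined"):
            raise ValueError("R_conf > 0 required iff kind == 'confined'")

    @property
    def truth_class(self) -> str:
        return KIND_TO_CLASS[self.kind]


@dataclass(frozen=True)
class SwitchingSchedule:
    """Ordered motion modes for a stop-and-go style mixed trajectory."""

    segments: tuple[tuple[MotionModel, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((m, int(n)) for m, n in self.segments)
        object.__setattr__(self, "segments", segs)
        if any(n < 5 for _, n in segs):
            raise ValueError(
                "every schedule segment needs at least 5 frames to be recoverable"
            )
        if self.n_frames < 10:
            raise ValueError("schedule must total at least 10 frames")

    @property
    def n_frames(self) -> int:
        return sum(n for _, n in self.segments)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging geometry of a time-lapse confocal acquisition.

    Defaults emulate a 500-frame stack at 204 ms/frame, 0.1 um pixels,
    a 0.13 um PSF SD and a 256 x 256 px field of view.
    """

    dt: float = 0.204
    n_frames: int = 500
    pixel_size: float = 0.1
    image_shape: tuple[int, int] = (256, 256)
    psf_sigma: float = 0.13
    photons_per_spot: float = 500.0
    background: float = 10.0
    particle_diameter: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def fov_um(self) -> tuple[float, float]:
        ny, nx = self.image_shape
        return (ny * self.pixel_size, nx * self.pixel_size)


@dataclass
class Trajectory:
    """One particle's time-ordered 2-D positions.

    ``frames`` are integer frame indices (strictly increasing; interior gaps
    of up to a few frames are allowed and preserved), ``x``/``y`` are in um,
    ``dt`` is the frame interval in seconds.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_spots(self) -> int:
        return len(self.frames)

    @property
    def span(self) -> int:
        """Number of frames from first to last spot, inclusive."""
        if len(self.frames) == 0:
            return 0
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subtrack(self, start: int, stop: int) -> "Trajectory":
        """Slice by spot index (``stop`` exclusive)."""
        return Trajectory(
            track_id=self.track_id,
            frames=self.frames[start:stop],
            x=self.x[start:stop],
            y=self.y[start:stop],
            dt=self.dt,
        )


@dataclass
class TrackSet:
    """A set of trajectories from one acquisition, sharing dt."""

    trajectories: list[Trajectory]
    dt: float
    pixel_size: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique")
        for t in self.trajectories:
            if not np.isclose(t.dt, self.dt):
                raise ValueError("all trajectories must share the TrackSet dt")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def n_spots(self) -> int:
        return sum(t.n_spots for t in self.trajectories)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the two-step segmentation/classification.

    ``v_t`` splits go (drifted) from stop (mixed) spans of the windowed
    speed; ``Lc1``/``tc1`` seed and ``Lc2``/``tc2`` grow confinement zones;
    ``D_block``/``D_lim`` separate immobile / slow / fast diffusivity; a
    non-immobile segment with MSD log-log half-exponent gamma >=
    ``gamma_drift`` is classified as drifted in the second step.
    """

    v_t: float = 0.2
    window: int = 5
    min_spots: int = 5
    Lc1: float = 1.8
    tc1: int = 5
    Lc2: float = 1.4
    tc2: int = 7
    D_block: float = 2e-3
    D_lim: float = 1e-2
    gamma_drift: float = 0.75
    tad_window: int = 10

    def __post_init__(self) -> None:
        if not self.Lc2 < self.Lc1:
            raise ValueError("Lc2 must be < Lc1")
        if not self.tc1 <= self.tc2:
            raise ValueError("tc1 must be <= tc2")
        if not self.D_block < self.D_lim:
            raise ValueError("D_block must be < D_lim")
        if not self.v_t > 0:
            raise ValueError("v_t must be > 0")
        if self.window < 3:
            raise ValueError("velocity window must be >= 3 frames")
        if self.min_spots < 2:
            raise ValueError("min_spots must be >= 2")
        if self.tad_window < 3:
            raise ValueError("tad_window must be >= 3 frames")


@dataclass
class MomentSpectrum:
    """Displacement moments of orders 1..6 and their scaling exponents.

    ``moments[p-1, l]`` is the time-averaged moment of order ``p`` at lag
    ``lags[l]`` (frames); ``mss_slopes[p-1]`` is the slope of
    log mu_p vs log lag; ``gamma`` is half the MSD exponent (order-2 slope
    over 2); ``D12`` is the short-lag diffusivity from the first two MSD
    lags (slope of MSD vs lag time over 4, intercept absorbing noise).
    """

    orders: np.ndarray
    lags: np.ndarray
    moments: np.ndarray
    mss_slopes: np.ndarray
    gamma: float
    D12: float
    n_spots: int
    dt: float

    @property
    def msd(self) -> np.ndarray:
        return self.moments[1]


@dataclass
class ClassifiedSegment:
    """A (sub)trajectory span tagged with its motion class."""

    track_id: int
    start_frame: int
    end_frame: int
    label: MotionClass
    sublabel: SubLabel
    D12: float
    gamma: float
    n_spots: int
    start_index: int = 0
    end_index: int = 0

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must be > start_frame")
        if SUBLABEL_TO_LABEL[self.sublabel] != self.label:
            raise ValueError(
                f"label {self.label!r} inconsistent with sublabel {self.sublabel!r}"
            )


@dataclass
class MobilitySummary:
    """Per-acquisition length percentages of the three motion classes."""

    acquisition_id: str
    pct_blocked: float
    pct_diffusive: float
    pct_drifted: float
    n_tracks: int
    n_spots: int

    def __post_init__(self) -> None:
        total = self.pct_blocked + self.pct_diffusive + self.pct_drifted
        if self.n_spots > 0 and abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, expected 100")


@dataclass
class CorrelationStack:
    """Spatiotemporal correlation maps G(xi, eta, tau), one per time lag."""

    lags: np.ndarray  # seconds
    G: np.ndarray  # (n_lags, ny, nx), zero spatial lag at the center
    pixel_size: float
    dt: float


@dataclass
class iMSDCurve:
    """sigma^2(tau) from correlation widths, plus the anomalous-law fit."""

    tau: np.ndarray
    sigma2: np.ndarray
    fit_offset: float = np.nan
    fit_Dm: float = np.nan
    fit_alpha: float = np.nan
    fit_cov: np.ndarray | None = None


@dataclass
class GranuleCluster:
    """A DBSCAN cluster of SMLM localizations sized as a granule."""

    cluster_id: int
    member_indices: np.ndarray
    centroid: tuple[float, float]
    area_nm2: float
    diameter_nm: float
    contour_wkt: str
    degenerate: bool = False

    @property
    def n_locs(self) -> int:
        return len(self.member_indices)
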