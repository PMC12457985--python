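"""Two-step trajectory segmentation and motion-mode classification.

Step 1 (stop-and-go): a moving 5-frame windowed speed is thresholded at
``v_t`` (default 0.2 um/s); sustained fast runs become *drifted* segments,
the rest remain *mixed*.

Step 2 (MSS-TAD): mixed segments are scanned for transient arrests of
diffusion (confinement zones where the local diffusivity is improbably low
relative to the segment average, detected with a seed-and-threshold
strategy on a Simson-Sheetz confinement index), and every resulting
(sub)trajectory is classified from its displacement-moment spectrum:
*blocked* (immobile) below ``D_block``, *diffusive* (slow/fast) in between
and above ``D_lim``, and super-diffusive segments (gamma >= gamma_drift)
merged into the *drifted* category.

Results are reported as "length" percentages: the fraction of all
classified spots (frames) falling in each category.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    ClassifiedSegment,
    ClassifierParams,
    MobilitySummary,
    MomentSpectrum,
    TrackSet,
    Trajectory,
)

logger = logging.getLogger(__name__)

__all__ = [
    "window_velocity",
    "stop_and_go_segment",
    "displacement_moments",
    "tad_detect",
    "classify_segment",
    "classify_trackset",
    "d12_gamma_distribution",
    "segments_to_dataframe",
]


# ---------------------------------------------------------------------------
# step 1: windowed speed and stop-and-go segmentation


def window_velocity(traj: Trajectory, window: int = 5) -> np.ndarray:
    """Per-spot speed over a centered moving window (um/s).

    The speed at spot i is the net displacement between the window's end
    spots divided by the true elapsed time (frame difference times dt, so
    interior gaps widen the denominator rather than being interpolated).
    Edge spots use truncated windows of at least 3 spots.
    """
    n = traj.n_spots
    if n < 3:
        raise ValueError("trajectory must have at least 3 spots for a windowed speed")
    half = window // 2
    idx = np.arange(n)
    j1 = np.maximum(idx - half, 0)
    j2 = np.minimum(idx + half, n - 1)
    dx = traj.x[j2] - traj.x[j1]
    dy = traj.y[j2] - traj.y[j1]
    dt_true = (traj.frames[j2] - traj.frames[j1]) * traj.dt
    return np.hypot(dx, dy) / dt_true


def _merge_short_runs(runs: list[list], min_len: int) -> list[list]:
    """Absorb runs shorter than ``min_len`` into a flanking run.

    Each run is ``[state, start, stop)`` in spot indices. The longer
    neighbor wins; ties go to the preceding one. Adjacent same-state runs
    coalesce after each absorption, so every spot stays in exactly one run.
    """
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [r[2] - r[1] for r in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_len]
        if not short:
            break
        i = min(short, key=lambda k: (lengths[k], k))
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = len(runs) - 2
        else:
            prev_len, next_len = lengths[i - 1], lengths[i + 1]
            j = i - 1 if prev_len >= next_len else i + 1
        runs[i][0] = runs[j][0]
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged
    return runs


def _bool_runs(mask: np.ndarray) -> list[list]:
    runs: list[list] = []
    for i, state in enumerate(mask):
        if runs and runs[-1][0] == bool(state):
            runs[-1][2] = i + 1
        else:
            runs.append([bool(state), i, i + 1])
    return runs


def stop_and_go_segment(
    traj: Trajectory, params: ClassifierParams | None = None
) -> list[tuple[int, int, str]]:
    """Split a trajectory at crossings of the windowed-speed threshold.

    Returns ``(start, stop, kind)`` spot-index spans with kind
    ``"drifted_step1"`` (speed >= v_t) or ``"mixed"``; every spot belongs
    to exactly one span. Runs shorter than ``min_spots`` are absorbed into
    a flanking span rather than dropped.
    """
    params = params or ClassifierParams()
    speeds = window_velocity(traj, params.window)
    runs = _merge_short_runs(_bool_runs(speeds >= params.v_t), params.min_spots)
    return [
        (start, stop, "drifted_step1" if state else "mixed") for state, start, stop in runs
    ]


# ---------------------------------------------------------------------------
# displacement moments / moment scaling spectrum


def displacement_moments(
    traj: Trajectory, orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
) -> MomentSpectrum:
    """Time-averaged displacement moments mu_p(lag) for p in ``orders``.

    Lags run from 1 frame to ``max(n // 4, 5)`` frames (capped at the
    track span); all same-track spot pairs separated by exactly that many
    frames contribute, so interior gaps skip unavailable pairs rather than
    interpolating. The MSS slope gamma_p is the least-squares slope of
    log mu_p vs log lag; ``gamma`` is half the MSD (p = 2) exponent and
    ``D12`` the slope of an intercept-bearing linear fit of the MSD over
    the first two lags divided by 4.
    """
    n = traj.n_spots
    if n < 5:
        raise ValueError("displacement moments need at least 5 spots")
    frames = traj.frames
    pos = traj.positions
    span = int(frames[-1] - frames[0])
    L_max = min(max(n // 4, 5), span)
    lags = np.arange(1, L_max + 1)
    orders_arr = np.asarray(orders)

    moments = np.full((len(orders_arr), len(lags)), np.nan)
    for li, lag in enumerate(lags):
        target = frames + lag
        j = np.searchsorted(frames, target)
        valid = j < n
        valid[valid] &= frames[j[valid]] == target[valid]
        if not np.any(valid):
            continue
        d = np.linalg.norm(pos[j[valid]] - pos[valid], axis=1)
        for oi, p in enumerate(orders_arr):
            moments[oi, li] = np.mean(d**p)

    have = np.isfinite(moments[0])
    if have.sum() < 2:
        raise ValueError("fewer than 2 valid lags: cannot form a moment spectrum")

    mss_slopes = np.zeros(len(orders_arr))
    log_lag = np.log(lags.astype(float))
    for oi in range(len(orders_arr)):
        mu = moments[oi]
        ok = np.isfinite(mu) & (mu > 0)
        if ok.sum() >= 2:
            mss_slopes[oi] = np.polyfit(log_lag[ok], np.log(mu[ok]), 1)[0]
        else:
            mss_slopes[oi] = 0.0  # degenerate (e.g. coincident spots)

    msd = moments[list(orders_arr).index(2)] if 2 in orders_arr else moments[1]
    D12 = _short_lag_diffusivity(lags, msd, traj.dt)
    gamma = mss_slopes[list(orders_arr).index(2)] / 2.0 if 2 in orders_arr else 0.0
    if not np.isfinite(gamma):
        gamma = 0.0

    return MomentSpectrum(
        orders=orders_arr,
        lags=lags,
        moments=moments,
        mss_slopes=mss_slopes,
        gamma=float(gamma),
        D12=float(D12),
        n_spots=n,
        dt=traj.dt,
    )


def _short_lag_diffusivity(lags: np.ndarray, msd: np.ndarray, dt: float) -> float:
    """Slope/4 of MSD vs lag time over the first two available lags."""
    ok = np.isfinite(msd)
    use = ok & np.isin(lags, (1, 2))
    if use.sum() < 2:
        idx = np.nonzero(ok)[0][:2]
        if len(idx) < 2:
            return 0.0
        use = np.zeros_like(ok)
        use[idx] = True
    slope = np.polyfit(lags[use] * dt, msd[use], 1)[0]
    return slope / 4.0


def _safe_moments(traj: Trajectory) -> MomentSpectrum:
    """Moments with a degenerate fallback (coincident spots, gap-starved)."""
    try:
        return displacement_moments(traj)
    except ValueError:
        return MomentSpectrum(
            orders=np.arange(1, 7),
            lags=np.array([1]),
            moments=np.zeros((6, 1)),
            mss_slopes=np.zeros(6),
            gamma=0.0,
            D12=0.0,
            n_spots=traj.n_spots,
            dt=traj.dt,
        )


# ---------------------------------------------------------------------------
# step 2: transient arrest of diffusion (confinement zones)


def confinement_index(
    traj: Trajectory, D_bar: float, window: int = 10
) -> tuple[np.ndarray, np.ndarray, int]:
    """Simson-Sheetz confinement likelihood on sliding windows.

    For each sliding window of ``window`` spots, with R the maximum
    displacement from the window's first point and t the true window
    duration, the probability that free diffusion at the segment-average
    diffusivity ``D_bar`` stays within R follows
    log10 psi = 0.2048 - 2.5117 (D_bar t / R^2); the window index is
    L_win = max(0, -log10 psi - 1).

    Returns ``(L, L_win, W)``: the per-spot likelihood (mean of L_win over
    windows covering the spot), the raw per-window series (indexed by
    window start) and the effective window length.
    """
    n = traj.n_spots
    W = min(window, n)
    pos = traj.positions
    acc = np.zeros(n)
    cnt = np.zeros(n)
    L_win = np.zeros(max(n - W + 1, 0))
    for j in range(n - W + 1):
        seg = pos[j : j + W]
        R = np.max(np.linalg.norm(seg - seg[0], axis=1))
        t = (traj.frames[j + W - 1] - traj.frames[j]) * traj.dt
        if R <= 0:
            Lwin = np.inf
        else:
            log10_psi = 0.2048 - 2.5117 * (D_bar * t / R**2)
            Lwin = max(0.0, -log10_psi - 1.0)
        L_win[j] = Lwin
        acc[j : j + W] += Lwin
        cnt[j : j + W] += 1
    cnt[cnt == 0] = 1
    return acc / cnt, L_win, W


def _zones_from_likelihood(
    L: np.ndarray,
    params: ClassifierParams,
    L_win: np.ndarray | None = None,
    window: int | None = None,
) -> list[tuple[int, int]]:
    """Seed-and-threshold zone detection on a likelihood series.

    Seeds are maximal runs with L >= Lc1 of at least ``tc1`` spots
    (endpoints inclusive). Each seed grows outward while the adjacent
    per-spot L stays >= Lc2 and, when the per-window series is supplied,
    absorbs every window whose own likelihood is >= Lc2 and that overlaps
    the zone — the spot-averaged L is diluted near zone edges by windows
    straddling the boundary, so edge recovery needs the window-level
    evidence. Grown zones shorter than ``tc2`` are discarded and
    overlapping zones merged. Returns inclusive (start, end) intervals.
    """
    n = len(L)
    seeds = []
    for state, start, stop in _bool_runs(L >= params.Lc1):
        if state and stop - start >= params.tc1:
            seeds.append((start, stop - 1))
    win_hits = (
        np.nonzero(L_win >= params.Lc2)[0] if L_win is not None and window else np.empty(0, int)
    )
    zones = []
    for s0, s1 in seeds:
        a, b = s0, s1
        changed = True
        while changed:
            changed = False
            while a > 0 and L[a - 1] >= params.Lc2:
                a -= 1
                changed = True
            while b < n - 1 and L[b + 1] >= params.Lc2:
                b += 1
                changed = True
            for j in win_hits:
                if j <= b and j + window - 1 >= a:  # type: ignore[operator]
                    if j < a:
                        a = j
                        changed = True
                    if j + window - 1 > b:  # type: ignore[operator]
                        b = j + window - 1  # type: ignore[operator]
                        changed = True
        if b - a + 1 >= params.tc2:
            zones.append((a, b))
    merged: list[list[int]] = []
    for a, b in sorted(zones):
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def tad_detect(
    traj: Trajectory,
    params: ClassifierParams | None = None,
    D_bar: float | None = None,
) -> list[tuple[int, int]]:
    """Find confinement zones (transient arrests) in a mixed segment.

    Returns inclusive spot-index intervals. ``D_bar`` defaults to the
    segment's own short-lag diffusivity; a degenerate (non-positive)
    average diffusivity makes the whole segment one zone.
    """
    params = params or ClassifierParams()
    n = traj.n_spots
    if n < params.tc2:
        return []
    if D_bar is None:
        D_bar = _safe_moments(traj).D12
    if not np.isfinite(D_bar) or D_bar <= 0:
        return [(0, n - 1)]
    L, L_win, W = confinement_index(traj, D_bar, params.tad_window)
    return _zones_from_likelihood(L, params, L_win, W)


def _partition_with_zones(
    n: int, zones: list[tuple[int, int]], min_spots: int
) -> list[tuple[int, int]]:
    """Cut [0, n) at zone boundaries; absorb sub-minimum pieces.

    Zone intervals are inclusive; the returned pieces are half-open
    (start, stop) spans covering every spot exactly once, each at least
    ``min_spots`` long where possible (undersized pieces merge into the
    longer neighbor, ties to the preceding one).
    """
    if not zones:
        return [(0, n)]
    pieces: list[list] = []
    cursor = 0
    for zi, (a, b) in enumerate(zones):
        if a > cursor:
            pieces.append([False, cursor, a])
        pieces.append([True, a, b + 1])
        cursor = b + 1
    if cursor < n:
        pieces.append([False, cursor, n])
    # reuse run-absorption, but identity here is positional, not by state:
    # give each piece a unique tag so only explicit merges coalesce
    tagged = [[i, p[1], p[2]] for i, p in enumerate(pieces)]
    merged = _merge_short_runs(tagged, min_spots)
    return [(start, stop) for _, start, stop in merged]


# ---------------------------------------------------------------------------
# classification


def classify_segment(
    ms: MomentSpectrum, params: ClassifierParams | None = None
) -> tuple[str, str]:
    """Map a moment spectrum to (label, sublabel).

    immobile if D12 < D_block; else drifted (step 2) if gamma >=
    gamma_drift; else slow below D_lim, fast above — slow and fast both
    report as diffusive.
    """
    params = params or ClassifierParams()
    if ms.D12 < params.D_block:
        return "blocked", "immobile"
    if ms.gamma >= params.gamma_drift:
        return "drifted", "drifted_step2"
    if ms.D12 < params.D_lim:
        return "diffusive", "slow"
    return "diffusive", "fast"


def _make_segment(
    traj: Trajectory, start: int, stop: int, label: str, sublabel: str, ms: MomentSpectrum
) -> ClassifiedSegment:
    return ClassifiedSegment(
        track_id=traj.track_id,
        start_frame=int(traj.frames[start]),
        end_frame=int(traj.frames[stop - 1]),
        label=label,  # type: ignore[arg-type]
        sublabel=sublabel,  # type: ignore[arg-type]
        D12=ms.D12,
        gamma=ms.gamma,
        n_spots=stop - start,
        start_index=start,
        end_index=stop,
    )


def classify_trackset(
    ts: TrackSet,
    params: ClassifierParams | None = None,
    acquisition_id: str = "",
) -> tuple[list[ClassifiedSegment], MobilitySummary]:
    """Run the full two-step pipeline on a filtered TrackSet.

    Every spot of every analyzable track (>= min_spots spots) lands in
    exactly one classified segment; the summary's length percentages are
    100 x (spots in category) / (total classified spots).
    """
    params = params or ClassifierParams()
    segments: list[ClassifiedSegment] = []
    n_tracks = 0
    skipped = 0
    for traj in ts.trajectories:
        if traj.n_spots < params.min_spots:
            skipped += 1
            continue
        n_tracks += 1
        for i0, i1, kind in stop_and_go_segment(traj, params):
            sub = traj.subtrack(i0, i1)
            if kind == "drifted_step1":
                ms = _safe_moments(sub)
                segments.append(_make_segment(traj, i0, i1, "drifted", "drifted_step1", ms))
                continue
            zones = tad_detect(sub, params)
            for j0, j1 in _partition_with_zones(sub.n_spots, zones, params.min_spots):
                piece = sub.subtrack(j0, j1)
                ms = _safe_moments(piece)
                label, sublabel = classify_segment(ms, params)
                segments.append(
                    _make_segment(traj, i0 + j0, i0 + j1, label, sublabel, ms)
                )
    if skipped:
        logger.info("classify_trackset: skipped %d tracks with < %d spots", skipped, params.min_spots)

    counts = {"blocked": 0, "diffusive": 0, "drifted": 0}
    for seg in segments:
        counts[seg.label] += seg.n_spots
    total = sum(counts.values())
    if total == 0:
        warnings.warn("classify_trackset: no classifiable tracks", stacklevel=2)
        summary = MobilitySummary(acquisition_id, 0.0, 0.0, 0.0, 0, 0)
    else:
        summary = MobilitySummary(
            acquisition_id=acquisition_id,
            pct_blocked=100.0 * counts["blocked"] / total,
            pct_diffusive=100.0 * counts["diffusive"] / total,
            pct_drifted=100.0 * counts["drifted"] / total,
            n_tracks=n_tracks,
            n_spots=total,
        )
    return segments, summary


# ---------------------------------------------------------------------------
# joint distribution and tabular output


@dataclass
class JointDistribution:
    """Binned joint density of (log10 D12, gamma) with marginal modes."""

    hist: np.ndarray
    log10_D12_edges: np.ndarray
    gamma_edges: np.ndarray
    D12_mode: float
    gamma_mode: float
    n_segments: int


def d12_gamma_distribution(
    segments,
    bins: int = 40,
    log10_D12_range: tuple[float, float] = (-5.0, 0.0),
    gamma_range: tuple[float, float] = (0.0, 1.5),
) -> JointDistribution:
    """Joint histogram of per-segment (log10 D12, gamma).

    Accepts anything exposing ``.D12`` and ``.gamma`` (classified segments
    or raw moment spectra). Segments with non-positive D12 fall outside
    the log axis and only the in-range values are binned; modes are the
    bin centers of the marginal maxima.
    """
    d12 = np.array([s.D12 for s in segments], dtype=float)
    gam = np.array([s.gamma for s in segments], dtype=float)
    x_edges = np.linspace(*log10_D12_range, bins + 1)
    y_edges = np.linspace(*gamma_range, bins + 1)
    if len(d12) == 0:
        return JointDistribution(
            np.zeros((bins, bins)), x_edges, y_edges, np.nan, np.nan, 0
        )
    pos = d12 > 0
    logd = np.full_like(d12, -np.inf)
    logd[pos] = np.log10(d12[pos])
    hist, _, _ = np.histogram2d(logd, gam, bins=[x_edges, y_edges])

    def _mode(values: np.ndarray, edges: np.ndarray) -> float:
        h, _ = np.histogram(values, bins=edges)
        if h.sum() == 0:
            return np.nan
        i = int(np.argmax(h))
        return 0.5 * (edges[i] + edges[i + 1])

    d12_mode = 10 ** _mode(logd[np.isfinite(logd)], x_edges)
    gamma_mode = _mode(gam[np.isfinite(gam)], y_edges)
    return JointDistribution(hist, x_edges, y_edges, float(d12_mode), float(gamma_mode), len(d12))


def segments_to_dataframe(segments: list[ClassifiedSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": [s.track_id for s in segments],
            "start_frame": [s.start_frame for s in segments],
            "end_frame": [s.end_frame for s in segments],
            "label": [s.label for s in segments],
            "sublabel": [s.sublabel for s in segments],
            "D12": [s.D12 for s in segments],
            "gamma": [s.gamma for s in segments],
            "n_spots": [s.n_spots for s in segments],
        }
    )
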