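"""Granule sizing from SMLM localization tables.

Localization tables (ThunderSTORM dialect: frame, x, y, sigma, uncertainty,
all nm) are quality-filtered, clustered with DBSCAN (eps = 50 nm,
minPts = 8), and each cluster — one secretory granule — is sized by
building a 2-D histogram of its member localizations, taking the largest
8-connected occupied region as the granule footprint, and reporting the
equivalent-circle diameter 2 sqrt(area / pi) of that footprint.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union
from skimage.measure import label as cc_label
from sklearn.cluster import DBSCAN

from .models import GranuleCluster

logger = logging.getLogger(__name__)

__all__ = [
    "load_localizations",
    "filter_localizations",
    "cluster_localizations",
    "cluster_diameter",
    "analyze_localizations",
]

_COLUMN_ALIASES = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "sigma [nm]": "sigma",
    "uncertainty [nm]": "uncertainty",
    "uncertainty_xy [nm]": "uncertainty",
    "x": "x",
    "y": "y",
    "sigma": "sigma",
    "uncertainty": "uncertainty",
}


def load_localizations(path: str | Path) -> pd.DataFrame:
    """Read a ThunderSTORM-dialect CSV into (frame, x, y, sigma, uncertainty) nm."""
    df = pd.read_csv(path)
    df = df.rename(columns={c: _COLUMN_ALIASES[c] for c in df.columns if c in _COLUMN_ALIASES})
    missing = [c for c in ("frame", "x", "y", "sigma", "uncertainty") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing localization column(s) {', '.join(missing)}")
    return df[["frame", "x", "y", "sigma", "uncertainty"]].astype(
        {"frame": int, "x": float, "y": float, "sigma": float, "uncertainty": float}
    )


def filter_localizations(
    table: pd.DataFrame,
    sigma_max: float = 130.0,
    unc_max: float = 40.0,
    skip_frames: int = 500,
) -> pd.DataFrame:
    """Post-filter localizations before clustering.

    Removes the first ``skip_frames`` frames (pre-convergence of the blinking
    buffer) and any localization with sigma > ``sigma_max`` nm or
    uncertainty > ``unc_max`` nm (both strict). Order-independent and
    idempotent; removal counts are logged per criterion.
    """
    if table.empty:
        return table.copy()
    early = table["frame"] <= skip_frames
    wide = table["sigma"] > sigma_max
    uncertain = table["uncertainty"] > unc_max
    logger.info(
        "filter_localizations: removed %d early-frame, %d sigma, %d uncertainty of %d",
        int(early.sum()), int(wide.sum()), int(uncertain.sum()), len(table),
    )
    return table[~(early | wide | uncertain)].copy()


def cluster_localizations(
    table: pd.DataFrame, eps: float = 50.0, min_pts: int = 8
) -> tuple[pd.DataFrame, np.ndarray]:
    """DBSCAN on (x, y) with Euclidean metric.

    ``min_pts`` counts the point itself plus its eps-neighbors (the classic
    convention). Point order is fixed by sorting on (frame, x, y) so the
    order-dependent assignment of shared border points is deterministic.
    Returns the sorted table and a parallel label array (-1 = noise).
    """
    sorted_table = table.sort_values(["frame", "x", "y"], kind="mergesort").reset_index(drop=True)
    if sorted_table.empty:
        return sorted_table, np.empty(0, dtype=int)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(
        sorted_table[["x", "y"]].to_numpy()
    )
    return sorted_table, labels


def cluster_diameter(
    points_nm: np.ndarray, bin_nm: float = 10.0
) -> tuple[float, float, str, bool]:
    """Equivalent-circle diameter of one cluster from its occupied-bin contour.

    A 2-D histogram of the member localizations at ``bin_nm`` resolution is
    thresholded at occupancy >= 1; the largest 8-connected occupied region
    is the granule footprint, its area the bin count times bin_nm^2, and
    the diameter 2 sqrt(area/pi). Exactly collinear clusters are flagged
    and sized by their bounding extent instead.

    Returns ``(diameter_nm, area_nm2, contour_wkt, degenerate)``.
    """
    pts = np.asarray(points_nm, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty cluster")

    if _is_collinear(pts):
        extent = _max_extent(pts)
        return float(extent), 0.0, "LINESTRING EMPTY", True

    x0 = np.floor(pts[:, 0].min() / bin_nm) * bin_nm
    y0 = np.floor(pts[:, 1].min() / bin_nm) * bin_nm
    ix = ((pts[:, 0] - x0) // bin_nm).astype(int)
    iy = ((pts[:, 1] - y0) // bin_nm).astype(int)
    mask = np.zeros((iy.max() + 1, ix.max() + 1), dtype=bool)
    mask[iy, ix] = True
    comps = cc_label(mask, connectivity=2)
    largest = np.argmax(np.bincount(comps.ravel())[1:]) + 1
    region = comps == largest
    area = float(region.sum()) * bin_nm**2
    diameter = 2.0 * np.sqrt(area / np.pi)

    ys, xs = np.nonzero(region)
    cells = [
        box(x0 + cx * bin_nm, y0 + cy * bin_nm, x0 + (cx + 1) * bin_nm, y0 + (cy + 1) * bin_nm)
        for cy, cx in zip(ys, xs)
    ]
    poly = unary_union(cells)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return diameter, area, poly.wkt, False


def _is_collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    d = pts - pts[0]
    cross = d[:, 0] * d[1, 1] - d[:, 1] * d[1, 0]
    if np.allclose(d[1], 0):
        return bool(np.allclose(d, 0))
    return bool(np.all(np.abs(cross) <= tol * np.max(np.abs(d)) ** 2))


def _max_extent(pts: np.ndarray) -> float:
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    return float(np.linalg.norm(hi - lo))


def analyze_localizations(
    table: pd.DataFrame,
    eps: float = 50.0,
    min_pts: int = 8,
    bin_nm: float = 10.0,
    sigma_max: float = 130.0,
    unc_max: float = 40.0,
    skip_frames: int = 500,
    prefiltered: bool = False,
) -> tuple[list[GranuleCluster], pd.DataFrame]:
    """Filter, cluster and size a localization table.

    Returns the clusters and a one-row-per-cluster summary table
    (cluster_id, n_locs, centroid, area, diameter, contour WKT).
    """
    filtered = table if prefiltered else filter_localizations(
        table, sigma_max, unc_max, skip_frames
    )
    sorted_table, labels = cluster_localizations(filtered, eps, min_pts)
    clusters: list[GranuleCluster] = []
    for cid in sorted(set(labels) - {-1}):
        members = np.nonzero(labels == cid)[0]
        pts = sorted_table.loc[members, ["x", "y"]].to_numpy()
        diameter, area, wkt, degenerate = cluster_diameter(pts, bin_nm)
        clusters.append(
            GranuleCluster(
                cluster_id=int(cid),
                member_indices=members,
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                area_nm2=area,
                diameter_nm=diameter,
                contour_wkt=wkt,
                degenerate=degenerate,
            )
        )
    df = pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "n_locs": [c.n_locs for c in clusters],
            "centroid_x": [c.centroid[0] for c in clusters],
            "centroid_y": [c.centroid[1] for c in clusters],
            "area_nm2": [c.area_nm2 for c in clusters],
            "diameter_nm": [c.diameter_nm for c in clusters],
            "contour_wkt": [c.contour_wkt for c in clusters],
        }
    )
    return clusters, df
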