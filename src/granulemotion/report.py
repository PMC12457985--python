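"""Condition-level aggregation and statistical comparison of mobility summaries.

Aggregation mirrors the standard summary-table shape — per-condition mean
and SD of each motion-category length percentage with the number of
acquisitions N (means over acquisitions, never over spots). Pairwise
comparison gates each category on Shapiro-Wilk normality per group, uses a
Welch t-test when both groups pass (no equal-variance assumption) and a
Mann-Whitney test otherwise, then applies the Holm-Sidak step-down
correction across the three categories at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import MobilitySummary

logger = logging.getLogger(__name__)

__all__ = ["aggregate", "compare_conditions", "summaries_to_dataframe"]

CATEGORIES = ("blocked", "diffusive", "drifted")


def summaries_to_dataframe(
    summaries: list[MobilitySummary], condition: str | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "acquisition_id": [s.acquisition_id for s in summaries],
            "blocked": [s.pct_blocked for s in summaries],
            "diffusive": [s.pct_diffusive for s in summaries],
            "drifted": [s.pct_drifted for s in summaries],
            "n_tracks": [s.n_tracks for s in summaries],
            "n_spots": [s.n_spots for s in summaries],
        }
    )
    if condition is not None:
        df.insert(0, "condition", condition)
    return df


def aggregate(
    summaries: list[MobilitySummary], condition_labels: list[str]
) -> pd.DataFrame:
    """Per-condition mean +- SD of each category percentage, with N.

    One row per condition with columns ``<category>_mean``,
    ``<category>_sd`` and ``N``; single-acquisition conditions report
    SD = 0 and are flagged. Invariant to acquisition order.
    """
    if len(summaries) != len(condition_labels):
        raise ValueError("one condition label per summary required")
    df = pd.DataFrame(
        {
            "condition": condition_labels,
            "blocked": [s.pct_blocked for s in summaries],
            "diffusive": [s.pct_diffusive for s in summaries],
            "drifted": [s.pct_drifted for s in summaries],
        }
    )
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        row: dict = {"condition": cond, "N": len(grp)}
        for cat in CATEGORIES:
            row[f"{cat}_mean"] = grp[cat].mean()
            row[f"{cat}_sd"] = grp[cat].std(ddof=1) if len(grp) > 1 else 0.0
        row["single_acquisition"] = len(grp) == 1
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CategoryTest:
    category: str
    test: str
    p_raw: float
    p_adj: float
    reject: bool
    skipped: bool = False


def compare_conditions(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category two-group comparison with Holm-Sidak correction.

    ``group_a``/``group_b`` are per-acquisition tables with columns
    blocked/diffusive/drifted (as from :func:`summaries_to_dataframe`).
    Categories with fewer than 3 acquisitions in either group are skipped
    (flagged) and excluded from the correction.
    """
    results: list[CategoryTest] = []
    for cat in CATEGORIES:
        a = np.asarray(group_a[cat], dtype=float)
        b = np.asarray(group_b[cat], dtype=float)
        if len(a) < 3 or len(b) < 3:
            results.append(CategoryTest(cat, "none", np.nan, np.nan, False, skipped=True))
            continue
        normal_a = stats.shapiro(a).pvalue > normality_alpha
        normal_b = stats.shapiro(b).pvalue > normality_alpha
        if normal_a and normal_b:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            name = "welch_t"
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            name = "mann_whitney"
        results.append(CategoryTest(cat, name, float(p), np.nan, False))

    tested = [r for r in results if not r.skipped]
    if tested:
        with np.errstate(divide="ignore"):  # p_raw == 1 is legitimate
            reject, p_adj, _, _ = multipletests(
                [r.p_raw for r in tested], alpha=alpha, method="holm-sidak"
            )
        for r, pa, rej in zip(tested, p_adj, reject):
            r.p_adj = float(min(pa, 1.0))
            r.reject = bool(rej)
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "test": [r.test for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "reject": [r.reject for r in results],
            "skipped": [r.skipped for r in results],
        }
    )


def plot_joint_distribution(joint, path) -> None:
    """Render a (log10 D12, gamma) joint histogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    extent = (
        joint.log10_D12_edges[0],
        joint.log10_D12_edges[-1],
        joint.gamma_edges[0],
        joint.gamma_edges[-1],
    )
    ax.imshow(joint.hist.T, origin="lower", aspect="auto", extent=extent, cmap="viridis")
    ax.set_xlabel(r"$\log_{10} D_{12}$ ($\mu$m$^2$/s)")
    ax.set_ylabel(r"$\gamma$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
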