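"""Summary statistics and plot-ready exports over approach records.

Reporting conventions: distances are reported as unsigned values, summaries
as mean +/- standard deviation (SD with ddof=1, not SEM), and repeated
localizations as the mean square deviation (MSD) about their centroid —
``sqrt(mean ||p - centroid||^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import decompose_separation, rotation_aligning
from .phantom import ApproachRecord

__all__ = [
    "records_to_table",
    "PrecisionReport",
    "summarize",
    "mean_square_deviation",
    "outlier_filter",
    "point_cloud_export",
    "SOMA_REFERENCE_RADIUS",
]

#: radius of the reference soma sphere drawn in point clouds (a typical
#: mouse pyramidal neuron cell body)
SOMA_REFERENCE_RADIUS = 5.0

_METRICS = ("r_lateral", "r_axial", "r_total", "surface_distance")


def records_to_table(records: list[ApproachRecord]) -> pd.DataFrame:
    """Per-approach metrics table. Signed axial components are reported as
    absolute values; approaches without metrics get NaN rows."""
    rows = []
    for i, rec in enumerate(records):
        m = rec.metrics
        rows.append({
            "approach_id": i,
            "strategy": rec.strategy,
            "r_lateral": m.r_lateral if m else np.nan,
            "r_axial": abs(m.r_axial) if m else np.nan,
            "r_total": m.r_total if m else np.nan,
            "surface_distance": rec.surface_distance if m else np.nan,
            "adaptive_step_r_lateral": rec.adaptive_step_r_lateral,
            "success": rec.success,
            "snr": rec.snr,
            "seed": rec.seed,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PrecisionReport:
    """mean +/- SD (ddof=1) and N per metric, per strategy."""

    stats: dict  # {strategy: {metric: {"mean": .., "sd": .. or None, "n": ..}}}

    def format(self, strategy: str, metric: str = "r_lateral") -> str:
        s = self.stats[strategy][metric]
        sd = "n/a" if s["sd"] is None else f"{s['sd']:.2f}"
        return f"{metric} = {s['mean']:.2f} ± {sd} μm, N = {s['n']}"


def summarize(table: pd.DataFrame) -> PrecisionReport:
    """Per-strategy mean, SD (ddof=1, ``None`` for a single row) and N for
    each distance metric, over non-excluded rows with finite metrics."""
    if len(table) == 0:
        raise ValueError("empty approach table")
    if "excluded" in table.columns:
        table = table[~table["excluded"]]
    stats: dict = {}
    for strategy, grp in table.groupby("strategy"):
        stats[strategy] = {}
        for metric in _METRICS:
            vals = grp[metric].dropna().to_numpy()
            n = len(vals)
            stats[strategy][metric] = {
                "mean": float(np.mean(vals)) if n else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if n > 1 else None,
                "n": n,
            }
    return PrecisionReport(stats=stats)


def mean_square_deviation(points) -> float:
    """MSD of repeated localizations about their centroid:
    sqrt(mean squared distance to the mean point)."""
    pts = np.asarray([p.to_array() if hasattr(p, "to_array") else p for p in points],
                     dtype=float)
    centroid = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))


def outlier_filter(table: pd.DataFrame, threshold: float = 40.0) -> pd.DataFrame:
    """Flag rows with r_total beyond the threshold as excluded (kept in the
    table, dropped from statistics). Returns a copy with an ``excluded``
    column; the exclusion count is stored in ``df.attrs``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = table.copy()
    out["excluded"] = out["r_total"] > threshold
    out.attrs["n_excluded"] = int(out["excluded"].sum())
    return out


def point_cloud_export(records: list[ApproachRecord], axis,
                       reference=(1.0, 0.0, 0.0)) -> pd.DataFrame:
    """Final pipette positions in a target-centered frame rotated so the
    pipette axis is the fixed ``reference`` direction.

    The rotation preserves every point's lateral/axial decomposition; the
    returned frame includes the 5 um soma reference radius in ``attrs``.
    """
    rot = rotation_aligning(axis, reference)
    rows = []
    for i, rec in enumerate(records):
        if rec.final_tip is None or rec.final_target is None:
            continue
        rel = rot @ (rec.final_tip - rec.final_target)
        rows.append({"approach_id": i, "strategy": rec.strategy,
                     **dict(zip(("u", "v", "w"), rel))})
    df = pd.DataFrame(rows)
    df.attrs["soma_radius_um"] = SOMA_REFERENCE_RADIUS
    df.attrs["axis_reference"] = tuple(map(float, reference))
    return df
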