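"""Per-segment dynamics metrics for dendritic protrusions.

All percentages are normalised by N0, the number of protrusions present at
the start of the recording (time 0):

* formation % = F / N0 · 100, and likewise elimination, lability, motility;
* survival % = N_end / N0 · 100 (protrusions persisting at the end);
* turnover % = (F + E + L) / N0 · 100 (net gain and loss);
* Δmovement % = (F + E + L + M) / N0 · 100 = turnover + motility.

Density is protrusion count per 10 µm of dendrite segment. Percentages are
computed per segment/cell and then averaged across cells (mean of ratios);
rounding to one decimal happens only at reporting time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from protrudyn.errors import MetricsError, ParameterError
from protrudyn.protdetect import protrusion_density
from protrudyn.protrack import EventLog

__all__ = [
    "DynamicsMetrics",
    "compute_metrics",
    "summarize_groups",
    "delta_movement",
    "METRIC_NAMES",
]


@dataclass
class DynamicsMetrics:
    """The eight per-segment measures of protrusion dynamics."""

    density_per_10um: float
    formation_pct: float
    elimination_pct: float
    lability_pct: float
    motility_pct: float
    survival_pct: float
    turnover_pct: float
    delta_movement_pct: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        """Reporting precision: one decimal by default."""
        return {k: round(v, decimals) for k, v in self.as_dict().items()}


METRIC_NAMES = [f.name for f in fields(DynamicsMetrics)]


def delta_movement(turnover_pct: float, motility_pct: float) -> float:
    """Δmovement from its two components (exact additive identity)."""
    return turnover_pct + motility_pct


def compute_metrics(log: EventLog, segment_length_um: float) -> DynamicsMetrics:
    """All eight metrics from an event log and the segment length.

    Density uses N0 (the protrusion count at time 0). Segments with N0 = 0
    are undefined under the per-segment normalisation and raise
    :class:`MetricsError` so that callers can exclude and log them.
    """
    if log.n0 <= 0:
        raise MetricsError("metrics undefined for N0 = 0; segment excluded")
    if not segment_length_um > 0:
        raise ParameterError("segment length must be positive")
    scale = 100.0 / log.n0
    turnover = (log.formed + log.eliminated + log.labile) * scale
    motility = log.motile * scale
    return DynamicsMetrics(
        density_per_10um=protrusion_density(log.n0, segment_length_um),
        formation_pct=log.formed * scale,
        elimination_pct=log.eliminated * scale,
        lability_pct=log.labile * scale,
        motility_pct=motility,
        survival_pct=log.n_end * scale,
        turnover_pct=turnover,
        delta_movement_pct=delta_movement(turnover, motility),
    )


def summarize_groups(
    per_cell: pd.DataFrame,
    group_col: str = "group",
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean, sample SD (n−1 denominator) and n for each metric.

    ``per_cell`` holds one row per cell with a group label column plus metric
    columns. Groups of size 1 get SD 0 with a warning.
    """
    if metrics is None:
        metrics = [c for c in METRIC_NAMES if c in per_cell.columns]
    if group_col not in per_cell.columns:
        raise ParameterError(f"missing group column {group_col!r}")
    if not metrics:
        raise ParameterError("no metric columns found")
    rows = []
    for group, sub in per_cell.groupby(group_col, sort=True):
        if len(sub) == 1:
            warnings.warn(
                f"group {group!r} has a single cell; SD reported as 0",
                stacklevel=2,
            )
        for m in metrics:
            vals = sub[m].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    group_col: group,
                    "metric": m,
                    "mean": float(np.mean(vals)),
                    "sd": sd,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)
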