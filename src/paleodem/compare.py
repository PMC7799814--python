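"""Cross-proxy comparison: common slicing, min-max scaling and Pearson
correlation matrices.

The SPD (per-year) and the settlement proxies (per 100-year slice) are put
on the same slice grid by averaging the SPD within each slice.  Proxies are
min-max scaled to [0, 1] for plotting; Pearson's r is unaffected by that
affine rescaling, so correlation matrices are the same either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aoristic import TimeSliceSeries
from .errors import DegenerateSeriesError, ValidationError
from .spd import SPD


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r and two-sided p over a slice window."""

    labels: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    window: tuple[float, float]
    n: int
    meta: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Boolean mask of off-diagonal pairs with p below ``alpha``."""
        mask = self.p < alpha
        np.fill_diagonal(mask.values, False)
        return mask


def spd_to_slices(spd: SPD, slice_edges) -> TimeSliceSeries:
    """Average the per-year SPD within each slice.

    The half-open convention assigns year θ to the slice with
    older ≥ θ > younger; the SPD grid must cover every slice fully.
    """
    edges = np.asarray(slice_edges, dtype=float)
    grid = np.asarray(spd.grid, dtype=float)
    if edges[0] > grid[0] or edges[-1] < grid[-1] - 1:
        raise ValidationError("SPD grid does not cover the requested slices")
    vals = np.empty(edges.size - 1)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (grid <= a) & (grid > b)
        if not sel.any():
            raise ValidationError("empty slice: SPD grid too coarse for slice width")
        vals[i] = spd.value[sel].mean()
    return TimeSliceSeries(edges, vals, "spd")


def minmax_normalize(series):
    """Scale to [0, 1]: (x − min) / (max − min).

    Accepts a :class:`TimeSliceSeries` (returned as a new series) or a
    plain array.  A constant input has no scale and raises
    :class:`DegenerateSeriesError`.
    """
    if isinstance(series, TimeSliceSeries):
        vals = minmax_normalize(series.values)
        return TimeSliceSeries(
            series.slice_edges, vals, series.proxy_label, dict(series.meta, normalized="minmax")
        )
    x = np.asarray(series, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateSeriesError("constant series cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def _series_values(series) -> np.ndarray:
    return series.values if isinstance(series, TimeSliceSeries) else np.asarray(series, float)


def correlation_matrix(
    series_set: dict[str, TimeSliceSeries],
    window: tuple[float, float] | None = None,
) -> CorrelationMatrix:
    """Pairwise Pearson correlations between proxies on a shared slice grid.

    ``window = (older, younger)`` restricts the comparison to slices lying
    wholly inside it (e.g. 6,000-4,000 cal BP keeps 20 of 30 slices).
    Two-sided p-values come from the t transform of r with n − 2 degrees of
    freedom; no multiple-testing correction is applied.
    """
    if len(series_set) < 2:
        raise ValidationError("need at least two series")
    labels = list(series_set)
    first = series_set[labels[0]]
    if not isinstance(first, TimeSliceSeries):
        raise ValidationError("series must be TimeSliceSeries on a shared grid")
    edges = first.slice_edges
    for lab in labels[1:]:
        s = series_set[lab]
        if not np.array_equal(s.slice_edges, edges):
            raise ValidationError(f"series {lab!r} is on a different slice grid")
    if window is None:
        keep = np.ones(edges.size - 1, dtype=bool)
        window = (float(edges[0]), float(edges[-1]))
    else:
        a, b = window
        keep = (edges[:-1] <= a) & (edges[1:] >= b)
    n = int(keep.sum())
    if n < 3:
        raise ValidationError("need at least 3 slices in the window")
    data = np.vstack([series_set[lab].values[keep] for lab in labels])
    k = len(labels)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ri, pi = stats.pearsonr(data[i], data[j])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    return CorrelationMatrix(
        labels=labels,
        r=pd.DataFrame(r, index=labels, columns=labels),
        p=pd.DataFrame(p, index=labels, columns=labels),
        window=(float(window[0]), float(window[1])),
        n=n,
    )
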