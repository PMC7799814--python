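"""Time-slice settlement proxies from site occupation phases.

Survey and excavation data date occupation in phases of very different
chronological precision (from one century to a couple of millennia).  Three
proxies put them on a common 100-year slice grid:

* **raw counts** — a phase contributes 1 to every slice it overlaps;
* **aoristic weights** — a phase's unit probability is spread uniformly
  over its span, so each slice receives overlap / phase length and every
  phase contributes total weight 1;
* **randomized start** — Monte-Carlo occupations of fixed duration
  (default 100 yr) placed uniformly within the phase, counting the mean
  per-slice occupancy across runs.

A fourth series sums settlement area (ha) per slice, raw or
aoristically weighted, as an urban-population proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import interval_overlap
from .errors import SchemaError, ValidationError

PHASE_COLUMNS = ("site_id", "start", "end")


@dataclass
class SitePhase:
    """One occupation phase of one site, bounds in cal BP (start older)."""

    site_id: str
    start: float
    end: float
    survey_id: str | None = None
    area_ha: float | None = None
    urban: bool = False
    lon: float | None = None
    lat: float | None = None
    zone: str | None = None

    def __post_init__(self) -> None:
        if not self.start > self.end:
            raise ValidationError(
                f"{self.site_id}: phase start {self.start} must be older than end {self.end}"
            )
        if self.urban and (self.area_ha is None or self.area_ha < 10):
            raise ValidationError(f"{self.site_id}: urban sites must have area_ha ≥ 10")


@dataclass
class TimeSliceSeries:
    """Values on a descending slice-edge grid (edges has len(values)+1)."""

    slice_edges: np.ndarray
    values: np.ndarray
    proxy_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slice_edges = np.asarray(self.slice_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.slice_edges.size != self.values.size + 1:
            raise ValidationError("slice_edges must have len(values) + 1 entries")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.slice_edges[:-1] + self.slice_edges[1:])

    @property
    def n_slices(self) -> int:
        return int(self.values.size)


def _phase_arrays(phases) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(phases, pd.DataFrame):
        missing = [c for c in ("start", "end") if c not in phases.columns]
        if missing:
            raise SchemaError(f"phase table missing columns {missing}")
        starts = phases["start"].to_numpy(dtype=float)
        ends = phases["end"].to_numpy(dtype=float)
    else:
        starts = np.asarray([p.start for p in phases], dtype=float)
        ends = np.asarray([p.end for p in phases], dtype=float)
    if np.any(starts <= ends):
        raise ValidationError("every phase must satisfy start > end (older > younger)")
    return starts, ends


def _is_empty(phases) -> bool:
    return phases.empty if isinstance(phases, pd.DataFrame) else len(phases) == 0


def _overlap_matrix(starts, ends, edges) -> np.ndarray:
    """(n_phases, n_slices) overlap lengths with half-open slices."""
    a = edges[:-1][None, :]  # older slice edges
    b = edges[1:][None, :]
    return interval_overlap(starts[:, None], ends[:, None], a, b)


def aoristic_weights(phase, slice_edges) -> np.ndarray:
    """Per-slice aoristic weights of a single phase.

    The weight of a slice is its overlap with the phase divided by the
    phase length, so the weights over the phase's whole span sum to 1.  A
    phase spanning 4,000-3,600 cal BP on 100-year slices gets weight 0.25
    in each of the four slices it covers.
    """
    if isinstance(phase, SitePhase):
        start, end = phase.start, phase.end
    else:
        start, end = (float(v) for v in phase)
    if not start > end:
        raise ValidationError("phase must have start > end (zero-length phases are invalid)")
    edges = np.asarray(slice_edges, dtype=float)
    ov = interval_overlap(start, end, edges[:-1], edges[1:])
    return ov / (start - end)


def raw_counts(phases, slice_edges) -> TimeSliceSeries:
    """Number of phases overlapping each slice (phase-level counting)."""
    edges = np.asarray(slice_edges, dtype=float)
    if _is_empty(phases):
        return TimeSliceSeries(edges, np.zeros(edges.size - 1), "count")
    starts, ends = _phase_arrays(phases)
    ov = _overlap_matrix(starts, ends, edges)
    return TimeSliceSeries(edges, (ov > 0).sum(axis=0).astype(float), "count")


def aoristic_series(phases, slice_edges) -> TimeSliceSeries:
    """Summed aoristic weights per slice over all phases."""
    edges = np.asarray(slice_edges, dtype=float)
    if _is_empty(phases):
        return TimeSliceSeries(edges, np.zeros(edges.size - 1), "aoristic")
    starts, ends = _phase_arrays(phases)
    ov = _overlap_matrix(starts, ends, edges)
    w = ov / (starts - ends)[:, None]
    return TimeSliceSeries(edges, w.sum(axis=0), "aoristic")


def randomized_start(
    phases,
    slice_edges,
    duration: float = 100.0,
    nsim: int = 1000,
    rng: np.random.Generator | None = None,
    return_runs: bool = False,
):
    """Monte-Carlo randomized-start occupancy per slice.

    Each run assigns every phase an occupation of length ``duration`` whose
    start is uniform within the phase (phases shorter than ``duration`` are
    occupied throughout); the slice value is the number of occupations
    overlapping the slice, and the series is the per-slice mean over runs.
    With ``return_runs`` the full (nsim, n_slices) matrix is also returned.
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    edges = np.asarray(slice_edges, dtype=float)
    n_slices = edges.size - 1
    starts, ends = _phase_arrays(phases)
    n = starts.size
    lengths = starts - ends
    long = lengths >= duration
    runs = np.empty((nsim, n_slices))
    a = edges[:-1][None, :]
    b = edges[1:][None, :]
    # short phases occupy their whole span in every run
    short_counts = (
        (_overlap_matrix(starts[~long], ends[~long], edges) > 0).sum(axis=0)
        if np.any(~long)
        else np.zeros(n_slices)
    )
    s_lo = ends[long] + duration
    s_hi = starts[long]
    for i in range(nsim):
        s = rng.uniform(s_lo, s_hi) if s_lo.size else np.empty(0)
        ov = interval_overlap(s[:, None], (s - duration)[:, None], a, b)
        runs[i] = (ov > 0).sum(axis=0) + short_counts
    series = TimeSliceSeries(
        edges,
        runs.mean(axis=0),
        "random_start",
        meta={"nsim": nsim, "duration": duration},
    )
    if return_runs:
        return series, runs
    return series


def summed_area(phases, slice_edges, weighting: str = "raw") -> TimeSliceSeries:
    """Summed settlement area (ha) per slice, raw or aoristically weighted.

    Phases without an area are excluded; their count is recorded in
    ``meta['n_missing_area']``.
    """
    if weighting not in ("raw", "aoristic"):
        raise ValidationError("weighting must be 'raw' or 'aoristic'")
    edges = np.asarray(slice_edges, dtype=float)
    if isinstance(phases, pd.DataFrame):
        if "area_ha" not in phases.columns:
            raise SchemaError("phase table has no 'area_ha' column")
        areas = phases["area_ha"].to_numpy(dtype=float)
    else:
        areas = np.asarray(
            [np.nan if p.area_ha is None else p.area_ha for p in phases], dtype=float
        )
    have = np.isfinite(areas)
    n_missing = int(np.sum(~have))
    if isinstance(phases, pd.DataFrame):
        phases = phases.loc[have]
    else:
        phases = [p for p, ok in zip(phases, have) if ok]
    areas = areas[have]
    if areas.size == 0:
        return TimeSliceSeries(
            edges, np.zeros(edges.size - 1), "area", meta={"n_missing_area": n_missing}
        )
    starts, ends = _phase_arrays(phases)
    ov = _overlap_matrix(starts, ends, edges)
    if weighting == "raw":
        vals = ((ov > 0) * areas[:, None]).sum(axis=0)
    else:
        vals = (ov / (starts - ends)[:, None] * areas[:, None]).sum(axis=0)
    return TimeSliceSeries(
        edges, vals.astype(float), "area", meta={"n_missing_area": n_missing, "weighting": weighting}
    )
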