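"""Summed probability distributions (SPDs) of calibrated radiocarbon dates.

Dates are filtered (lab error, anthropogenic origin, marine reservoir,
collection window), grouped within sites into 50-¹⁴C-year bins so
oversampled contexts do not dominate, and the bin-mean densities are summed
per calendar year.  Each bin contributes the arithmetic mean of its members'
calibrated densities, so a bin of normalized dates carries total mass ≈ 1
regardless of how many measurements it holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .calibration import CalibratedDensity, CalibrationCurve, calibrate
from .config import AnalysisConfig
from .errors import EmptySubsetError, SchemaError

REQUIRED_DATE_COLUMNS = ("lab_id", "site_id", "cra", "error")


@dataclass
class DateBin:
    """Site-level aggregate of dates within ``bin_width`` ¹⁴C years."""

    site_id: str
    member_ids: list[str]
    density: CalibratedDensity
    mark: str | None = None

    @property
    def n_dates(self) -> int:
        return len(self.member_ids)


@dataclass
class SPD:
    """Per-calendar-year summed density over the analysis window.

    ``ext_grid``/``ext_value``, when present, carry the same sum on a grid
    padded beyond the analysis window; the tails are kept internally for
    null-model fitting and simulation (so edge mass is comparable between
    observed and simulated SPDs) but results are reported in-window only.
    """

    grid: np.ndarray
    value: np.ndarray
    meta: dict = field(default_factory=dict)
    ext_grid: np.ndarray | None = None
    ext_value: np.ndarray | None = None

    @property
    def mass(self) -> float:
        return float(self.value.sum())


def _require_columns(dates: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_DATE_COLUMNS if c not in dates.columns]
    if missing:
        raise SchemaError(f"date table missing columns {missing}")


def filter_dates(
    dates: pd.DataFrame,
    config: AnalysisConfig | None = None,
    return_log: bool = False,
):
    """Apply the standard exclusion rules to a date table.

    Retains rows with lab error ≤ ``max_error``, an anthropogenic origin
    (``anthropogenic`` column, default True), no marine reservoir problem
    (``marine`` column, default False) and a CRA inside the uncalibrated
    collection window.  With ``return_log`` also returns a table naming the
    exclusion reason for every dropped row.
    """
    config = config or AnalysisConfig()
    _require_columns(dates)
    older, younger = config.collection_window_uncal
    err = dates["error"].to_numpy(dtype=float)
    cra = dates["cra"].to_numpy(dtype=float)
    anthro = (
        dates["anthropogenic"].to_numpy(dtype=bool)
        if "anthropogenic" in dates.columns
        else np.ones(len(dates), dtype=bool)
    )
    marine = (
        dates["marine"].to_numpy(dtype=bool)
        if "marine" in dates.columns
        else np.zeros(len(dates), dtype=bool)
    )
    reasons = np.full(len(dates), "", dtype=object)
    reasons[~((cra <= older) & (cra >= younger))] = "cra outside collection window"
    reasons[marine] = "marine reservoir"
    reasons[~anthro] = "non-anthropogenic"
    reasons[err > config.max_error] = f"error > {config.max_error:g}"
    keep = reasons == ""
    kept = dates.loc[keep].reset_index(drop=True)
    if return_log:
        log = dates.loc[~keep, ["lab_id"]].copy()
        log["reason"] = reasons[~keep]
        return kept, log.reset_index(drop=True)
    return kept


def bin_dates(
    dates: pd.DataFrame,
    curve: CalibrationCurve,
    config: AnalysisConfig | None = None,
    normalize: bool = False,
    mark_column: str | None = None,
) -> list[DateBin]:
    """Group dates into site-level bins by complete-linkage clustering.

    Within each site, CRAs are clustered agglomeratively (complete linkage)
    and the dendrogram is cut at ``bin_width``; dates at different sites are
    never co-binned.  Each bin's density is the arithmetic mean of its
    members' calibrated densities.  ``mark_column`` (e.g. ``"zone"``)
    attaches the members' majority label to the bin for permutation tests.
    """
    config = config or AnalysisConfig()
    _require_columns(dates)
    bins: list[DateBin] = []
    for site_id, grp in dates.groupby("site_id", sort=True):
        cras = grp["cra"].to_numpy(dtype=float)
        if len(grp) == 1:
            labels = np.array([1])
        else:
            z = linkage(cras[:, None], method="complete")
            labels = fcluster(z, t=config.bin_width, criterion="distance")
        for lab in np.unique(labels):
            sub = grp.iloc[np.flatnonzero(labels == lab)]
            dens = [
                calibrate((r.cra, r.error), curve, normalize=normalize)
                for r in sub.itertuples()
            ]
            mean = _mean_density(dens, normalize)
            mark = None
            if mark_column is not None:
                mark = sub[mark_column].mode().iloc[0]
            bins.append(
                DateBin(
                    site_id=str(site_id),
                    member_ids=[str(x) for x in sub["lab_id"]],
                    density=mean,
                    mark=mark,
                )
            )
    return bins


def _mean_density(densities: list[CalibratedDensity], normalized: bool) -> CalibratedDensity:
    """Arithmetic mean of densities defined on (possibly different) supports."""
    old = max(float(d.grid[0]) for d in densities)
    young = min(float(d.grid[-1]) for d in densities)
    grid = np.arange(old, young - 1, -1)
    acc = np.zeros(grid.size)
    for d in densities:
        # position of year y within the union grid is old - y
        pos = (old - d.grid).astype(int)
        acc[pos] += d.density
    acc /= len(densities)
    return CalibratedDensity(grid=grid, density=acc, normalized=normalized)


def sum_spd(
    bins: list[DateBin],
    config: AnalysisConfig | None = None,
    normalized: bool | None = None,
) -> SPD:
    """Sum bin densities per calendar year on the analysis-window grid."""
    config = config or AnalysisConfig()
    if not bins:
        raise EmptySubsetError("no bins to sum")
    grid = config.grid
    pad = int(config.simulation_pad)
    ext = np.arange(float(grid[0]) + pad, float(grid[-1]) - pad - 1, -1.0)
    older = float(ext[0])
    acc = np.zeros(ext.size)
    for b in bins:
        pos = (older - b.density.grid).astype(int)
        ok = (pos >= 0) & (pos < ext.size)
        np.add.at(acc, pos[ok], b.density.density[ok])
    if normalized is None:
        normalized = bool(bins[0].density.normalized)
    n_dates = int(sum(b.n_dates for b in bins))
    return SPD(
        grid=grid,
        value=acc[pad : pad + grid.size],
        meta={
            "n_dates": n_dates,
            "n_bins": len(bins),
            "normalized": normalized,
            "window": config.analysis_window_cal,
        },
        ext_grid=ext,
        ext_value=acc,
    )


def make_spd(
    dates: pd.DataFrame,
    curve: CalibrationCurve,
    config: AnalysisConfig | None = None,
    normalize: bool = False,
    prefilter: bool = True,
) -> SPD:
    """Filter → bin → sum in one call."""
    config = config or AnalysisConfig()
    if prefilter:
        dates = filter_dates(dates, config)
    if dates.empty:
        raise EmptySubsetError("no dates survive filtering")
    bins = bin_dates(dates, curve, config, normalize=normalize)
    return sum_spd(bins, config, normalized=normalize)


def subset_spd(
    dates: pd.DataFrame,
    curve: CalibrationCurve,
    config: AnalysisConfig | None = None,
    normalize: bool = False,
    material_class: str | None = None,
    zone: str | None = None,
    region: str | None = None,
) -> SPD:
    """SPD of the dates matching the given predicates.

    The subset is filtered, re-binned within itself and summed with the same
    configuration as the full SPD (so zone SPDs of one-date sites add up to
    the full SPD).  An empty subset raises :class:`EmptySubsetError`.
    """
    sel = pd.Series(True, index=dates.index)
    for column, wanted in (
        ("material_class", material_class),
        ("zone", zone),
        ("region", region),
    ):
        if wanted is None:
            continue
        if column not in dates.columns:
            raise SchemaError(f"date table has no {column!r} column")
        sel &= dates[column] == wanted
    sub = dates.loc[sel]
    if sub.empty:
        raise EmptySubsetError(
            f"no dates match material_class={material_class} zone={zone} region={region}"
        )
    return make_spd(sub, curve, config, normalize=normalize)


def region_summary(dates: pd.DataFrame, bins: list[DateBin] | None = None) -> pd.DataFrame:
    """Counts and percentage shares of dates (and optionally bins) by region."""
    if "region" not in dates.columns:
        raise SchemaError("date table has no 'region' column")
    out = dates.groupby("region").size().rename("n_dates").to_frame()
    out["pct_dates"] = 100.0 * out["n_dates"] / len(dates)
    if bins is not None:
        site_region = dates.drop_duplicates("site_id").set_index("site_id")["region"]
        bin_regions = pd.Series([site_region.get(b.site_id) for b in bins], name="region")
        bc = bin_regions.value_counts().rename("n_bins")
        out = out.join(bc, how="left").fillna({"n_bins": 0})
        out["n_bins"] = out["n_bins"].astype(int)
        out["pct_bins"] = 100.0 * out["n_bins"] / len(bins)
    return out.sort_values("n_dates", ascending=False)
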