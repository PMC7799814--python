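"""Radiocarbon calibration against a tabulated calibration curve.

A calibration curve maps calendar years BP to the conventional ¹⁴C age a
sample of that calendar age would measure, with a 1σ curve uncertainty.
Calibrating a lab measurement ``cra ± error`` evaluates, for every calendar
year θ on a 1-year grid, the Normal density of ``cra`` under mean m(θ) and
standard deviation sqrt(error² + s(θ)²), where m and s are the linearly
interpolated curve mean and error.  The resulting per-year values form the
date's calendar-age density, used either raw ("unnormalized") or rescaled to
unit mass ("normalized").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import CalibrationRangeError, CurveFormatError, ValidationError

_SQRT2PI = np.sqrt(2.0 * np.pi)

# |z| beyond which a Normal density is treated as zero when locating a
# date's calendar support; the 1e-5 tail trim happens inside this range.
_Z_CUT = 6.0


class CalibrationCurve:
    """Tabulated calendar-year → ¹⁴C-age mapping with curve uncertainty.

    Knots are canonicalized to ascending cal BP; a 1-year linear
    interpolation grid over the curve span is cached on first use.
    """

    def __init__(self, cal_bp, c14_bp, sigma_curve, name: str = "") -> None:
        cal = np.asarray(cal_bp, dtype=float)
        c14 = np.asarray(c14_bp, dtype=float)
        sig = np.asarray(sigma_curve, dtype=float)
        if not (cal.size == c14.size == sig.size):
            raise CurveFormatError("cal_bp, c14_bp and sigma_curve must have equal length")
        if cal.size < 2:
            raise CurveFormatError("calibration curve needs at least 2 knots")
        d = np.diff(cal)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            cal, c14, sig = cal[::-1], c14[::-1], sig[::-1]
        else:
            raise CurveFormatError("cal_bp must be strictly monotone")
        if np.any(sig < 0):
            raise CurveFormatError("sigma_curve must be non-negative")
        self.cal_bp = cal
        self.c14_bp = c14
        self.sigma_curve = sig
        self.name = name
        self._fine: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # -- interpolation ----------------------------------------------------
    @property
    def cal_min(self) -> float:
        return float(self.cal_bp[0])

    @property
    def cal_max(self) -> float:
        return float(self.cal_bp[-1])

    def c14_at(self, theta):
        """Interpolated curve mean m(θ) in ¹⁴C years BP."""
        self._check_span(theta)
        return np.interp(theta, self.cal_bp, self.c14_bp)

    def sigma_at(self, theta):
        """Interpolated 1σ curve uncertainty s(θ)."""
        self._check_span(theta)
        return np.interp(theta, self.cal_bp, self.sigma_curve)

    def _check_span(self, theta) -> None:
        t = np.asarray(theta, dtype=float)
        if np.any(t < self.cal_min) or np.any(t > self.cal_max):
            raise CalibrationRangeError(
                f"calendar year outside curve span [{self.cal_min}, {self.cal_max}] cal BP"
            )

    def fine_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(cal, m, s) on the cached 1-year ascending grid."""
        if self._fine is None:
            cal = np.arange(np.ceil(self.cal_min), np.floor(self.cal_max) + 1.0)
            m = np.interp(cal, self.cal_bp, self.c14_bp)
            s = np.interp(cal, self.cal_bp, self.sigma_curve)
            self._fine = (cal, m, s)
        return self._fine

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CalibrationCurve({self.name or 'unnamed'}, "
            f"{self.cal_bp.size} knots, span {self.cal_min:.0f}-{self.cal_max:.0f} cal BP)"
        )


@dataclass
class RadiocarbonDate:
    """One dated sample: lab measurement plus archaeological context."""

    lab_id: str
    site_id: str
    cra: float
    error: float
    material_class: str = "other"
    lon: float | None = None
    lat: float | None = None
    zone: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.error <= 0:
            raise ValidationError(f"{self.lab_id}: lab error must be positive")


@dataclass
class CalibratedDensity:
    """Per-calendar-year density on a contiguous 1-year grid, oldest first."""

    grid: np.ndarray
    density: np.ndarray
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.density = np.asarray(self.density, dtype=float)

    @property
    def mass(self) -> float:
        return float(self.density.sum())

    @property
    def mode(self) -> float:
        """Calendar year of maximum density."""
        return float(self.grid[int(np.argmax(self.density))])


class UncalSample(NamedTuple):
    """A back-sampled ¹⁴C measurement for Monte-Carlo simulation."""

    cra: float
    error: float


# ---------------------------------------------------------------------------
# curve file parsing


def read_curve(path, dialect: str | None = None) -> CalibrationCurve:
    """Read a calibration curve from an IntCal ``.14c`` file or a CSV.

    The ``.14c`` dialect is comma-separated with ``#`` comment/header lines
    and columns CAL BP, ¹⁴C age BP, 1σ error (extra columns ignored).  The
    ``csv`` dialect expects a header naming columns ``cal_bp``, ``c14_bp``
    and ``error`` (case-insensitive; ``sigma`` accepted for ``error``).
    """
    path = Path(path)
    if dialect is None:
        dialect = "intcal14c" if path.suffix.lower() == ".14c" else "csv"
    if dialect == "intcal14c":
        return _read_intcal(path)
    if dialect == "csv":
        return _read_curve_csv(path)
    raise ValueError(f"unknown curve dialect {dialect!r}")


def _read_intcal(path: Path) -> CalibrationCurve:
    cal, c14, sig = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 3:
                raise CurveFormatError(f"{path}:{lineno}: expected ≥3 comma-separated columns")
            try:
                cal.append(float(parts[0]))
                c14.append(float(parts[1]))
                sig.append(float(parts[2]))
            except ValueError as exc:
                raise CurveFormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    if len(cal) < 2:
        raise CurveFormatError(f"{path}: fewer than 2 data rows")
    return CalibrationCurve(cal, c14, sig, name=path.stem)


def _read_curve_csv(path: Path) -> CalibrationCurve:
    import pandas as pd

    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    rename = {"sigma": "error", "sigma_curve": "error", "14c_bp": "c14_bp", "calbp": "cal_bp"}
    df = df.rename(columns=rename)
    missing = {"cal_bp", "c14_bp", "error"} - set(df.columns)
    if missing:
        raise CurveFormatError(f"{path}: missing columns {sorted(missing)}")
    return CalibrationCurve(df["cal_bp"], df["c14_bp"], df["error"], name=path.stem)


# ---------------------------------------------------------------------------
# calibration


def _as_cra_error(date) -> tuple[float, float]:
    if isinstance(date, RadiocarbonDate):
        return float(date.cra), float(date.error)
    cra, error = date
    return float(cra), float(error)


def calibrate(
    date,
    curve: CalibrationCurve,
    normalize: bool = False,
    tail_mass: float = 1e-5,
) -> CalibratedDensity:
    """Calibrate one date to a per-calendar-year density.

    ``date`` is a :class:`RadiocarbonDate` or a ``(cra, error)`` pair.
    Support is trimmed where the cumulative mass outside is below
    ``tail_mass`` per side; with ``normalize`` the retained densities are
    rescaled to sum to 1.
    """
    cra, error = _as_cra_error(date)
    if error <= 0:
        raise ValidationError("lab error must be positive")
    cal, m, s = curve.fine_grid()
    sd = np.hypot(error, s)
    z = (cra - m) / sd
    inside = np.abs(z) <= _Z_CUT
    if not inside.any():
        raise CalibrationRangeError(
            f"cra {cra} outside curve ¹⁴C coverage (min |z| = {np.abs(z).min():.1f})"
        )
    idx = np.flatnonzero(inside)
    i0, i1 = idx[0], idx[-1] + 1
    dens = np.exp(-0.5 * z[i0:i1] ** 2) / (sd[i0:i1] * _SQRT2PI)
    # trim tails at cumulative relative mass `tail_mass` per side
    c = np.cumsum(dens)
    total = c[-1]
    lo = int(np.searchsorted(c, tail_mass * total))
    hi = int(np.searchsorted(c, (1.0 - tail_mass) * total)) + 1
    dens = dens[lo:hi]
    grid = cal[i0 + lo : i0 + hi]
    if normalize:
        dens = dens / dens.sum()
    return CalibratedDensity(
        grid=grid[::-1].copy(),
        density=dens[::-1].copy(),
        normalized=normalize,
        meta={"cra": cra, "error": error, "curve": curve.name},
    )


def density_matrix(
    cras,
    errors,
    curve: CalibrationCurve,
    grid: np.ndarray,
    normalize: bool = False,
) -> np.ndarray:
    """Per-year densities for many dates on a shared descending grid.

    Returns an ``(n_dates, len(grid))`` matrix.  For normalized densities
    each row is rescaled by its total mass over the full curve span (the
    mass is evaluated on a padded grid so truncation at the window edges
    does not bias the normalization).
    """
    cras = np.atleast_1d(np.asarray(cras, dtype=float))
    errors = np.atleast_1d(np.asarray(errors, dtype=float))
    if np.any(errors <= 0):
        raise ValidationError("lab errors must be positive")
    grid = np.asarray(grid)
    cal, m, s = curve.fine_grid()
    g_old, g_young = float(grid[0]), float(grid[-1])
    if normalize:
        pad = float(_Z_CUT * (errors.max() + s.max()))
    else:
        pad = 0.0
    a0 = max(cal[0], np.floor(g_young - pad))
    a1 = min(cal[-1], np.ceil(g_old + pad))
    j0 = int(a0 - cal[0])
    j1 = int(a1 - cal[0]) + 1
    sd = np.hypot(errors[:, None], s[None, j0:j1])
    z = (cras[:, None] - m[None, j0:j1]) / sd
    mat = np.exp(-0.5 * z**2) / (sd * _SQRT2PI)
    if normalize:
        totals = mat.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise CalibrationRangeError("a date has zero mass on the curve span")
        mat = mat / totals
    # extract window columns in descending-grid order
    cols = (grid.astype(float) - a0).astype(int)
    if cols.min() < 0 or cols.max() >= mat.shape[1]:
        raise CalibrationRangeError("analysis grid extends beyond curve coverage")
    return mat[:, cols]


def uncalibrate_sample(
    theta: float,
    curve: CalibrationCurve,
    lab_error: float,
    rng: np.random.Generator,
) -> UncalSample:
    """Back-sample a ¹⁴C age for calendar year ``theta``.

    Draws cra = m(θ) + ε with ε ~ Normal(0, s(θ)) and attaches the given
    lab error; used to turn simulated calendar years into simulated lab
    measurements for Monte-Carlo null models.
    """
    m = float(curve.c14_at(theta))
    s = float(curve.sigma_at(theta))
    cra = m + (rng.normal(0.0, s) if s > 0 else 0.0)
    return UncalSample(cra=cra, error=float(lab_error))
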