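"""Regression-based phenotype estimators for batch assays.

Every exchange-phenotype parameter of the community model is measured by an
ordinary regression on a small assay table:

* ``max_growth_rate`` — steepest ln(fluorescence) slope over short sliding
  windows of a microscopy growth curve;
* ``fit_moser`` — nonlinear fit of growth rate vs metabolite concentration
  to the Moser law g = gmax * L^n / (K^n + L^n);
* ``release_rate_batch`` — slope of supernatant metabolite concentration
  against the time-integrated live-cell density in a starvation culture;
* ``utilization_per_birth`` — reciprocal through-origin slope of final cell
  yield against input metabolite concentration within the linear range;
* ``propagate_ratio_error`` — uncorrelated-error propagation for ratios such
  as the exchange ratio r/u;
* ``density_from_beads`` — absolute cell density from flow-cytometry
  cell:bead event ratios against a bead density standard;
* ``calibrate_bioassay`` — monotone standard curve turning tester-strain
  yield (turbidity) into metabolite concentration;
* ``steady_state_rate`` — post-lag ln(density) slope of a community growth
  curve.

Assay tables are plain DataFrames wrapped with per-column unit tags; all
concentration-like columns are converted to fmole/ml internally
(1 µM = 1e6 fmole/ml).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Model as LmModel
from scipy import stats

from .model_core import MoserParams

__all__ = [
    "AssayTable",
    "RateEstimate",
    "RatioWithError",
    "MoserFit",
    "BioassayCalibration",
    "max_growth_rate",
    "fit_moser",
    "release_rate_batch",
    "utilization_per_birth",
    "propagate_ratio_error",
    "density_from_beads",
    "calibrate_bioassay",
    "infer_concentration",
    "steady_state_rate",
    "UM_TO_FMOLE_PER_ML",
]

UM_TO_FMOLE_PER_ML = 1e6
_UNIT_FACTORS = {"fmole/ml": 1.0, "uM": UM_TO_FMOLE_PER_ML, "µM": UM_TO_FMOLE_PER_ML}

#: columns that must be non-negative in a valid assay table
_NONNEG = (
    "density",
    "live_density",
    "final_density",
    "concentration",
    "input_concentration",
    "turbidity",
)


@dataclass
class AssayTable:
    """Labeled assay columns with unit tags.

    ``data`` holds named columns of equal length (time in hr, densities in
    cells/ml, fluorescence/turbidity in arbitrary units).  ``units`` maps
    concentration-like column names to their unit ("uM" or "fmole/ml",
    default fmole/ml).  An optional ``replicate`` column groups rows.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.data.columns:
            if col in _NONNEG and (self.data[col] < 0).any():
                raise ValueError(f"column {col!r} contains negative values")
        if "time" in self.data.columns:
            groups = (
                self.data.groupby("replicate")["time"]
                if "replicate" in self.data.columns
                else [(None, self.data["time"])]
            )
            for _, t in groups:
                if (np.diff(t.to_numpy(float)) < 0).any():
                    raise ValueError("times must be non-decreasing within a replicate")
        for col, unit in self.units.items():
            if unit not in _UNIT_FACTORS:
                raise ValueError(f"unknown unit {unit!r} for column {col!r}")

    def column(self, name: str, canonical: bool = True) -> np.ndarray:
        """Column as float array, converted to canonical units (fmole/ml)."""
        x = self.data[name].to_numpy(dtype=float)
        if canonical:
            x = x * _UNIT_FACTORS.get(self.units.get(name, "fmole/ml"), 1.0)
        return x

    @classmethod
    def read(cls, path, units: Optional[Mapping[str, str]] = None) -> "AssayTable":
        """Read a TSV/CSV assay table (separator inferred from suffix)."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep), dict(units or {}))

    def write(self, path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.data.to_csv(path, sep=sep, index=False)


def _as_table(table) -> AssayTable:
    if isinstance(table, AssayTable):
        return table
    return AssayTable(pd.DataFrame(table))


@dataclass(frozen=True)
class RateEstimate:
    """A fitted rate with its standard error.

    ``window`` is the (start, stop) index range of the points used;
    ``flag`` is None for a clean estimate, otherwise a short reason the
    estimate should not be trusted (e.g. the maximal slope fell in the final
    window, so the assay may have ended too early).
    """

    value: float
    se: float
    window: tuple[int, int]
    n_points: int
    flag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if self.window[1] - self.window[0] < 3:
            raise ValueError("estimation window must span at least 3 points")

    @property
    def ci2(self) -> tuple[float, float]:
        """value ± 2*se, the plotting convention for these rates."""
        return (self.value - 2 * self.se, self.value + 2 * self.se)


@dataclass(frozen=True)
class RatioWithError:
    value: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class MoserFit:
    """Result of a Moser-law fit; ``converged`` is never silently coerced."""

    params: Optional[MoserParams]
    stderr: dict[str, Optional[float]]
    rmse: float
    converged: bool
    message: str = ""


# ---------------------------------------------------------------------------
# growth-rate estimators
# ---------------------------------------------------------------------------

def _window_slopes(t: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Least-squares slope of y vs t for every consecutive window of w points."""
    n = len(t)
    return np.array(
        [np.polyfit(t[i : i + w], y[i : i + w], 1)[0] for i in range(n - w + 1)]
    )


def max_growth_rate(
    curve,
    window_points: int = 3,
    exclude_before: float = 0.0,
) -> RateEstimate:
    """Maximal growth rate: the steepest positive slope of ln(fluorescence)
    against time over consecutive windows of 3–4 points.

    ``exclude_before`` drops time points earlier than the given hour before
    the search; cells emerging from starvation show a few hours of residual
    growth fueled by internal metabolite stores, which is not limited by the
    external concentration and must not be mistaken for the maximal rate.

    The estimate is flagged ``"max_at_end"`` when the steepest window is the
    final one (the assay was too short to see the rate peak) and
    ``"no_positive_slope"`` when the curve never increases.
    """
    if window_points not in (3, 4):
        raise ValueError("window_points must be 3 or 4")
    table = _as_table(curve)
    t = table.column("time", canonical=False)
    f = table.column("fluorescence", canonical=False)
    keep = t >= exclude_before
    t, f = t[keep], f[keep]
    offset = int(np.argmax(keep)) if keep.any() else 0
    if len(t) < window_points:
        raise ValueError("fewer time points than the window size")
    if (f <= 0).any():
        raise ValueError("fluorescence must be positive to take logs")
    lf = np.log(f)
    slopes = _window_slopes(t, lf, window_points)
    i = int(np.argmax(slopes))
    window = (offset + i, offset + i + window_points)
    res = stats.linregress(t[i : i + window_points], lf[i : i + window_points])
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    flag = None
    if slopes[i] <= 0:
        flag = "no_positive_slope"
    elif i == len(slopes) - 1:
        flag = "max_at_end"
    return RateEstimate(
        value=float(slopes[i]), se=se, window=window, n_points=window_points, flag=flag
    )


def _moser(L, gmax, K, n):
    return gmax * L**n / (K**n + L**n)


def fit_moser(table, weights: Optional[np.ndarray] = None) -> MoserFit:
    """Fit growth rate vs concentration to the Moser law.

    Initialization: gmax at the largest observed rate, K at the
    concentration whose rate is nearest gmax/2, n = 1; n is bounded to
    (0, 10].  Requires >= 4 distinct concentrations, one of them near
    saturation for gmax to be identifiable.
    """
    at = _as_table(table)
    L = at.column("concentration")
    g = at.column("rate", canonical=False)
    if len(np.unique(L)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    gmax0 = float(np.max(g))
    if gmax0 <= 0:
        raise ValueError("rates must include positive values")
    K0 = float(L[np.argmin(np.abs(g - gmax0 / 2.0))])
    K0 = max(K0, 1e-12)
    model = LmModel(_moser)
    p = model.make_params(gmax=gmax0, K=K0, n=1.0)
    p["gmax"].set(min=1e-12)
    p["K"].set(min=1e-12)
    p["n"].set(min=1e-6, max=10.0)
    try:
        result = model.fit(g, p, L=L, weights=weights)
    except Exception as exc:  # lmfit raises on pathological inputs
        return MoserFit(None, {}, np.nan, False, f"fit failed: {exc}")
    stderr = {k: (result.params[k].stderr) for k in ("gmax", "K", "n")}
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    ok = bool(result.success)
    params = None
    if ok:
        try:
            params = MoserParams(
                gmax=float(result.params["gmax"].value),
                K=float(result.params["K"].value),
                n=float(result.params["n"].value),
            )
        except ValueError as exc:
            ok = False
            return MoserFit(None, stderr, rmse, False, f"invalid parameters: {exc}")
    return MoserFit(params, stderr, rmse, ok, result.message if not ok else "")


# ---------------------------------------------------------------------------
# release and utilization
# ---------------------------------------------------------------------------

def release_rate_batch(assay) -> RateEstimate:
    """Per-cell metabolite release rate (fmole/cell/hr) from a starvation
    batch culture.

    The released amount per ml is the release rate times the time integral
    of live-cell density, so the rate is the slope of supernatant
    concentration against cumulative ∫ n_live dt (trapezoid rule).  The
    intercept is left free: washed cultures can carry a small time-zero
    supernatant concentration.
    """
    table = _as_table(assay)
    t = table.column("time", canonical=False)
    n_live = table.column("live_density", canonical=False)
    conc = table.column("concentration")
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    integral = np.concatenate([[0.0], np.cumsum(np.diff(t) * (n_live[1:] + n_live[:-1]) / 2.0)])
    res = stats.linregress(integral, conc)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return RateEstimate(value=float(res.slope), se=se, window=(0, len(t)), n_points=len(t))


def utilization_per_birth(
    assay,
    linear_max: float = 25.0 * UM_TO_FMOLE_PER_ML,
    inoculum: float = 0.0,
) -> RatioWithError:
    """Metabolite utilized per cell birth (fmole/cell) from a yield assay.

    Within the linear range (input concentration <= ``linear_max``,
    fmole/ml) the final density is proportional to the input metabolite;
    the through-origin slope is births per fmole, and utilization per birth
    is its reciprocal, with the slope's standard error propagated through
    the reciprocal.  ``inoculum`` (cells/ml) is subtracted from the final
    densities so that only metabolite-supported births are counted.
    """
    table = _as_table(assay)
    x = table.column("input_concentration")
    y = table.column("final_density", canonical=False) - inoculum
    keep = x <= linear_max
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points within the linear range")
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx
    if slope <= 0:
        raise ValueError("non-positive yield slope; utilization undefined")
    dof = len(x) - 1
    s2 = float(np.sum((y - slope * x) ** 2)) / dof if dof > 0 else 0.0
    se_slope = np.sqrt(s2 / sxx)
    return RatioWithError(value=1.0 / slope, sigma=float(se_slope / slope**2))


def propagate_ratio_error(
    A: float, sigma_A: float, B: float, sigma_B: float
) -> RatioWithError:
    """Ratio f = A/B with uncorrelated errors:
    sigma_f = |f| * sqrt((sigma_A/A)^2 + (sigma_B/B)^2)."""
    if B == 0:
        raise ValueError("denominator B must be nonzero")
    if sigma_A < 0 or sigma_B < 0:
        raise ValueError("sigmas must be >= 0")
    if A == 0:
        if sigma_A > 0:
            raise ValueError("relative error undefined for A = 0 with sigma_A > 0")
        return RatioWithError(0.0, 0.0)
    f = A / B
    sigma = abs(f) * np.sqrt((sigma_A / A) ** 2 + (sigma_B / B) ** 2)
    return RatioWithError(float(f), float(sigma))


# ---------------------------------------------------------------------------
# calibrations
# ---------------------------------------------------------------------------

def density_from_beads(
    cell_events: float,
    bead_events: float,
    bead_stock_density: float,
    vol_sample: float,
    vol_beads: float,
    dilution_factor: float = 1.0,
) -> float:
    """Absolute cell density (cells/ml) from flow-cytometry event counts.

    A known volume of a bead stock of known density is spiked into the
    sample, so the cell:bead event ratio converts directly to density:
    (cells/beads) * bead_stock * (vol_beads/vol_sample) * dilution.
    """
    if bead_events <= 0:
        raise ValueError("bead_events must be positive")
    return float(
        cell_events
        / bead_events
        * bead_stock_density
        * (vol_beads / vol_sample)
        * dilution_factor
    )


@dataclass(frozen=True)
class BioassayCalibration:
    """Monotone piecewise-linear standard curve: turbidity -> concentration.

    ``turbidity``/``concentration`` are the replicate-averaged standards in
    increasing order; queries outside [turbidity[0], turbidity[-1]] are
    flagged rather than extrapolated.
    """

    turbidity: np.ndarray
    concentration: np.ndarray  # fmole/ml


def calibrate_bioassay(standards) -> BioassayCalibration:
    """Build a standard curve from (concentration, turbidity) standards.

    Replicate readings at the same concentration are averaged; the averaged
    turbidities must be non-decreasing in concentration (a tester-strain
    yield assay saturates but never inverts) or the standards are rejected
    with diagnostics.
    """
    table = _as_table(standards)
    df = pd.DataFrame(
        {
            "concentration": table.column("concentration"),
            "turbidity": table.column("turbidity", canonical=False),
        }
    )
    mean = df.groupby("concentration", sort=True)["turbidity"].mean()
    if len(mean) < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    turb = mean.to_numpy(float)
    conc = mean.index.to_numpy(float)
    drops = np.diff(turb) < 0
    if drops.any():
        bad = conc[1:][drops]
        raise ValueError(
            "averaged standards are not monotone: turbidity decreases at "
            f"concentration(s) {bad.tolist()} fmole/ml"
        )
    return BioassayCalibration(turbidity=turb, concentration=conc)


def infer_concentration(
    calibration: BioassayCalibration, turbidity: float
) -> tuple[Optional[float], Optional[str]]:
    """Invert the standard curve at one turbidity reading.

    Returns ``(concentration, flag)``; out-of-range readings give
    ``(None, "below_range")`` or ``(None, "above_range")`` instead of an
    extrapolated value.
    """
    lo, hi = calibration.turbidity[0], calibration.turbidity[-1]
    if turbidity < lo:
        return None, "below_range"
    if turbidity > hi:
        return None, "above_range"
    value = float(np.interp(turbidity, calibration.turbidity, calibration.concentration))
    return value, None


# ---------------------------------------------------------------------------
# community growth-rate regression
# ---------------------------------------------------------------------------

def steady_state_rate(
    table,
    lag_policy: str | float = "auto",
    density_cap: float = 1e8,
    final_window_rtol: float = 0.20,
) -> RateEstimate:
    """Steady-state growth rate from a (time, density) series.

    Regresses ln(density) on time after excluding the initial lag phase and
    any points at or above ``density_cap`` (cells/ml), where growth leaves
    the exchange-limited regime.  ``lag_policy`` is either a time cutoff in
    hours (points strictly earlier are dropped) or ``"auto"``: leading
    points are dropped until the local 3-point slope is within
    ``final_window_rtol`` of the slope over the trailing quarter of the
    retained series.  The plotting convention for these rates is ± 2*se
    (see :attr:`RateEstimate.ci2`).
    """
    at = _as_table(table)
    t = at.column("time", canonical=False)
    n = at.column("density", canonical=False)
    keep = n < density_cap
    t, n = t[keep], n[keep]
    if (n <= 0).any():
        raise ValueError("densities must be positive to take logs")
    ln = np.log(n)

    if isinstance(lag_policy, str):
        if lag_policy != "auto":
            raise ValueError(f"unknown lag_policy {lag_policy!r}")
        start = 0
        m = len(t)
        k = max(3, m // 4)
        if m < k + 3:
            raise ValueError("too few points for automatic lag detection")
        ref = float(np.polyfit(t[m - k :], ln[m - k :], 1)[0])
        while start <= m - max(k, 3) - 1:
            local = float(np.polyfit(t[start : start + 3], ln[start : start + 3], 1)[0])
            if ref != 0 and abs(local - ref) / abs(ref) <= final_window_rtol:
                break
            start += 1
    else:
        start = int(np.searchsorted(t, float(lag_policy), side="left"))

    t, ln = t[start:], ln[start:]
    if len(t) < 3:
        raise ValueError("fewer than 3 points retained after lag exclusion")
    res = stats.linregress(t, ln)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return RateEstimate(
        value=float(res.slope), se=se, window=(start, start + len(t)), n_points=len(t)
    )
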