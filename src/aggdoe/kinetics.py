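"""Growth kinetics and aggregate-stability metrics for suspension cultures.

An iPSC aggregate is treated as a sphere of randomly packed 10 µm cells
(packing fraction 0.64).  From the day-1 mean diameter the cell content of an
average aggregate is inferred; the exponential growth rate K fitted from
daily counts then predicts how large that aggregate should be a few days
later if size changes only through proliferation.  The relative gap between
the observed and predicted day-3 volume — "aggregate % error" — separates
fusion (observed larger, positive) from breakage/instability (negative).

All volumes are µm³ and diameters µm; K is per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeometryConstants",
    "ReactorSeries",
    "GrowthEstimate",
    "AggregateStability",
    "sphere_volume",
    "diameter_from_volume",
    "cells_per_aggregate",
    "predict_future_cells",
    "predicted_volume",
    "aggregate_pct_error",
    "fit_growth_rate",
    "diameter_stats",
    "stability_from_series",
    "qpcr_normalize",
]


@dataclass(frozen=True)
class GeometryConstants:
    """Geometric assumptions behind the aggregate % error statistic.

    ``horizon_days`` is the exponent multiplier of the cell-number
    prediction, N_3P = N_1 * exp(K * horizon_days); the published value is 3
    even though the day-1 → day-3 comparison spans 2 days.  Pass
    ``horizon_days`` equal to the actual interval for the internally
    consistent variant (see docs/methods.md).
    """

    cell_diameter: float = 10.0  # µm
    packing_density: float = 0.64
    horizon_days: float = 3.0

    def __post_init__(self) -> None:
        if self.cell_diameter <= 0:
            raise ValueError("cell_diameter must be > 0")
        if not 0 < self.packing_density <= 1:
            raise ValueError("packing_density must be in (0, 1]")

    @property
    def cell_volume(self) -> float:
        """Single-cell volume V_c = (4/3)π(d/2)³; 523.6 µm³ at the default."""
        return sphere_volume(self.cell_diameter / 2.0)


def sphere_volume(radius):
    """Volume of a sphere, (4/3)·π·r³."""
    r = np.asarray(radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    out = (4.0 / 3.0) * math.pi * r**3
    return float(out) if np.isscalar(radius) else out


def diameter_from_volume(volume):
    """Diameter of the sphere with the given volume (inverse of sphere_volume)."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be >= 0")
    out = 2.0 * (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
    return float(out) if np.isscalar(volume) else out


def cells_per_aggregate(V1: float, geom: GeometryConstants = GeometryConstants()) -> float:
    """Cells in an aggregate of volume V1: N1 = (V1 / V_c) · packing density.

    The count is a continuous ratio and is deliberately not rounded.
    """
    if V1 < 0:
        raise ValueError("V1 must be >= 0")
    return (V1 / geom.cell_volume) * geom.packing_density


def predict_future_cells(
    N1: float, K: float, geom: GeometryConstants = GeometryConstants()
) -> float:
    """Predicted cells per aggregate after the horizon: N_3P = N1·exp(K·h)."""
    if N1 < 0:
        raise ValueError("N1 must be >= 0")
    return N1 * math.exp(K * geom.horizon_days)


def predicted_volume(
    N3P: float, geom: GeometryConstants = GeometryConstants()
) -> float:
    """Aggregate volume holding N3P cells: V_3P = N_3P·V_c / packing density."""
    if N3P < 0:
        raise ValueError("N3P must be >= 0")
    return N3P * geom.cell_volume / geom.packing_density


def aggregate_pct_error(V3: float, V3P: float) -> float:
    """Aggregate % error = (V3 − V3P)/V3 on day-3 volumes.

    Positive: the observed aggregate is larger than proliferation alone
    predicts (fusion).  Negative: smaller (breakage/instability).
    """
    if V3 <= 0:
        raise ValueError("observed volume V3 must be > 0")
    return (V3 - V3P) / V3


@dataclass
class ReactorSeries:
    """Daily measurements from one bioreactor run.

    ``counts``: day -> replicate cell concentrations (cells/ml, triplicate in
    the assay).  ``diameters``: day -> aggregate diameter sample (µm, >=30 in
    the assay).  ``viability``: day -> percent, optional.
    """

    run_id: str
    counts: dict[int, np.ndarray] = field(default_factory=dict)
    diameters: dict[int, np.ndarray] = field(default_factory=dict)
    viability: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = {int(d): np.asarray(v, dtype=float) for d, v in self.counts.items()}
        self.diameters = {
            int(d): np.asarray(v, dtype=float) for d, v in self.diameters.items()
        }
        for d, v in self.counts.items():
            if np.any(v <= 0):
                raise ValueError(f"run {self.run_id}, day {d}: counts must be > 0")
        for d, v in self.diameters.items():
            if np.any(v <= 0):
                raise ValueError(f"run {self.run_id}, day {d}: diameters must be > 0")

    @property
    def days(self) -> list[int]:
        return sorted(set(self.counts) | set(self.diameters))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for day in sorted(self.counts):
            for rep, val in enumerate(self.counts[day], start=1):
                rows.append((self.run_id, day, "count", rep, val))
        for day in sorted(self.diameters):
            for rep, val in enumerate(self.diameters[day], start=1):
                rows.append((self.run_id, day, "diameter", rep, val))
        for day in sorted(self.viability):
            rows.append((self.run_id, day, "viability", 1, self.viability[day]))
        return pd.DataFrame(
            rows, columns=["run_id", "day", "measurement_type", "replicate", "value"]
        )


def series_to_frame(series_list: list[ReactorSeries]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in series_list], ignore_index=True)


def series_from_frame(df: pd.DataFrame) -> list[ReactorSeries]:
    out = []
    for run_id, grp in df.groupby("run_id", sort=False):
        counts, diams, viab = {}, {}, {}
        for (day, mtype), sub in grp.groupby(["day", "measurement_type"]):
            vals = sub["value"].to_numpy(float)
            if mtype == "count":
                counts[int(day)] = vals
            elif mtype == "diameter":
                diams[int(day)] = vals
            elif mtype == "viability":
                viab[int(day)] = float(vals.mean())
        out.append(ReactorSeries(str(run_id), counts, diams, viab))
    return out


@dataclass(frozen=True)
class GrowthEstimate:
    K: float  # 1/day
    doubling_time: float  # days; nan when K <= 0
    r2_fit: float


def fit_growth_rate(series: ReactorSeries) -> GrowthEstimate:
    """Specific growth rate from a log-linear fit of daily mean counts.

    ln(mean count) is regressed on day by least squares across all days with
    counts; the doubling time is ln2/K for positive K (nan otherwise, flagged
    rather than raised — declining cultures are a real outcome).
    """
    days = sorted(series.counts)
    if len(days) < 2:
        raise ValueError(f"run {series.run_id}: need >= 2 days of counts")
    t = np.array(days, dtype=float)
    y = np.log([series.counts[d].mean() for d in days])
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    K = float(slope)
    td = math.log(2) / K if K > 0 else math.nan
    return GrowthEstimate(K=K, doubling_time=td, r2_fit=r2)


def diameter_stats(series: ReactorSeries) -> tuple[pd.DataFrame, float]:
    """Per-day mean and sample SD of aggregate diameters, plus the slope
    (µm/day) of the mean diameter over days.

    A day with a single measurement gets SD = nan (undefined, not zero).
    """
    days = sorted(series.diameters)
    if not days:
        raise ValueError(f"run {series.run_id}: no diameter measurements")
    rows = []
    for d in days:
        v = series.diameters[d]
        sd = float(np.std(v, ddof=1)) if v.size >= 2 else math.nan
        rows.append((d, float(v.mean()), sd, v.size))
    df = pd.DataFrame(rows, columns=["day", "mean", "sd", "n"])
    if len(days) >= 2:
        slope = float(np.polyfit(df["day"], df["mean"], 1)[0])
    else:
        slope = math.nan
    return df, slope


@dataclass(frozen=True)
class AggregateStability:
    """The full Eq-chain output for one reactor."""

    V1: float
    V3: float
    V3P: float
    N1: float
    N3P: float
    pct_error: float
    diameter_sd: float
    diameter_slope: float


def stability_from_series(
    series: ReactorSeries,
    geom: GeometryConstants = GeometryConstants(),
    day_initial: int = 1,
    day_final: int = 3,
) -> AggregateStability:
    """Chain volume → cells → growth prediction → % error for one reactor.

    Uses the mean diameter on ``day_initial`` and ``day_final`` and the
    growth rate fitted from the count series.  The prediction exponent is
    K·geom.horizon_days regardless of the day interval (published
    convention); construct ``geom`` with ``horizon_days = day_final −
    day_initial`` for the interval-consistent variant.
    """
    for day in (day_initial, day_final):
        if day not in series.diameters:
            raise ValueError(f"run {series.run_id}: no diameters for day {day}")
    growth = fit_growth_rate(series)
    d1 = float(series.diameters[day_initial].mean())
    d3 = float(series.diameters[day_final].mean())
    V1 = sphere_volume(d1 / 2.0)
    V3 = sphere_volume(d3 / 2.0)
    N1 = cells_per_aggregate(V1, geom)
    N3P = predict_future_cells(N1, growth.K, geom)
    V3P = predicted_volume(N3P, geom)
    stats, slope = diameter_stats(series)
    sd_final = float(stats.loc[stats["day"] == day_final, "sd"].iloc[0])
    return AggregateStability(
        V1=V1,
        V3=V3,
        V3P=V3P,
        N1=N1,
        N3P=N3P,
        pct_error=aggregate_pct_error(V3, V3P),
        diameter_sd=sd_final,
        diameter_slope=slope,
    )


def qpcr_normalize(ct_target, ct_housekeeping):
    """Relative expression 1000 / 2^ΔCt with ΔCt = Ct_target − Ct_housekeeping.

    Higher expression (lower target Ct) gives a larger value; ΔCt = 0 maps to
    1000 expression units.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_h = np.asarray(ct_housekeeping, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_h))):
        raise ValueError("Ct values must be finite")
    out = 1000.0 / np.power(2.0, ct_t - ct_h)
    return float(out) if np.isscalar(ct_target) else out
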