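"""mito-gTEMP ratiometric thermometry.

The mT-Sapphire/Sirius emission ratio rises with temperature (Sirius dims as
temperature climbs, mT-Sapphire does not), and — because both proteins are
expressed from one self-cleaving polyprotein — the ratio is independent of
expression level. An in-vivo calibration staircase (oligomycin-treated cells
stepped 30→42 °C in 3 °C increments, kept under 35 min of UV illumination)
yields a linear ratio-vs-temperature function whose inversion, extrapolated
beyond 42 °C where cells cannot survive calibration, gives absolute
mitochondrial temperatures.

Pipeline entry points: :func:`compute_ratio`, :func:`fit_ratio_calibration`,
:func:`infer_temperature_trace`, and the :class:`GtempThermometry` model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traces import FluorescenceTrace, CALIBRATION_EVENT, rolling_mean
from .mty import _segment_steps

__all__ = [
    "RatioSeries",
    "RatioCalibration",
    "TemperatureTrace",
    "compute_ratio",
    "check_drug_background",
    "fit_ratio_calibration",
    "infer_temperature_trace",
    "summarize_interval",
    "peak_temperature",
    "GtempThermometry",
    "GtempThermometryResults",
]

#: hard photodamage limit on the span of a calibration record (seconds)
PHOTODAMAGE_LIMIT_S = 35.0 * 60.0


@dataclass
class RatioSeries:
    """mT-Sapphire/Sirius ratio with denominator-floor masking."""

    times: np.ndarray
    values: np.ndarray          # NaN where masked
    mask: np.ndarray            # True where the Sirius denominator hit the floor

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


@dataclass
class RatioCalibration:
    """Linear ratio-vs-temperature calibration, R(T) = c0 + c1·T."""

    c0: float
    c1: float
    calibrated_range: tuple[float, float] = (30.0, 42.0)
    r_squared: float = 1.0
    n_replicates: int = 1
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.c1 == 0:
            raise ValueError("zero calibration slope: not invertible")

    def predict(self, temperature):
        return self.c0 + self.c1 * np.asarray(temperature, dtype=float)

    def invert(self, ratio):
        return (np.asarray(ratio, dtype=float) - self.c0) / self.c1


@dataclass
class TemperatureTrace:
    """Inferred mitochondrial temperature trajectory.

    ``extrapolated`` marks samples whose ratio was inverted outside the
    calibrated range — reported, never clipped, mirroring the dotted-line
    convention for extrapolated calibration curves.
    """

    times: np.ndarray
    temperatures: np.ndarray
    extrapolated: np.ndarray
    method: str = "GTEMP"

    def __post_init__(self) -> None:
        if not (self.times.size == self.temperatures.size == self.extrapolated.size):
            raise ValueError("times, temperatures and mask must share one length")

    @property
    def extrapolated_fraction(self) -> float:
        valid = ~np.isnan(self.temperatures)
        return float(self.extrapolated[valid].mean()) if valid.any() else 0.0


def compute_ratio(
    trace: FluorescenceTrace,
    floor_fraction: float = 0.01,
    max_masked_fraction: float = 0.10,
) -> RatioSeries:
    """Elementwise mT-Sapphire / Sirius ratio.

    Samples whose Sirius denominator falls below ``floor_fraction`` of that
    channel's median are masked (NaN), not zero-filled; more than
    ``max_masked_fraction`` masked samples aborts with a denominator-collapse
    error.
    """
    if trace.n_channels != 2:
        raise ValueError("ratio requires a two-channel (mT-Sapphire, Sirius) trace")
    sapphire, sirius = trace.channels[0], trace.channels[1]
    floor = floor_fraction * float(np.median(sirius))
    mask = sirius <= floor
    if mask.mean() > max_masked_fraction:
        raise ValueError(
            f"denominator collapse: {mask.mean():.0%} of Sirius samples at the floor")
    values = np.where(mask, np.nan, sapphire / np.where(mask, 1.0, sirius))
    return RatioSeries(times=trace.times.copy(), values=values, mask=mask)


def check_drug_background(
    blank_with_drug: FluorescenceTrace,
    blank_without_drug: FluorescenceTrace,
    ratio_tol: float = 0.02,
) -> tuple[bool, dict]:
    """Is a drug's cell-free background compatible with ratiometry?

    PASS when the mean channel ratio shifts by at most ``ratio_tol``
    (relative) between the drug-free and drug-containing blanks — individual
    channels may shift as long as the ratio does not (oligomycin-style);
    a ratio shift (antimycin-style, mostly at the Sirius wavelength) FAILs.
    """
    if blank_with_drug.times.size != blank_without_drug.times.size:
        raise ValueError("blank records must have equal duration")
    r_with = float(np.nanmean(compute_ratio(blank_with_drug).values))
    r_without = float(np.nanmean(compute_ratio(blank_without_drug).values))
    shift = abs(r_with - r_without) / abs(r_without)
    per_channel = {}
    for i, name in enumerate(("sapphire", "sirius")):
        m_with = float(blank_with_drug.channels[i].mean())
        m_without = float(blank_without_drug.channels[i].mean())
        per_channel[name] = dict(
            mean_with_drug=m_with, mean_without_drug=m_without,
            relative_shift=(m_with - m_without) / m_without,
        )
    verdict = shift <= ratio_tol
    return verdict, dict(ratio_shift=shift, ratio_tol=ratio_tol,
                         channels=per_channel)


def _calibration_points(
    trace: FluorescenceTrace,
    equilibration_discard: float,
    averaging_window: float,
    min_interval: float,
) -> tuple[list[tuple[float, float]], list[str]]:
    span = float(trace.times[-1] - trace.times[0]) + trace.dt
    if span >= PHOTODAMAGE_LIMIT_S:
        raise ValueError(
            f"photodamage window exceeded: record spans {span / 60:.1f} min "
            f">= {PHOTODAMAGE_LIMIT_S / 60:.0f} min")
    step_times = trace.event_times(CALIBRATION_EVENT)
    if len(step_times) < 2:
        raise ValueError("need at least 2 calibration-step events")
    ratio = compute_ratio(trace)
    points, warnings = _segment_steps(
        trace.times, ratio.values, trace.setpoints, step_times,
        float(trace.times[-1] + trace.dt),
        equilibration_discard, averaging_window, min_interval,
    )
    return points, warnings


def fit_ratio_calibration(
    traces: FluorescenceTrace | list[FluorescenceTrace],
    equilibration_discard: float = 120.0,
    averaging_window: float = 60.0,
    min_interval: float = 120.0,
    pool_points: bool = False,
) -> RatioCalibration:
    """Fit the ratio-vs-imposed-temperature line from staircase record(s).

    Each record must stay under the 35 min photodamage limit. Per-step ratio
    means (equilibration discarded, final ``averaging_window`` seconds
    averaged) are regressed on the imposed temperature by OLS. Replicates
    are pooled by averaging per-replicate coefficients (default) or by a
    single fit over all points (``pool_points=True``).
    """
    if isinstance(traces, FluorescenceTrace):
        traces = [traces]
    if not traces:
        raise ValueError("need at least one calibration trace")
    all_points: list[list[tuple[float, float]]] = []
    warnings: list[str] = []
    for tr in traces:
        pts, warns = _calibration_points(tr, equilibration_discard,
                                         averaging_window, min_interval)
        temps = {round(T, 9) for T, _ in pts}
        if len(temps) < 2:
            raise ValueError("singular design: < 2 distinct calibration temperatures")
        if len(temps) < 3:
            warnings.append("calibration staircase covers only 2 distinct temperatures")
        all_points.append(pts)
        warnings.extend(warns)

    def _fit(points):
        T = np.array([p[0] for p in points])
        R = np.array([p[1] for p in points])
        res = stats.linregress(T, R)
        r2 = 1.0 if len(points) == 2 else float(res.rvalue**2)
        return float(res.slope), float(res.intercept), r2

    if pool_points:
        c1, c0, r2 = _fit([p for pts in all_points for p in pts])
    else:
        fits = [_fit(pts) for pts in all_points]
        c1 = float(np.mean([f[0] for f in fits]))
        c0 = float(np.mean([f[1] for f in fits]))
        r2 = float(np.mean([f[2] for f in fits]))
    temps_all = [p[0] for pts in all_points for p in pts]
    return RatioCalibration(
        c0=c0, c1=c1,
        calibrated_range=(float(min(temps_all)), float(max(temps_all))),
        r_squared=r2, n_replicates=len(traces), warnings=warnings,
    )


def infer_temperature_trace(
    ratio: RatioSeries | np.ndarray,
    calibration: RatioCalibration,
    times: np.ndarray | None = None,
) -> TemperatureTrace:
    """Invert the calibration: T(t) = (R(t) − c0) / c1, no clipping.

    Samples inverted outside the calibrated range carry the extrapolation
    flag; masked ratio samples propagate as NaN.
    """
    if isinstance(ratio, RatioSeries):
        values, t = ratio.values, ratio.times
    else:
        values = np.asarray(ratio, dtype=float)
        t = np.asarray(times, dtype=float) if times is not None \
            else np.arange(values.size, dtype=float)
    temp = calibration.invert(values)
    lo, hi = calibration.calibrated_range
    with np.errstate(invalid="ignore"):
        extrapolated = (temp < lo) | (temp > hi)
    extrapolated &= ~np.isnan(temp)
    return TemperatureTrace(times=t.copy(), temperatures=temp,
                            extrapolated=extrapolated)


def summarize_interval(
    temps: TemperatureTrace,
    intervals: list[tuple[float, float]],
) -> list[dict]:
    """Mean ± SD of the temperature over half-open intervals in minutes.

    Intervals are ``[start, end)`` in minutes since the start of the record;
    SD is the sample standard deviation (n−1). Empty or out-of-record
    intervals raise.
    """
    out = []
    t_end = temps.times[-1]
    for start_min, end_min in intervals:
        a, b = start_min * 60.0, end_min * 60.0
        if b <= a:
            raise ValueError(f"empty interval ({start_min}, {end_min}) min")
        if a > t_end:
            raise ValueError(f"interval ({start_min}, {end_min}) min beyond record end")
        sel = (temps.times >= a) & (temps.times < b)
        vals = temps.temperatures[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"interval ({start_min}, {end_min}) min contains no samples")
        out.append(dict(
            start_min=float(start_min), end_min=float(end_min),
            mean_c=float(vals.mean()),
            sd_c=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            n=int(vals.size),
            extrapolated_fraction=float(temps.extrapolated[sel].mean()),
        ))
    return out


def peak_temperature(
    temps: TemperatureTrace,
    window: tuple[float, float],
    smooth_window: float = 60.0,
) -> float:
    """Maximum smoothed temperature within a ``(start, end)`` minute window.

    Boxcar smoothing before the maximum avoids the upward noise bias of a
    raw per-sample argmax.
    """
    a, b = window[0] * 60.0, window[1] * 60.0
    sel = (temps.times >= a) & (temps.times < b)
    if not np.any(sel):
        raise ValueError("peak window contains no samples")
    dt = float(temps.times[1] - temps.times[0]) if temps.times.size > 1 else 1.0
    width = max(int(round(smooth_window / dt)), 1)
    filled = temps.temperatures.copy()
    nan = np.isnan(filled)
    if nan.all():
        raise ValueError("temperature trace entirely masked")
    if nan.any():
        filled[nan] = np.interp(temps.times[nan], temps.times[~nan],
                                filled[~nan])
    smooth = rolling_mean(filled, width)
    return float(smooth[sel].max())


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class GtempThermometry:
    """Ratiometric thermometry model for one two-channel trace.

    Needs a :class:`RatioCalibration` (from :func:`fit_ratio_calibration`,
    derived for the same cell line); ``fit()`` computes the channel ratio and
    inverts it into a temperature trajectory.
    """

    def __init__(
        self,
        trace: FluorescenceTrace,
        calibration: RatioCalibration,
        floor_fraction: float = 0.01,
    ) -> None:
        if trace.n_channels != 2:
            raise ValueError("gTEMP analysis expects a two-channel trace")
        self.trace = trace
        self.calibration = calibration
        self.floor_fraction = floor_fraction

    @classmethod
    def from_file(cls, path, calibration, **kwargs) -> "GtempThermometry":
        from .io import load_trace_table
        return cls(load_trace_table(path), calibration, **kwargs)

    def fit(self) -> "GtempThermometryResults":
        ratio = compute_ratio(self.trace, floor_fraction=self.floor_fraction)
        temps = infer_temperature_trace(ratio, self.calibration)
        return GtempThermometryResults(model=self, ratio=ratio,
                                       temperature_trace=temps)


@dataclass
class GtempThermometryResults:
    """Inferred temperature trajectory plus summaries for one trace."""

    model: GtempThermometry
    ratio: RatioSeries
    temperature_trace: TemperatureTrace

    def interval_summary(self, intervals: list[tuple[float, float]]) -> list[dict]:
        return summarize_interval(self.temperature_trace, intervals)

    def peak(self, window: tuple[float, float], smooth_window: float = 60.0) -> float:
        return peak_temperature(self.temperature_trace, window, smooth_window)

    def to_dict(self, intervals: list[tuple[float, float]] | None = None) -> dict:
        cal = self.model.calibration
        d = dict(
            method="GTEMP",
            calibration=dict(
                c0=cal.c0, c1=cal.c1,
                calibrated_range_c=list(cal.calibrated_range),
                r_squared=cal.r_squared, n_replicates=cal.n_replicates,
            ),
            n_masked_samples=self.ratio.n_masked,
            extrapolated_fraction=self.temperature_trace.extrapolated_fraction,
            warnings=list(cal.warnings),
        )
        if intervals:
            d["intervals"] = self.interval_summary(intervals)
        return d

    def summary(self) -> str:
        cal = self.model.calibration
        tt = self.temperature_trace
        valid = tt.temperatures[~np.isnan(tt.temperatures)]
        lines = [
            "mito-gTEMP thermometry results",
            "=" * 46,
            f"calibration            R = {cal.c0:+.5f} {cal.c1:+.5f}·T "
            f"(r² = {cal.r_squared:.4f}, n = {cal.n_replicates})",
            f"calibrated range       {cal.calibrated_range[0]:.0f}–"
            f"{cal.calibrated_range[1]:.0f} °C",
            f"temperature range      {valid.min():.2f}–{valid.max():.2f} °C",
            f"extrapolated fraction  {tt.extrapolated_fraction:.1%}",
            f"masked samples         {self.ratio.n_masked}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tt = self.temperature_trace
        ax.plot(tt.times / 60.0, tt.temperatures, lw=0.8,
                label="inferred T_mito")
        if tt.extrapolated.any():
            ex = np.where(tt.extrapolated, tt.temperatures, np.nan)
            ax.plot(tt.times / 60.0, ex, lw=0.8, ls="--",
                    label="extrapolated")
        lo, hi = self.model.calibration.calibrated_range
        ax.axhspan(lo, hi, alpha=0.1, color="tab:blue", label="calibrated range")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("temperature (°C)")
        ax.legend(loc="best", fontsize="small")
        return ax
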