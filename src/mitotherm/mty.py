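"""MTY single-channel thermometry: plateau screening, internal step
calibration, and linear conversion of fluorescence shifts into temperature
shifts.

The measurement principle: MTY fluorescence falls roughly linearly with the
temperature the dye senses. Each experiment ends with an internal calibration
— the Peltier jacket is stepped up and down by ±3 °C — so the fluorescence
change produced by a drug can be converted into °C using that experiment's
own response, cancelling gain, label-uptake and autofluorescence differences
between trials. A trace is only usable when the post-drug signal settles to
a plateau; records that keep drifting (dye leakage) are flagged unstable and
their estimates withheld.

Use either the operation functions directly or the
:class:`MtyThermometry` model: ``MtyThermometry(trace).fit()`` returns a
:class:`MtyThermometryResults` carrying the calibration line, the signed
temperature shift, stability verdict and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traces import CALIBRATION_EVENT, FluorescenceTrace, rolling_mean

__all__ = [
    "CalibrationFit",
    "TemperatureShiftEstimate",
    "detect_plateau",
    "check_stability",
    "segment_calibration_steps",
    "fit_step_calibration",
    "estimate_temperature_shift",
    "estimate_peak_shift",
    "quantify_rewarming",
    "MtyThermometry",
    "MtyThermometryResults",
]

#: default plateau criterion: sliding-window slope below this fraction of the
#: pre-drug baseline intensity, per minute
DEFAULT_SLOPE_TOL_FRACTION = 1e-3


@dataclass
class CalibrationFit:
    """Fitted fluorescence(or ratio)-vs-temperature line from internal steps."""

    slope: float                     # AU per °C (negative for MTY)
    intercept: float
    r_squared: float
    temperature_range: tuple[float, float]
    n_points: int
    extrapolation_used: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration needs at least 2 points")
        lo, hi = self.temperature_range
        if not lo < hi:
            raise ValueError("temperature_range must satisfy min < max")

    @property
    def span(self) -> float:
        return self.temperature_range[1] - self.temperature_range[0]


@dataclass
class TemperatureShiftEstimate:
    """Signed mitochondrial temperature shift with provenance.

    ``delta_t`` is negative for cooling (an OXPHOS inhibitor makes MTY
    fluorescence rise, and the calibration slope is negative).
    ``magnitude`` is what the literature reports as a "temperature decrease".
    """

    delta_t: float
    sd: float | None
    method: str
    baseline_window: tuple[float, float]
    response_window: tuple[float, float]
    stable: bool
    extrapolated: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def magnitude(self) -> float:
        return abs(self.delta_t)


# ---------------------------------------------------------------------------
# plateau and stability
# ---------------------------------------------------------------------------

def sliding_window_slopes(series: np.ndarray, width: int, dt: float) -> np.ndarray:
    """Least-squares slope (AU per second) of every length-``width`` window.

    Computed by correlating the series with the centered-index kernel, which
    is the closed form of per-window OLS on a uniform time base and avoids
    the cancellation error of running-sum formulations.
    """
    f = np.asarray(series, dtype=float)
    k = np.arange(width, dtype=float)
    kernel = k - k.mean()
    denom = float(np.sum(kernel**2)) * dt
    num = np.correlate(f, kernel, mode="valid")
    return num / denom


def detect_plateau(
    series,
    window: float,
    slope_tol: float,
    dt: float = 1.0,
    times=None,
) -> float | None:
    """Onset time of the first window whose trend slope is below tolerance.

    ``window`` in seconds, ``slope_tol`` in AU per minute. Returns the start
    time of the first sliding window whose least-squares slope magnitude is
    below ``slope_tol``, or ``None`` when no window qualifies.
    """
    f = np.asarray(series, dtype=float)
    if window <= 0 or slope_tol <= 0:
        raise ValueError("window and slope_tol must be positive")
    width = int(round(window / dt))
    if width < 2:
        raise ValueError("window must cover at least 2 samples")
    if f.size < width:
        raise ValueError("series shorter than the plateau window")
    slopes_per_min = sliding_window_slopes(f, width, dt) * 60.0
    hits = np.flatnonzero(np.abs(slopes_per_min) < slope_tol)
    if hits.size == 0:
        return None
    t0 = np.asarray(times, dtype=float) if times is not None \
        else np.arange(f.size) * dt
    return float(t0[hits[0]])


def _baseline_level(trace: FluorescenceTrace, t_drug: float, span: float = 60.0,
                    channel: int = 0) -> float:
    start = max(trace.times[0], t_drug - span)
    return trace.window_mean(start, t_drug, channel=channel)


def check_stability(
    trace: FluorescenceTrace,
    drug_event: str,
    min_span: float = 600.0,
    plateau_window: float = 300.0,
    slope_tol: float | None = None,
    channel: int = 0,
) -> tuple[bool, dict]:
    """Does the post-drug signal reach a plateau before the record ends?

    The search segment runs from the drug event to the first calibration
    step (or end of record). ``slope_tol`` defaults to 0.1% of the pre-drug
    baseline intensity per minute. Raises when the record extends less than
    ``min_span`` seconds beyond the drug event.
    """
    t_drug = trace.first_event(drug_event)
    if t_drug is None:
        raise ValueError(f"drug event {drug_event!r} not found in trace")
    if trace.times[-1] - t_drug < min_span:
        raise ValueError("insufficient post-drug record")
    cal_times = [t for t in trace.event_times(CALIBRATION_EVENT) if t > t_drug]
    t_end = min(cal_times) if cal_times else trace.times[-1] + trace.dt
    sel = (trace.times >= t_drug) & (trace.times < t_end)
    segment = trace.channels[channel, sel]
    seg_times = trace.times[sel]
    if slope_tol is None:
        slope_tol = DEFAULT_SLOPE_TOL_FRACTION * _baseline_level(trace, t_drug, channel=channel)
    onset = None
    if segment.size >= int(round(plateau_window / trace.dt)):
        onset = detect_plateau(segment, plateau_window, slope_tol,
                               dt=trace.dt, times=seg_times)
    diag = dict(drug_time=t_drug, segment_end=float(t_end),
                plateau_onset=onset, slope_tol=float(slope_tol),
                plateau_window=plateau_window)
    return onset is not None, diag


# ---------------------------------------------------------------------------
# internal step calibration
# ---------------------------------------------------------------------------

def _segment_steps(
    times: np.ndarray,
    series: np.ndarray,
    setpoints: np.ndarray,
    step_times: list[float],
    end_time: float,
    equilibration_discard: float,
    averaging_window: float,
    min_interval: float,
) -> tuple[list[tuple[float, float]], list[str]]:
    points: list[tuple[float, float]] = []
    warnings: list[str] = []
    bounds = list(step_times) + [end_time]
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t1 - t0 < min_interval:
            warnings.append(
                f"calibration steps {t1 - t0:.0f} s apart, below the "
                f"{min_interval:.0f} s minimum interval")
        w_start = max(t1 - averaging_window, t0 + equilibration_discard)
        sel = (times >= w_start) & (times < t1)
        if not np.any(sel):
            raise ValueError(
                "calibration step too short to average after the "
                "equilibration discard")
        imposed = float(setpoints[sel][-1])
        # nanmean: ratiometric callers mask denominator-floor samples as NaN
        points.append((imposed, float(np.nanmean(series[sel]))))
    return points, warnings


def segment_calibration_steps(
    trace: FluorescenceTrace,
    equilibration_discard: float = 120.0,
    averaging_window: float = 60.0,
    min_interval: float = 240.0,
    channel: int = 0,
    series: np.ndarray | None = None,
) -> tuple[list[tuple[float, float]], list[str]]:
    """Per-step (imposed °C, mean signal) pairs from the calibration staircase.

    Each step spans from its event to the next event (or end of record); the
    first ``equilibration_discard`` seconds are dropped (thermal lag) and the
    final ``averaging_window`` seconds averaged. The imposed temperature is
    read from the setpoint track. ``series`` overrides the raw channel (used
    by the ratiometric pipeline to pass the channel ratio).

    Returns ``(points, warnings)``; steps closer than ``min_interval`` are
    flagged but still measured.
    """
    step_times = trace.event_times(CALIBRATION_EVENT)
    if len(step_times) < 2:
        raise ValueError("need at least 2 calibration-step events")
    values = np.asarray(series, dtype=float) if series is not None \
        else trace.channels[channel]
    points, warnings = _segment_steps(
        trace.times, values, trace.setpoints, step_times,
        float(trace.times[-1] + trace.dt),
        equilibration_discard, averaging_window, min_interval,
    )
    if len({round(T, 9) for T, _ in points}) < 2:
        raise ValueError("calibration steps must cover >= 2 distinct setpoints")
    return points, warnings


def fit_step_calibration(
    step_points: list[tuple[float, float]],
    warnings: list[str] | None = None,
) -> CalibrationFit:
    """Ordinary least-squares line through the (temperature, signal) points."""
    if len(step_points) < 2:
        raise ValueError("need at least 2 calibration points")
    temps = np.array([T for T, _ in step_points], dtype=float)
    values = np.array([v for _, v in step_points], dtype=float)
    if np.allclose(temps, temps[0]):
        raise ValueError("singular design: all calibration temperatures identical")
    res = stats.linregress(temps, values)
    r2 = 1.0 if len(step_points) == 2 else float(res.rvalue**2)
    warn = list(warnings or [])
    if res.slope >= 0:
        warn.append("suspicious calibration: non-negative MTY slope")
    if r2 < 0.9:
        warn.append(f"suspicious calibration: r² = {r2:.3f} < 0.9")
    return CalibrationFit(
        slope=float(res.slope), intercept=float(res.intercept), r_squared=r2,
        temperature_range=(float(temps.min()), float(temps.max())),
        n_points=len(step_points), warnings=warn,
    )


# ---------------------------------------------------------------------------
# temperature-shift estimation
# ---------------------------------------------------------------------------

def _drug_event_label(trace: FluorescenceTrace) -> str:
    for _, lab in trace.events:
        if lab != CALIBRATION_EVENT:
            return lab
    raise ValueError("trace carries no drug event")


def default_windows(
    trace: FluorescenceTrace, drug_event: str, span: float = 60.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Baseline = ``span`` s before the drug; response = ``span`` s before the
    first calibration step."""
    t_drug = trace.first_event(drug_event)
    if t_drug is None:
        raise ValueError(f"drug event {drug_event!r} not found in trace")
    cal_times = [t for t in trace.event_times(CALIBRATION_EVENT) if t > t_drug]
    if not cal_times:
        raise ValueError("no calibration step after the drug event")
    t_cal = min(cal_times)
    return (t_drug - span, t_drug), (t_cal - span, t_cal)


def estimate_temperature_shift(
    trace: FluorescenceTrace,
    fit: CalibrationFit,
    baseline_window: tuple[float, float] | None = None,
    response_window: tuple[float, float] | None = None,
    drug_event: str | None = None,
    stability_min_span: float = 600.0,
    channel: int = 0,
) -> TemperatureShiftEstimate:
    """Convert the baseline→response fluorescence shift into °C.

    ``delta_t = (mean F over response − mean F over baseline) / slope``; with
    MTY's negative slope a fluorescence rise reads as cooling (negative
    ``delta_t``). The estimate is flagged ``stable=False`` — and should be
    withheld from reporting — when no post-drug plateau exists.
    """
    if fit.slope == 0:
        raise ValueError("zero calibration slope: shift not identifiable")
    drug = drug_event or _drug_event_label(trace)
    if baseline_window is None or response_window is None:
        base_w, resp_w = default_windows(trace, drug)
        baseline_window = baseline_window or base_w
        response_window = response_window or resp_w
    f_base = trace.window_mean(*baseline_window, channel=channel)
    f_resp = trace.window_mean(*response_window, channel=channel)
    delta_t = (f_resp - f_base) / fit.slope
    stable, _ = check_stability(trace, drug, min_span=stability_min_span,
                                channel=channel)
    extrapolated = abs(delta_t) > fit.span
    if extrapolated:
        fit.extrapolation_used = True
    warnings = list(fit.warnings)
    if not stable:
        warnings.append("no post-drug plateau: estimate withheld (stable=False)")
    return TemperatureShiftEstimate(
        delta_t=float(delta_t), sd=None, method="MTY",
        baseline_window=tuple(baseline_window),
        response_window=tuple(response_window),
        stable=stable, extrapolated=extrapolated, warnings=warnings,
    )


def _smoothed_post_drug(trace, drug_event, smooth_window, channel):
    t_drug = trace.first_event(drug_event)
    if t_drug is None:
        raise ValueError(f"drug event {drug_event!r} not found in trace")
    cal_times = [t for t in trace.event_times(CALIBRATION_EVENT) if t > t_drug]
    t_end = min(cal_times) if cal_times else trace.times[-1] + trace.dt
    sel = (trace.times >= t_drug) & (trace.times < t_end)
    if not np.any(sel):
        raise ValueError("no post-drug samples")
    width = max(int(round(smooth_window / trace.dt)), 1)
    smooth = rolling_mean(trace.channels[channel, sel], width)
    return trace.times[sel], smooth, t_drug


def estimate_peak_shift(
    trace: FluorescenceTrace,
    fit: CalibrationFit,
    drug_event: str | None = None,
    baseline_window: tuple[float, float] | None = None,
    smooth_window: float = 60.0,
    channel: int = 0,
) -> float:
    """Temperature-decrease magnitude at the post-drug fluorescence peak.

    For scenarios that rewarm after an initial drop, the transient extreme of
    the (smoothed) fluorescence marks the maximal cooling; this returns
    ``(F_peak − F_baseline) / |slope|`` in °C. Smoothing before the peak is
    taken avoids the upward bias of a raw noisy argmax.
    """
    if fit.slope == 0:
        raise ValueError("zero calibration slope: shift not identifiable")
    drug = drug_event or _drug_event_label(trace)
    _, smooth, t_drug = _smoothed_post_drug(trace, drug, smooth_window, channel)
    if baseline_window is None:
        baseline_window = (t_drug - 60.0, t_drug)
    f_base = trace.window_mean(*baseline_window, channel=channel)
    f_peak = float(smooth.max())
    return (f_peak - f_base) / abs(fit.slope)


def quantify_rewarming(
    trace: FluorescenceTrace,
    fit: CalibrationFit,
    drug_event: str,
    timepoints: list[float],
    smooth_window: float = 60.0,
    channel: int = 0,
) -> np.ndarray:
    """Rewarming in °C at the given timepoints (minutes after the drug).

    ``rewarming(t) = (F_peak − F(t)) / |slope|`` for t after the post-drug
    fluorescence peak, 0 before it; F is the smoothed signal. Suitable for
    pooling means ± SD across replicate traces.
    """
    if fit.slope == 0:
        raise ValueError("zero calibration slope")
    seg_times, smooth, t_drug = _smoothed_post_drug(
        trace, drug_event, smooth_window, channel)
    i_peak = int(np.argmax(smooth))
    f_peak, t_peak = float(smooth[i_peak]), float(seg_times[i_peak])
    out = []
    for minutes in timepoints:
        t = t_drug + minutes * 60.0
        if t > seg_times[-1]:
            raise ValueError(f"timepoint {minutes} min beyond the usable record")
        if t <= t_peak:
            out.append(0.0)
        else:
            f_t = float(smooth[np.searchsorted(seg_times, t)])
            out.append(max((f_peak - f_t) / abs(fit.slope), 0.0))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class MtyThermometry:
    """Single-trace MTY thermometry model.

    Parameters mirror the operations above; ``fit()`` runs stability
    screening, staircase segmentation, OLS calibration and the shift
    estimate, returning a :class:`MtyThermometryResults`.
    """

    def __init__(
        self,
        trace: FluorescenceTrace,
        drug_event: str | None = None,
        baseline_window: tuple[float, float] | None = None,
        response_window: tuple[float, float] | None = None,
        equilibration_discard: float = 120.0,
        averaging_window: float = 60.0,
        plateau_window: float = 300.0,
        slope_tol: float | None = None,
        stability_min_span: float = 600.0,
        min_step_interval: float = 240.0,
    ) -> None:
        if trace.n_channels != 1:
            raise ValueError("MTY analysis expects a single-channel trace")
        self.trace = trace
        self.drug_event = drug_event or _drug_event_label(trace)
        self.baseline_window = baseline_window
        self.response_window = response_window
        self.equilibration_discard = equilibration_discard
        self.averaging_window = averaging_window
        self.plateau_window = plateau_window
        self.slope_tol = slope_tol
        self.stability_min_span = stability_min_span
        self.min_step_interval = min_step_interval

    @classmethod
    def from_file(cls, path, **kwargs) -> "MtyThermometry":
        from .io import load_trace_table
        return cls(load_trace_table(path), **kwargs)

    def fit(self) -> "MtyThermometryResults":
        stable, stab_diag = check_stability(
            self.trace, self.drug_event, min_span=self.stability_min_span,
            plateau_window=self.plateau_window, slope_tol=self.slope_tol,
        )
        points, warnings = segment_calibration_steps(
            self.trace, self.equilibration_discard, self.averaging_window,
            self.min_step_interval,
        )
        calibration = fit_step_calibration(points, warnings)
        estimate = estimate_temperature_shift(
            self.trace, calibration, self.baseline_window,
            self.response_window, drug_event=self.drug_event,
            stability_min_span=self.stability_min_span,
        )
        return MtyThermometryResults(
            model=self, estimate=estimate, calibration=calibration,
            step_points=points, diagnostics=dict(stability=stab_diag),
        )


@dataclass
class MtyThermometryResults:
    """Fitted MTY thermometry results for one trace."""

    model: MtyThermometry
    estimate: TemperatureShiftEstimate
    calibration: CalibrationFit
    step_points: list[tuple[float, float]]
    diagnostics: dict

    @property
    def delta_t(self) -> float:
        return self.estimate.delta_t

    @property
    def magnitude(self) -> float:
        return self.estimate.magnitude

    @property
    def stable(self) -> bool:
        return self.estimate.stable

    def rewarming(self, timepoints: list[float], smooth_window: float = 60.0):
        return quantify_rewarming(self.model.trace, self.calibration,
                                  self.model.drug_event, timepoints,
                                  smooth_window=smooth_window)

    def peak_magnitude(self, smooth_window: float = 60.0) -> float:
        return estimate_peak_shift(self.model.trace, self.calibration,
                                   self.model.drug_event,
                                   smooth_window=smooth_window)

    def to_dict(self) -> dict:
        est, cal = self.estimate, self.calibration
        return dict(
            method="MTY",
            delta_t_c=est.delta_t,
            magnitude_c=est.magnitude,
            stable=est.stable,
            extrapolated=est.extrapolated,
            baseline_window_s=list(est.baseline_window),
            response_window_s=list(est.response_window),
            calibration=dict(
                slope_au_per_c=cal.slope, intercept_au=cal.intercept,
                r_squared=cal.r_squared,
                temperature_range_c=list(cal.temperature_range),
                n_points=cal.n_points,
            ),
            warnings=est.warnings,
            diagnostics=self.diagnostics,
        )

    def summary(self) -> str:
        est, cal = self.estimate, self.calibration
        lines = [
            "MTY thermometry results",
            "=" * 46,
            f"temperature shift      {est.delta_t:+9.3f} °C",
            f"decrease magnitude     {est.magnitude:9.3f} °C",
            f"stable plateau         {est.stable}",
            f"calibration slope      {cal.slope:9.3f} AU/°C "
            f"(r² = {cal.r_squared:.4f}, n = {cal.n_points})",
            f"calibrated range       {cal.temperature_range[0]:.1f}–"
            f"{cal.temperature_range[1]:.1f} °C"
            + ("  [extrapolated]" if est.extrapolated else ""),
        ]
        for w in est.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Trace with analysis windows; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.model.trace
        ax.plot(tr.times / 60.0, tr.channels[0], lw=0.8, label="MTY fluorescence")
        for (a, b), color, lab in (
            (self.estimate.baseline_window, "tab:green", "baseline"),
            (self.estimate.response_window, "tab:red", "response"),
        ):
            ax.axvspan(a / 60.0, b / 60.0, alpha=0.2, color=color, label=lab)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("fluorescence (AU)")
        ax.legend(loc="best", fontsize="small")
        return ax
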