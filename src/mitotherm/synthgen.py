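"""Forward simulation of mitochondrial-thermometry experiments.

The generator produces every input the analysis pipelines consume:

* cuvette thermal dynamics — a Peltier setpoint protocol relaxed through a
  first-order lag (the cuvette takes ~2 min to equilibrate with the jacket);
* ground-truth mitochondrial temperature trajectories for the study's
  scenarios (OXPHOS-inhibitor cooling, substrate starvation and rescue,
  AOX-mediated rewarming, anisomycin transients);
* probe fluorescence rendering for the MTY dye (single channel, intensity
  falling with temperature) and the mito-gTEMP reporter pair (temperature
  -insensitive mT-Sapphire over temperature-sensitive Sirius);
* sub-mitochondrial fractionation readings with per-fraction
  autofluorescence backgrounds.

All randomness is seeded; at zero noise every rendering step is exactly
invertible by the corresponding analysis module, which is what makes
parameter-recovery testing possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .traces import CALIBRATION_EVENT, FluorescenceTrace

SCENARIO_NAMES = (
    "baseline",
    "inhibitor",
    "starvation",
    "substrate_rescue",
    "bka",
    "aox_inhibitor",
    "anisomycin",
)

#: fraction labels used throughout the fractionation accounting
MITOPLAST_SPLIT = ("mitoplast_pellet", "om_ims_supernatant")
SMP_SPLIT = ("smp_pellet", "matrix_supernatant")
FRACTION_SPLITS = {"mitoplast": MITOPLAST_SPLIT, "smp": SMP_SPLIT}


# ---------------------------------------------------------------------------
# thermal protocol and scenario
# ---------------------------------------------------------------------------

@dataclass
class TemperatureProtocol:
    """Peltier setpoint schedule with first-order cuvette lag.

    ``steps`` are ``(time_s, new_setpoint_c)`` pairs with strictly increasing
    times; the cuvette relaxes toward the current setpoint with time constant
    ``lag_time_constant`` (seconds). The default lag of 40 s puts ~3 time
    constants — practical equilibration — at about two minutes.
    """

    initial_setpoint: float
    steps: list[tuple[float, float]] = field(default_factory=list)
    lag_time_constant: float = 40.0

    def __post_init__(self) -> None:
        if self.lag_time_constant < 0:
            raise ValueError("lag_time_constant must be >= 0")
        times = [t for t, _ in self.steps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("step times must be strictly increasing")
        for sp in [self.initial_setpoint] + [s for _, s in self.steps]:
            if not 0.0 <= sp <= 60.0:
                raise ValueError(f"setpoint {sp} °C outside the [0, 60] °C range")

    def setpoint_track(self, times: np.ndarray) -> np.ndarray:
        """Setpoint active at each sample time (steps apply from their time on)."""
        track = np.full(times.shape, self.initial_setpoint, dtype=float)
        for t_step, sp in self.steps:
            track[times >= t_step] = sp
        return track


def build_peltier_trace(
    protocol: TemperatureProtocol, duration: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the cuvette temperature under a setpoint protocol.

    Exact first-order step response per sample:
    ``T[i+1] = S + (T[i] - S) * exp(-dt / tau)`` with ``S`` the setpoint in
    force over the interval. Zero lag reproduces the setpoint track exactly.

    Returns ``(times, cuvette_temperature)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if any(t >= duration for t, _ in protocol.steps):
        raise ValueError("protocol step beyond trace duration")
    times = np.arange(0.0, duration, dt)
    setpoints = protocol.setpoint_track(times)
    tau = protocol.lag_time_constant
    if tau == 0:
        return times, setpoints.copy()
    decay = math.exp(-dt / tau)
    temp = np.empty_like(setpoints)
    temp[0] = protocol.initial_setpoint  # cuvette equilibrated before the record
    for i in range(1, temp.size):
        s = setpoints[i]
        temp[i] = s + (temp[i - 1] - s) * decay
    return times, temp


@dataclass
class ThermalScenario:
    """Ground-truth thermal state of one simulated experiment.

    ``elevation(t)`` is the mitochondrial temperature elevation E(t) above the
    cuvette; the probe senses ``T_mito(t) = T_cuvette(t) + E(t)``.
    ``truth_drop`` records the configured elevation loss (signed; negative for
    a transient warming) so recovery tests can compare against it.
    """

    name: str
    ambient: float
    elevation: Callable[[np.ndarray], np.ndarray]
    protocol: TemperatureProtocol
    duration: float
    dt: float = 1.0
    events: list[tuple[float, str]] = field(default_factory=list)
    truth_drop: float = 0.0
    params: dict = field(default_factory=dict)

    def sample(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Times, setpoints, cuvette and sensed mitochondrial temperature."""
        times, cuvette = build_peltier_trace(self.protocol, self.duration, self.dt)
        setpoints = self.protocol.setpoint_track(times)
        elev = np.asarray(self.elevation(times), dtype=float)
        if np.any(elev < -1e-9):
            raise ValueError("scenario produced negative elevation")
        return times, setpoints, cuvette, cuvette + np.clip(elev, 0.0, None)


def mty_protocol(
    ambient: float = 37.0,
    cal_start: float = 2700.0,
    step_amplitude: float = 3.0,
    step_duration: float = 300.0,
    lag: float = 40.0,
) -> TemperatureProtocol:
    """Terminal ±step internal-calibration staircase: up, down, back to ambient."""
    return TemperatureProtocol(
        initial_setpoint=ambient,
        steps=[
            (cal_start, ambient + step_amplitude),
            (cal_start + step_duration, ambient - step_amplitude),
            (cal_start + 2 * step_duration, ambient),
        ],
        lag_time_constant=lag,
    )


def gtemp_staircase_protocol(
    ambient: float = 37.0,
    start: float = 900.0,
    low: float = 30.0,
    high: float = 42.0,
    step: float = 3.0,
    step_duration: float = 180.0,
    lag: float = 40.0,
) -> TemperatureProtocol:
    """In-vivo ratio-calibration staircase: shift to ``low`` then climb to ``high``."""
    temps = np.arange(low, high + 0.5 * step, step)
    steps = [(start + i * step_duration, float(T)) for i, T in enumerate(temps)]
    return TemperatureProtocol(ambient, steps, lag_time_constant=lag)


def constant_protocol(ambient: float = 37.0, lag: float = 40.0) -> TemperatureProtocol:
    return TemperatureProtocol(ambient, [], lag_time_constant=lag)


# --- scenario builders -----------------------------------------------------

_AOX_PRESETS = {
    # per-inhibitor rewarming kinetics; the study reports only qualitative
    # differences, so amplitudes/time constants are modelling choices
    "rotenone": dict(rewarm_tau=1800.0, rewarm_fraction=1.0),
    "antimycin": dict(rewarm_tau=1500.0, rewarm_fraction=0.7),
    "kcn": dict(rewarm_tau=1500.0, rewarm_fraction=0.6),
}


def build_scenario(
    name: str,
    params: dict | None = None,
    protocol: TemperatureProtocol | None = None,
) -> ThermalScenario:
    """Construct a ground-truth scenario by name.

    Supported names: ``baseline``, ``inhibitor``, ``starvation``,
    ``substrate_rescue``, ``bka``, ``aox_inhibitor``, ``anisomycin``.
    ``params`` overrides the scenario's defaults; ``protocol`` overrides the
    default Peltier schedule (terminal ±3 °C staircase for MTY-style
    scenarios, constant for starvation-type records).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    p = dict(params or {})
    ambient = float(p.pop("ambient", 37.0))
    dt = float(p.pop("dt", 1.0))
    builder = _SCENARIO_BUILDERS[name]
    return builder(name, ambient, dt, p, protocol)


def _require_nonneg(value: float, what: str) -> float:
    if value < 0:
        raise ValueError(f"{what} must be non-negative, got {value}")
    return float(value)


def _baseline(name, ambient, dt, p, protocol):
    e0 = _require_nonneg(p.pop("initial_elevation", 16.0), "initial elevation")
    duration = float(p.pop("duration", 3600.0))
    proto = protocol or mty_protocol(ambient)
    return ThermalScenario(
        name, ambient, lambda t: np.full(np.shape(t), e0), proto, duration, dt,
        events=[], truth_drop=0.0, params=dict(initial_elevation=e0),
    )


def _inhibitor(name, ambient, dt, p, protocol):
    e0 = _require_nonneg(p.pop("initial_elevation", 18.0), "initial elevation")
    residual = _require_nonneg(p.pop("residual_elevation", 0.0), "residual elevation")
    if residual > e0:
        raise ValueError("residual elevation exceeds initial elevation")
    t_drug = float(p.pop("drug_time", 600.0))
    tau = _require_nonneg(p.pop("decay_tau", 180.0), "decay time constant")
    drug = str(p.pop("inhibitor", "oligomycin"))
    duration = float(p.pop("duration", 3600.0))

    def elev(t):
        t = np.asarray(t, dtype=float)
        rel = np.clip(t - t_drug, 0.0, None)
        dec = np.exp(-rel / tau) if tau > 0 else (rel == 0).astype(float)
        return residual + (e0 - residual) * np.where(t < t_drug, 1.0, dec)

    proto = protocol or mty_protocol(ambient)
    return ThermalScenario(
        name, ambient, elev, proto, duration, dt,
        events=[(t_drug, drug)], truth_drop=e0 - residual,
        params=dict(initial_elevation=e0, residual_elevation=residual,
                    drug_time=t_drug, decay_tau=tau, inhibitor=drug),
    )


def _starvation(name, ambient, dt, p, protocol):
    e_peak = _require_nonneg(p.pop("peak_elevation", 16.5), "peak elevation")
    rise_tau = _require_nonneg(p.pop("rise_tau", 150.0), "rise time constant")
    t_peak = float(p.pop("peak_time", 600.0))
    drop = _require_nonneg(p.pop("decline_drop", 4.0), "decline drop")
    t_ref = float(p.pop("reference_time", 2100.0))
    duration = float(p.pop("duration", 2100.0))
    rate = drop / (t_ref - t_peak)
    e_at_peak = e_peak * (1.0 - math.exp(-t_peak / rise_tau)) if rise_tau else e_peak

    def elev(t):
        t = np.asarray(t, dtype=float)
        rise = e_peak * (1.0 - np.exp(-t / rise_tau)) if rise_tau else np.full(t.shape, e_peak)
        decline = e_at_peak - rate * (t - t_peak)
        return np.clip(np.where(t <= t_peak, rise, decline), 0.0, None)

    proto = protocol or constant_protocol(ambient)
    return ThermalScenario(
        name, ambient, elev, proto, duration, dt,
        events=[(0.0, "resuspension")], truth_drop=drop,
        params=dict(peak_elevation=e_peak, rise_tau=rise_tau, peak_time=t_peak,
                    decline_drop=drop, reference_time=t_ref),
    )


def _substrate_rescue(name, ambient, dt, p, protocol):
    e_peak = _require_nonneg(p.pop("peak_elevation", 18.0), "peak elevation")
    rise_tau = _require_nonneg(p.pop("rise_tau", 150.0), "rise time constant")
    t_sub = float(p.pop("substrate_time", 600.0))
    deficit = _require_nonneg(p.pop("recovery_deficit", 2.0), "recovery deficit")
    rec_tau = _require_nonneg(p.pop("recovery_tau", 300.0), "recovery time constant")
    duration = float(p.pop("duration", 2100.0))
    e_target = max(e_peak - deficit, 0.0)
    e_at_sub = e_peak * (1.0 - math.exp(-t_sub / rise_tau)) if rise_tau else e_peak

    def elev(t):
        t = np.asarray(t, dtype=float)
        rise = e_peak * (1.0 - np.exp(-t / rise_tau)) if rise_tau else np.full(t.shape, e_peak)
        rel = np.clip(t - t_sub, 0.0, None)
        settle = e_target + (e_at_sub - e_target) * np.exp(-rel / rec_tau)
        return np.clip(np.where(t <= t_sub, rise, settle), 0.0, None)

    proto = protocol or constant_protocol(ambient)
    return ThermalScenario(
        name, ambient, elev, proto, duration, dt,
        events=[(0.0, "resuspension"), (t_sub, "substrate")], truth_drop=deficit,
        params=dict(peak_elevation=e_peak, substrate_time=t_sub,
                    recovery_deficit=deficit, recovery_tau=rec_tau),
    )


def _bka(name, ambient, dt, p, protocol):
    p.setdefault("initial_elevation", 16.5)
    p.setdefault("drug_time", 660.0)  # addition at 11 min
    p.setdefault("decay_tau", 600.0)
    drop = _require_nonneg(p.pop("drop", 5.0), "elevation drop")
    e0 = float(p["initial_elevation"])
    if drop > e0:
        raise ValueError("drop exceeds initial elevation")
    p["residual_elevation"] = e0 - drop
    p.setdefault("inhibitor", "bka")
    p.setdefault("duration", 2100.0)
    if protocol is None:
        protocol = constant_protocol(ambient)
    scn = _inhibitor(name, ambient, dt, p, protocol)
    scn.params["drop"] = drop
    return scn


def _aox_inhibitor(name, ambient, dt, p, protocol):
    drug = str(p.pop("inhibitor", "rotenone"))
    preset = _AOX_PRESETS.get(drug, _AOX_PRESETS["rotenone"])
    e0 = _require_nonneg(p.pop("initial_elevation", 16.0), "initial elevation")
    drop = _require_nonneg(p.pop("drop", 10.0), "elevation drop")
    if drop > e0:
        raise ValueError("drop exceeds initial elevation (negative elevation requested)")
    t_drug = float(p.pop("drug_time", 600.0))
    tau = _require_nonneg(p.pop("decay_tau", 180.0), "decay time constant")
    delay = _require_nonneg(p.pop("rewarm_delay", 900.0), "rewarming delay")
    rew_tau = _require_nonneg(p.pop("rewarm_tau", preset["rewarm_tau"]), "rewarming tau")
    frac = float(p.pop("rewarm_fraction", preset["rewarm_fraction"]))
    duration = float(p.pop("duration", 7200.0))

    def elev(t):
        t = np.asarray(t, dtype=float)
        rel = np.clip(t - t_drug, 0.0, None)
        cooling = drop * (1.0 - np.exp(-rel / tau))
        rel_r = np.clip(t - t_drug - delay, 0.0, None)
        rewarm = frac * drop * (1.0 - np.exp(-rel_r / rew_tau))
        return np.clip(np.minimum(e0 - cooling + rewarm, e0), 0.0, None)

    proto = protocol or mty_protocol(ambient, cal_start=6000.0)
    return ThermalScenario(
        name, ambient, elev, proto, duration, dt,
        events=[(t_drug, drug)], truth_drop=drop,
        params=dict(initial_elevation=e0, drop=drop, drug_time=t_drug,
                    decay_tau=tau, rewarm_delay=delay, rewarm_tau=rew_tau,
                    rewarm_fraction=frac, inhibitor=drug),
    )


def _anisomycin(name, ambient, dt, p, protocol):
    e0 = _require_nonneg(p.pop("initial_elevation", 16.0), "initial elevation")
    amp = _require_nonneg(p.pop("amplitude", 5.2), "bump amplitude")
    t_drug = float(p.pop("drug_time", 600.0))
    rise_tau = max(_require_nonneg(p.pop("rise_tau", 300.0), "rise tau"), 1e-9)
    decay_tau = max(_require_nonneg(p.pop("decay_tau", 4000.0), "decay tau"), 1e-9)
    duration = float(p.pop("duration", 7200.0))

    def bump(x):
        return amp * (1.0 - np.exp(-x / rise_tau)) * np.exp(-x / decay_tau)

    x_star = rise_tau * math.log(1.0 + decay_tau / rise_tau)
    peak_rise = float(bump(np.array([x_star]))[0])

    def elev(t):
        t = np.asarray(t, dtype=float)
        rel = np.clip(t - t_drug, 0.0, None)
        return e0 + np.where(t < t_drug, 0.0, bump(rel))

    proto = protocol or mty_protocol(ambient, cal_start=6000.0)
    return ThermalScenario(
        name, ambient, elev, proto, duration, dt,
        events=[(t_drug, "anisomycin")], truth_drop=-peak_rise,
        params=dict(initial_elevation=e0, amplitude=amp, drug_time=t_drug,
                    rise_tau=rise_tau, decay_tau=decay_tau, peak_rise=peak_rise),
    )


_SCENARIO_BUILDERS = {
    "baseline": _baseline,
    "inhibitor": _inhibitor,
    "starvation": _starvation,
    "substrate_rescue": _substrate_rescue,
    "bka": _bka,
    "aox_inhibitor": _aox_inhibitor,
    "anisomycin": _anisomycin,
}


# ---------------------------------------------------------------------------
# probe models and trace rendering
# ---------------------------------------------------------------------------

@dataclass
class MtyProbeModel:
    """Mito Thermo Yellow rendering model.

    Fluorescence falls approximately linearly with sensed temperature:
    ``F = quench_factor * gain * (1 - relative_slope*(T - T_ref)
    - curvature*(T - T_ref)**2) * exp(-bleach_rate*t) + autofluorescence``.
    ``leakage`` adds an unbounded slow post-drug rise (dye leaking back into
    the medium), the artifact that makes some drug/cell-line combinations
    uncalibratable.
    """

    gain: float = 1000.0
    relative_slope: float = 0.01      # fraction per °C
    reference_temperature: float = 37.0
    autofluorescence: float = 50.0
    bleach_rate: float = 0.0          # per second
    leakage: bool = False
    leak_rate: float = 0.01           # fraction of gain per minute, when leaking
    quench_factor: float = 1.0
    curvature: float = 0.0            # optional mild nonlinearity, per °C²; off by default

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 0.0 < self.relative_slope < 0.1:
            raise ValueError("relative_slope must lie in (0, 0.1) per °C")
        if self.autofluorescence < 0 or self.bleach_rate < 0:
            raise ValueError("autofluorescence and bleach_rate must be >= 0")
        if self.quench_factor <= 0:
            raise ValueError("quench_factor must be positive")

    def response(self, temperature: np.ndarray) -> np.ndarray:
        """Noise-free, bleach-free fluorescence at the given sensed temperature."""
        dT = np.asarray(temperature, dtype=float) - self.reference_temperature
        shape = 1.0 - self.relative_slope * dT - self.curvature * dT**2
        return self.quench_factor * self.gain * shape + self.autofluorescence


@dataclass
class GtempProbeModel:
    """mito-gTEMP (mT-Sapphire / Sirius) rendering model.

    mT-Sapphire is temperature-insensitive; Sirius brightness falls with
    temperature, modelled reciprocal-linearly so the channel ratio is exactly
    affine in temperature: with zero backgrounds
    ``R(T) = sapphire_gain * (1 + sirius_slope*(T - T_ref))``.
    """

    expression: float = 1000.0        # per-trial expression level, AU
    sirius_slope: float = 0.02        # fraction per °C
    sapphire_gain: float = 1.0
    reference_temperature: float = 37.0
    channel_backgrounds: tuple[float, float] = (0.0, 0.0)   # (A_sap, A_sir)
    drug_background_shift: tuple[float, float] = (0.0, 0.0)  # applied to blanks

    def __post_init__(self) -> None:
        if self.expression <= 0:
            raise ValueError("expression must be positive")
        if self.sirius_slope <= 0:
            raise ValueError("sirius_slope must be positive")
        if any(b < 0 for b in self.channel_backgrounds):
            raise ValueError("channel backgrounds must be >= 0")

    def ratio_line(self) -> tuple[float, float]:
        """(intercept, slope) of the background-free ratio-vs-temperature line."""
        c1 = self.sapphire_gain * self.sirius_slope
        c0 = self.sapphire_gain * (1.0 - self.sirius_slope * self.reference_temperature)
        return c0, c1

    def channels(self, temperature: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dT = np.asarray(temperature, dtype=float) - self.reference_temperature
        denom = 1.0 + self.sirius_slope * dT
        if np.any(denom <= 0):
            raise ValueError("temperature out of the probe's physical range")
        a_sap, a_sir = self.channel_backgrounds
        f_sap = np.full(dT.shape, self.expression * self.sapphire_gain + a_sap)
        f_sir = self.expression / denom + a_sir
        return f_sap, f_sir


def _scenario_events(scenario: ThermalScenario) -> list[tuple[float, str]]:
    events = list(scenario.events)
    events += [(t, CALIBRATION_EVENT) for t, _ in scenario.protocol.steps]
    return sorted(events)


def render_mty_trace(
    scenario: ThermalScenario,
    probe: MtyProbeModel | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FluorescenceTrace:
    """Render a single-channel MTY fluorescence trace from a scenario.

    ``noise_sd`` is the per-sample Gaussian noise SD as a fraction of the
    probe gain. Raises if the configured parameters produce a negative
    intensity anywhere (unphysical).
    """
    probe = probe or MtyProbeModel()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times, setpoints, _, t_mito = scenario.sample()
    f = probe.response(t_mito)
    if probe.bleach_rate:
        f = (f - probe.autofluorescence) * np.exp(-probe.bleach_rate * times) \
            + probe.autofluorescence
    if probe.leakage:
        drug_times = [t for t, lab in scenario.events if lab != CALIBRATION_EVENT]
        t_drug = min(drug_times) if drug_times else 0.0
        ramp = probe.leak_rate * probe.gain / 60.0 * np.clip(times - t_drug, 0.0, None)
        f = f + ramp
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd * probe.gain, size=f.shape)
    if np.any(f < 0):
        raise ValueError("rendered intensity negative — probe parameters unphysical")
    meta = dict(
        ambient=scenario.ambient, scenario=scenario.name, seed=seed,
        truth_drop=scenario.truth_drop, noise_sd=noise_sd, method="MTY",
        inhibitor=scenario.params.get("inhibitor"),
    )
    return FluorescenceTrace(times, f[np.newaxis, :], setpoints,
                             _scenario_events(scenario), meta)


def render_gtemp_trace(
    scenario: ThermalScenario,
    probe: GtempProbeModel | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FluorescenceTrace:
    """Render a two-channel (mT-Sapphire, Sirius) mito-gTEMP trace."""
    probe = probe or GtempProbeModel()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times, setpoints, _, t_mito = scenario.sample()
    f_sap, f_sir = probe.channels(t_mito)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f_sap = f_sap + rng.normal(0.0, noise_sd * probe.expression, size=f_sap.shape)
        f_sir = f_sir + rng.normal(0.0, noise_sd * probe.expression, size=f_sir.shape)
    stacked = np.vstack([f_sap, f_sir])
    if np.any(stacked < 0):
        raise ValueError("rendered intensity negative — probe parameters unphysical")
    meta = dict(
        ambient=scenario.ambient, scenario=scenario.name, seed=seed,
        truth_drop=scenario.truth_drop, noise_sd=noise_sd, method="GTEMP",
        inhibitor=scenario.params.get("inhibitor"),
    )
    return FluorescenceTrace(times, stacked, setpoints,
                             _scenario_events(scenario), meta)


def render_gtemp_blank(
    probe: GtempProbeModel,
    with_drug: bool,
    duration: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ambient: float = 37.0,
) -> FluorescenceTrace:
    """Cell-free blank for drug-background QC.

    Channels carry only the configured backgrounds, plus the probe's
    ``drug_background_shift`` when ``with_drug`` is true. Relative noise is
    taken against each channel's background level.
    """
    a_sap, a_sir = probe.channel_backgrounds
    if a_sap <= 0 or a_sir <= 0:
        raise ValueError("blank rendering needs positive channel backgrounds")
    d_sap, d_sir = probe.drug_background_shift if with_drug else (0.0, 0.0)
    times = np.arange(0.0, duration, dt)
    rng = np.random.default_rng(seed)
    f_sap = np.full(times.shape, a_sap + d_sap)
    f_sir = np.full(times.shape, a_sir + d_sir)
    if noise_sd > 0:
        f_sap = f_sap + rng.normal(0.0, noise_sd * (a_sap + d_sap), times.shape)
        f_sir = f_sir + rng.normal(0.0, noise_sd * (a_sir + d_sir), times.shape)
    stacked = np.clip(np.vstack([f_sap, f_sir]), 0.0, None)
    meta = dict(blank=True, with_drug=with_drug, seed=seed, method="GTEMP")
    return FluorescenceTrace(times, stacked, np.full(times.shape, ambient),
                             [], meta)


# ---------------------------------------------------------------------------
# fractionation
# ---------------------------------------------------------------------------

@dataclass
class FractionationExperiment:
    """Labelled/unlabelled fluorescence readings per sub-mitochondrial fraction.

    ``readings`` is a tidy table with columns ``trial``, ``fraction``,
    ``labelled_AU``, ``unlabelled_AU``; fractions come in the two pellet /
    supernatant splits (mitoplast vs OM/IMS, then SMP vs matrix), both splits
    of a trial drawn from the same simulated mitochondrial pool.
    """

    readings: pd.DataFrame
    n_trials: int

    def __post_init__(self) -> None:
        required = {"trial", "fraction", "labelled_AU", "unlabelled_AU"}
        missing = required - set(self.readings.columns)
        if missing:
            raise ValueError(f"fractionation table missing columns {sorted(missing)}")
        if (self.readings[["labelled_AU", "unlabelled_AU"]] < 0).any().any():
            raise ValueError("fluorescence readings must be non-negative")

    def split_readings(self, split: str) -> pd.DataFrame:
        pellet, supernatant = FRACTION_SPLITS[split]
        sub = self.readings[self.readings["fraction"].isin([pellet, supernatant])]
        return sub.copy()


def simulate_fractionation(
    retention_mitoplast: float,
    retention_smp: float,
    autofluorescence_levels: dict[str, float] | float = 0.0,
    noise_sd: float = 0.0,
    n_trials: int = 2,
    seed: int | None = None,
    pool: float = 1000.0,
) -> FractionationExperiment:
    """Simulate the two-step fractionation fluorescence readings.

    Step 1 splits the labelled pool between the mitoplast pellet (fraction
    ``retention_mitoplast``) and the OM/IMS supernatant; step 2 sonicates the
    mitoplast material and splits it between SMP pellet (``retention_smp``)
    and matrix supernatant. Labelled readings are signal + fraction
    autofluorescence; unlabelled readings are autofluorescence alone; noise
    is Gaussian with SD ``noise_sd`` × the noise-free reading.
    """
    for r, what in ((retention_mitoplast, "retention_mitoplast"),
                    (retention_smp, "retention_smp")):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{what} must lie in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    fractions = list(MITOPLAST_SPLIT) + list(SMP_SPLIT)
    if isinstance(autofluorescence_levels, dict):
        auto = {f: float(autofluorescence_levels.get(f, 0.0)) for f in fractions}
    else:
        auto = {f: float(autofluorescence_levels) for f in fractions}
    if any(v < 0 for v in auto.values()):
        raise ValueError("autofluorescence levels must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(1, n_trials + 1):
        mito_pool = pool
        signal = {
            MITOPLAST_SPLIT[0]: retention_mitoplast * mito_pool,
            MITOPLAST_SPLIT[1]: (1.0 - retention_mitoplast) * mito_pool,
        }
        smp_pool = signal[MITOPLAST_SPLIT[0]]
        signal[SMP_SPLIT[0]] = retention_smp * smp_pool
        signal[SMP_SPLIT[1]] = (1.0 - retention_smp) * smp_pool
        for frac in fractions:
            labelled = signal[frac] + auto[frac]
            unlabelled = auto[frac]
            if noise_sd > 0:
                labelled += rng.normal(0.0, noise_sd * labelled)
                unlabelled += rng.normal(0.0, noise_sd * unlabelled) if unlabelled else 0.0
            rows.append(dict(trial=trial, fraction=frac,
                             labelled_AU=max(labelled, 0.0),
                             unlabelled_AU=max(unlabelled, 0.0)))
    return FractionationExperiment(pd.DataFrame(rows), n_trials=n_trials)
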