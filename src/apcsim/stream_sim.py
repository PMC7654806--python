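"""Synthetic larva streams and the sensor traces they produce.

Ground truth is a list of arrival events (a larva's leading edge reaching
the sensor window).  Arrivals follow a Poisson process — the reservoir is
stirred, so larvae reach the capillary independently at a rate set by
concentration x flow.  The sampled light-intensity series is then built
from a baseline with optional linear drift and Gaussian sensor noise, from
which each passing particle subtracts a rectangular occlusion pulse: the
diagnostic traces the device exports show near-rectangular below-baseline
peaks only ~20 samples wide, so no finer pulse shape is warranted (a
1-sample linear ramp can be enabled to soften edges).

Detection operates on the *deviation* (baseline - sample): larvae block
light, so a deeper dip is a larger deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .hydraulics import (
    CapillaryGeometry,
    DEFAULT_GEOMETRY,
    HydraulicState,
    drain_step,
    stream_velocity,
)

__all__ = [
    "ArrivalModel",
    "LarvaEvent",
    "NoiseModel",
    "SensorTrace",
    "generate_arrivals",
    "generate_contaminants",
    "synthesize_trace",
    "trace_is_calibrated",
]


@dataclass(frozen=True)
class LarvaEvent:
    """One larva's passage: arrival time (s), occlusion depth, body length (mm)."""

    arrival_time: float
    amplitude: float
    body_length: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")


@dataclass(frozen=True)
class ContaminantEvent:
    """A short, shallow dip from debris (food particles, eggshells) or an
    electronic glitch."""

    arrival_time: float
    amplitude: float
    duration_ms: float = 0.5


@dataclass
class ArrivalModel:
    """Arrival process configuration.

    ``lps`` is the mean throughput in larvae per second.  In ``"fixed"``
    mode the Poisson rate is constant; in ``"depletion"`` mode the rate is
    concentration x instantaneous flow, so it declines as the reservoir
    drains.  Occlusion amplitudes are truncated-normal: mean 100, sd 20,
    floor 10 intensity units.  With sensor noise sd ~6 these defaults make
    detection clean for trigger thresholds of 2.5-6 baseline standard
    deviations while thresholds of 7-8 start to miss the weakest pulses.

    ``contaminant_rate`` (events/sec, default 0) adds debris pulses with
    exponentially distributed amplitude ``contaminant_amp_mean`` and fixed
    short duration ``contaminant_duration_ms``.
    """

    lps: float = 25.0
    mode: str = "fixed"  # "fixed" | "depletion"
    duration: float = 10.0
    seed: Optional[int] = None
    amplitude_mean: float = 100.0
    amplitude_sd: float = 20.0
    amplitude_floor: float = 10.0
    body_length: float = 1.0
    contaminant_rate: float = 0.0
    contaminant_amp_mean: float = 30.0
    contaminant_duration_ms: float = 0.5

    def __post_init__(self) -> None:
        if self.lps < 0:
            raise ValueError("lps must be non-negative")
        if self.mode not in ("fixed", "depletion"):
            raise ValueError(f"unknown arrival mode {self.mode!r}")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")


@dataclass
class NoiseModel:
    """Sensor baseline and noise.

    ``baseline`` is the clear-water light reading; ``noise_std`` the
    per-sample Gaussian sd; ``drift_rate`` a slow linear baseline change
    (units/sec) emulating changing water absorbance.  The device is
    calibrated until the sensor-value sd is below ``calibration_limit``
    (18 units); traces violating that are flagged uncalibrated.
    """

    baseline: float = 500.0
    noise_std: float = 6.0
    drift_rate: float = 0.0
    calibration_limit: float = 18.0

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


@dataclass
class SensorTrace:
    """A sampled light-intensity series plus its ground truth.

    ``sampling_rate`` is in samples per msec (device: ~10, i.e. 10 kHz).
    ``intensities`` is the raw sensor series, floored at 0 (full
    occlusion).  ``truth`` and ``contaminant_truth`` are the events the
    series was built from.
    """

    sampling_rate: float
    intensities: np.ndarray
    truth: List[LarvaEvent] = field(default_factory=list)
    contaminant_truth: List[ContaminantEvent] = field(default_factory=list)
    baseline: float = 500.0

    def __len__(self) -> int:
        return len(self.intensities)

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.intensities)) * self.dt_ms

    @property
    def duration_s(self) -> float:
        return len(self.intensities) / (self.sampling_rate * 1000.0)


def _rng(seed: Optional[int | np.random.SeedSequence | np.random.Generator]):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float, n: int) -> np.ndarray:
    """Truncated-normal draws by rejection (truncation point well below
    the mean for the defaults, so rejection is cheap)."""
    if n == 0:
        return np.empty(0)
    if sd == 0:
        if mean < floor:
            raise ValueError("degenerate amplitude distribution below floor")
        return np.full(n, float(mean))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[draw >= floor]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_arrivals(model: ArrivalModel,
                      hydraulic: Optional[HydraulicState] = None,
                      rng: Optional[np.random.Generator] = None) -> List[LarvaEvent]:
    """Draw ground-truth larva arrivals over ``model.duration`` seconds.

    Fixed-rate mode is a homogeneous Poisson process at ``model.lps``.
    Depletion-coupled mode thins a homogeneous process at the initial rate
    down to rate(t) = concentration x flow(t), with flow evaluated on a
    draining copy of ``hydraulic`` — the rate never increases over a run.
    """
    rng = _rng(rng if rng is not None else model.seed)
    if model.lps == 0 or model.duration == 0:
        return []
    if model.mode == "fixed":
        times = _homogeneous_arrivals(rng, model.lps, model.duration)
    else:
        if hydraulic is None:
            raise ValueError("depletion mode requires a HydraulicState")
        times = _depletion_arrivals(rng, model, hydraulic)
    amps = _truncated_normal(rng, model.amplitude_mean, model.amplitude_sd,
                             model.amplitude_floor, len(times))
    return [LarvaEvent(float(t), float(a), model.body_length)
            for t, a in zip(times, amps)]


def _homogeneous_arrivals(rng: np.random.Generator, rate: float,
                          duration: float) -> np.ndarray:
    # sequential exponential gaps: the event prefix is invariant when the
    # horizon is extended, which run_dispense relies on
    times = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        times.append(t)
        t += rng.exponential(1.0 / rate)
    return np.asarray(times)


def _depletion_arrivals(rng: np.random.Generator, model: ArrivalModel,
                        hydraulic: HydraulicState) -> np.ndarray:
    q0 = hydraulic.flow
    if q0 <= 0:
        return np.empty(0)
    conc = model.lps / q0  # larvae/ml pinned to the configured initial LPS
    # flow trajectory on a coarse grid (head moves slowly)
    grid_dt = 0.05
    n_steps = int(np.ceil(model.duration / grid_dt)) + 1
    flows = np.empty(n_steps)
    state = hydraulic
    for i in range(n_steps):
        flows[i] = state.flow
        state = drain_step(state, grid_dt)
    # Ogata thinning against the (maximal) initial rate
    rate_max = conc * q0
    times = []
    t = rng.exponential(1.0 / rate_max)
    while t < model.duration:
        rate_t = conc * flows[min(int(t / grid_dt), n_steps - 1)]
        if rng.uniform() < rate_t / rate_max:
            times.append(t)
        t += rng.exponential(1.0 / rate_max)
    return np.asarray(times)


def generate_contaminants(model: ArrivalModel,
                          rng: Optional[np.random.Generator] = None
                          ) -> List[ContaminantEvent]:
    """Poisson debris events at ``model.contaminant_rate`` per second."""
    rng = _rng(rng if rng is not None else model.seed)
    if model.contaminant_rate <= 0 or model.duration == 0:
        return []
    times = _homogeneous_arrivals(rng, model.contaminant_rate, model.duration)
    amps = rng.exponential(model.contaminant_amp_mean, size=len(times))
    return [ContaminantEvent(float(t), float(a), model.contaminant_duration_ms)
            for t, a in zip(times, amps)]


def synthesize_trace(events: Sequence[LarvaEvent],
                     noise: NoiseModel,
                     geometry: CapillaryGeometry = DEFAULT_GEOMETRY,
                     hydraulic: Optional[HydraulicState] = None,
                     *,
                     velocity: Optional[float] = None,
                     duration: Optional[float] = None,
                     sampling_rate: float = 10.0,
                     contaminants: Sequence[ContaminantEvent] = (),
                     ramp_samples: int = 0,
                     rng: Optional[np.random.Generator] = None,
                     seed: Optional[int] = None) -> SensorTrace:
    """Build the sampled intensity series for a set of arrival events.

    Each larva occludes the window for (sensor_window + body_length) /
    velocity, subtracting a rectangular dip of its amplitude; overlapping
    larvae superimpose additively and the series is floored at 0 (full
    occlusion).  Contaminants subtract shorter dips of their own duration.
    ``velocity`` (mm/s) may be given directly or derived from
    ``hydraulic.flow`` and the capillary bore.

    Raises if events are present but the stream is stationary.
    """
    if velocity is None:
        if hydraulic is None:
            raise ValueError("need either velocity or a HydraulicState")
        velocity = stream_velocity(hydraulic.flow, geometry.inner_diameter)
    if (len(events) or len(contaminants)) and velocity <= 0:
        raise ValueError("zero stream velocity with pending events")
    if any(events[i].arrival_time > events[i + 1].arrival_time
           for i in range(len(events) - 1)):
        raise ValueError("events must be sorted by arrival time")

    if duration is None:
        last = 0.0
        if events:
            last = max(last, events[-1].arrival_time)
        if contaminants:
            last = max(last, max(c.arrival_time for c in contaminants))
        duration = last + 0.01
    n = int(round(duration * sampling_rate * 1000.0))
    dt_s = 1.0 / (sampling_rate * 1000.0)
    rng = _rng(rng if rng is not None else seed)

    t = np.arange(n) * dt_s
    series = np.full(n, noise.baseline, dtype=float)
    if noise.drift_rate:
        series += noise.drift_rate * t
    if noise.noise_std > 0:
        series += rng.normal(0.0, noise.noise_std, size=n)

    occlusion = np.zeros(n)
    for ev in events:
        width_s = (geometry.sensor_window + ev.body_length) / velocity
        _add_pulse(occlusion, ev.arrival_time, width_s, ev.amplitude,
                   dt_s, ramp_samples)
    for c in contaminants:
        _add_pulse(occlusion, c.arrival_time, c.duration_ms / 1000.0,
                   c.amplitude, dt_s, ramp_samples)
    series -= occlusion
    np.maximum(series, 0.0, out=series)
    return SensorTrace(sampling_rate=sampling_rate, intensities=series,
                       truth=list(events), contaminant_truth=list(contaminants),
                       baseline=noise.baseline)


def _add_pulse(occlusion: np.ndarray, start_s: float, width_s: float,
               amplitude: float, dt_s: float, ramp_samples: int) -> None:
    i0 = int(np.ceil(start_s / dt_s))
    i1 = int(np.ceil((start_s + width_s) / dt_s))
    i0 = max(i0, 0)
    i1 = min(i1, len(occlusion))
    if i1 <= i0:
        return
    occlusion[i0:i1] += amplitude
    if ramp_samples > 0:
        for k in range(1, ramp_samples + 1):
            frac = amplitude * (ramp_samples + 1 - k) / (ramp_samples + 1)
            if i0 - k >= 0:
                occlusion[i0 - k] += frac
            if i1 + k - 1 < len(occlusion):
                occlusion[i1 + k - 1] += frac


def trace_is_calibrated(trace: SensorTrace, noise: NoiseModel,
                        window: int = 500) -> bool:
    """Check the device's calibration gate: rolling intensity sd below
    ``noise.calibration_limit`` everywhere outside pulses."""
    quiet = np.ones(len(trace), dtype=bool)
    dt_s = trace.dt_ms / 1000.0
    for ev in trace.truth:
        i0 = max(int(ev.arrival_time / dt_s) - 2, 0)
        i1 = min(int((ev.arrival_time + 0.01) / dt_s) + 2, len(trace))
        quiet[i0:i1] = False
    for c in trace.contaminant_truth:
        i0 = max(int(c.arrival_time / dt_s) - 2, 0)
        i1 = min(int((c.arrival_time + c.duration_ms / 1000.0) / dt_s) + 2,
                 len(trace))
        quiet[i0:i1] = False
    x = trace.intensities
    for start in range(0, len(x) - window + 1, window):
        block = slice(start, start + window)
        if quiet[block].all():
            if np.std(x[block]) >= noise.calibration_limit:
                return False
    return True
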