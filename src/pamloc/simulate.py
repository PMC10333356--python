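"""Multichannel rendering of positioned sources on a hydrophone array.

Propagation follows a near-field spherical-spreading model: each source's
waveform arrives at each hydrophone delayed by the exact source-hydrophone
distance over the sound speed (fractional-sample accurate, windowed-sinc
interpolation) and attenuated by 20*log10(range) transmission loss.
Levels are expressed in dB re 1 uPa; ``calibration_db`` maps that physical
scale onto digital full scale (a level equal to ``calibration_db`` at the
hydrophone renders with amplitude 1.0).  Samples outside [-1, 1] are
hard-clipped and the clipped fraction is reported, never silent.

Interfering noise is rendered as positioned point sources by design, so a
localizer can lock onto an interfering vessel exactly as it would in the
field; an optional diffuse (uncorrelated per-channel) noise term exists
but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0 as _bessel_i0

from .geometry import Bearing, HydrophoneArray, bearing_to_unit_vector
from .signals import Waveform

__all__ = [
    "SimulationError",
    "SourceSpec",
    "Scenario",
    "MultichannelAudio",
    "slant_range",
    "source_xyz",
    "received_level",
    "scenario_snr",
    "render",
    "fractional_delay_kernel",
]

MIN_SOURCE_DISTANCE = 0.1  # m; sources closer to a hydrophone are invalid


class SimulationError(ValueError):
    """Invalid scenario or rendering request."""


@dataclass(frozen=True)
class SourceSpec:
    """One emitting source.

    ``position`` is (bearing azimuth deg, horizontal range m, depth m)
    relative to the array center; ``source_level`` is in dB re 1 uPa p-p
    at 1 m; ``onset`` is the emission time in seconds.
    """

    waveform: Waveform
    source_level: float
    position: tuple[float, float, float]
    onset: float = 0.0

    def __post_init__(self) -> None:
        _, rng, depth = self.position
        if rng <= 0:
            raise SimulationError("horizontal range must be positive")
        if depth < 0:
            raise SimulationError("depth must be >= 0")
        if not np.isfinite(self.source_level):
            raise SimulationError("source_level must be finite")


@dataclass(frozen=True)
class Scenario:
    """A full simulated scene: array, target sources, interferences."""

    array: HydrophoneArray
    sources: tuple[SourceSpec, ...]
    interferences: tuple[SourceSpec, ...] = ()
    duration: float = 5.0
    sample_rate: float = 48_000.0
    sound_speed: float = 1500.0
    calibration_db: float = 170.0
    seed: int = 0
    diffuse_noise_db: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "interferences", tuple(self.interferences))
        if self.sound_speed <= 0:
            raise SimulationError("sound_speed must be positive")
        for s in self.sources + self.interferences:
            if s.onset + s.waveform.duration > self.duration + 1e-9:
                raise SimulationError(
                    "scenario duration does not cover source onset + length"
                )


@dataclass(frozen=True)
class MultichannelAudio:
    """Synchronized per-hydrophone streams, float full-scale [-1, 1]."""

    channels: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        ch = np.atleast_2d(np.asarray(self.channels, dtype=float))
        ch.setflags(write=False)
        object.__setattr__(self, "channels", ch)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def slant_range(position: tuple[float, float, float]) -> float:
    """Straight-line distance from array center: sqrt(range^2 + depth^2)."""
    _, rng, depth = position
    if rng <= 0:
        raise SimulationError("horizontal range must be positive")
    return float(np.hypot(rng, depth))


def source_xyz(position: tuple[float, float, float]) -> np.ndarray:
    """Cartesian source position: range along the bearing in the horizontal
    plane, depth straight down (-z)."""
    azimuth, rng, depth = position
    if rng <= 0:
        raise SimulationError("horizontal range must be positive")
    u = bearing_to_unit_vector(Bearing(azimuth, 0.0))
    return rng * u - np.array([0.0, 0.0, depth])


def received_level(level_db: float, range_m: float) -> float:
    """Spherical-spreading received level: SL - 20*log10(range / 1 m)."""
    if range_m <= 0:
        raise SimulationError("range must be positive")
    return level_db - 20.0 * np.log10(range_m)


def scenario_snr(target: SourceSpec, interference: SourceSpec) -> float:
    """SNR (dB) at the array center: received target level minus received
    interference level, both via spherical spreading over slant range."""
    rl_t = received_level(target.source_level, slant_range(target.position))
    rl_n = received_level(
        interference.source_level, slant_range(interference.position)
    )
    return rl_t - rl_n


def fractional_delay_kernel(mu: float, n_taps: int = 64,
                            beta: float = 8.6) -> np.ndarray:
    """Kaiser-windowed sinc interpolation kernel for a fractional delay
    ``mu`` in [0, 1) samples.

    The kernel is centered so that convolving with it delays a band-limited
    signal by exactly ``mu`` samples (plus the integer kernel offset
    ``n_taps // 2 - 1`` removed by the caller).
    """
    half = n_taps // 2
    m = np.arange(-half + 1, half + 1, dtype=float)
    x = m - mu
    window = np.where(
        np.abs(x) <= half,
        _bessel_i0(beta * np.sqrt(np.clip(1.0 - (x / half) ** 2, 0.0, 1.0)))
        / _bessel_i0(beta),
        0.0,
    )
    return np.sinc(x) * window


def _add_delayed(buffer: np.ndarray, waveform: np.ndarray,
                 delay_samples: float, gain: float, n_taps: int = 64) -> None:
    """Add ``gain * waveform`` delayed by ``delay_samples`` (fractional)
    into ``buffer`` in place."""
    i0 = int(np.floor(delay_samples))
    mu = delay_samples - i0
    kernel = fractional_delay_kernel(mu, n_taps=n_taps)
    contrib = np.convolve(waveform, kernel) * gain
    start = i0 - (n_taps // 2 - 1)
    lo = max(start, 0)
    hi = min(start + contrib.size, buffer.size)
    if hi <= lo:
        return
    buffer[lo:hi] += contrib[lo - start: hi - start]


def render(scenario: Scenario, clip: bool = True) -> MultichannelAudio:
    """Render the scenario to synchronized multichannel audio.

    Each source contributes, on each hydrophone, its waveform delayed by
    the exact propagation time and scaled to amplitude
    ``10**((SL - 20*log10(d) - calibration_db) / 20)`` where ``d`` is the
    source-hydrophone distance.  Contributions are summed over all sources
    and interferences; with ``clip=True`` samples are hard-clipped to
    [-1, 1] and the clipped fraction reported.
    """
    sr = scenario.sample_rate
    n = int(round(scenario.duration * sr))
    positions = scenario.array.positions
    out = np.zeros((positions.shape[0], n))
    for src in scenario.sources + scenario.interferences:
        if abs(src.waveform.sample_rate - sr) > 1e-9:
            raise SimulationError(
                f"waveform sample rate {src.waveform.sample_rate} != "
                f"scenario rate {sr}"
            )
        xyz = source_xyz(src.position)
        for h, p in enumerate(positions):
            d = float(np.linalg.norm(xyz - p))
            if d < MIN_SOURCE_DISTANCE:
                raise SimulationError(
                    f"source at {src.position} is within "
                    f"{MIN_SOURCE_DISTANCE} m of hydrophone {h}"
                )
            gain = 10.0 ** (
                (src.source_level - 20.0 * np.log10(d)
                 - scenario.calibration_db) / 20.0
            )
            delay = (src.onset + d / scenario.sound_speed) * sr
            _add_delayed(out[h], src.waveform.samples, delay, gain)
    if scenario.diffuse_noise_db is not None:
        rng = np.random.default_rng(scenario.seed)
        sigma = 10.0 ** (
            (scenario.diffuse_noise_db - scenario.calibration_db) / 20.0
        )
        out += sigma * rng.standard_normal(out.shape)
    clipped_fraction = 0.0
    if clip:
        n_clipped = int(np.count_nonzero(np.abs(out) > 1.0))
        clipped_fraction = n_clipped / out.size
        out = np.clip(out, -1.0, 1.0)
    return MultichannelAudio(
        channels=out, sample_rate=sr, clipped_fraction=clipped_fraction
    )
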