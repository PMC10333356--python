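"""Sliding-window spectrogram detection with a pluggable classifier.

The front-end converts fixed-length single-channel audio windows into
dB-scaled power spectrograms cropped to the 800 Hz - 10 kHz analysis band,
resampled to a fixed 256 (frequency) x 128 (time) input shape and min-max
normalized to [0, 1] — the representation a window classifier consumes.

A classifier is any deterministic callable mapping a
:class:`NormalizedSpectrogram` to a confidence in [0, 1].  The shipped
:class:`EnergyClassifier` scores windows by their in-band energy relative
to a recording-level noise floor through a logistic link; a trained neural
classifier can be plugged in through the same contract.

Windows with confidence at or above the threshold are positive; maximal
runs of consecutive positive windows are merged into
:class:`DetectionEvent` s with per-window position labels
(first / intermediate / last).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy import signal as sps
from scipy.special import expit

__all__ = [
    "NormalizedSpectrogram",
    "DetectionEvent",
    "EnergyClassifier",
    "preprocess_window",
    "baseline_classifier",
    "estimate_noise_floor",
    "sliding_window_detect",
    "iter_windows",
]

SPEC_SHAPE = (256, 128)
FREQ_SPAN = (800.0, 10_000.0)
POWER_EPS = 1e-20  # power floor before dB conversion (-200 dB), far below
                   # any renderable signal so silence never masks one

#: Deterministic mapping NormalizedSpectrogram -> confidence in [0, 1].
Classifier = Callable[["NormalizedSpectrogram"], float]


@dataclass(frozen=True)
class NormalizedSpectrogram:
    """A 256 x 128 min-max-normalized dB power spectrogram.

    ``inband_db`` is a side statistic computed before normalization: the
    peak-over-time of the mean in-band power per STFT frame, in dB — the
    energy feature the baseline classifier uses.  ``degenerate`` marks
    windows whose spectrogram was constant (e.g. digital silence), where
    min-max normalization is undefined and the values are all zero.
    """

    values: np.ndarray
    window_span: tuple[float, float]
    freq_span: tuple[float, float] = FREQ_SPAN
    inband_db: float = float("-inf")
    degenerate: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != SPEC_SHAPE:
            raise ValueError(f"spectrogram shape {vals.shape} != {SPEC_SHAPE}")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def bin_frequencies(self) -> np.ndarray:
        """Center frequency of each of the 256 bins (Hz, ascending)."""
        lo, hi = self.freq_span
        edges = np.linspace(lo, hi, SPEC_SHAPE[0] + 1)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class DetectionEvent:
    """A maximal run of consecutive positive sliding windows."""

    start: float
    end: float
    confidence: float
    window_confidences: list[float]
    position_labels: list[str]
    window_spans: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")

    def overlaps(self, start: float, end: float) -> bool:
        return self.start < end and start < self.end


def preprocess_window(
    samples: np.ndarray,
    sample_rate: float,
    window_span: tuple[float, float] | None = None,
    nperseg: int = 2048,
    overlap: float = 0.75,
) -> NormalizedSpectrogram:
    """Transform an audio window into the normalized network input shape.

    Pipeline: Hann STFT power spectrum -> dB -> crop to 800 Hz - 10 kHz ->
    bilinear resample to 256 x 128 -> min-max normalize to [0, 1].
    An all-constant window yields an all-zero spectrogram flagged
    ``degenerate``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel window")
    nperseg = int(min(nperseg, x.size))
    if nperseg < 16:
        raise ValueError("window too short for one STFT frame")
    noverlap = int(nperseg * overlap)
    freqs, times, power = sps.spectrogram(
        x, fs=sample_rate, window="hann", nperseg=nperseg,
        noverlap=noverlap, mode="psd",
    )
    band = (freqs >= FREQ_SPAN[0]) & (freqs <= FREQ_SPAN[1])
    if band.sum() < 2 or power.shape[1] < 1:
        raise ValueError("window/band too small for a spectrogram")
    inband = power[band]
    inband_db = 10.0 * np.log10(inband.mean(axis=0).max() + POWER_EPS)
    db = 10.0 * np.log10(inband + POWER_EPS)
    if db.shape[1] == 1:
        db = np.repeat(db, 2, axis=1)
    zoom = (SPEC_SHAPE[0] / db.shape[0], SPEC_SHAPE[1] / db.shape[1])
    resized = ndimage.zoom(db, zoom, order=1, mode="nearest", grid_mode=True)
    resized = resized[: SPEC_SHAPE[0], : SPEC_SHAPE[1]]
    if resized.shape != SPEC_SHAPE:  # guard against rounding in zoom
        pad = [(0, SPEC_SHAPE[0] - resized.shape[0]),
               (0, SPEC_SHAPE[1] - resized.shape[1])]
        resized = np.pad(resized, pad, mode="edge")
    vmin, vmax = resized.min(), resized.max()
    if window_span is None:
        window_span = (0.0, x.size / sample_rate)
    if vmax - vmin < 1e-12:
        return NormalizedSpectrogram(
            values=np.zeros(SPEC_SHAPE), window_span=window_span,
            inband_db=inband_db, degenerate=True,
        )
    return NormalizedSpectrogram(
        values=(resized - vmin) / (vmax - vmin), window_span=window_span,
        inband_db=inband_db,
    )


@dataclass(frozen=True)
class EnergyClassifier:
    """Logistic in-band-energy classifier (baseline stand-in for a trained
    network).

    Confidence is ``sigmoid((inband_db - noise_floor_db) / scale_db)``:
    0.5 for a window at the noise floor, strictly increasing in in-band
    energy.  ``noise_floor_db`` should be the median per-window in-band
    statistic of the same recording (see :func:`estimate_noise_floor`).
    """

    noise_floor_db: float
    scale_db: float = 4.0

    def __call__(self, spec: NormalizedSpectrogram) -> float:
        return float(expit((spec.inband_db - self.noise_floor_db)
                           / self.scale_db))


def baseline_classifier(spec: NormalizedSpectrogram,
                        noise_floor: float,
                        scale_db: float = 4.0) -> float:
    """Functional form of :class:`EnergyClassifier`."""
    return EnergyClassifier(noise_floor, scale_db)(spec)


def iter_windows(n_samples: int, sample_rate: float, window_size: float,
                 step_size: float) -> list[tuple[int, int]]:
    """Start/stop sample indices of all full sliding windows."""
    w = int(round(window_size * sample_rate))
    s = int(round(step_size * sample_rate))
    if s < 1 or w < 1:
        raise ValueError("window and step must be at least one sample")
    return [(i, i + w) for i in range(0, n_samples - w + 1, s)]


def estimate_noise_floor(samples: np.ndarray, sample_rate: float,
                         window_size: float = 2.0,
                         step_size: float = 0.5) -> float:
    """Median per-window in-band energy statistic of a recording (dB)."""
    spans = iter_windows(len(samples), sample_rate, window_size, step_size)
    if not spans:
        return 10.0 * np.log10(POWER_EPS)
    stats = [
        preprocess_window(samples[a:b], sample_rate).inband_db
        for a, b in spans
    ]
    return float(np.median(stats))


def sliding_window_detect(
    samples: np.ndarray,
    sample_rate: float,
    window_size: float = 2.0,
    step_size: float = 0.5,
    threshold: float = 0.92,
    classifier: Classifier | None = None,
) -> list[DetectionEvent]:
    """Frame-wise classification of one channel, merged into events.

    Windows of ``window_size`` seconds advance by ``step_size``; windows
    whose confidence reaches ``threshold`` are positive, and maximal runs
    of consecutive positive windows become one :class:`DetectionEvent`.
    If no classifier is supplied, an :class:`EnergyClassifier` is built
    from the recording's own median noise floor.
    """
    if not 0 < step_size <= window_size:
        raise ValueError("need 0 < step_size <= window_size")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    x = np.asarray(samples, dtype=float)
    spans = iter_windows(x.size, sample_rate, window_size, step_size)
    if not spans:
        warnings.warn("audio shorter than one window; no detections",
                      stacklevel=2)
        return []
    specs = [
        preprocess_window(
            x[a:b], sample_rate,
            window_span=(a / sample_rate, b / sample_rate),
        )
        for a, b in spans
    ]
    if classifier is None:
        floor = float(np.median([s.inband_db for s in specs]))
        classifier = EnergyClassifier(floor)
    confidences = [classifier(spec) for spec in specs]
    events: list[DetectionEvent] = []
    run: list[int] = []
    for i, conf in enumerate(confidences):
        if conf >= threshold:
            run.append(i)
        elif run:
            events.append(_make_event(run, spans, confidences, sample_rate))
            run = []
    if run:
        events.append(_make_event(run, spans, confidences, sample_rate))
    return events


def _position_labels(n: int) -> list[str]:
    if n == 1:
        return ["first"]
    return ["first"] + ["intermediate"] * (n - 2) + ["last"]


def _make_event(run: Sequence[int], spans, confidences,
                sample_rate: float) -> DetectionEvent:
    window_spans = [
        (spans[i][0] / sample_rate, spans[i][1] / sample_rate) for i in run
    ]
    confs = [confidences[i] for i in run]
    return DetectionEvent(
        start=window_spans[0][0],
        end=window_spans[-1][1],
        confidence=max(confs),
        window_confidences=confs,
        position_labels=_position_labels(len(run)),
        window_spans=window_spans,
    )
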