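"""Config-file loading (YAML) and CSV report writers.

Array geometry files carry a name, a list of [x, y, z] positions in
meters, and optional drift/sink angles; positions are re-centered on load
and the applied offset is logged.  Scenario files mirror the experiment
grids: an array (by name or inline), target sources and interferences
with signal specs, levels, and (bearing, range, depth) positions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import HydrophoneArray, build_streamer_array, long_array, short_array
from .signals import Waveform, call_preset, make_chirp, make_noise, make_tonal_call
from .simulate import Scenario, SourceSpec, scenario_snr

__all__ = [
    "load_array",
    "save_array",
    "waveform_from_spec",
    "load_scenario",
    "write_manifest",
    "write_detections",
    "write_localizations",
]

log = logging.getLogger("pamloc")


def _array_from_dict(spec: dict) -> HydrophoneArray:
    if "builtin" in spec:
        return {"long": long_array, "short": short_array}[spec["builtin"]]()
    if "streamer" in spec:
        s = spec["streamer"]
        return build_streamer_array(
            int(s["n_per_streamer"]), float(s["hydrophone_spacing"]),
            float(s["streamer_separation"]), name=spec.get("name", "streamer"),
        )
    positions = np.asarray(spec["positions"], dtype=float)
    offset = positions.mean(axis=0)
    if np.linalg.norm(offset) > 1e-9:
        log.info("re-centered array %r by offset %s m",
                 spec.get("name", "array"), np.round(offset, 6).tolist())
    return HydrophoneArray.from_positions(
        spec.get("name", "array"), positions,
        azimuth_a=float(spec.get("azimuth_a", 0.0)),
        elevation_e=float(spec.get("elevation_e", 0.0)),
        recenter=True,
    )


def load_array(path) -> HydrophoneArray:
    """Load an array geometry from YAML/JSON; re-centers positions."""
    with open(path) as fh:
        return _array_from_dict(yaml.safe_load(fh))


def save_array(path, array: HydrophoneArray) -> None:
    data = {
        "name": array.name,
        "positions": [[float(v) for v in row] for row in array.positions],
        "azimuth_a": float(array.azimuth_a),
        "elevation_e": float(array.elevation_e),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def waveform_from_spec(spec: dict, sample_rate: float,
                       seed: int = 0) -> Waveform:
    """Build a waveform from a signal spec mapping.

    ``type`` selects the generator: ``chirp`` (duration), ``call``
    (preset or contour + n_harmonics + duration), ``noise``
    (kind + duration).
    """
    kind = spec.get("type")
    if kind == "chirp":
        return make_chirp(float(spec.get("duration", 0.002)), sample_rate)
    if kind == "call":
        if "preset" in spec:
            return call_preset(spec["preset"],
                               float(spec.get("duration", 1.0)), sample_rate,
                               int(spec.get("n_harmonics", 4)))
        contour = [(float(t), float(f)) for t, f in spec["contour"]]
        return make_tonal_call(contour, int(spec.get("n_harmonics", 4)),
                               float(spec.get("duration", 1.0)), sample_rate)
    if kind == "noise":
        return make_noise(spec.get("kind", "white"),
                          float(spec["duration"]), sample_rate,
                          int(spec.get("seed", seed)))
    raise ValueError(f"unknown signal type {kind!r}")


def _source_from_dict(spec: dict, sample_rate: float, seed: int) -> SourceSpec:
    az, rng, depth = spec["position"]
    return SourceSpec(
        waveform=waveform_from_spec(spec["signal"], sample_rate, seed),
        source_level=float(spec["level"]),
        position=(float(az), float(rng), float(depth)),
        onset=float(spec.get("onset", 0.0)),
    )


def load_scenario(path) -> Scenario:
    """Load a full scenario config from YAML/JSON."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    sample_rate = float(cfg.get("sample_rate", 48_000.0))
    seed = int(cfg.get("seed", 0))
    return Scenario(
        array=_array_from_dict(cfg["array"]),
        sources=tuple(_source_from_dict(s, sample_rate, seed)
                      for s in cfg.get("sources", [])),
        interferences=tuple(_source_from_dict(s, sample_rate, seed + 1)
                            for s in cfg.get("interferences", [])),
        duration=float(cfg.get("duration", 5.0)),
        sample_rate=sample_rate,
        sound_speed=float(cfg.get("sound_speed", 1500.0)),
        calibration_db=float(cfg.get("calibration_db", 170.0)),
        seed=seed,
    )


def write_manifest(path, scenario: Scenario) -> pd.DataFrame:
    """Ground-truth manifest CSV: one row per target source with onset,
    bearing, range, depth, and per-interference SNR."""
    rows = []
    for k, src in enumerate(scenario.sources):
        row = {
            "source": k, "onset_s": src.onset,
            "bearing_deg": src.position[0], "range_m": src.position[1],
            "depth_m": src.position[2], "source_level_db": src.source_level,
            "label": src.waveform.label,
        }
        for j, noise in enumerate(scenario.interferences):
            row[f"snr_db_interference_{j}"] = scenario_snr(src, noise)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def write_detections(path, events, channel: int = 0) -> pd.DataFrame:
    """Detection report CSV: channel, start_s, end_s, confidence,
    n_windows."""
    frame = pd.DataFrame([
        {
            "channel": channel, "start_s": ev.start, "end_s": ev.end,
            "confidence": ev.confidence,
            "n_windows": len(ev.window_confidences),
        }
        for ev in events
    ], columns=["channel", "start_s", "end_s", "confidence", "n_windows"])
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def write_localizations(path, rows: list[dict]) -> pd.DataFrame:
    """Localization report CSV (one row per localized window/event)."""
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
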