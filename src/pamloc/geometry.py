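"""Hydrophone array geometries, bearings, and rigid array rotations.

Coordinate convention (right-handed): +y is forward (direction of travel),
+x is starboard, +z is up.  Bearings are (azimuth, elevation) in degrees:
azimuth 0 deg points forward and increases clockwise viewed from above
(90 deg = starboard), wrapped to [-180, 180); elevation is positive up,
in [-90, 90].  Arrays are towed streamer pairs: two parallel lines of
hydrophones along the forward axis, re-centered so the geometric array
center is the coordinate origin.

Array drift is modelled as a rigid azimuth rotation ``a`` about +z and
sinking as an elevation rotation ``e`` tilting the forward axis (negative
``e`` = streamers sinking below the horizontal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "Bearing",
    "HydrophoneArray",
    "build_streamer_array",
    "long_array",
    "short_array",
    "rotate_array",
    "rotation_matrix",
    "bearing_to_unit_vector",
    "unit_vector_to_bearing",
    "wrap_degrees",
]

CENTER_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid array geometry or bearing input."""


def wrap_degrees(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class Bearing:
    """Direction to a source: azimuth (deg, clockwise from forward) and
    elevation (deg, positive up)."""

    azimuth: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "azimuth", float(wrap_degrees(self.azimuth)))
        object.__setattr__(self, "elevation", float(self.elevation))
        if not -90.0 <= self.elevation <= 90.0:
            raise GeometryError(
                f"elevation {self.elevation} outside [-90, 90] degrees"
            )


@dataclass(frozen=True)
class HydrophoneArray:
    """A named, centered set of hydrophone positions.

    Parameters
    ----------
    name : str
        Label for the geometry (e.g. ``"long"``, ``"short"``).
    positions : (n, 3) array
        Hydrophone coordinates in meters relative to the geometric array
        center.  Must be centered: ``mean(positions) == 0`` within 1e-9 m.
    azimuth_a, elevation_e : float
        Rotation angles (degrees) already applied to the geometry,
        recording drift and sink state.
    """

    name: str
    positions: np.ndarray
    azimuth_a: float = 0.0
    elevation_e: float = 0.0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("positions must be an (n, 3) array")
        if pos.shape[0] < 2:
            raise GeometryError("an array needs at least 2 hydrophones")
        if not np.all(np.isfinite(pos)):
            raise GeometryError("positions must be finite")
        if np.linalg.norm(pos.mean(axis=0)) > CENTER_TOL:
            raise GeometryError(
                "positions are not centered on the origin; use "
                "HydrophoneArray.from_positions(..., recenter=True)"
            )
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        if self.aperture <= 0.0:
            raise GeometryError("aperture must be positive (degenerate array)")

    @classmethod
    def from_positions(
        cls,
        name: str,
        positions: np.ndarray,
        azimuth_a: float = 0.0,
        elevation_e: float = 0.0,
        recenter: bool = True,
    ) -> "HydrophoneArray":
        """Build an array, optionally shifting positions so their mean is
        the origin.  Returns the array; the applied offset is recoverable
        as ``mean(original positions)``."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        if recenter and pos.size:
            pos = pos - pos.mean(axis=0)
        return cls(name, pos, azimuth_a, elevation_e)

    @property
    def n_hydrophones(self) -> int:
        return self.positions.shape[0]

    @property
    def aperture(self) -> float:
        """Maximum pairwise hydrophone distance in meters."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).max())

    def baselines(self, ref_channel: int) -> np.ndarray:
        """Distances (m) from each hydrophone to the reference hydrophone."""
        return np.linalg.norm(
            self.positions - self.positions[ref_channel], axis=1
        )


def build_streamer_array(
    n_per_streamer: int,
    hydrophone_spacing: float,
    streamer_separation: float,
    name: str = "streamer",
) -> HydrophoneArray:
    """Two parallel streamers of ``n_per_streamer`` hydrophones each.

    Streamers run along +y (forward); the first hydrophone of each streamer
    is the front-most.  Channels are ordered H0..H(n-1) down the left
    (port) streamer, then the right (starboard) streamer, matching the
    field convention that H0 and H(n) lead the two streamers.  The result
    is re-centered on the geometric array center.
    """
    if n_per_streamer < 1:
        raise GeometryError("n_per_streamer must be >= 1")
    if hydrophone_spacing <= 0 or streamer_separation <= 0:
        raise GeometryError("spacing and separation must be positive")
    ys = -hydrophone_spacing * np.arange(n_per_streamer, dtype=float)
    half = streamer_separation / 2.0
    left = np.column_stack([np.full_like(ys, -half), ys, np.zeros_like(ys)])
    right = np.column_stack([np.full_like(ys, half), ys, np.zeros_like(ys)])
    return HydrophoneArray.from_positions(
        name, np.vstack([left, right]), recenter=True
    )


def long_array() -> HydrophoneArray:
    """Long towed array: 4 hydrophones per streamer, 2.8 m apart,
    streamers 8.5 m apart."""
    return build_streamer_array(4, 2.8, 8.5, name="long")


def short_array() -> HydrophoneArray:
    """Short towed array: 4 hydrophones per streamer, 1.5 m apart,
    streamers 8.5 m apart."""
    return build_streamer_array(4, 1.5, 8.5, name="short")


def rotation_matrix(a: float, e: float) -> np.ndarray:
    """Rotation for drift azimuth ``a`` then sink elevation ``e`` (degrees).

    Applied as an intrinsic composition: elevation first tilts the forward
    axis (+y) toward +z for positive ``e``, then azimuth rotates clockwise
    viewed from above.  The forward axis maps exactly onto the unit vector
    of bearing ``(a, e)``.
    """
    ar, er = np.deg2rad(a), np.deg2rad(e)
    ca, sa = np.cos(ar), np.sin(ar)
    ce, se = np.cos(er), np.sin(er)
    # clockwise-from-above azimuth: +y -> +x for positive a
    rz = np.array([[ca, sa, 0.0], [-sa, ca, 0.0], [0.0, 0.0, 1.0]])
    # elevation about +x: +y -> +z for positive e
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ce, -se], [0.0, se, ce]])
    return rz @ rx


def rotate_array(array: HydrophoneArray, a: float, e: float) -> HydrophoneArray:
    """Rigidly rotate an array by drift azimuth ``a`` and sink elevation
    ``e`` (degrees); pairwise distances are preserved."""
    if not (np.isfinite(a) and np.isfinite(e)):
        raise GeometryError("rotation angles must be finite")
    rot = rotation_matrix(a, e)
    return HydrophoneArray(
        array.name,
        array.positions @ rot.T,
        azimuth_a=array.azimuth_a + a,
        elevation_e=array.elevation_e + e,
    )


def bearing_to_unit_vector(b: Bearing) -> np.ndarray:
    """Unit pointing vector: (sin az cos el, cos az cos el, sin el)."""
    az, el = np.deg2rad(b.azimuth), np.deg2rad(b.elevation)
    return np.array(
        [np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)]
    )


def unit_vector_to_bearing(v: np.ndarray) -> Bearing:
    """Inverse of :func:`bearing_to_unit_vector`; azimuth wrapped to
    [-180, 180)."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0 or not np.isfinite(norm):
        raise GeometryError("cannot derive a bearing from a zero vector")
    x, y, z = v / norm
    elevation = np.rad2deg(np.arcsin(np.clip(z, -1.0, 1.0)))
    azimuth = np.rad2deg(np.arctan2(x, y))
    return Bearing(azimuth=float(wrap_degrees(azimuth)), elevation=float(elevation))
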