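"""Shared dose containers.

Conventions used throughout the package: lateral position ``x`` and depth
``z`` are in mm, dose in Gy.  ``x = 0`` is the field centre, ``z = 0`` the
phantom surface.  Grids are cell-centered with strictly increasing
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["DepthDose", "Profile1D", "DoseGrid2D"]


def _validated_axis(values: Any, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return arr


def _validated_dose(values: Any, name: str = "dose") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < -1e-9):
        raise ValueError(f"{name} must be non-negative")
    return np.clip(arr, 0.0, None)


@dataclass
class DepthDose:
    """Dose versus depth along a fixed lateral position (a PDD curve)."""

    z: np.ndarray
    dose: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = _validated_axis(self.z, "z")
        self.dose = _validated_dose(self.dose)
        if self.dose.shape != self.z.shape:
            raise ValueError("z and dose must have the same length")

    def interp(self, z: Any) -> np.ndarray:
        """Linearly interpolated dose at depth(s) ``z`` (edge-extended)."""
        return np.interp(np.asarray(z, dtype=float), self.z, self.dose)

    def scaled(self, factor: float) -> "DepthDose":
        return DepthDose(self.z.copy(), self.dose * float(factor), dict(self.meta))


@dataclass
class Profile1D:
    """Lateral dose profile at a fixed depth."""

    x: np.ndarray
    dose: np.ndarray
    depth_tag: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = _validated_axis(self.x, "x")
        self.dose = _validated_dose(self.dose)
        if self.dose.shape != self.x.shape:
            raise ValueError("x and dose must have the same length")

    @property
    def pitch(self) -> float:
        """Median sample spacing in mm."""
        return float(np.median(np.diff(self.x)))

    def interp(self, x: Any) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.x, self.dose)


@dataclass
class DoseGrid2D:
    """Dose in the lateral(x) x depth(z) plane, ``dose[ix, iz]`` in Gy."""

    x_coords: np.ndarray
    z_coords: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.x_coords = _validated_axis(self.x_coords, "x_coords")
        self.z_coords = _validated_axis(self.z_coords, "z_coords")
        self.dose = _validated_dose(self.dose)
        expected = (self.x_coords.size, self.z_coords.size)
        if self.dose.shape != expected:
            raise ValueError(
                f"dose shape {self.dose.shape} does not match grid {expected}"
            )

    def lateral_profile(self, z: float) -> Profile1D:
        """Profile at depth ``z`` (linear interpolation between grid rows)."""
        z = float(z)
        if not (self.z_coords[0] <= z <= self.z_coords[-1]):
            raise ValueError(f"depth {z} mm outside grid")
        col = np.array(
            [np.interp(z, self.z_coords, self.dose[i]) for i in range(self.x_coords.size)]
        )
        return Profile1D(self.x_coords.copy(), col, depth_tag=z)

    def depth_profile(self, x: float) -> DepthDose:
        """Depth-dose curve at lateral position ``x``."""
        x = float(x)
        if not (self.x_coords[0] <= x <= self.x_coords[-1]):
            raise ValueError(f"lateral position {x} mm outside grid")
        row = np.array(
            [np.interp(x, self.x_coords, self.dose[:, j]) for j in range(self.z_coords.size)]
        )
        return DepthDose(self.z_coords.copy(), row, meta={"lateral_pos_mm": x})
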