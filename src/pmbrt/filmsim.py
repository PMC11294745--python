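"""Synthetic film scanner: forward model from a dose plane to a film scan.

Inverts the per-channel calibration to get the netOD a film would develop,
adds OD-domain scanner noise, applies an optional in-plane rotation (the
misalignment the aligner has to undo) and renders 16-bit RGB pixels.
Deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage import transform

from .core import DoseGrid2D
from .film import CalibrationCurve, FilmScan

__all__ = ["default_calibration_triple", "film_digitize", "DEFAULT_BLANK"]

DEFAULT_BLANK = np.array([60000.0, 59000.0, 55000.0])

# Representative EBT-XD-like channel sensitivities (red most sensitive).
_DEFAULT_PARAMS = {
    "red": (8.0, 35.0, 2.5),
    "green": (12.0, 45.0, 2.8),
    "blue": (25.0, 60.0, 3.0),
}


def default_calibration_triple() -> list[CalibrationCurve]:
    """The engine's ground-truth three-channel calibration set."""
    return [
        CalibrationCurve(channel=ch, b1=b1, b2=b2, n=n, n_points=22)
        for ch, (b1, b2, n) in _DEFAULT_PARAMS.items()
    ]


def film_digitize(
    dose: DoseGrid2D,
    cal: list[CalibrationCurve] | None = None,
    dpi: float = 300.0,
    noise_sd: float = 0.0,
    rotation: float = 0.0,
    seed: int = 0,
    blank: np.ndarray = DEFAULT_BLANK,
    disturbance: float | np.ndarray = 1.0,
) -> FilmScan:
    """Render a dose plane as a scanned film (rows = depth, cols = lateral).

    Parameters
    ----------
    dose
        The plane to expose; doses above the calibration maximum are
        rendered at the maximum and flagged in ``saturation_mask``.
    cal
        Three-channel calibration; defaults to the engine's ground truth.
    noise_sd
        Gaussian scanner noise in OD units, i.i.d. per pixel and channel.
    rotation
        In-plane misalignment in degrees applied to the exposed film.
    disturbance
        Multiplicative netOD perturbation (film-thickness variation); a
        scalar or a per-pixel map.
    """
    if cal is None:
        cal = default_calibration_triple()
    if dpi <= 0:
        raise ValueError("dpi must be > 0")
    cal = {c.channel: c for c in cal}
    pitch = 25.4 / dpi

    x0, x1 = dose.x_coords[0], dose.x_coords[-1]
    z0, z1 = dose.z_coords[0], dose.z_coords[-1]
    xs = np.arange(x0, x1 + pitch / 2, pitch)
    zs = np.arange(z0, z1 + pitch / 2, pitch)
    interp = RegularGridInterpolator(
        (dose.x_coords, dose.z_coords), dose.dose,
        bounds_error=False, fill_value=0.0,
    )
    xx, zz = np.meshgrid(xs, zs)  # rows = depth
    img_dose = interp(np.stack([xx.ravel(), zz.ravel()], axis=1)).reshape(zz.shape)

    if rotation != 0.0:
        img_dose = transform.rotate(img_dose, rotation, resize=False, order=1, mode="edge")

    hi = cal["red"].valid_dose_range[1]
    saturation = img_dose > hi
    exposed = np.minimum(img_dose, hi)

    rng = np.random.default_rng(seed)
    channels = []
    for ch in ("red", "green", "blue"):
        od = cal[ch].netod(exposed) * disturbance
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=od.shape)
        od = np.clip(od, 0.0, None)
        px = np.rint(blank[("red", "green", "blue").index(ch)] * 10.0 ** (-od))
        channels.append(np.clip(px, 0, 65535).astype(np.uint16))

    return FilmScan(
        pixels=np.stack(channels, axis=-1),
        dpi=dpi,
        blank_reference=np.asarray(blank, dtype=float),
        saturation_mask=saturation,
        meta={
            "x0_mm": float(xs[0]), "z0_mm": float(zs[0]),
            "rotation_deg": float(rotation), "noise_sd": float(noise_sd),
            "seed": int(seed),
        },
    )
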