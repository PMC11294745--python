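"""Radiochromic film dosimetry: netOD calibration and film-to-dose conversion.

The film signal is the net optical density netOD = log10(blank / pixel),
mapped to dose through the rational calibration form

    dose(netOD) = b1 * netOD + b2 * netOD**n

fitted per colour channel.  ``to_dose`` supports single-channel inversion
and a multichannel mode that cancels a per-pixel thickness-like
disturbance: the measured ODs are modelled as (1 + delta) * OD_ch(D) with
one scalar dose D and one scalar disturbance delta per pixel, solved by
least squares across the three channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, signal
from skimage import transform

from .core import DepthDose, Profile1D

__all__ = [
    "FilmScan",
    "CalibrationCurve",
    "DoseMap2D",
    "net_od",
    "fit_calibration",
    "to_dose",
    "rotate_align",
    "extract_lateral_profile",
    "extract_depth_profile",
]

CHANNELS = ("red", "green", "blue")


@dataclass
class FilmScan:
    """A digitized film: 3-channel 16-bit pixels, rows = depth, cols = lateral."""

    pixels: np.ndarray
    dpi: float
    blank_reference: np.ndarray
    orientation_tag: Literal["landscape", "portrait"] = "landscape"
    saturation_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.dtype != np.uint16:
            if np.any(self.pixels < 0) or np.any(self.pixels > 65535):
                raise ValueError("pixel values must be within [0, 65535]")
            self.pixels = self.pixels.astype(np.uint16)
        if self.dpi <= 0:
            raise ValueError("dpi must be > 0")
        self.blank_reference = np.asarray(self.blank_reference, dtype=float)
        if self.blank_reference.shape != (3,):
            raise ValueError("blank_reference must have 3 per-channel values")
        if np.any(self.blank_reference <= 0):
            raise ValueError("blank_reference must be > 0 per channel")

    @property
    def pixel_pitch(self) -> float:
        """Pixel spacing in mm (25.4 / dpi)."""
        return 25.4 / self.dpi


@dataclass
class CalibrationCurve:
    """Per-channel netOD -> dose mapping, dose = b1*netOD + b2*netOD**n."""

    channel: Literal["red", "green", "blue"]
    b1: float
    b2: float
    n: float
    valid_dose_range: tuple[float, float] = (0.4, 40.0)
    n_points: int = 0
    fit_rms_gy: float = 0.0
    loo_rms_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.b1 < 0 or self.b2 < 0 or self.n <= 1.0:
            # b1, b2 >= 0 and n > 1 guarantee strict monotonicity on od > 0
            raise ValueError("calibration must be strictly increasing (b1,b2>=0, n>1)")
        if self.b1 == 0 and self.b2 == 0:
            raise ValueError("degenerate calibration")

    def dose(self, netod) -> np.ndarray:
        od = np.clip(np.asarray(netod, dtype=float), 0.0, None)
        return self.b1 * od + self.b2 * od ** self.n

    def _od_grid(self, dose_max: float) -> tuple[np.ndarray, np.ndarray]:
        od_hi = 1.0
        while float(self.dose(od_hi)) < dose_max and od_hi < 64.0:
            od_hi *= 2.0
        od = np.linspace(0.0, od_hi, 20000)
        return od, self.dose(od)

    def netod(self, dose) -> np.ndarray:
        """Inverse mapping dose -> netOD (monotone, interpolated)."""
        dose = np.asarray(dose, dtype=float)
        od_grid, dose_grid = self._od_grid(max(float(np.max(dose)), self.valid_dose_range[1]) * 1.1 + 1.0)
        return np.interp(np.clip(dose, 0.0, None), dose_grid, od_grid)


@dataclass
class DoseMap2D:
    """Dose map reconstructed from a film scan; rows = depth, cols = lateral."""

    dose: np.ndarray
    pixel_pitch: float
    origin: tuple[float, float] = (0.0, 0.0)
    saturation_mask: np.ndarray | None = None
    low_confidence_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 2:
            raise ValueError("dose must be 2D")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        ok = np.ones_like(self.dose, dtype=bool)
        if self.saturation_mask is not None:
            ok &= ~self.saturation_mask
        if np.any(self.dose[ok] < -1e-9):
            raise ValueError("dose must be non-negative outside masked pixels")
        self.dose = np.clip(self.dose, 0.0, None)

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.dose.shape[1]) * self.pixel_pitch

    @property
    def z_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.dose.shape[0]) * self.pixel_pitch


def net_od(scan: FilmScan) -> np.ndarray:
    """Per-channel netOD map, OD = log10(blank / pixel), clamped at 0.

    Zero pixels (fully opaque, unphysical) come back as NaN rather than
    infinity.
    """
    px = scan.pixels.astype(float)
    od = np.full(px.shape, np.nan)
    valid = px > 0
    blank = scan.blank_reference[np.newaxis, np.newaxis, :]
    od[valid] = np.log10(np.broadcast_to(blank, px.shape)[valid] / px[valid])
    od[valid] = np.clip(od[valid], 0.0, None)
    return od


def _loo_rms_pct(doses: np.ndarray, ods: np.ndarray, p0: Sequence[float]) -> float:
    errs = []
    for i in range(doses.size):
        mask = np.ones(doses.size, dtype=bool)
        mask[i] = False
        try:
            popt, _ = optimize.curve_fit(
                lambda od, b1, b2, n: b1 * od + b2 * od ** n,
                ods[mask], doses[mask], p0=p0, sigma=doses[mask],
                bounds=([0.0, 0.0, 1.01], [np.inf, np.inf, 8.0]), maxfev=20000,
            )
        except RuntimeError:  # pragma: no cover - pathological leave-one-out fit
            continue
        pred = popt[0] * ods[i] + popt[1] * ods[i] ** popt[2]
        errs.append((pred - doses[i]) / doses[i])
    return 100.0 * float(np.sqrt(np.mean(np.square(errs)))) if errs else float("nan")


def fit_calibration(
    doses: Sequence[float],
    ods: Sequence[float],
    channel: Literal["red", "green", "blue"],
    valid_dose_range: tuple[float, float] = (0.4, 40.0),
) -> CalibrationCurve:
    """Fit the rational calibration form to (dose, netOD) points.

    Requires at least 5 points inside the valid dose range and a
    monotone dose-OD relationship; reports the leave-one-out dose RMS
    error in percent.
    """
    doses = np.asarray(doses, dtype=float)
    ods = np.asarray(ods, dtype=float)
    if doses.shape != ods.shape or doses.ndim != 1:
        raise ValueError("doses and ods must be 1D arrays of equal length")
    if doses.size < 5:
        raise ValueError("need at least 5 calibration points")
    lo, hi = valid_dose_range
    if np.any(doses < lo - 1e-9) or np.any(doses > hi + 1e-9):
        raise ValueError(f"calibration doses must lie within [{lo}, {hi}] Gy")
    order = np.argsort(doses)
    doses, ods = doses[order], ods[order]
    if not np.all(np.diff(ods) > 0):
        bad = int(np.argmin(np.diff(ods)))
        raise ValueError(
            "calibration data not monotone: netOD does not increase between "
            f"doses {doses[bad]:.2f} and {doses[bad + 1]:.2f} Gy"
        )

    p0 = (doses[-1] / max(ods[-1], 1e-6) * 0.5, doses[-1] / max(ods[-1], 1e-6) * 0.5, 2.0)
    # relative weighting: film accuracy is judged in percent, not Gy
    popt, _ = optimize.curve_fit(
        lambda od, b1, b2, n: b1 * od + b2 * od ** n,
        ods, doses, p0=p0, sigma=doses,
        bounds=([0.0, 0.0, 1.01], [np.inf, np.inf, 8.0]), maxfev=20000,
    )
    resid = doses - (popt[0] * ods + popt[1] * ods ** popt[2])
    return CalibrationCurve(
        channel=channel,
        b1=float(popt[0]), b2=float(popt[1]), n=float(popt[2]),
        valid_dose_range=valid_dose_range,
        n_points=int(doses.size),
        fit_rms_gy=float(np.sqrt(np.mean(resid ** 2))),
        loo_rms_pct=_loo_rms_pct(doses, ods, popt),
    )


def _multichannel_solve(
    od_map: np.ndarray, cals: Sequence[CalibrationCurve], dose_hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (dose, disturbance) from the 3-channel consistency problem.

    Model: od_meas_ch = (1 + delta) * od_cal_ch(D).  For each candidate D
    the optimal delta is closed-form, leaving a 1D profile-likelihood
    residual |m|^2 - (m.c)^2/|c|^2 minimized over a dose grid with
    parabolic refinement.
    """
    grid = np.concatenate([
        np.linspace(0.0, 1.0, 120, endpoint=False),
        np.geomspace(1.0, dose_hi, 360),
    ])
    c = np.stack([cal.netod(grid) for cal in cals], axis=1)  # (G, 3)
    c2 = np.sum(c ** 2, axis=1)
    c2[c2 == 0] = np.inf  # exclude the degenerate D = 0 candidate

    h, w, _ = od_map.shape
    m = od_map.reshape(-1, 3)
    m = np.nan_to_num(m, nan=0.0)
    dose = np.empty(m.shape[0])
    delta = np.empty(m.shape[0])
    chunk = 65536
    for s in range(0, m.shape[0], chunk):
        mm = m[s:s + chunk]
        score = (mm @ c.T) ** 2 / c2[np.newaxis, :]  # (N, G)
        j = np.argmax(score, axis=1)
        # parabolic refinement on the dose axis around the grid optimum
        jj = np.clip(j, 1, grid.size - 2)
        y0, y1, y2 = (score[np.arange(len(jj)), jj - 1],
                      score[np.arange(len(jj)), jj],
                      score[np.arange(len(jj)), jj + 1])
        denom = y0 - 2 * y1 + y2
        with np.errstate(invalid="ignore", divide="ignore"):
            shift = np.where(np.abs(denom) > 1e-30, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.nan_to_num(shift)
        shift = np.clip(shift, -1.0, 1.0)
        d_opt = grid[jj] + shift * np.where(shift > 0, grid[np.minimum(jj + 1, grid.size - 1)] - grid[jj],
                                            grid[jj] - grid[jj - 1])
        d_opt = np.where(j == 0, 0.0, d_opt)
        dose[s:s + chunk] = np.clip(d_opt, 0.0, None)
        cd = np.stack([cal.netod(dose[s:s + chunk]) for cal in cals], axis=1)
        num = np.sum(mm * cd, axis=1)
        den = np.sum(cd ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            delta[s:s + chunk] = np.where(den > 0, num / den - 1.0, 0.0)
        delta[s:s + chunk] = np.nan_to_num(delta[s:s + chunk])
    return dose.reshape(h, w), delta.reshape(h, w)


def to_dose(
    scan: FilmScan,
    cal: CalibrationCurve | Sequence[CalibrationCurve],
    method: Literal["single_channel", "multichannel"] = "single_channel",
) -> DoseMap2D:
    """Convert a film scan to a dose map.

    ``single_channel`` inverts one channel's calibration; ``multichannel``
    needs all three curves and additionally estimates a per-pixel
    disturbance (stored in ``meta['disturbance']``).  Doses below the
    calibration minimum are flagged low-confidence; saturated pixels
    (dose at or above the calibration maximum) are masked.
    """
    od = net_od(scan)
    if method == "single_channel":
        if not isinstance(cal, CalibrationCurve):
            cal = next(c for c in cal if isinstance(c, CalibrationCurve))
        ch = CHANNELS.index(cal.channel)
        od_ch = np.nan_to_num(od[:, :, ch], nan=np.inf)
        od_grid, dose_grid = cal._od_grid(cal.valid_dose_range[1] * 1.2)
        dose = np.interp(od_ch, od_grid, dose_grid)
        meta = {"method": "single_channel", "channel": cal.channel}
        ref_cal = cal
    elif method == "multichannel":
        cals = list(cal)
        if len(cals) != 3:
            raise ValueError("multichannel requires three calibration curves")
        cals = sorted(cals, key=lambda c: CHANNELS.index(c.channel))
        dose, delta = _multichannel_solve(od, cals, cals[0].valid_dose_range[1] * 1.2)
        meta = {"method": "multichannel", "disturbance": delta}
        ref_cal = cals[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    lo, hi = ref_cal.valid_dose_range
    saturated = dose >= hi
    if scan.saturation_mask is not None:
        saturated |= scan.saturation_mask
    low_conf = dose < lo
    return DoseMap2D(
        dose=dose,
        pixel_pitch=scan.pixel_pitch,
        origin=(
            float(scan.meta.get("x0_mm", 0.0)),
            float(scan.meta.get("z0_mm", 0.0)),
        ),
        saturation_mask=saturated,
        low_confidence_mask=low_conf,
        meta=meta,
    )


def _rotated(dose: np.ndarray, angle: float) -> np.ndarray:
    return transform.rotate(dose, angle, resize=False, order=1, mode="edge")


def _comb_sharpness(dose: np.ndarray, angle: float) -> float:
    prof = _rotated(dose, angle).mean(axis=0)
    return float(np.var(prof))


def rotate_align(
    dose_map: DoseMap2D,
    mode: Literal["manual", "auto"] = "auto",
    angle: float | None = None,
) -> DoseMap2D:
    """Align the slit comb vertically (slits along the depth axis).

    ``auto`` finds the rotation in [-10, 10] degrees that maximizes the
    variance of the depth-collapsed lateral profile — sharpest comb wins.
    The applied angle is stored in ``meta['rotation_applied_deg']``.
    """
    if mode == "manual":
        if angle is None:
            raise ValueError("manual mode requires an angle")
        if abs(angle) > 10.0:
            raise ValueError("|angle| must be <= 10 degrees")
        applied = float(angle)
    elif mode == "auto":
        coarse = np.arange(-10.0, 10.001, 0.5)
        scores = [_comb_sharpness(dose_map.dose, a) for a in coarse]
        best = coarse[int(np.argmax(scores))]
        res = optimize.minimize_scalar(
            lambda a: -_comb_sharpness(dose_map.dose, a),
            bounds=(best - 0.6, best + 0.6), method="bounded",
            options={"xatol": 2e-3},
        )
        applied = float(res.x)
        aligned_prof = _rotated(dose_map.dose, applied).mean(axis=0)
        peaks, _ = signal.find_peaks(aligned_prof, prominence=0.05 * aligned_prof.max())
        if len(peaks) == 0:
            raise ValueError(
                "auto alignment found no comb structure; use mode='manual'"
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = _rotated(dose_map.dose, applied)
    meta = dict(dose_map.meta)
    meta["rotation_applied_deg"] = applied
    return DoseMap2D(
        dose=out, pixel_pitch=dose_map.pixel_pitch, origin=dose_map.origin,
        saturation_mask=dose_map.saturation_mask,
        low_confidence_mask=dose_map.low_confidence_mask, meta=meta,
    )


def _field_center(x: np.ndarray, dose_row: np.ndarray) -> float:
    """Comb centre: midpoint of the outermost peaks; map centre for open fields."""
    if dose_row.max() > 0:
        peaks, _ = signal.find_peaks(dose_row, prominence=0.05 * dose_row.max())
        if len(peaks) >= 2:
            return 0.5 * (x[peaks[0]] + x[peaks[-1]])
        if len(peaks) == 1:
            return float(x[peaks[0]])
    return 0.5 * (x[0] + x[-1])


def extract_lateral_profile(
    dose_map: DoseMap2D, depth: float, band_px: int = 3
) -> Profile1D:
    """Lateral profile at ``depth``, averaged over ``band_px`` rows.

    Positions are reported relative to the detected field centre, which is
    stored in ``meta['center_mm']`` (map frame).
    """
    z = dose_map.z_coords
    if not (z[0] <= depth <= z[-1]):
        raise ValueError(f"depth {depth} mm outside map [{z[0]}, {z[-1]}]")
    if band_px < 1:
        raise ValueError("band_px must be >= 1")
    i = int(np.argmin(np.abs(z - depth)))
    half = band_px // 2
    lo = max(0, i - half)
    hi = min(z.size, lo + band_px)
    row = dose_map.dose[lo:hi].mean(axis=0)
    x = dose_map.x_coords
    center = _field_center(x, row)
    return Profile1D(
        x - center, row, depth_tag=float(depth),
        meta={"center_mm": center, "band_px": band_px, "source": "film"},
    )


def extract_depth_profile(
    dose_map: DoseMap2D, lateral_pos: float, avg_px: int = 5
) -> DepthDose:
    """Depth-dose at ``lateral_pos`` (map frame), averaged over ``avg_px`` columns."""
    if avg_px < 1 or avg_px % 2 == 0:
        raise ValueError("avg_px must be a positive odd count (centered window)")
    x = dose_map.x_coords
    if not (x[0] <= lateral_pos <= x[-1]):
        raise ValueError(f"lateral position {lateral_pos} mm outside map")
    j = int(np.argmin(np.abs(x - lateral_pos)))
    half = avg_px // 2
    if j - half < 0 or j + half >= x.size:
        raise ValueError("averaging window exceeds the map")
    col = dose_map.dose[:, j - half:j + half + 1].mean(axis=1)
    return DepthDose(
        dose_map.z_coords, col,
        meta={"lateral_pos_mm": float(x[j]), "avg_px": avg_px, "source": "film"},
    )
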