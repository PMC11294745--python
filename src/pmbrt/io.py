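"""File formats and run configuration.

Units are fixed at file boundaries: mm, Gy, MeV, keV/um.  Profiles and
depth doses are CSV (columns ``x_mm,dose_Gy`` / ``z_mm,dose_Gy``), dose
planes are long-format CSV (``x_mm,z_mm,dose_Gy``) with a JSON sidecar of
grid metadata, film scans are 48-bit RGB TIFF with the dpi tag set, and
configuration / calibration / gamma reports are JSON.  Config files are
schema-validated; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from .core import DepthDose, DoseGrid2D, Profile1D
from .engine import BeamSpec, CollimatorSpec, PhantomGridSpec, QuenchModel
from .film import CalibrationCurve, FilmScan
from .letcorr import LETCorrectionCurve

__all__ = [
    "RunConfig",
    "read_profile_csv", "write_profile_csv",
    "read_depth_dose_csv", "write_depth_dose_csv",
    "read_grid_csv", "write_grid_csv",
    "read_film_tiff", "write_film_tiff",
    "read_calibration_json", "write_calibration_json",
    "read_correction_csv", "write_correction_csv",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BeamConfig(_Strict):
    energy_MeV: float
    spot_sigma_mm: float = 3.0
    sad_mm: float = 9100.0
    fluence_mode: Literal["uniform", "spot_sum"] = "uniform"
    spot_spacing_mm: float = 5.0
    mu_scale: float = 1.0


class CollimatorConfig(_Strict):
    n_slits: int = 5
    slit_width_mm: float = 0.4
    ctc_mm: float = 2.8
    thickness_mm: float = 65.0
    slit_length_mm: float = 50.0
    jitter_mm: list[float] | None = None
    leakage: float = 0.03
    exit_sigma_mm: float = 0.3
    exit_theta_rad: float = 7.0e-3


class GridConfig(_Strict):
    dx_mm: float = 0.1
    dz_mm: float = 0.5
    x_extent_mm: float = 60.0
    z_extent_mm: float = 170.0
    air_gap_mm: float = 60.0


class QuenchConfig(_Strict):
    k: float = 0.03
    let_ref: float = 0.9


class RunConfig(_Strict):
    """Validated engine + analysis configuration (single seed for all noise)."""

    beam: BeamConfig
    collimator: CollimatorConfig = Field(default_factory=CollimatorConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    quench: QuenchConfig = Field(default_factory=QuenchConfig)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def beam_spec(self) -> BeamSpec:
        return BeamSpec(
            energy=self.beam.energy_MeV,
            spot_sigma_surface=self.beam.spot_sigma_mm,
            sad=self.beam.sad_mm,
            fluence_mode=self.beam.fluence_mode,
            spot_spacing=self.beam.spot_spacing_mm,
            mu_scale=self.beam.mu_scale,
        )

    def collimator_spec(self) -> CollimatorSpec:
        c = self.collimator
        return CollimatorSpec(
            n_slits=c.n_slits, slit_width=c.slit_width_mm, ctc=c.ctc_mm,
            thickness=c.thickness_mm, slit_length=c.slit_length_mm,
            per_slit_width_jitter=None if c.jitter_mm is None else np.asarray(c.jitter_mm),
            leakage=c.leakage, exit_sigma=c.exit_sigma_mm, exit_theta=c.exit_theta_rad,
        )

    def grid_spec(self) -> PhantomGridSpec:
        g = self.grid
        return PhantomGridSpec(
            x_extent=g.x_extent_mm, z_extent=g.z_extent_mm,
            dx=g.dx_mm, dz=g.dz_mm, air_gap=g.air_gap_mm,
        )

    def quench_model(self) -> QuenchModel:
        return QuenchModel(k=self.quench.k, let_ref=self.quench.let_ref)

    def sha256(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode("utf-8")
        ).hexdigest()


# ---------------------------------------------------------------------------
# CSV containers
# ---------------------------------------------------------------------------

def _read_numeric_csv(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {list(columns)}")
    for c in columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as err:
            raise ValueError(
                f"{path}: column {c!r} is not numeric ({err}); note that the "
                "decimal separator must be '.', not ','"
            ) from None
    return df


def _require_increasing(values: np.ndarray, what: str, path) -> None:
    if values.size > 1 and not np.all(np.diff(values) > 0):
        raise ValueError(f"{path}: {what} must be strictly increasing")


def write_profile_csv(p: Profile1D, path: str | Path, sidecar: dict | None = None) -> None:
    pd.DataFrame({"x_mm": p.x, "dose_Gy": p.dose}).to_csv(path, index=False, float_format="%.9g")
    side = {"depth_mm": p.depth_tag, **{k: v for k, v in p.meta.items() if _jsonable(v)}}
    if sidecar:
        side.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(side, indent=1))


def read_profile_csv(path: str | Path) -> Profile1D:
    df = _read_numeric_csv(path, ("x_mm", "dose_Gy"))
    x = df["x_mm"].to_numpy()
    _require_increasing(x, "x_mm", path)
    meta = {}
    depth = None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        depth = meta.pop("depth_mm", None)
    return Profile1D(x, df["dose_Gy"].to_numpy(), depth_tag=depth, meta=meta)


def write_depth_dose_csv(d: DepthDose, path: str | Path, sidecar: dict | None = None) -> None:
    pd.DataFrame({"z_mm": d.z, "dose_Gy": d.dose}).to_csv(path, index=False, float_format="%.9g")
    side = {k: v for k, v in d.meta.items() if _jsonable(v)}
    if sidecar:
        side.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(side, indent=1))


def read_depth_dose_csv(path: str | Path) -> DepthDose:
    df = _read_numeric_csv(path, ("z_mm", "dose_Gy"))
    z = df["z_mm"].to_numpy()
    _require_increasing(z, "z_mm", path)
    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return DepthDose(z, df["dose_Gy"].to_numpy(), meta=meta)


def write_grid_csv(grid: DoseGrid2D, path: str | Path, sidecar: dict | None = None) -> None:
    xx, zz = np.meshgrid(grid.x_coords, grid.z_coords, indexing="ij")
    pd.DataFrame({
        "x_mm": xx.ravel(), "z_mm": zz.ravel(), "dose_Gy": grid.dose.ravel(),
    }).to_csv(path, index=False, float_format="%.9g")
    side = {
        "nx": int(grid.x_coords.size), "nz": int(grid.z_coords.size),
        "dx_mm": float(np.median(np.diff(grid.x_coords))),
        "dz_mm": float(np.median(np.diff(grid.z_coords))),
    }
    if sidecar:
        side.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(side, indent=1))


def read_grid_csv(path: str | Path) -> DoseGrid2D:
    df = _read_numeric_csv(path, ("x_mm", "z_mm", "dose_Gy"))
    x = np.unique(df["x_mm"].to_numpy())
    z = np.unique(df["z_mm"].to_numpy())
    dose = df["dose_Gy"].to_numpy().reshape(x.size, z.size)
    return DoseGrid2D(x, z, dose)


# ---------------------------------------------------------------------------
# film TIFF
# ---------------------------------------------------------------------------

def write_film_tiff(scan: FilmScan, path: str | Path) -> None:
    """48-bit RGB TIFF with the dpi tag set and scan metadata in the description."""
    desc = json.dumps({
        "blank_reference": scan.blank_reference.tolist(),
        "orientation_tag": scan.orientation_tag,
        **{k: v for k, v in scan.meta.items() if _jsonable(v)},
    })
    tifffile.imwrite(
        path, scan.pixels, photometric="rgb",
        resolution=(scan.dpi, scan.dpi), resolutionunit="INCH",
        description=desc,
    )


def read_film_tiff(path: str | Path) -> FilmScan:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is None or unit is None or int(unit.value) != 2:  # 2 = inch
            raise ValueError(
                f"{path}: TIFF has no inch-based XResolution (dpi) tag; "
                "the pixel pitch cannot be derived"
            )
        num, den = res.value
        dpi = num / den
        desc = page.tags.get("ImageDescription")
    meta = {}
    blank = np.array([65535.0, 65535.0, 65535.0])
    orientation = "landscape"
    if desc is not None:
        try:
            meta = json.loads(desc.value)
            blank = np.asarray(meta.pop("blank_reference", blank), dtype=float)
            orientation = meta.pop("orientation_tag", orientation)
        except json.JSONDecodeError:
            pass
    return FilmScan(
        pixels=pixels, dpi=dpi, blank_reference=blank,
        orientation_tag=orientation, meta=meta,
    )


# ---------------------------------------------------------------------------
# calibration and correction curves
# ---------------------------------------------------------------------------

def write_calibration_json(cals: list[CalibrationCurve], path: str | Path) -> None:
    payload = [{
        "channel": c.channel, "b1": c.b1, "b2": c.b2, "n": c.n,
        "valid_dose_range_Gy": list(c.valid_dose_range),
        "n_points": c.n_points, "fit_rms_Gy": c.fit_rms_gy,
        "loo_rms_pct": None if np.isnan(c.loo_rms_pct) else c.loo_rms_pct,
    } for c in cals]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_calibration_json(path: str | Path) -> list[CalibrationCurve]:
    payload = json.loads(Path(path).read_text())
    return [CalibrationCurve(
        channel=e["channel"], b1=e["b1"], b2=e["b2"], n=e["n"],
        valid_dose_range=tuple(e.get("valid_dose_range_Gy", (0.4, 40.0))),
        n_points=e.get("n_points", 0),
        fit_rms_gy=e.get("fit_rms_Gy", 0.0),
        loo_rms_pct=e.get("loo_rms_pct") or float("nan"),
    ) for e in payload]


def write_correction_csv(corr: LETCorrectionCurve, path: str | Path) -> None:
    pd.DataFrame({"z_mm": corr.z, "ratio": corr.ratio}).to_csv(
        path, index=False, float_format="%.9g"
    )
    Path(str(path) + ".json").write_text(json.dumps({
        "threshold": corr.threshold,
        "activation_depth_mm": None if not np.isfinite(corr.activation_depth)
        else corr.activation_depth,
        "energy_MeV": corr.energy_tag,
    }, indent=1))


def read_correction_csv(path: str | Path) -> LETCorrectionCurve:
    df = _read_numeric_csv(path, ("z_mm", "ratio"))
    side = json.loads(Path(str(path) + ".json").read_text())
    act = side.get("activation_depth_mm")
    return LETCorrectionCurve(
        z=df["z_mm"].to_numpy(), ratio=df["ratio"].to_numpy(),
        activation_depth=float("nan") if act is None else float(act),
        threshold=side.get("threshold", 1.005),
        energy_tag=side.get("energy_MeV"),
    )


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None), list, tuple))
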