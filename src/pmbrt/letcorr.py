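"""Depth-dependent LET-quenching correction for film depth doses.

Workflow: an open-field film PDD is scaled onto a reference (calculated)
PDD at the distal D90 crossing, the two curves are divided to give a
correction ratio, the ratio is activated only once it stays above a 1.005
threshold, and the resulting curve multiplies the (quenched) minibeam
peak and valley PDDs.  The correction never reduces dose and leaves
everything proximal of the activation depth untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DepthDose

__all__ = [
    "LETCorrectionCurve",
    "match_at_d90",
    "derive_correction",
    "apply_correction",
]

DEFAULT_THRESHOLD = 1.005
# consecutive above-threshold samples needed before the correction activates
DEBOUNCE_SAMPLES = 3


@dataclass
class LETCorrectionCurve:
    """Multiplicative film correction ratio versus depth.

    ratio == 1 proximal of ``activation_depth`` and >= 1 beyond it;
    ``activation_depth`` is NaN when the ratio never crossed the threshold.
    """

    z: np.ndarray
    ratio: np.ndarray
    activation_depth: float = float("nan")
    threshold: float = DEFAULT_THRESHOLD
    energy_tag: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.z.shape != self.ratio.shape:
            raise ValueError("z and ratio must have the same length")
        if np.any(self.ratio < 1.0 - 1e-12):
            raise ValueError("correction ratio must be >= 1 everywhere")
        if np.isfinite(self.activation_depth):
            proximal = self.z < self.activation_depth - 1e-9
            if np.any(self.ratio[proximal] != 1.0):
                raise ValueError("ratio must be 1 proximal of the activation depth")

    def interp(self, z) -> np.ndarray:
        return np.interp(np.asarray(z, dtype=float), self.z, self.ratio)


def _distal_crossing(curve: DepthDose, frac: float) -> float:
    """Depth of the distal crossing of frac * max(dose); error if absent."""
    d = curve.dose
    target = frac * d.max()
    imax = int(np.argmax(d))
    distal = d[imax:]
    below = np.where(distal < target)[0]
    if below.size == 0:
        raise ValueError(
            f"curve has no distal {100 * frac:.0f}% crossing; cannot match"
        )
    i = imax + below[0]
    return float(np.interp(target, [d[i], d[i - 1]], [curve.z[i], curve.z[i - 1]]))


def match_at_d90(
    film: DepthDose, ref: DepthDose
) -> tuple[DepthDose, float, float]:
    """Scale the film PDD onto the reference at the distal D90 depth.

    The match depth is where the reference falls through 90% of its
    maximum on the distal side; the film is multiplied by
    ref(match) / film(match).  Returns (scaled film, scale, match depth).
    """
    match_depth = _distal_crossing(ref, 0.90)
    _ = _distal_crossing(film, 0.90)  # both curves must have a distal falloff
    ref_val = float(ref.interp(match_depth))
    film_val = float(film.interp(match_depth))
    if film_val <= 0:
        raise ValueError("film dose vanishes at the match depth")
    scale = ref_val / film_val
    return film.scaled(scale), scale, match_depth


def derive_correction(
    ref: DepthDose,
    film_scaled: DepthDose,
    threshold: float = DEFAULT_THRESHOLD,
    energy_tag: float | None = None,
) -> LETCorrectionCurve:
    """Correction ratio ref / film on the film depth grid.

    The raw ratio activates at the shallowest depth where it stays above
    ``threshold`` for at least three consecutive samples (debounce against
    noise); it is 1 proximal of that depth and clipped at 1 from below
    beyond it.  Depths where the film signal has collapsed (< 0.1% of its
    maximum) inherit the last usable ratio.
    """
    z = film_scaled.z
    ref_on_film = ref.interp(z)
    film_d = film_scaled.dose
    usable = film_d > 1e-3 * film_d.max()
    raw = np.ones_like(z)
    raw[usable] = ref_on_film[usable] / film_d[usable]
    if np.any(usable) and not usable[-1]:
        last = np.max(np.where(usable)[0])
        raw[last + 1:] = raw[last]

    above = raw > threshold
    activation = float("nan")
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= DEBOUNCE_SAMPLES:
            activation = float(z[i - DEBOUNCE_SAMPLES + 1])
            break

    ratio = np.ones_like(raw)
    if np.isfinite(activation):
        distal = z >= activation
        ratio[distal] = np.clip(raw[distal], 1.0, None)
    return LETCorrectionCurve(
        z=z.copy(), ratio=ratio, activation_depth=activation,
        threshold=threshold, energy_tag=energy_tag,
    )


def apply_correction(pdd: DepthDose, corr: LETCorrectionCurve) -> DepthDose:
    """Multiply a film PDD by the correction ratio (edge-extended in depth).

    Warns when the PDD's energy tag disagrees with the correction's —
    corrections are energy specific and must not be reused across beams.
    """
    pdd_energy = pdd.meta.get("energy_MeV")
    if (
        corr.energy_tag is not None
        and pdd_energy is not None
        and abs(float(pdd_energy) - float(corr.energy_tag)) > 1e-6
    ):
        warnings.warn(
            f"applying a {corr.energy_tag} MeV correction to a "
            f"{pdd_energy} MeV depth dose",
            stacklevel=2,
        )
    out = pdd.dose * corr.interp(pdd.z)
    meta = dict(pdd.meta)
    meta["let_corrected"] = True
    return DepthDose(pdd.z.copy(), out, meta)
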