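# Methods

`pmbrt` implements the dosimetric commissioning analysis for proton minibeam
radiotherapy (pMBRT): converting film scans to dose, correcting the film's
LET-dependent under-response in depth-dose measurements, extracting
peak/valley structure and PVDR from minibeam dose planes, modelling the
finite footprint of scanned point detectors, and comparing profiles with a
1D gamma index. Because commissioning data (film scans, Monte Carlo phase
spaces) are not distributable, every analysis stage is driven by a synthetic
minibeam dose engine whose behaviour is documented here. All internal units
are mm, Gy, MeV and keV/µm.

## The synthetic minibeam engine

### Depth dose

Mono-energetic Bragg curves use the analytic parameterization built on the
power-law range-energy relation

    R0 [cm] = α E^p,   α = 0.0022 cm·MeV⁻ᵖ,  p = 1.77,

with Gaussian range straggling folded in analytically via parabolic
cylinder functions (fluence-reduction slope β = 0.012 cm⁻¹, local
energy-absorption fraction γ = 0.6). Straggling width is the quadrature
sum of the Bortfeld mono-energetic term 0.012·R0^0.935 and a beamline
energy spread of max(1 MeV, 0.6 % of E), chosen to give clinically typical
distal-falloff widths. Far proximal of the peak the straggling-free closed
form is used; the two branches are blended linearly over ζ = (R0−z)/σ ∈
[8, 12] so the curve stays smooth and unimodal. Curves are normalized to
`mu_scale` Gy at the surface. The distal 80 % falloff depth reproduces
α E^p to well under 1 %, and the entrance-plateau-to-peak ratio lies in
0.19–0.26 for 70–180 MeV.

### Lateral beamlet spread

A beamlet leaving a slit is Gaussian with depth-dependent sigma

    σ²(z; g) = σ_exit² + θ_exit²·(g + z)² + σ_MCS²(z),

where g is the air gap, σ_exit = 0.3 mm and θ_exit = 7 mrad are effective
collimator-exit spreads (they absorb slit-edge scatter and the in-slit
angular acceptance; both are `CollimatorSpec` fields), and σ_MCS is the
Fermi–Eyges spatial moment ∫(z−u)²T(u)du of the Rossi scattering power
T = (E_s/pv)²/X₀ (E_s = 15 MeV, X₀ = 36.08 cm for water), evaluated with
the power-law residual-range/energy relation and frozen beyond R0. The
resulting σ_MCS at end of range is ≈2.5 % of the range, the textbook value
for protons in water.

### Minibeam plane

    D(x, z) = PDD(z) · [mask ⊛ N(0, σ(z; g))](x) + leakage · PDD(z)

The slit mask (default five 0.4 mm slits, c-t-c 2.8/3.2/4.0 mm, optional
per-slit width jitter) is convolved analytically with the Gaussian via erf
differences, so lateral mass is conserved exactly when leakage = 0. The
`leakage` fraction (default 0.03) is an effective valley floor standing in
for collimator transmission plus in-phantom halo; without it the Gaussian
model produces unrealistically large PVDRs at shallow depth. Incident
fluence is uniform by default ("uniformly scanned" pencil beam); a
`spot_sum` mode sums discrete 5 mm-spaced Gaussian spots. Scoring is
cell-centered, 0.1 mm laterally and 0.5 mm in depth by default, with the
lateral axis constructed symmetric about x = 0 (the grid must span the
slits plus a 5σ margin or the convolution would be truncated — this is an
error, not a warning).

With these defaults the engine's PVDR at 1 cm depth is ≈4.9 (c-t-c 2.8 mm,
6 cm air gap), falls monotonically with depth to 1.0 near the end of range,
falls with increasing air gap (≈14 at 2 cm gap → ≈2.7 at 8 cm) and rises
with c-t-c (≈4.9 / 6.9 / 9.5 for 2.8 / 3.2 / 4.0 mm). These match the
direction and rough magnitude of measured minibeam commissioning data; no
attempt is made to reproduce absolute published values, which depend on an
unreleased beam model. One finite-array artefact is worth knowing: beyond
the comb-merge depth the five-beamlet envelope curvature lets the
centre-to-valley-column ratio creep ~0.2–2 % above 1; the PVDR = 1 claim
is therefore asserted at the 10 cm table depth with ±0.01 tolerance.

### LET proxy and film quenching

The dose-averaged LET proxy is

    LET(z) = L_ent(E) + B·(max(R0 − z, 0) + c)^(−q),  B = 0.25, c = 0.1 mm, q = 1.5,

held constant beyond R0. L_ent is 1.7× the power-law stopping power
(0.9 keV/µm at 150 MeV, 1.6 at 70 MeV); the distal maximum lands at
8–10 keV/µm. The shape is deliberately a flat plateau with a spike confined
to the last millimetre of range: film under-response must be negligible at
the distal D90 depth for the open-field correction procedure (below) to be
self-consistent, which is also what measured film shows — quenching is a
feature of the stopping region, not of the plateau.

Film response is modelled as relative efficiency

    RE(LET) = (1 + k·let_ref) / (1 + k·LET), clipped at 1,

multiplying the true dose. With the default k = 0.03 (keV/µm)⁻¹ and
let_ref at the entrance LET, the film under-reads by ≈19 % at the distal
edge and <0.5 % at the Bragg peak. k = 0 is the exact identity.

## Film chain

`film_digitize` renders a dose plane as a 48-bit RGB scan (default
300 dpi, pixel pitch 25.4/dpi = 0.0847 mm — the pitch is always derived
from the dpi tag) by inverting the per-channel calibration, optionally
multiplying netOD by a thickness-like disturbance, adding Gaussian OD
noise, applying an in-plane rotation, and quantizing against per-channel
blank values. Doses above the 40 Gy calibration ceiling are rendered at
the ceiling and flagged per pixel. All randomness flows from one integer
seed; identical seeds give bit-identical scans.

Calibration uses the rational radiochromic form dose = b₁·netOD +
b₂·netOD^n per channel (defaults: red 8/35/2.5, green 12/45/2.8, blue
25/60/3.0 — red most sensitive), valid over 0.4–40 Gy, fitted by
relative-weighted least squares (σ ∝ dose) so accuracy is uniform in
percent rather than in Gy; the reported leave-one-out dose RMS is the
honest per-point accuracy. A calibration point is an ROI-averaged reading,
so the generator assigns it 0.3 % netOD uncertainty; with 22 points the
LOO error is then ≤1 %.

`to_dose` inverts one channel, or solves per pixel the multichannel
consistency problem od_ch = (1+δ)·od_ch(D) — one dose and one
thickness-like disturbance per pixel, reduced to a 1D profile-likelihood
scan over dose with a closed-form δ, followed by parabolic refinement.
The multichannel mode recovers an injected 2 % disturbance to ≈0.02 %
median dose error where single-channel inversion is biased by ≈2.5 %.
Doses below 0.4 Gy are flagged low-confidence; saturated pixels are
masked.

`rotate_align` finds the scan rotation (±10°) maximizing the variance of
the depth-collapsed lateral profile — the comb is sharpest when the slits
are vertical — with a 0.5° coarse scan plus bounded refinement; injected
rotations are recovered to ≈0.01°. Bilinear resampling throughout.
Lateral profiles are band-averaged (default 3 rows) and re-centered on the
comb (midpoint of the outermost peaks; map centre for open fields); depth
profiles average a centred odd window (default 5 columns).

## LET-quenching correction

Following standard open-field practice: the film PDD is scaled onto the
reference PDD at the depth where the reference falls through 90 % of its
maximum on the distal side (dose scaling only — both curves share a
physical depth axis, so no range shift is applied by default); the
correction ratio is ref/film on the film grid; it activates at the
shallowest depth where it stays above 1.005 for three consecutive samples
(debounce against noise — the threshold alone is one sample of 0.5 %
noise); proximal of activation the ratio is 1, beyond it it is clipped at
1 from below, and depths where the film signal has collapsed inherit the
last usable value. Corrections carry an energy tag and warn when applied
across energies. The same curve is applied to peak and valley minibeam
PDDs — an assumption inherited from the open-field derivation; valley LET
spectra differ in reality, which synthetic data cannot probe.

End to end, with engine quenching at k ∈ {0.02, 0.03, 0.05}, the corrected
minibeam peak and valley PDDs agree with truth to ≲1.2 % RMS distal of the
activation depth; the residual is the constant RE at the D90 match depth
(the procedure's intrinsic normalization error), not a shape error. At
k = 0 the procedure is the exact identity.

## Profile analysis

Peaks are local maxima with prominence ≥5 % of the profile maximum and
separation ≥0.6·c-t-c; each valley is the minimum between adjacent peaks.
Extremum positions get sub-sample parabolic refinement; extremum doses
stay at the sampled value (refining doses biases jagged profiles). PVDR is
the highest peak over the mean of its two adjacent valleys; exact ties
between peaks resolve to the most central one, and an outermost highest
peak falls back to its single interior valley with a flag. PVDR versus
depth fixes the peak and valley columns at a reference depth (default the
shallowest requested) and ratios the depth profiles, NaN-masking depths
where the valley signal has vanished.

The central average dose is the trapezoidal mean over a 3·c-t-c window
centred on the comb — with five slits this spans the four interior valley
regions.

Detector footprints: edge-on discs average with a boxcar of the active
thickness (microDiamond 1 µm, Razor diode 20 µm — effectively the
identity at any realistic pitch); face-on discs use the chord-length
weighted kernel w(u) = √((d/2)²−u²) of the full diameter (4 mm / 1 mm),
which is the physically correct areal weighting and measurably different
from a boxcar. Kernels are unit-mass, so period averages are conserved;
profiles must be sampled at ≤ width/50 or the request errors. Scanned
detector positions refer to the proximal face; edge-on readings belong
diameter/2 deeper (a 4 mm microDiamond at nominal 45 mm reads at 47 mm),
face-on readings thickness/2 deeper.

## 1D gamma

γ(x_r) = min over x_e of √(((D_e−D_r)/(τ_D·D_norm))² + ((x_e−x_r)/τ_d)²),
evaluated at reference samples inside the ROI spanning 2 mm beyond the
outermost reference peaks, with no low-dose cut-off by default. D_norm is
the reference maximum inside the ROI (global mode, the default, consistent
with quoting a single percentage) or the local reference dose. The
evaluated profile is piecewise linear, and on each linear segment γ² is
quadratic in position, so the engine minimizes each segment in closed form
— no search-grid granularity error. `gamma_1d` restricts the search to
±5·τ_d around each reference point (points whose window leaves the
evaluated profile are flagged); `gamma_oracle` is the verification twin:
no window, no pruning, exhaustive over the profile resampled at 1 µm. On
randomized engine profile pairs the two agree to <10⁻⁹ and criteria
nesting (loosening a tolerance never lowers the pass rate) holds by
construction.

## Numerical and interface choices

- Single integer seed per configuration; no hidden global randomness.
- Config files are JSON, schema-validated with unknown keys rejected.
- Dose planes, profiles and correction curves are CSV with JSON sidecars;
  film scans are 48-bit RGB TIFF with the dpi tag required on read
  (a printed "0.8 mm at 300 dpi" style pitch is never trusted over the
  tag). Decimal separator is '.', rejected otherwise with a hint.
- Depths may be displayed in cm in reports; storage is always mm.
- Problem sizes used by the test suite and the acceptance script — dose
  planes of ~600×340 cells, film scans of ~0.5 Mpx, a 100-pair gamma
  campaign — are chosen so the full analysis chain reruns from scratch in
  well under a minute per stage on one CPU.

## What the synthetic data does and does not show

The generator reproduces the *structure* of commissioning data: Bragg
curves with realistic falloffs, slit combs that blur and merge with depth,
air-gap and c-t-c dependence of PVDR, depth-only LET quenching, film
digitization with noise, misrotation, saturation and channel disturbances,
and detector footprint averaging. It omits nuclear halo (beyond the flat
leakage floor), scanner lateral-response maps, film darkening dynamics,
slit-by-slit machining asymmetries (available via jitter but off by
default), measurement setup drift, and any mixed-energy (SOBP) LET
spectrum — the correction module explicitly targets mono-energetic beams.
Passing tests therefore demonstrate that the analysis chain is correct and
self-consistent under a faithful forward model, not that any specific
published measurement is reproduced; published PVDR tables and gamma pass
rates depend on an unreleased beam model and Monte Carlo transport and are
matched in trend only.
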