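# pmbrt — proton minibeam dosimetric commissioning toolkit

Proton minibeam radiotherapy (pMBRT) delivers spatially fractionated dose
through sub-millimetre slits: a comb of high-dose peaks separated by
low-dose valleys, characterized by the peak-to-valley dose ratio
(PVDR = D_peak / D_valley). Commissioning such fields on a clinical
machine is a dosimetry problem at the edge of what detectors can resolve:
radiochromic film has the spatial resolution but under-reads where the
linear energy transfer (LET) rises near the Bragg peak, and point
detectors like the PTW microDiamond (4 mm disc, 1 µm thick) only resolve
the comb when scanned edge-on.

`pmbrt` is a Python library for the full analysis chain a physicist runs
during pMBRT commissioning:

- **film dosimetry** — netOD calibration (dose = b₁·netOD + b₂·netOD^n per
  colour channel, 0.4–40 Gy), single-channel and disturbance-cancelling
  multichannel film-to-dose conversion, automatic comb-based rotation
  alignment, lateral/depth profile extraction;
- **LET-quenching correction** — match an open-field film depth dose to a
  reference at the distal D90, divide, threshold at 1.005, and apply the
  ratio to minibeam peak/valley depth doses;
- **profile analysis** — peak/valley detection, PVDR and PVDR-vs-depth,
  central 3×c-t-c average dose, detector volume averaging (edge-on boxcar
  vs face-on chord-weighted disc) and the proximal-face → detector-centre
  depth correction;
- **1D gamma** — γ(x_r) = min_x √(((D_e−D_r)/(τ_D·D_norm))² + ((x−x_r)/τ_d)²)
  at clinical minibeam criteria (3 %/0.1 mm, 3 %/0.2 mm), with an
  exhaustive brute-force oracle twin for verification;
- **a synthetic minibeam dose engine** — analytic Bragg curves
  (R0 = αE^p range law with straggling), Fermi–Eyges beamlet broadening,
  slit-mask ⊛ Gaussian dose planes, an LET proxy with film quenching, and
  a film scanner forward model (48-bit RGB TIFF, dpi-tagged, seeded
  noise) — so every stage is testable without measured data.

See `docs/methods.md` for the models and their assumptions.

## Worked example

`examples/` holds one short script per capability. The LET-correction
round trip (`python examples/let_correction.py`) prints:

```
film under-response: 18.8% at its worst (z = 162.8 mm, near the 156 mm range)
D90 match at 155.7 mm, film scale factor 1.0119
correction activates at 156.2 mm, max ratio 1.216
corrected PDD vs truth, distal of activation: 1.18% RMS
```

A 150 MeV open-field film PDD, quenched by the engine's LET model,
under-reads by ~19 % at the distal edge; after the D90 match and the
1.005-thresholded ratio, the corrected curve agrees with the true depth
dose to ~1 % RMS beyond the activation depth. The engine's comb behaves
like commissioning data (`python examples/simulate_minibeam.py`):

```
field size: 1.1 cm (lateral extent of the 5-slit comb)
at 1 cm depth: 5 peaks, 4 valleys, peak spacing 2.80 mm
depth_cm  pvdr
      1   4.86
      5   1.26
     10   1.00
```

and the detector-orientation study
(`python examples/detector_volume_averaging.py`) shows why scan geometry
matters:

```
ideal    PVDR  4.86   central 3-ctc average 1.383 Gy
face-on  PVDR  1.15   central 3-ctc average 1.383 Gy
gamma vs ideal: edge-on 100% at 3%/0.1 mm, face-on 6% at 3%/0.2 mm
```

the 4 mm face-on footprint flattens the comb (PVDR 4.9 → 1.15) yet
preserves the window-averaged dose to well under 2 %.

A thin CLI wraps the same library calls
(`pmbrt simulate|calibrate|film2dose|pdd|letcorr|pvdr|gamma`); every run
writes a provenance record with the config hash and seed, and identical
seeds reproduce outputs byte for byte.

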