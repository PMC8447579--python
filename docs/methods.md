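# Methods

This note documents the models, parameter choices and numerical
conventions in `sifpipe`. Units: radiances in mW m⁻² nm⁻¹ sr⁻¹,
irradiances in mW m⁻² nm⁻¹, PPFD in µmol m⁻² s⁻¹, PAR in W m⁻² (or
mW m⁻² where noted), wavelengths in nm, times in decimal hours.

## 1. Biophysical chain

The downscaling rests on a small set of spectral indices computed from
top-of-canopy reflectance `R(λ)` using band means over half-open windows
`[lo, hi)`:

- NIR window 795–810 nm, red window 665–680 nm, visible window 400–700 nm.
- **WDRVI** = (α·NIR − red)/(α·NIR + red) with α = 0.1. The weighting
  linearizes the index over dense canopies where NDVI saturates.
- **fAPAR_green** = 0.516·WDRVI + 0.726, clamped to [0, 1]. The slope and
  intercept are the calibrated linear mapping used throughout; at
  WDRVI = 0 the mapping returns 0.726 exactly.
- **fAPAR_chl** = k·fAPAR_green with k = 0.79, the fraction of green-leaf
  absorption attributable to chlorophyll.
- **FCVI** = R(NIR at 770 nm) − mean visible reflectance, using the
  reflectance band nearest 770 nm (within ±5 nm). FCVI approximates the
  product fAPAR_chl·f_esc for dense canopies.
- **PPFD→PAR**: PAR [W m⁻²] = 0.219 · PPFD [µmol m⁻² s⁻¹]; PAR in
  mW m⁻² is 1000× that. The unit chain PAR_mW/PPFD = 219 is exact by
  construction.

## 2. Forward model and instrument

At-sensor radiance around the O₂-A band is simulated on a 0.05 nm grid as

```
L(λ) = E_g(λ)·cos(SZA)·T_down(λ,d)·T_up(λ,d)·R(λ)/π
     + SIF_canopy·g(λ)·T_up(λ,d) + L_path(λ,d)
```

and convolved with a Gaussian spectral response (FWHM 0.28 nm) to a
regular 0.11 nm band grid over 670–780 nm. `g(λ)` is the far-red
fluorescence shape: a Gaussian peaking at 740 nm with σ = 25 nm,
normalized to 1 at 760 nm, so the retrieved amplitude *is* SIF₇₆₀.

The parametric atmosphere is a Beer–Lambert O₂-A model: transmittance
`T = exp(−k(λ)·d)` where `k` sums six Gaussian line groups between 759.4
and 768.8 nm with a core optical depth of 2.3 at unit effective distance
`d`; the downwelling path is 1.5× the upwelling one (two-way slant
geometry); ground irradiance is 1200·(1 − 3·10⁻⁴(λ−760)) mW m⁻² nm⁻¹;
path radiance is 0.2·d/(1+d)·(λ/760)⁻⁴; the spherical-albedo coupling
term is omitted (negligible at these albedos; an extension point). A
tabulated atmosphere (λ × d arrays, NetCDF) interpolates log-linearly in
`d`, which is exact for Beer–Lambert transmittances.

Sensor noise is Gaussian, per band, with σ = L/SNR (signal-dependent),
seeded per overpass.

## 3. SFM retrieval

The spectral fitting method solves, per pixel over the 750–770 nm window,

```
L_model(λ) = E_down(λ,d)·P(λ)/π + A·g(λ)·T_up(λ,d) + L_path(λ,d)
```

with `P` a degree-2 polynomial in (λ−760)/10 and `A` the SIF amplitude.
All free parameters enter linearly, so the fit is a linear least-squares
problem solved by SVD on a column-normalized design matrix; one factorization
serves every pixel at a given `d`. Three steps:

1. **Reference pixels**: non-vegetated pixels with NDVI ≤ 0.1 (inclusive).
   When only radiance is available, a radiance-band NDVI proxy
   (670–680 vs 770–780 nm band means) is used — a documented dialect of
   the reflectance index. At most 2000 references are used (seeded
   subsample) for calibration speed.
2. **Distance calibration**: the effective-distance scale `d*` is the
   value at which the mean retrieved SIF over the reference pixels is
   zero (soil does not fluoresce at 760 nm). The sweep covers
   d ∈ [0.5, 2.0] in steps of 0.05; a sign change is refined by secant
   iteration, otherwise the |mean| minimum is refined by parabolic
   interpolation. The mean (not median, not per-pixel zero crossing) is
   the objective: it is smooth in `d` and unbiased under symmetric noise.
3. **Per-pixel fit at d\***: amplitudes below the negative-SIF floor
   −A_floor (A_floor = 1 mW m⁻² nm⁻¹ sr⁻¹) are flagged as failed; small
   negative values are *kept* to avoid truncation bias in scene
   statistics.

**Condition guard.** With the O₂-A band present the normalized design has
condition number ≈ 16; with no absorption structure the SIF column is
collinear with the polynomial and the condition jumps to ≈ 800. The
threshold `max_condition = 100` separates the two regimes; an
unidentifiable design at every calibration distance yields an all-failed
result (flags set, `d*` = NaN), never a silent zero.

Fit-window width (20 nm), polynomial degree (2) and the zero-SIF
objective are package defaults, chosen once as stated above, not asserted
as anyone else's choices.

## 4. Downscaling and normalization

- **Escape fraction**: f_esc = FCVI / fAPAR_chl, defined only where
  FCVI ≥ 0.18 (below that the index is dominated by soil and noise) and
  fAPAR_chl > 0. Values above 1 are masked, not clipped — clipping would
  bias field statistics. Each invalid pixel carries exactly one flag
  (valid / low FCVI / f_esc > 1 / non-positive fAPAR / missing).
- **Leaf-level SIF**: SIF_leaf = π·SIF_canopy / f_esc (hemispheric
  emission from the directional canopy radiance). The inverse
  (f_esc·SIF_leaf/π) reproduces canopy SIF to machine precision.
- **Yields**: eps_PAR = π·SIF/PAR, eps_APARchl = π·SIF/(fAPAR_chl·PAR),
  eps_FCVI = π·SIF_canopy/(FCVI·PAR). By construction
  eps_FCVI ≡ eps_APARchl wherever f_esc comes from the FCVI relation —
  the cancellation is algebraic and is asserted pixelwise (≤10⁻¹² relative)
  on every run.

## 5. Synthetic study conditions

The scene generator defines the study conditions. A 128 × 128 pixel scene
(1 m GSD) contains two rectangular fields per crop archetype inside a
bare-soil margin; six overpasses at 10:10, 11:30, 12:30, 14:40, 16:10 and
17:15 local time; latitude 50.62°, day of year 180; clear-sky PPFD
follows cos(SZA) with a 2000 µmol m⁻² s⁻¹ maximum at zenith.

Crop archetypes (mean fAPAR_chl, mean f_esc, f_esc diurnal amplitude,
yield scale, NPQ depth):

| archetype | fAPAR_chl | f_esc | f_esc rise | eps_max | NPQ depth |
|---|---|---|---|---|---|
| sugarbeet-like | 0.74 | 0.60 | 0.08 | 0.9·10⁻⁴ | 0.08 |
| wheat-like | 0.62 | 0.55 | 0.00 | 5.5·10⁻⁵ | 0.35 |
| orchard-like | 0.50 | 0.55 | 0.05 | 8.0·10⁻⁵ | 0.20 |

Physiology: the apparent yield follows a light-response saturation
PPFD/(PPFD+600) scaled by (1 − NPQ_depth·H(t)), where H is a first-order
low-pass filter (τ = 1.5 h) of normalized PAR. The lag makes the
afternoon branch of the yield-vs-light loop sit below the morning branch
at matched PAR — the hysteresis signature. The sugarbeet-like f_esc rises
smoothly from 10:00 to 14:30 (leaf re-orientation) and then plateaus; the
wheat-like crop has constant leaf-angle structure, hence time-constant,
spatially uniform f_esc — which is why its canopy-leaf correlation is ≈1
by construction. Per-pixel heterogeneity is log-normal-like in yield and
Gaussian in f_esc (sugarbeet 0.05, wheat 0.0, orchard 0.12 relative).

Truth invariants hold exactly: SIF_leaf = eps·fAPAR_chl·PAR_mW and
SIF_canopy = f_esc·SIF_leaf/π, both as array identities.

**Reflectance modes.** `consistent` builds, for every vegetated pixel, a
flat-visible / smooth red edge (700–750 nm) / flat-NIR spectrum whose
band algebra inverts exactly to the pixel's fAPAR_green and
fAPAR_chl·f_esc. The construction is invertible only while
WDRVI > (α−1)/(α+1) ≈ −0.818; vegetated pixels below that floor keep an
FCVI-exact spectrum but are flagged (`noninvertible_mask`), never
silently altered. `toy_rt` is an independent two-component mixture with
pigment structure in the visible and a sloped NIR, so index inversion is
only approximate (median f_esc error ≲ 15 % over dense canopies) — a
robustness check, not a validation target. Pigment features belong to
vegetation; bare soil is spectrally flat in both modes.

## 6. Diurnal analysis conventions

- Field membership is pixel-center containment in the field polygon
  (`shapely.contains_xy`); a pixel whose center lies on the boundary is
  outside.
- Percentiles p0–p100 use NumPy's default linear interpolation; all field
  statistics carry the pixel count `n` used.
- Canopy-leaf correlation is the Pearson r over a field's valid pixels;
  fields with < 3 valid pixels are omitted, zero-variance fields are
  reported NaN and flagged degenerate. Crop-level r is the unweighted
  mean over that crop's non-degenerate fields.
- Hysteresis tables pair each overpass's field-mean yield with its light
  driver (scene PAR, or field-mean APAR_chl); they require ≥ 2 overpasses
  in chronological order, and single-overpass pipeline runs emit an empty
  table.

## 7. Numerical and statistical choices

- The retrieval design matrix is column-normalized before SVD; condition
  numbers quoted are for the normalized design.
- At SNR 500, propagating per-band noise through the least-squares design
  gives an amplitude noise floor of σ_A/SIF ≈ 2.7 % per pixel; recovery
  claims at the 1 % level therefore refer to the scene-level (mean)
  relative error of the product, with per-pixel scatter bounded by the
  propagated noise. The retrieval bias itself is zero to within two
  standard errors at SNR 250 when the atmosphere is known.
- Seeds derive from `numpy.random.SeedSequence(seed).spawn()`, reduced
  mod 2³¹, one stream per stage and overpass; a fixed seed yields
  bit-identical outputs.
- Problem sizes in the test suite: 32 × 32 scenes for unit and property
  tests, 128 × 128 for end-to-end recovery checks, 64 × 64 for the
  six-overpass diurnal runs — the sizes at which the statistics of
  interest are stable.

## 8. Interfaces

Spectral cubes read/write as NetCDF (classic format, `scipy` engine) or
ENVI BSQ (text header + float32); single-band maps as GeoTIFF with JSON
metadata in the image description; field layouts as GeoJSON; PAR series
as CSV; the atmosphere table as NetCDF; run configuration as YAML with
unknown keys rejected. The CLI (`sifpipe`) is a thin layer over the
library: each stage reads its predecessor's artifacts from the
configured output directory.
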