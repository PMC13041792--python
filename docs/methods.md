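# Methods

This note documents the models, conventions and numerical choices behind
`ramanprep`, and what the synthetic forward model does and does not
emulate.

## Coordinate systems and the Spectrum contract

A spectrum is an axis paired with intensities in one of four coordinate
systems: detector pixel (0-based), absolute wavenumber ṽ = 10⁷/λ (cm⁻¹),
Raman shift Δṽ = 10⁷/λ_laser − ṽ (cm⁻¹), or wavelength (nm). Axes are
kept strictly increasing; readers accept descending vendor exports and
sort them with intensities in lockstep, but duplicate axis values are
rejected so downstream interpolation is always well defined. Processed
output is written tab-delimited with Python's shortest round-trip float
representation, which makes write→read lossless and output files
byte-stable — the foundation of the hash-based reproducibility checks.
Spreadsheet (.xlsx) I/O is limited to 15 significant digits by the
format itself; text formats carry full doubles.

## X-axis calibration

**Peak refinement.** The Savitzky–Golay first derivative (default
window 7, order 2) of the lamp spectrum defines peak spans: the apex is
the +→− derivative sign change nearest the user's click (search
half-width 15 px), and the span extends to the flanking sign changes.
The refined position is the intensity centroid over the span, computed
on span-local baseline-corrected intensities (the span minimum is
subtracted before weighting). On a flat background this equals the plain
centroid Σp·I/ΣI; with a sloping lamp pedestal it removes the first-order
bias the pedestal would otherwise inject into the centroid. The
defaults were chosen once for ~2.5 px-wide emission lines on a
1000–2000 px detector.

**Cubic fit.** The pixel→wavenumber cubic is fitted on a centered and
scaled pixel basis (`numpy.polynomial.Polynomial.fit`) and converted
back to raw-pixel coefficients a₀..a₃ for storage, because a raw cubic
Vandermonde on pixels up to ~2000 is badly conditioned. Four distinct
pixels are the mathematical minimum; fewer than six raises a warning
(seven is typical practice). Residual diagnostics (per-pair residuals,
RMS) are attached to the fit and stored in the record.

**Laser wavelength.** Per-peak estimates 10⁷/(ṽ_abs(p_i)+Δṽ_ref,i) are
combined by the arithmetic mean; the per-peak values and their max−min
spread are retained so a wild outlier (a mis-assigned band) is visible.
When every denominator is equal the estimate is exact by construction.

**Axis convention.** The calibration record stores the per-pixel Raman
shift in pixel order (typically decreasing, since ṽ_abs grows with p);
`calibrate_spectrum` attaches it to intensities and sorts ascending.

## Spectral response correction

All three pathways produce the same `CorrectionFactor` contract
(strictly positive, strictly increasing axis) so the pipeline's P2 stage
does not care where the factor came from. Shared conventions: the
normalization point is the sample nearest the axis midpoint unless a
centre wavelength is given; the radiance table is fitted with an
order-5 polynomial (matching the SRM quintic convention) before
evaluation on the measured axis; SRM post-ratio smoothing defaults to
Savitzky–Golay window 15, order 3. The SRM certificate carries an
explicit variable convention (Raman shift vs wavelength) because
different standards define their quintic in different variables; no
certificate is bundled — it is an input. Factors are resampled onto
spectrum grids by linear interpolation, with extrapolation refused.

## The P1–P8 pipeline

Stage order is a constant of the implementation; the configuration can
activate or bypass stages but contains no ordering field, so reordering
is unexpressible. Conventions that the formulas alone do not fix:

* **P4 truncation** uses the closed interval [start, stop] (default
  900–1700 cm⁻¹, the biological fingerprint window).
* **P5 binning** anchors half-open bins [v₀+kΔb, v₀+(k+1)Δb) at the
  first truncated axis value, reports bin centres v₀+(k+0.5)Δb, and
  keeps a nonempty trailing partial bin. An empty interior bin (input
  grid coarser than Δb, default 3.5 cm⁻¹) is an error naming the bin
  rather than a silently interpolated value.
* **P6 smoothing** defaults to "none": absent configuration must not
  imply hidden processing.
* **P7 fluorescence subtraction** is the classic modpoly iteration:
  fit a polynomial (default order 5, exposed), replace the working
  spectrum by the pointwise minimum of itself and the fit, repeat. The
  working sequence is monotonically non-increasing, so it converges;
  iteration stops when the sup-norm change drops below
  tolerance × (input max − min), default 10⁻⁴, or at the iteration cap
  (default 100). Fits run on the axis mapped to [−1, 1] for
  conditioning. The converged envelope is biased low near broad peaks —
  an inherent property of lower-envelope baselines, visible in the
  tests as a residual that shrinks with peak width.
* **P3** is an explicit no-op object kept in the stage sequence (and in
  every provenance log, flagged `noop`) so a future cosmic-ray remover
  can slot in without renumbering.
* **P8** mean normalization is the default; area uses the trapezoidal
  integral over the axis; max scales the maximum to 1.

## Configuration, provenance, batch

Both JSON schemas are strict (`extra="forbid"`): an unknown or
misspelled key is a named error, never a silent default. The only
defaults are the documented ones (900/1700/3.5, smoothing none).
Instrument descriptions carry explicit `requires_calibration` /
`requires_src` flags, defaulting to off for Renishaw-class
(pre-calibrated) systems and on otherwise; the open `custom` system
makes the mechanism independent of the named instrument list.

Provenance entries store SHA-256 hashes of a canonical JSON
serialization of each stage's input and output (sorted keys, shortest
round-trip float repr), plus the verbatim configuration snapshots.
Replay re-runs the embedded configuration on the original input and
compares output hashes — the operational definition of reproducibility
used in the tests. Batch and single-spectrum modes call the same
`process_one`; batch output names embed the key parameters and a
timestamp (`stem__s900_e1700_b3.5_nmean__YYYYmmddTHHMMSS.txt`), and
per-file failures are isolated in the report.

## The synthetic forward model

The generator emulates the measurement chain with known ground truth: a
1340-px detector whose true dispersion cubic (9390, 2.7, −1.5·10⁻⁵,
10⁻⁹) covers both bundled reference libraries at 785 nm-class
excitation; Gaussian emission lines (width 2.5 px, height 1000, pedestal
50 counts) placed at the pixel roots of the cubic; sample spectra built
as gain × (bands + quadratic fluorescence) + Gaussian noise (σ = 2
counts by default) + optional single-pixel spikes, with bands loosely
modelled on common biological Raman features (1004, 1095, 1250, 1445,
1655 cm⁻¹). White-light pairs relate a smooth quadratic lamp profile and
its gain-distorted measurement.

What it does **not** emulate: detector nonlinearity and saturation,
wavelength-dependent noise, peak-shape asymmetry, real lamp line
blending, or radiometrically meaningful radiance units. Tests passing
on these fixtures therefore demonstrate the correctness of the
algorithms and the reproducibility contracts, not robustness to every
real-instrument pathology.

Problem sizes used throughout the tests and the acceptance script —
1340-px spectra, 7 lamp lines, 22 acetaminophen bands, 7-file batches,
≤ a few hundred modpoly iterations — keep any single check under a few
seconds while exercising full-size detector geometry.

## Known limitations

* Peak-to-line matching is user-supplied (ordered picks); there is no
  automatic assignment.
* P7 implements exactly the pointwise-minimum update; no asymmetric
  weighting variants (arPLS, SNIP) are provided.
* Cosmic-ray removal is a placeholder by design.
* The bundled libraries pin the published counts and endpoints; interior
  Ne–Ar values are curated from standard emission-line tables and
  interior acetaminophen values from ASTM-style band lists, and should
  be re-verified against a certificate before metrological use.
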