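# Methods

## Spectral convention

All spectra live on one-third octave band grids with exact base-10 midband
frequencies `f_c = 10^(n/10)` Hz (n an integer; 6.3–1,250 Hz is n = 8…31) and
edges `f_c · 10^(±1/20)`, so consecutive bands tile the axis exactly. Nominal
labels (6.3, 8, 10, …) are used only in files; all computation uses exact
centers. Band values are RMS accelerations per band (m/s²), not densities,
so every scalar summary is a root sum of squares. This matches the squared-sum
structure of the tool-specific transmissibility formulas and makes the
tri-axial total obey `A_t = sqrt(A_y² + A_xz²)` identically.

## Hand-arm weighting W_h

Three realizations are available (`weighting.mode`):

- `iso_wh` (default for the weighted mode): magnitude product of the standard
  analog filters — two-pole Butterworth band-limiting (high-pass 6.31 Hz,
  low-pass 1258.9 Hz) and the a–v transition (zero and two-pole section at
  15.915 Hz, Q = 0.64) — evaluated at exact band centers.
- `table`: the standard's published per-band factors.
- `unity`: all 1.0 (the unweighted-acceleration variant).

At exact midband frequencies the filter and the table agree to the table's
three printed significant figures (verified per band in the test suite), so
the choice does not affect any conclusion; the table mode exists so results
cannot hinge on filter-constant transcription. Above 500 Hz all factors are
≤ 0.0314, which is why the weighted assessment is insensitive to
high-frequency glove resonances and why the unweighted variant is computed
alongside it.

## Transmissibility synthesis

Point measurements carry a response spectrum (laser-vibrometer point on the
dorsal finger) and the handle excitation spectrum, per subject, glove (or the
bare-hand sentinel `bare`), finger, area (1 = fingertip region, ≤ 4 points;
2 = proximal region, ≤ 6 points), direction, and hand-force condition.
The pipeline:

1. select one force condition (default 30 N grip + 50 N push, the condition
   used for glove evaluation);
2. per point: finger transmissibility = response/excitation; glove
   transmissibility = gloved/bare ratio, requiring a bare-hand record with
   identical tags;
3. arithmetic mean over points within each area (points weighted equally;
   index and middle fingers pooled, as are left/right hands);
4. per subject and area: combine directions — `T_xz = sqrt((T_x²+T_z²)/2)`,
   `T_xyz = sqrt((T_x²+T_y²+T_z²)/3)`;
5. full-finger spectrum = mean of the two area spectra;
6. mean over subjects;
7. low-frequency extension and truncation at 500 Hz.

Averaging acts on transmissibility magnitudes (not squares) at every level.
Per-subject direction-combining precedes the subject mean; with the
alternative order (combine subject-mean directional spectra) results differ
only at second order in between-subject variance, but the implemented order
follows the synthesis sequence described for the original measurements.

**Low-frequency extension.** The laboratory rig drives 16–500 Hz only; below
~16 Hz gloves move with the finger and transmissibility is ≈ 1. Bands
6.3–12.5 Hz are filled by interpolating from exactly 1.0 at 6.3 Hz to the
measured 16 Hz value. The default abscissa is log-frequency (equal increments
per band index — e.g. a 16 Hz value of 1.4 yields 1.0, 1.1, 1.2, 1.3, 1.4
across the five bands), which is grid-independent on a log-uniform grid; a
linear-in-Hz switch exists for sensitivity checks.

## Tool spectra

CSV ingest (`tool,freq_hz,ax_ms2,ay_ms2,az_ms2`) with a fixed axis
convention: `y` is axial shear along the handle/finger axis, `x`/`z` are
compression; files document the shear axis as free text rather than remapping
(the direction must be fixed when the measurement is taken). Bands missing
from a spectrum are taken as zero. A strict/lenient validation switch governs
tools with an all-zero axis (several literature spectra genuinely lack
high-frequency content on one axis). The assessment band range is
6.3–500 Hz for both weighted and unweighted modes, since glove spectra do not
exist above 500 Hz; unweighted totals therefore understate tools with
substantial 500–1,250 Hz content (percussive tools, bucking bars), which
biases the unweighted R values of such tools toward optimism but is unlikely
to reorder the gloves.

## Tool-specific values and classification

The energy-weighted values (see README for the formulas) are computed by a
vectorized band sum; an independent naive per-band loop serves as the test
oracle (agreement to 1e−12 on random draws). Key properties, all tested:
T values are invariant to uniform scaling of the tool spectrum; `T_xzy` lies
between `T_y` and `T_xz`; if the glove spectra are ≤ 1 on every band then all
T ≤ 1 and R ≥ 0 (convexity of an energy-weighted mean); unity spectra give
T = 1 for any tool.

**Zero-energy directions.** If a tool has no energy on an axis in the band
range, that directional value is reported as NaN and excluded from reports
rather than set to a fabricated 1.0; the total value remains defined whenever
total energy is nonzero (its denominator uses total energy).

**Full-finger strategy.** Default `spectrum_mean`: average the fingertip and
proximal spectra per band, then evaluate — the same order as the synthesis.
`value_mean` (mean of the two locations' scalar values) is available; the
two differ on heterogeneous spectra by design, and published full-finger
reductions are not exactly recoverable from the two printed per-location
values, consistent with spectrum-level averaging having been used.

**Classification.** R is rounded to integer percent (half away from zero,
the precision of published reduction tables) and compared to the threshold
(default 10 %). The default comparison is inclusive (≥, "10 % or more"); a
strict (>) flag exists and is the comparison under which the weighted
neoprene count of three reduced tools obtains.

## Synthetic data generator

The generator stands in for the laboratory experiment and the literature
tool spectra; it emulates their structure, not any specific measured curve.

- **Glove model.** Per direction × location, a base-excitation
  single-resonance magnitude
  `T(f) = sqrt((1+(2ζr)²)/((1−r²)²+(2ζr)²))`, r = f/f_n, optionally plus an
  amplitude-scaled second mode (added as a deviation from unity so the
  low-frequency limit stays 1) and a plateau floor. Excitation is flat across
  the 16–500 Hz bands at 19.6 m/s² total RMS per direction, the level used in
  the laboratory protocol. Measurement noise is multiplicative lognormal,
  `exp(N(0, σ))` per band/point (default σ = 0.05): acceleration ratios are
  positive and errors scale with level, and the geometric mean over draws
  converges to the noiseless curve (tested at 1,000 draws, < 2 %). Defaults:
  6 subjects, 4 fingertip and 6 proximal points, one force condition
  (30 N grip + 50 N push). Bare-hand records (curve ≡ 1, noisy) are emitted
  so the full ratio pipeline runs.
- **Tool model.** Triangular amplitude envelope in band-index (log-frequency)
  around a dominant band with a half-width in bands, optional harmonic
  copies and lognormal ripple; energy split between shear (fraction f_y) and
  the two compression axes (equal halves of 1 − f_y); scaled so the
  unweighted 6.3–500 Hz total equals the requested magnitude exactly.
- **Scenario suite.** Four glove archetypes (gel-, bladder-, bubble-,
  neoprene-like) and four tool archetypes (low-frequency < 25 Hz dominant,
  broad impact, high-frequency compression, 80 Hz shear-dominant). Peak
  magnitudes are illustrative. One deliberate simplification: the real
  bubble glove's fingertip compression peak sits near 40 Hz, but a
  single-resonance base-excitation curve amplifies everything below
  `√2·f_n`, so a 40 Hz resonance would contradict the near-unity behavior
  below 25 Hz that the synthesis assumes; the bubble-like preset therefore
  uses 80 Hz. Consequently the suite demonstrates the method's qualitative
  contrasts (shear-sensitivity, resonance matching, low-frequency
  neutrality), not any glove's measured spectrum — passing scenario tests
  says the *method* orders archetypes correctly, not that the presets
  reproduce real gloves.

Seeds are explicit arguments everywhere (`numpy.random.default_rng`); no
global state, and identical seed + preset gives bit-identical output.

## Numerical and interface choices

- Grids are value objects keyed by band index; mismatched grids are rejected,
  never silently aligned.
- Transmissibility values must be finite and > 0; excitation must be > 0 on
  every band (zero-excitation bands are named in the error).
- The packaged transcriptions of the published summary tables are verified by
  sha256 at load. Rows whose printed totals fail the vector-sum identity by
  more than 0.01 (the pavement tamper in both modes, and three further rows
  off by 0.012–0.016) carry `identity_ok = False` and are excluded from
  identity checks explicitly rather than silently.
- Report tables print T to 2 decimals and R to integer percent, mirroring the
  published precision so fixture comparisons are well defined.
- Problem sizes in the test suite (e.g. 100 random draws for oracle
  equivalence, 100 seeds for parameter recovery, 6-subject generations) were
  chosen to make the statistical assertions stable at the stated bounds.

## Known limitations

- Glove spectra end at 500 Hz; tools with strong content above 500 Hz are
  only partially assessed (see above).
- The 10 % match threshold is a reporting convention, not a health-based
  criterion; no exposure-duration (A(8)) dose is computed.
- The generator does not model grip/push-force dependence of
  transmissibility, finger-to-finger variation, or the multi-peak structure
  of real glove spectra beyond an optional second mode.
- Published per-glove×tool tables cannot be reproduced from raw spectra here
  because the underlying glove and tool spectra were published only as
  figures; verification against them is via transcribed summary tables and
  algebraic identities instead.
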