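# Methods

`pureshift` simulates and analyses pure-shift ¹H NMR metabolomics data: a
spin-system/cohort simulator for aqueous fruit-extract spectra, a chunked
(interferogram) acquisition model for PSYCHE and SAPPHIRE-PSYCHE, the
standard processing chain, and the downstream STOCSY and PLS-DA
chemometrics.  This note records the models, the defaults, and the design
choices that were genuinely open.

## Spin systems and the signal model

A metabolite is a set of proton groups (label, shift in ppm relative to
TSP = 0, equivalent-proton count, symmetric J-coupling list).  The shipped
library covers the published resonances of Cape-gooseberry (*Physalis
peruviana*) aqueous extracts — sugars (sucrose, α/β-glucose, β-fructose),
amino acids (proline, glutamic acid, glutamine, GABA, asparagine, alanine),
organic acids (malic, citric) and myo-inositol.  Published shifts are used
verbatim; **all J constants, and any group shift without a published value,
are literature-typical fixtures**, editable through the YAML round-trip.

Single-pulse FIDs use the weak-coupling (first-order) approximation: each
group contributes a multiplet built by successive ±J/2 binomial splits over
its partners, every line sharing one T2.  Strong-coupling artifacts (which
survive SAPPHIRE in practice, e.g. glutamate/glutamine/citrate) are
deliberately out of scope, as are pulse-shape, gradient and relaxation
details of the real experiment; the optional global `attenuation` factor
(default 1.0) stands in for the hardware sensitivity penalty of pure-shift
acquisition.

## Chunked pure-shift acquisition

The interferogram model keeps exactly the physics the method hinges on.
For chunk k, local time δ ∈ [0, τ), global time t = kτ + δ:

    s(p, k, δ) = Σ_g a_g · e^{i2πν_g t} · Π_j cos(πJ_j u_p(δ))^{n_j} · e^{−t/T2}

Chemical shift ν_g evolves continuously through reconstructed time while
J evolution restarts at each refocusing instant; u_p(δ) = (δ − pτ/m) mod τ
is the time since the nearest preceding instant.  The periodic modulation
throws sidebands at multiples of 1/τ around every resonance — with the
instrument defaults (5 kHz window, 16 chunks of 128 samples, τ = 25.6 ms)
at ±39.06 Hz, about 2% of the parent for J = 7 Hz.

SAPPHIRE displaces the refocusing instants by pτ/m over m = 8 increments.
Because the instants move rather than the chunk grid, the modulation of
increment p is the pτ/m-translate of the p = 0 modulation (this is also why
one extra compensation block is acquired); each sideband order q then
carries the exact phase e^{−i2πqp/m} and the increment average annihilates
orders 1..m−1, leaving a small residual comb at multiples of m/τ
(±312.5 Hz).  The zero-order coefficient sin(πJτ)/(πJτ) is the same for
every displacement, so the parent height is unchanged by the averaging.
The `mod τ` wrap is essential: without it the displaced cosines average to
a single re-phased cosine and the suppression largely disappears.  The
compensation chunk is stored (prepended by default) and skipped at
reconstruction; with this idealized model its content is bookkeeping only.

## Processing

Assembly concatenates the signal chunks in global-time order.  Processing
is apodize → halve the first point → zero-fill (default 32768) → FFT →
phase → real part; apodization is a 0.3 Hz exponential for single-pulse
spectra and a π/2-shifted sine bell — defined as cos(πn/2N), a pure cosine
window — for pure-shift spectra.  A Gaussian window (`gb_hz`, FWHM in Hz)
and a magnitude-mode output are provided for artifact metrology: the cosine
window's first sidelobes (≈3% at ±3.7 Hz for a 0.41 s record) are larger
than the sidebands being measured, and a chunking sideband has an arbitrary
complex phase, so its real-part maximum is displaced while its magnitude
maximum is not.  The sideband-offset measurement therefore uses a Gaussian
window just wide enough (3 Hz) to suppress truncation wiggles while keeping
the ±39 Hz comb resolved, on the magnitude spectrum.  Peak picking refines
positions by three-point parabolic interpolation (ties toward lower ppm);
at 32768 points over 5 kHz the grid step is 0.153 Hz ≈ 0.0003 ppm at
500 MHz, and the collapsed peaks of a noiseless run land within one step of
their library shifts.

One quantitation subtlety: PSYCHE conserves a multiplet's integral once the
sideband comb is included (the modulation is unity at every chunk start),
while SAPPHIRE cancels the sidebands destructively, leaving the parent at
the zero-order factor sin(πJτ)/(πJτ) (−5% at J = 7 Hz).  The ≥10%
quantitation errors of real pure-shift experiments come from unmodelled
hardware losses and are not reproduced here.

## Cohort simulation

Concentrations are log-normal: per metabolite, σ_log = √log(1+CV²) and mean
log(group mean × multiplier) − σ²/2, so the arithmetic mean matches the
design; draws are clipped to the 0.5–110 mM span of the quantified extract
constituents (truncation, not resampling).  Correlation is imposed on log
concentrations through block-assembled matrices (PSD-validated at
construction; blocks apply in order, later pairs overriding earlier ones,
which lets the default design state "sugars mutually +0.9, each −0.8
against sucrose").  Intramolecular covariance is automatic, since all
groups of a metabolite scale with its one concentration.  The default
six-region cohort uses n = 10 per region (7 for Celendin III; 57 samples),
CV = 0.2, and modest regional multipliers (±20–50% on a few metabolites)
as the class structure.  What the generator does **not** emulate: baseline
and phase distortions, pH-dependent shift drift, peak-shape heterogeneity,
and strong coupling — so passing tests demonstrate correctness of the
analysis chain, not robustness to real-data artifacts.

## Preprocessing, STOCSY, chemometrics

Alignment is segment-wise integer shifting against the mean spectrum,
scored on the unfilled overlap (edge-filled points would bias the score),
vacancies filled with the segment edge value, ties toward zero shift.
Exclusion (residual water 4.66–5.18 ppm plus configurable standard/empty
windows) precedes total-intensity normalization; both are idempotent.

STOCSY is Pearson correlation across samples at full resolution (no
bucketing); the 2D matrix supports column decimation purely as a
plotting-memory control, never for the 1D driver vector, which maps the
requested ppm to the nearest retained column.  Zero-variance columns get
r = 0 and a flag rather than an error.

PLS-DA regresses one-hot class membership on the Pareto-scaled matrix with
NIPALS (deflation of X and Y, Y-score initialized from the largest-variance
Y column, tolerance 1e-10 on the weight update).  The iteration cap is
10 000: with a multi-class Y the two leading covariance eigenvalues are
often close and linear convergence to 1e-10 genuinely needs thousands of
iterations; a small cap would reject valid problems.  Reporting is
per-component and non-cumulative: R²X_a = ‖t_a p_aᵀ‖²/‖X₀‖², R²Y analogous,
and Q²_a = 1 − PRESS_a/RSS_{a−1} with group-stratified seeded 5-fold CV
(the previous-component denominator convention; cumulative-Q² software
differs).  The Hotelling 95% region uses T²crit = 2(n²−1)/(n(n−2))·F(0.95;
2, n−2) along the score principal axes.  The loading/STOCSY overlay pairs a
component's X-loading vector with the driver's r² per point — a single
trace per point even for a 6-class Y, matching how such overlays are drawn;
full regression coefficient matrices are exposed separately.

## Problem sizes and verification fixtures

The canonical desk-scale fixtures are: a two-spin J = 7 Hz doublet (the
sideband fixture; the partner is placed 625 Hz away, on the residual
m/τ comb, so its order-8 sidebands coincide with the parent's comb instead
of contaminating intermediate search windows), a 1:2:1 triplet, a
two-metabolite independence cohort, and the full 57-sample six-region
extract.  The test suite and the acceptance script run these end-to-end in
well under a minute each; the full cohort pipeline (57 samples × three
acquisition modes, 32768-point spectra) takes ≈15 s.  Monte-Carlo checks
(correlation recovery at n = 10⁴, Hotelling coverage at n = 10⁵,
permutation-null Q² over 50 seeds) use fixed seeds throughout.

## Known limitations

- First-order multiplets only; no strong coupling, so the residual
  artifacts the real experiment shows at 2.13–2.16 ppm and 2.75–2.87 ppm
  have no counterpart here.
- The idealized SAPPHIRE cancellation is exact; real spectra retain
  hardware-limited residuals.
- Real-part "sideband" measurements bottom out at the apodization-tail
  floor of neighbouring lines (~0.01–0.05% of a parent); suppression claims
  beyond that floor are verified at the modulation level instead.
- The JCAMP-DX writer emits XYDATA (X++(Y..Y)) AFFN at 6 significant
  digits; compressed (DIF/DUP) encodings are read back only by tolerant
  parsers, not emitted.
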