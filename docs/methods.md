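# Methods

## The measurement being modeled

A single-fluorophore excitation-ratiometric kinase activity reporter carries a
circularly permuted GFP between a substrate peptide and a phospho-binding
domain. Phosphorylation shifts the chromophore population so that emission
under 480 nm excitation rises while emission under 400 nm excitation falls;
the per-ROI excitation ratio R = I480/I400 is therefore a monotone readout of
the phosphorylated sensor fraction, independent of expression level and
illumination gain. The package quantifies such recordings and, because raw
imaging data for this sensor class is rarely shared, ships a generator that
produces the same data structure with known ground truth.

## Synthetic-data generator

**Activation kinetics.** The phosphorylated fraction follows
f(t) = A·(1 − e^(−k(t−t_stim))) for t ≥ t_stim and 0 before, optionally
followed by exponential decay after an inhibitor addition. This
single-exponential form is the simplest kinetic that admits a closed-form
ground truth (plateau A, half-time ln2/k) and matches the summary statistics
such experiments report. Per-cell amplitude and rate are lognormal around the
population values with the mean preserved; amplitude draws above 1 are clipped
to 1 and logged. Heterogeneity of reporter responses across cells is a robust
experimental observation; lognormal is the standard non-negative
heterogeneity model.

**Defaults as study conditions.** Stimulus at 5 min; frame interval 0.5 min
(mid-range of typical 15–60 s acquisition); amplitude 1.0 (a saturating
stimulus); rise rate ln2/3.09 min⁻¹ (a fast, lysosome-like response);
cell-to-cell CV 0.16 (≈ the across-cell SD/mean of strong reporter responses);
sensor calibration r_min = 1.0, r_max = 2.8 so that full activation yields
ΔR/R0 = 1.8; channel brightness 5000 photons, giving a baseline ratio SD of
√(2/5000) ≈ 0.02; photobleaching 0.002 min⁻¹ per channel; read noise 3
photons; FRAP exchange rate ln2/8.84 min⁻¹. These values are fixed once as
the simulated study's conditions, not tuned per experiment.

**Channel rendering.** The intrinsic ratio is affine in the phospho fraction,
R(f) = r_min + (r_max − r_min)·f. This affinity is load-bearing: it makes the
generator's declared truths exact (ΔR/R0 = (r_max/r_min − 1)·A, and the
half-max time of R equal to that of f). An affine ratio cannot be produced by
two channels that are both affine in f, so the 480 nm channel is rendered
exactly linear, I480 = b480·(1 + α·f) with α = (r_max/r_min − 1)/2, and the
400 nm channel as the ratio-consistent monotone decrease
I400 = b400·(1 + α·f)/(1 + (r_max/r_min − 1)·f). Only the directionality of
the two channels is physically constrained; the split of the dynamic range
between them is a convention. Bleaching multiplies each channel by
e^(−λ_ch·t); equal per-channel rates cancel exactly in the ratio. Noise is
Gaussian shot noise with variance equal to the mean (the usual
Poisson-at-thousands-of-photons approximation for sCMOS detectors) plus
additive Gaussian read noise.

**Intensity grid.** All rendered intensities are snapped to multiples of
2⁻²⁰ photons (~10⁻⁶, far below any noise floor). On-grid float64 values below
~2³³ add and average without rounding error, so the noiseless
render → ROI-mean-extraction round trip is *bit*-exact by construction rather
than approximately exact.

**Geometry.** Cells are discs on a jittered lattice; each contains a nuclear
disc, a cytoplasmic annulus, disjoint lysosomal puncta (one ROI, several
connected components), and curvilinear mitochondrial paths. The geometry is
deliberately schematic — only ROI pixel statistics (areas, disjointness,
presence of a cell-free background) matter to the downstream analysis, not
organelle morphology. What passing tests therefore show about real data is
limited to the arithmetic of extraction and metrics; they say nothing about
segmentation quality, focus drift, or motion, which are out of scope.

## Quantification

Per frame and channel, an ROI trace is mean(ROI pixels) − mean(cell-free
background pixels). The background estimate is per-frame rather than a single
constant so that lamp drift and background bleaching are absorbed; this also
makes every trace exactly invariant to adding a constant to all pixels of a
frame. Background-corrected values ≤ 0 are retained but flagged; the ratio
stage masks those frames (a non-positive denominator or numerator makes the
ratio meaningless) and excludes them from all statistics.

## Response metrics

* **Baseline window**: all unmasked frames strictly before the stimulus
  (≥ 3 required, configurable).
* **Rmax**: raw post-stimulus maximum by default. An optional centered
  odd-width rolling mean is exposed because the raw maximum of a noisy trace
  is upward-biased by the extreme-value statistics of the noise — and under
  photon noise the plateau SD is ≈ R times the baseline SD, so at ΔR/R0 ≈ 1.8
  the bias reaches several percent. The package's recovery workflows (demo,
  acceptance script) use a 5-frame window (2.5 min, well below the 3.1 min
  response half-time); the default stays raw so the formula is the literal
  (Rmax − R0)/R0.
* **t½**: measured from the stimulus time to the first upward crossing of
  1 + ΔR/R0 / 2 on the normalized trace, linearly interpolated between the
  bracketing frames. If the frame before the crossing sits at or below
  baseline (a step straight out of rest), the crossing is assigned to the
  crossing frame itself — interpolating into a frame with no measurable rise
  would invent information. Traces with ΔR/R0 below a responder threshold
  (default 0.1) return NaN with a flag instead of a garbage time.
* **SNR**: ΔR/R0 over the baseline SD of the normalized ratio (sample SD,
  n−1 everywhere). A zero baseline SD (noiseless synthetic input) is an error
  rather than an infinite SNR.
* **Z-factor**: implemented as Z = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| with *means* in
  the denominator — the standard assay-window definition. Printed formulas
  for this statistic sometimes show σ in the denominator; that form is
  dimensionally inconsistent (it would not be unitless and degenerates when
  the two spreads are equal) and is treated here as a typographical slip, not
  reproduced. The negative population should be an independent control (e.g.
  a phospho-null reporter); per-cell baseline means of self-normalized traces
  are identically 1 and carry no information.
* **Group statistics**: mean ± SD/SEM per compartment and the unpaired
  two-tailed Welch t test with Satterthwaite degrees of freedom. Multiple-
  comparison procedures are intentionally out of scope.

## FRAP fitting

Traces are normalized to the pre-bleach mean (≥ 3 pre-bleach frames); an
optional double normalization against an unbleached reference ROI cancels
acquisition bleaching exactly and is off by default. The post-bleach segment,
re-zeroed to the first post-bleach frame, is fitted to
y(x) = a(1 − e^(−bx)) + c by bounded least squares (b > 0) with deterministic
initialization — c₀ the first post-bleach value, a₀ the last value minus c₀,
b₀ from a log-linear regression of (plateau − y) — and a three-point
multi-start on b₀ (×0.2, ×1, ×5) before declaring non-convergence. A fit that
fails or pins b at its bound reports `converged=False`; half-time and mobile
fraction then raise rather than return garbage. Definitions: t½ = ln2/b
(the half-time of an exponential approach), mobile fraction = a / bleach
depth, clipped to [0, 1 + 0.05]. Standard errors come from the Gauss–Newton
covariance (JᵀJ)⁻¹·SSE/dof. On noiseless model data the fit recovers (a, b, c)
to ~10⁻⁶ over the documented parameter box; at Gaussian noise SD 0.02 and 120
frames the median relative error on b is ~2–3%.

## Shuttle compartment model

Four species — cytoplasmic/nuclear × inactive/active — with mass-action
first-order kinetics. Activation (rate k_act, and k_act_nuc in the nucleus)
acts only while the stimulus indicator u(t) is on; dephosphorylation k_deact
acts in both compartments (a nuclear override is exposed, default equal,
since compartment-specific phosphatase activity is plausible but
unmeasured); import/export k_in/k_out apply to active and inactive species
alike, consistent with the experimental observation that photobleaching
recovery of the tagged kinase is unchanged by stimulation. Amounts (not
concentrations) are propagated; volumes are absorbed into the rates.

Because u(t) is piecewise constant the system is piecewise linear
time-invariant, and trajectories are propagated *exactly* by cached matrix
exponentials of the 4×4 generator — no ODE stepper, no stiffness issues, and
mass conservation at the 10⁻¹⁴ level. The in-silico photobleach zeroes the
nuclear label at the transport steady state and follows the inert label's
two-pool kinetics; its recovery rate is k_in + k_out, which approaches the
reservoir-limit value k_out (half-time ln2/k_out) when k_in ≪ k_out.

Default rates: k_act = ln2/3.09 min⁻¹ (cytoplasmic activation at the fast
measured response scale), k_in = k_out = ln2/(2·8.84) min⁻¹ so the exchange
half-time ln2/(k_in+k_out) equals the measured 8.84 min nuclear recovery,
k_deact = 0. The model is used for *scenario discrimination*, not rate
estimation: it reproduces the qualitative ordering (nuclear activity slower
than exchange; zero response under NLS sequestration; exchange-independent
response under in-situ activation), and no claim is made that its absolute
nuclear half-time matches any particular measured value — the rates are not
identifiable from the summary statistics alone.

Scenario half-times use the same first-crossing convention as the trace
metrics, with a plateau guard: the species must change by less than 0.1%
over the final 10% of the grid, otherwise the caller is told to extend the
horizon (the default report horizon is 360 min because the slowest relaxation
eigenvalue of the default scenario is ≈ 0.039 min⁻¹).

## Numerical and design notes

* Seeds are mandatory for every stochastic operation; a single pipeline seed
  fans out via `numpy.random.SeedSequence.spawn`, and identical seeds give
  bit-identical outputs (the CLI demo is byte-deterministic).
* Ratio masking: frames with a non-positive intensity in *either* channel are
  excluded — a positive ratio is required downstream.
* The step-vs-interpolation convention for t½, the per-frame background, and
  the full-post-stimulus Rmax window are declared choices where the
  experimental literature states none.
* Problem sizes in tests and the acceptance script (20-cell populations, 100
  FRAP replicates, 5×5 scenario grids, 96–128 px frames) were chosen as the
  smallest sizes at which the estimated quantities are statistically stable.

## Limitations

The generator emulates well-mixed ROIs with schematic geometry: no PSF, no
3D, no cell movement, no segmentation errors, no detector fixed-pattern
noise. The FRAP model is a single well-mixed pool (no diffusion geometry or
two-component recovery). The shuttle model ignores isoform differences and
upstream kinase dynamics, and treats transport as first-order with a single
effective rate pair. Conclusions transfer to real data only to the extent
those assumptions hold.
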