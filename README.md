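# ratiomet

Quantification of **excitation-ratiometric kinase-activity biosensor imaging**,
built for single-fluorophore reporters of AMPK activity (cpGFP-based "ExRai"
sensors) whose emission rises under 480 nm excitation and falls under 400 nm
excitation as the sensor is phosphorylated. The package covers the full
analysis chain a cell-signaling imaging lab runs on such data, plus a
synthetic-data generator with known ground truth so every stage is testable
without any microscope data.

## What it computes

Per ROI and time point, the excitation ratio and its baseline-normalized form:

    R(t) = I480(t) / I400(t),        R_norm(t) = R(t) / R0,

with `R0` the mean ratio over the pre-stimulus baseline and intensities
background-corrected per frame against a cell-free region. From each
normalized trace:

* **maximum ratio change** ΔR/R0 = (Rmax − R0)/R0,
* **time-to-half-maximum** t½ — first upward crossing of the half-maximal
  level after drug addition, linearly interpolated,
* **SNR** = ΔR/R0 divided by the baseline SD,
* population **Z-factor** Z = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|, plus descriptive
  summaries (mean ± SD/SEM) and the Welch two-sample t test.

Two model-fitting components follow the statsmodels model/results pattern:

* **FRAP** — nuclear photobleaching recovery fitted to
  y(x) = a(1 − e^(−bx)) + c by bounded nonlinear least squares
  (`ExponentialRecovery(trace).fit()`), yielding the exchange half-time
  t½ = ln2/b and mobile fraction a/depth with standard errors and a
  `summary()` table.
* **Shuttle model** — a four-state mass-action compartment model
  (cytoplasmic/nuclear × inactive/active) of cytoplasm-initiated nuclear
  kinase activity, propagated exactly by matrix exponentials. Its scenario
  report contrasts *shuttling*, *in-situ activation*, and *NLS-sequestration*
  and reproduces the diagnostic ordering: nuclear activity develops more
  slowly than the measured nucleocytoplasmic exchange.

## Worked example

```bash
ratiomet demo --out-dir demo_run --seed 7
```

renders a 6-cell, two-channel synthetic experiment (stack + masks + ground
truth), extracts background-corrected traces, computes per-ROI metrics, fits a
FRAP trace, runs the shuttle scenarios, and prints:

```json
{
  "dr_recovery_error_pct": 0.1944268648620542,
  "frap_t_half_min": 8.64280401160113,
  "frap_true_t_half_min": 8.84,
  "mean_dr_over_r0": 1.758434314477692,
  "mean_t_half_min": 3.2150624725919457,
  "n_rois": 24,
  "shuttle_nuclear_t_half_min": 25.2289232202958,
  "t_half_recovery_error_pct": 0.254686823258908,
  "z_factor": 0.8372292929517675
}
```

Reading this: across 24 ROIs the measured population-mean ΔR/R0 (1.76) and
t½ (3.2 min) recover the generator's ground truth to 0.2–0.3%; the FRAP fit
recovers an 8.84 min exchange half-time from a noisy trace to within 0.2 min;
the Z-factor of 0.84 against a phospho-null control population indicates a
wide assay window; and the shuttle model's nuclear-activity half-time
(25.2 min) exceeds its exchange half-time (8.84 min), the signature of
cytoplasm-initiated nuclear activity. Each run writes a `manifest.json`
(seed, config hash, versions) and is byte-reproducible for a given seed.

The same stages are available as `ratiomet simulate / quantify / analyze /
frap / shuttle`, and as library calls (`ratiomet.kinetics.compute_metrics`,
`ratiomet.frap.ExponentialRecovery`, `ratiomet.shuttle.ShuttleModel`, ...).

## Scope

No automated segmentation, registration, drift correction, optical PSF
simulation, diffusion-based FRAP models, or multiple-comparison statistics
(only the Welch t test and descriptive summaries). See `docs/methods.md` for
the model details, parameter defaults, numerical choices and limitations.
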