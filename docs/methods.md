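# Methods

Models, estimators, generator design, and numerical choices behind
`tmmspect`. All data are synthetic; every stochastic generator takes an
explicit integer seed and uses `numpy.random.default_rng` (no global state).

## 1. Kinetic model

Hyperpolarized [1-¹³C]-alanine (A) is transaminated to pyruvate (P) and
reduced onward to lactate (L). Longitudinal magnetizations follow the
unidirectional precursor-product chain with T1 relaxation:

```
dA/dt = u(t) − (1/T1a + k_ap) · A
dP/dt = k_ap · A − (1/T1p + k_pl) · P
dL/dt = k_pl · P − L/T1l
```

with `u(t)` the bolus input into the alanine pool. Default parameters:

| class | k_ap (1/s) | k_pl (1/s) | rationale |
| --- | --- | --- | --- |
| CONTROL | 0 | 0 | no conversion |
| TERT | 0.008 | 0.08 | abundant NADH drives pyruvate→lactate; lactate dominates |
| ALT | 0.008 | 0.002 | abundant α-KG drives transamination, little onward reduction; pyruvate dominates |

T1s default to 44 s (alanine) and 30 s (products); polarization 12 %. The
TERT/ALT classes differ in k_pl by 40-fold, comfortably above the ≥4-fold
separation the classification property requires.

### RF sampling

Each excitation with flip angle θ observes a transverse signal `s = m·sin θ`
and depletes the longitudinal pool by `cos θ`. Two schedules are built in:

* **cell study**: single flip 13°, TR 3 s, 100 excitations (300 s);
* **in vivo**: multi-flip — 3° on the alanine substrate (preserving its
  magnetization) and 30° on pyruvate/lactate (amplifying the weak product
  signals), TR 3 s, 60 excitations.

### Exact propagation

The system is linear and time-invariant on every interval where the bolus
rate is linear, so propagation between events uses a matrix exponential of a
5×5 augmented system (state `[A, P, L, u, 1]`) — no ODE solver tolerances.
Propagators are cached by `(dt, input slope)`; bolus knots split the
integration intervals so the input is exactly linear per segment.

Substrate-only decay has the closed form
`s(n) = m0·sin θ·(e^(−TR/T1)·cos θ)^n`, which the simulator matches to
≈1e−15 relative — this is the oracle for the conservation/closed-form tests.

### Bolus

* `instantaneous` (cell studies): the whole dose enters the alanine pool at
  t = 0.
* `trapezoid` (in vivo, 12 s injection): a symmetric trapezoid with rise =
  fall = 15 % of the duration (a design choice; only the total duration is
  physically specified). The profile integrates exactly to the dose.

## 2. Spectral synthesis and quantification

Spectra live on a uniform **descending** ppm axis (NMR convention); bin *i*
is centered at `center + bw/2 − (i + ½)·Δ`, Δ = bandwidth/n_points. Each
metabolite contributes a **unit-area absorption Lorentzian** (FWHM 0.12 ppm)
scaled by its signal, at 176.5 (alanine), 170.6 (pyruvate), and 183.2 ppm
(lactate). Noise is i.i.d. circular complex Gaussian, σ per real/imaginary
component per bin.

Quantification primitives (`tmmspect.spectra`):

* **Integration** = Riemann sum × bin spacing. A bin belongs to a window when
  its center lies in the closed interval (boundary ties included). Real mode
  sums the (signed) real part; magnitude mode sums |value| per bin and is
  positively biased by rectified noise — both are exposed because the
  original acquisition mode for the cell arrays is ambiguous.
* **Noise** σ = sample standard deviation (ddof = 1) of the **real part** of a
  designated signal-free region.
* **SNR** = maximum magnitude within the window divided by σ (conventional MR
  definition, not the integral).

### Integration windows: half-width 0.5 ppm

The default metabolite windows use half-width 0.5 ppm (≈4 linewidths). A
0.5 ppm half-width captures 92 % of each Lorentzian — identically for every
peak, so conversion *ratios* are unbiased — while keeping the positive noise
floor of magnitude-mode integration small. Wider windows (e.g. 1.5 ppm) add
noise area three times faster than signal and measurably bias low ratios
upward; the choice was made from this noise-free analysis, not tuned against
test outcomes.

## 3. Dynamic readouts (`tmmspect.dynamics`)

* **Build-up curves**: per-time window integrals; optional normalization to
  the maximum substrate integral and cell count (matching the live-cell
  convention) or per cell.
* **Ratios**: product/substrate either from the summed spectrum or as
  trapezoidal AUC ratios; both are labeled by `basis` because the source
  convention is ambiguous.
* **Classification** (`classify_tmm`): NONE when both ratios are below
  `min_conversion` (default 0.02); otherwise lactate dominance by
  ≥ `dominance_margin` (default 1.5) → TERT, pyruvate dominance → ALT, ties →
  NONE. Thresholds are configurable and recorded in every run summary.
* **T1 estimation**: with no conversion,
  `ln s(n) = const + n·(−TR/T1 + ln cos θ)`, so the log-linear fit gives
  `T1 = −TR/(slope − ln cos θ)`. Exact on noise-free data; requires strictly
  positive signals (callers fit the range where that holds).
* **Rate estimation**: least-squares fit of `(m0, k_ap, k_pl)` against the
  forward simulator with T1s held fixed — rates and relaxation are not
  jointly identifiable from a single-flip dataset. Bounds keep rates in
  [0, 1] /s; tolerances 1e−12.

### Identifiability and the recovery study

Under the single-flip 13° cell schedule with TERT-like rates the pyruvate
pool is nearly unobservable (its quasi-steady level is
`k_ap/(k_pl + 1/T1p + …) ≈ 7 %` of alanine), and the k_pl estimate from
noisy data is strongly right-skewed: at per-bin SNR 20 the mean bias reached
+34 % (TERT rates) to +136 % (ALT rates). This is an identifiability property
of the experiment, not an estimator bug — and it is exactly why the in vivo
design uses low flip on the substrate and 30° on the products. Under the
multi-flip schedule the parameter-recovery study measures bias of
−0.03 % (k_ap) and −0.50 % (k_pl) over 100 seeded replicates at per-bin
SNR 20 (tallest peak bin height / σ = 20).

## 4. EPSI analysis (`tmmspect.epsi`)

Scene: 8×8 grid over a 43×43 mm² field of view (in-plane voxels
43/8 = 5.375 mm), 128 spectral points over 20 ppm, TR 3 s, slice 8 mm. A 2×2
tumor block carries the class kinetics, a 2×2 contralateral block alanine
only, and two out-of-brain corner voxels are designated noise voxels.

* **Per-voxel quantification** is magnitude-mode: σ pooled from the noise
  voxels (real part, all frequencies and times), window integrals per time
  point, trapezoidal AUC over time, substrate SNR = max over time of the
  windowed peak SNR.
* **Ratio maps** are gated on the alanine SNR; invalid voxels carry **NaN,
  never 0**, so downstream statistics cannot silently absorb them.
* **Heatmaps**: separable Lanczos-2 interpolation
  (`L(x) = sinc(x)·sinc(x/2)`, support |x| < 2) of the ratio map
  (ratio-then-interpolate, recorded in the run summary). Output sample (i, j)
  sits at input coordinate (i/f, j/f), so original nodes are preserved
  exactly; per-sample weight renormalization reproduces constant fields
  exactly and excludes NaN (gated) voxels from the kernel sum instead of
  letting them poison their neighborhood.
* **Tumor volume** = Σ(slice contour areas) × slice thickness.

### SNR gate default: 5.0 (deviation from the nominal 3.0)

Under the SNR definition above, the statistic for a pure-noise voxel is the
*maximum* of ≈240 Rayleigh-distributed magnitudes (window bins × time
points), whose expected value is ≈3.3 σ — so a 3.0 gate passes essentially
every noise voxel. The default gate is therefore 5.0 (a noise voxel exceeds
5 σ with probability < 10⁻² per map; true voxels in all shipped scenes sit
at SNR > 50). The gate remains a config knob (`snr_threshold`) for other
noise regimes.

## 5. Statistics (`tmmspect.stats`)

* **PCA** via SVD of the centered (optionally autoscaled) table, with a
  deterministic sign convention: the largest-magnitude loading of each
  component is made positive. Explained-variance fractions sum to 1.
* **PLS-DA VIP** via NIPALS with the centered group indicator as response
  (one column for two groups). With `SS_a = (tᵀt)(qᵀq)` the Y-variance
  explained by component a and unit weights w_a,
  `VIP_j = √(p·Σ_a SS_a w_ja² / Σ_a SS_a)`; the identity `Σ_j VIP_j² = p` is
  validated on construction. VIP > 1.0 flags discriminating metabolites.
  Cross-checked against scikit-learn's PLS weights in the tests.
* **Welch's t** with Satterthwaite degrees of freedom (cross-checked against
  scipy to 1e−10); identical samples return t = 0, p = 1.
* **Holm–Šídák**: sorted ascending, `adj_(i) = 1 − (1 − p_(i))^(m−i+1)`, made
  monotone by a running maximum, rejected step-down while adj < α; results
  returned in the original order (cross-checked against statsmodels).
  Family-wise error under the global null is verified by simulation (1000
  seeds) to stay within α + 2 Monte-Carlo standard errors.

## 6. Assays (`tmmspect.assays`)

* **c-circle level** (ALT marker): per sample,
  `RQ = eff^−(Ct_tel − Ct_ref)` per condition (amplification efficiency 2.0
  by default) and level = RQ(with φ29) − RQ(without φ29). Negative levels are
  reported as-is (assay noise in ALT-negative samples). The generator
  `synth_ct_table` inverts exactly at zero Ct noise.
* **Saturation correction**: Ernst steady-state fraction
  `f = sin θ·(1 − E)/(1 − cos θ·E)`, `E = e^(−TR/T1)`; measured integrals are
  multiplied by 1/f.
* **Absolute ¹H quantification** against an external TSP reference
  (amount = conc[mM] × volume[µL] × 10⁶ fmol; 9 equivalent protons):
  per-nucleus integral ratio × reference amount × saturation correction /
  cell count.

## 7. I/O and provenance (`tmmspect.io_cli`)

* **Container**: HDF5 (no community standard exists for dissolution-DNP
  spectral arrays) with a `schema_version` attribute gating reads; axis,
  schedule, seed, and a JSON provenance block are always stored. Validation
  errors name the missing node path or the offending version.
* **Config**: YAML validated against a published key/type schema before any
  computation; errors name the offending key. Configs hash (SHA-256, 16 hex
  chars) into every run summary.
* **Results**: tables as CSV; maps and masks as NIfTI-1 with the voxel
  geometry in the affine (plus CSV copies of maps); a JSON summary with
  software version, seed, and config hash.
* **CLI**: `tmm simulate-cells | simulate-epsi | quantify-dynamic |
  quantify-epsi | stats | assay | demo-tmm`.

## 8. Generator realism and limits

The generators reproduce the *structure* of the experiments — kinetic
ordering, flip/TR bookkeeping, spatial layout, noise statistics — but are
deliberately simplified:

* Lorentzian peaks are perfectly phased absorption lines; no baseline roll,
  phase errors, B0 drift, or lipid/macromolecule background, so no phasing or
  apodization is implemented (a stated non-goal).
* The kinetic chain is unidirectional with a well-mixed single compartment;
  no perfusion modeling, reverse exchange, or vascular input dispersion
  beyond the trapezoid bolus.
* EPSI voxels are independent (no point-spread blurring between voxels or
  partial-volume mixing), and receiver noise is white complex Gaussian.
* Steady-state metabolite tables are log-normal around group means with a
  common CV; covariances between metabolites are not modeled.
* The qPCR model treats amplification efficiency as exact and shared.

These limits mean the suite validates *algorithms against their generating
models*, not biological effect sizes.

## 9. Known-failing acceptance criterion

The hyperpolarization-gain criterion requires a ≥10,000-fold enhancement of
12 % polarization over thermal equilibrium at 14 T, 298 K. With
P_thermal = tanh(ħγB/2kT), γ(¹³C) = 6.728284×10⁷ rad s⁻¹ T⁻¹, and CODATA
constants, P_thermal = 1.207×10⁻⁵ and the gain is **9,940** — 0.6 % below the
bound. The ">10,000-fold" figure is an order-of-magnitude claim about
dissolution DNP generally, not a computation at these exact conditions. The
physics is implemented faithfully and the acceptance test asserts the
criterion as written, so it fails; nudging the field, temperature, or γ to
manufacture a pass would misrepresent the physics.

## 10. Numerical choices

* Matrix exponentials via `scipy.linalg.expm` on 5×5 systems, cached.
* Nonlinear fits via `scipy.optimize.least_squares` (bounded, tol 1e−12).
* AUC by the trapezoidal rule on the acquisition grid.
* PCA via `numpy.linalg.svd`; NIPALS stops at relative score change 1e−12.
* All problem sizes are desk-scale: the full test suite runs in well under a
  minute of pure computation apart from the seeded-replicate studies
  (≈3 s each), and the acceptance script is deterministic and sub-second.
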