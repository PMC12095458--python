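# Methods

## Model

Tracer exchange between pulmonary blood and lung tissue is described by a
one-tissue compartment model. With C_B(t) the tracer concentration in the
pulmonary blood (right-ventricle cavity) and C_T(t) in lung tissue,

    dC_T/dt = K1 · C_B(t − j) − k2 · C_T(t),        C_B(0) = C_T(0) = 0,

whose solution is the convolution C_T = K1 · C_B(t − j) ⊗ exp(−k2 t).
K1 (mL of blood /min /cm³ of tissue) is the delivery rate and the PBF
estimate; k2 (/min) the washout rate; K1/k2 the water partition
coefficient; j an integer transit delay in seconds between the RV and the
lobe. The measured signal in a lung VOI mixes tissue with residual air and
intravascular blood:

    C_PET(t) = V_A·C_A(t) + V_B·C_B(t − j) + (1 − V_A − V_B)·C_T(t),

with C_A ≡ 0 (air carries no tracer). No radioactive-decay term appears:
the images are assumed decay-corrected. Rates are carried per-second
internally (the recursion below runs on a 1 s grid) and converted to
per-minute (×60) only at the reporting boundary.

### Discrete fitting form and analytic oracle

Fitting uses the explicit Euler recursion on the integer-second grid
i = 1…280,

    C_T(i) = K1 · C_B(i − j − 1) + (1 − k2) · C_T(i − 1),

with C_T(0) = 0 and input samples at negative indices set to zero. Note
the input is read one sample before the current step; the fitted delay
absorbs this offset, and empirically the one-step lag compensates most of
the phase error of the Euler kernel (the geometric kernel (1 − k2)^t has
mean lag (1 − k2)/k2; adding the extra sample restores the exponential
kernel's mean lag 1/k2).

An independent evaluator computes the exact convolution by trapezoidal
quadrature on a fine grid (default 0.05 s). The two agree within 2%
relative L2 for smooth bolus inputs with k2 ≤ 0.2 /s, and the discrepancy
falls monotonically as the recursion step is refined. The recursion's
factor 1 − k2·Δt (vs. exp(−k2·Δt)) means high-washout regions
(k2 ≈ 0.25 /s, as upper lobes can reach) carry a systematic
discretisation bias of order 10–20% in the fitted rates relative to
continuous-time truth; this is a property of the 1 s fitting form itself,
faithfully reproduced. When k2·Δt ≥ 1 the recursion factor is
non-positive; the forward model flags this with a warning but still
evaluates, because the optimiser may legitimately pass through such
values.

## Estimation

The objective is the sum of squared differences between the measured 1 s
TAC and C_PET over i = 1…280. Unconstrained coordinates map to valid
parameters via |·| for K1, k2 and the inverse logit for V_A, V_B; the
starting point is K1 = k2 = 1 (/s), V_A = V_B = 0.1. Minimisation is BFGS
with the exact analytic gradient (the recursion is linear in K1, and its
k2-derivative obeys the companion recursion d(i) = (1 − k2)d(i − 1) −
C_T(i − 1) at unit K1; the analytic gradient is what lets noiseless
recovery reach the 0.1% contract from the deliberately distant standard
starting point). Two deterministic safeguards wrap the search:

* **Saturation restarts.** A line search can throw an inverse-logit
  coordinate to |θ| ≫ 8, where its chain-rule factor v(1 − v) underflows
  and the direction goes numerically dead. Saturated coordinates are reset
  to their initial value and the search restarts with a fresh Hessian
  estimate, until no coordinate is saturated and the objective stops
  improving (at most 6 rounds; every fit restarts at least once).
* **Flat-manifold representative (full variant).** With C_A = 0 the signal
  depends on V_A and K1 only through (1 − V_A − V_B)·K1, so V_A is
  structurally unidentified and the optimiser may park it anywhere on an
  SSE-equivalent manifold. The reported fit slides along that manifold to
  the representative with V_A at its initial value (rescaling K1 to keep
  the flux product fixed) and polishes; the returned point is accepted
  only if its SSE is no worse. Fit results carry an explicit
  identifiability note, and the trustworthy quantity is `effective_flux =
  (1 − V_A − V_B)·K1`.

The delay is fixed by exhaustive search: one cold-started fit per
j ∈ {0,…,15}, keeping the j with the lowest SSE (smallest j on ties). The
full per-delay SSE trace is retained in the result.

### Model comparison

Three nested variants are compared: full (K1, k2, V_A, V_B, j), no_va
(V_A ≡ 0) and no_va_no_vb (V_A ≡ V_B ≡ 0). The least-squares AIC is
n·ln(SSE/n) + 2k with n = 280 and k counting the continuous parameters
plus one for the delay (5/4/3). Counting the delay is a package choice
(the grid search does estimate it); the constant offset cancels in
comparisons between variants, which all include j. SSE = 0 maps to −∞ so
a perfect fit ranks first. On data generated without an air term the
full variant can only match the no_va optimum (V_A is a reparametrisation
of K1), so its AIC sits ≈ 2 above and the median-AIC winner is no_va.

## VOI construction

Morphology is voxel-metric (anisotropic voxel sizes are ignored, matching
the voxel-count phrasing of the recipe) with the 6-connected cross
structuring element iterated per step; "adjacent" is read as face
adjacency. Lobes: hollow shell of depth 3 (mask minus its 3-fold erosion —
shell and core partition the mask exactly), minus all vessel masks dilated
2 iterations (~one PET voxel of spill-over margin per iteration,
configurable), then largest 26-connected component (permissive
connectivity avoids splitting thin structures; ties break toward the
smallest linear voxel index). RV: largest component only. Masks from a
different grid are resampled by nearest neighbour through shared physical
coordinates; source and target must span the same physical extent.

## TAC extraction and timing

The acquisition protocol is 24 frames (14×5 s, 3×10 s, 3×20 s, 4×30 s),
280 s total, started 30 s after the start of the tracer bolus (the offset
is retained as metadata). Frame values are time-averages over the frame —
PET frames integrate counts — and region TACs are anchored at frame
mid-times **on the scan clock** (2.5 s … 265 s), so the uniform
1 s analysis grid 0…280 covers the whole scan and the zero-concentration
boundary condition refers to scan start. (Anchoring on the injection clock
instead would insert a ~32 s artificial ramp shared by neither curve's
dynamics; on noiseless phantoms this inflates the SSE by two orders of
magnitude and badly distorts the fitted parameters.) Interpolation is
piecewise linear, anchored at (0, 0) before the first sample and holding
the last value after the last sample; a curve already on the grid is
returned bit-identically.

The input function averages, frame by frame, the RV voxels strictly above
the 90th percentile of that frame (linear-interpolation percentile;
both the percentile and the strictness are per-frame). If no voxel lies
strictly above (all values equal), the frame falls back to the plain VOI
mean and logs a warning.

## Synthetic data

The phantom emulates topology, not anatomy: five disjoint ellipsoid lobes
(two left, three right), a spherical RV between them whose 3-fold-eroded
core is the hot blood pool (cavity < 10% of RV voxels so the percentile
rule selects it; the wall carries 25% of the blood signal), four vessel
tubes crossing the upper lobes carrying pure blood signal, and air pockets
(zero signal) occupying 11% of each lobe, placed deeper than 4 erosion
steps so the depth-3 hollow shell excludes them. Default grid 48×48×72
voxels (≥ 40×40×56 is required for the RV cavity to survive erosion).

The bolus input is a gamma-variate (onset 25 s, peak 45 s after injection
start, sharpness 4, peak 90 kBq/mL — a plausible RV concentration for a
ManBq-scale water bolus) with a 12% recirculation plateau and optional
Gaussian noise (default SD 0.5 kBq/mL: "a clear peak and little noise");
the noiseless curve is normalised so its maximum equals the configured
peak. Lobe signals come from the analytic convolution (independent of the
fitting recursion) mixed by the volume fractions, then frame-averaged.
Phantom noise, when enabled, is Gaussian with SD ∝ sqrt(signal/frame
duration), mimicking reconstructed-PET count statistics. Per-lobe default
kinetics follow the observed pattern for this population: lowest flow in
the right lower lobe, much higher in the upper lobes, partition
coefficient ≈ 0.2, air fraction ≈ 11%, blood fraction a few percent.

Cohorts draw age ~ N(64.8, 9.33²) clipped to 30–83 years, a 56:47
female:male split at n = 103 (both configurable), height by sex, BMI ~
N(27, 4²), and a patient-level all-lobes PBF (base 1.21 mL/min/cm³,
between-patient SD 0.6) with optional additive female and over-65 shifts;
per-lobe PBF applies fixed lobe scale factors. What the phantoms do *not*
emulate: cardiac/respiratory motion, reconstruction physics and its
correlated noise, partial-volume blur, segmentation errors, or anatomical
shape. Passing tests therefore demonstrate correctness of the algorithms
under the stated model, not clinical accuracy on real scans.

## Test and acceptance problem sizes

Noiseless recovery runs 20 random parameter draws per variant against
data generated by the discrete model itself (recovering K1, k2, V_B to
0.1% and the delay exactly for the identifiable variant; the flux product
for the full variant). AIC selection uses 50 noisy TACs. Statistical
calibration uses 500 replicate 103-patient cohorts for the subgroup
battery type-I rate and 1000 replicates for the Spearman null.
Determinism reruns the full pipeline on a 2-patient cohort and compares
result files byte for byte. These sizes keep the whole suite and the
acceptance script to a few minutes on one CPU while leaving the Monte
Carlo margins comfortably inside the asserted bands.

## Known limitations

* The Euler recursion's rate bias at high k2 (above) propagates into
  end-to-end phantom fits; the pipeline test asserts recovery only within
  that bias envelope (±35%).
* V_A is never identified when C_A = 0; reported V_A is a convention (the
  initialisation representative), not an estimate.
* The Mann–Whitney implementation switches from the exact distribution to
  the tie-corrected normal approximation at combined n > 20 or any tie.
* Exact age-65 boundaries are assigned to the "over" group so the two age
  groups are exhaustive.
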