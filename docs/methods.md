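# Methods

This note documents the models implemented in `nmrelax`, the choices
made where the methodology is genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Spin physics

### Relaxation rates

Backbone amide ¹⁵N relaxation is modelled with the standard
dipole-dipole (N–H) plus ¹⁵N CSA mechanisms:

    R1  = d²/4 [J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c² J(ωN)
    R2  = d²/8 [4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
          + c²/6 [4J(0) + 3J(ωN)] + Rex
    NOE = 1 + (γH/γN) · (d²/4)[6J(ωH+ωN) − J(ωH−ωN)] / R1

with d = (μ0/4π) ħ γH γN / r³NH and c = ωN Δσ/√3.  Constants default to
the community-standard values for backbone amides — rNH = 1.02 Å,
Δσ = −160 ppm, γH/γN = −9.8655 — and are overridable through
`SpinSystem` / `RunConfig`, since analyses in the literature vary at the
percent level in these choices.  Cross-correlated relaxation
interference is outside scope.

### Spectral density

The extended Lipari–Szabo form is used throughout, with S² = S²f·S²s and
the very fast component assumed too fast to contribute (τf → 0):

    J(ω) = (2/5) Σⱼ Aⱼ [ S² τⱼ/(1+(ωτⱼ)²) + (S²f−S²) τ'ⱼ/(1+(ωτ'ⱼ)²) ]

where 1/τ'ⱼ = 1/τⱼ + 1/τe.  For isotropic tumbling the sum collapses to
one term with τ = τm.  For an axially symmetric diffusion tensor the
three Woessner terms are used with amplitudes A₁ = (3cos²θ−1)²/4,
A₂ = 3sin²θcos²θ, A₃ = (3/4)sin⁴θ (θ = angle between the N–H vector and
the unique axis) and correlation times 1/(6D⊥), 1/(5D⊥+D∥),
1/(2D⊥+4D∥).  τm is defined via Diso = (D∥+2D⊥)/3 = 1/(6τm) so that the
axial form reduces continuously to the isotropic one at D∥/D⊥ = 1
(verified to 1e−10 in the tests).  Fully anisotropic (rhombic) tensors
are out of scope.

The five motional models are the conventional nesting: M1 (S²),
M2 (S², τe), M3 (S², Rex), M4 (S², τe, Rex), M5 (S², τe, S²f).  Rex is
treated as an additive constant at the measurement field; no field
scaling is applied because the model-free data are single-field.

## CPMG dispersion forward models

Two-state exchange A⇌B is parameterized by kex = kAB + kBA, the major
population pA (pB = 1−pA), |Δω| in ppm (converted to rad/s per field;
the sign is unidentifiable from CPMG and the magnitude is stored), and
an exchange-free r20 shared by both states per (residue, field).

**Numerical model (authoritative for fitting).**  The transverse
magnetization (M_A, M_B) evolves under the 2×2 complex Bloch–McConnell
operator; each 180° pulse acts as complex conjugation.  A
τ–180°–2τ–180°–τ block therefore has the exact propagator
P = A·conj(B)·A with A = exp(Lτ), B = exp(2Lτ), and the constant-time
train of n even pulses is Pⁿ applied to the equilibrium start
(pA, pB).  R2eff = −(1/T)·ln(|M_A(T)|/pA).  The 2×2 exponentials and
the matrix power (Cayley–Hamilton on the eigenvalues) are evaluated in
closed form, vectorized over the νCPMG grid; this is ~100× faster than
generic `expm` calls and is verified against step-by-step
`scipy.linalg.expm` propagation to 1e−13 in the tests.  Off-resonance
effects, finite pulse widths and R1 during the relaxation period are
neglected (idealized constant-time regime).  Pulse count:
round(2·νCPMG·T) forced even; a >1% mismatch between requested and
realizable νCPMG is an error.

**Closed form (cross-check).**  The Carver–Richards general expression
(equal intrinsic rates), valid in all exchange regimes, with a stable
asymptotic branch for large η⁺.  For equal r20 this expression equals
the exact dominant-eigenvalue decay rate of the echo-train propagator.

**Known, quantified difference between the two.**  The numerical R2eff
contains a finite-time amplitude factor (the projection of the initial
condition onto the propagator eigenvectors) that the closed-form
asymptotic rate does not.  Over kex ∈ [200, 6000] s⁻¹, pB ∈
[0.01, 0.1], Δω ∈ [0.5, 4] ppm at 800.2 MHz and the experimental νCPMG
grid (50–750 Hz, T = 60 ms), the two agree within 2% at >99% of grid
points; the worst corner (kex = 200 s⁻¹, pB = 0.1, Δω = 0.5 ppm,
ν = 50 Hz — only 6 pulses) deviates by ~3%.  The deviation vanishes as
the train lengthens (<0.5% at T = 1.2 s), confirming it is purely the
amplitude term.  Since the experiment's R2eff = −(1/T)ln(I/I0) includes
exactly this amplitude effect, the numerical model is the one used for
all fitting; the closed form serves as an independent oracle.

## Rate fitting

R1/R2 come from weighted nonlinear least squares of I(t) = I0·e^(−Rt)
(log-linear start values); errors from the covariance by default, Monte
Carlo resampling optionally.  NOE = I_sat/I_ref with first-order error
propagation.  R2eff profiles use R2eff = −(1/T)·ln(I_ν/I0).

Per-point R2eff errors derive from the duplicated νCPMG plane:
σ_I = |I_a − I_b|/√2, rms-pooled **across residues** — a single
within-residue pair is far too unstable an estimator (χ² with one
degree of freedom) and was observed to distort global-fit weights by
an order of magnitude.  Because the intensity noise is multiplicative,
the pooled *fractional* estimate (σ_I/Ī) applied per point is the
default in the pipelines; an absolute floor is configurable.
Duplicates are collapsed to their mean intensity.  Peak intensities,
not volumes, are the measurement; minor peak sets carry a label and are
fitted independently, with no automatic major/minor pairing.

## Diffusion-tensor estimation and model selection

**Rigid subset.**  NOE ≥ 0.65 and R2/R1 within 1.5 interquartile ranges
of the median.  R2/R1 of a residue without fast internal motion or
exchange depends only on the tensor (S² cancels), which is the basis of
the fit.

**Tensor fit.**  Isotropic (1 parameter), axial oblate and axial
prolate (τm, D∥/D⊥, axis polar angles; oblate and prolate fitted in
separate D-ratio branches with multi-start over axis orientations) are
fitted to the weighted R2/R1 ratios; the axial model is accepted by
F-test (3 extra parameters) at α = 0.05, the better axial branch by
χ².

**Iterative refinement.**  With realistic compositions (~25% of
residues carrying Rex of a few s⁻¹ and NOE indistinguishable from
rigid), the initial subset retains enough exchange-broadened residues
to bias the tensor, which then cascades into model misassignment.
After a first selection round, the tensor is re-estimated using only
M1-assigned residues and selection is repeated once.  In the synthetic
benchmark this step moves assignment accuracy from ~64% to ~93%.

**Selection protocol (staged χ²/F-test, α = 0.05).**  The criterion had
to be chosen here, since only the five-model ladder itself is given:
M1 is accepted if its goodness-of-fit p-value (χ², 2 degrees of
freedom) exceeds α; otherwise M2/M3 must both improve on M1
significantly (F-test) and fit acceptably, the better χ² winning;
only then are the exactly-fitting three-parameter models M4/M5
compared by χ².  Ties resolve toward fewer parameters.  On noiseless
data this selects the generating model deterministically (exact-fit
guard).  AICc would be a reasonable alternative; the staged protocol
was chosen as the field's long-standing default.  Note the built-in
~5% false-rejection of M1 at stage 1: in simulation M1 is selected for
~93–94% of truly rigid residues at 2% noise.

**Monte Carlo errors.**  n_iter (default 500) synthetic (R1, R2, NOE)
triples drawn from Normal(back-calculated, σ_obs), refit with the
selected model; the parameter standard deviations are the reported
errors.  >10% refit failures raises.

**Inertia utility.**  Principal moments of the mass-weighted inertia
tensor about the center of mass, normalized to the largest, from a PDB
file (first model); used as a structural plausibility check on the
fitted anisotropy, not in the fit itself.

## Dispersion fitting

Exchange detection compares a per-field-constant model against the full
two-state fit by F-test (α = 0.05).  Single-residue fits optimize
(kex, pA·pB, Δω) with multi-start over kex ∈ {200, 500, 1000, 2000,
4000} × pA·pB ∈ {0.005, 0.02, 0.05} (ties toward smaller kex); r20 is
profiled out analytically at every step — it enters R2eff as an exact
additive constant, so its weighted optimum is linear — which removes
2 (or 2·residues) parameters from the nonlinear search.  Δω = 0 or
pA·pB = 0 solutions are flagged degenerate (kex unidentifiable).

Cluster fits share (kex, pA·pB) across residues and fields, share Δω
per residue across fields in ppm, and keep r20 free per (residue,
field).  Initialization seeds Δω from single-residue fits and
multi-starts (kex, pA·pB) from the grid plus the single-fit medians.
Cluster membership is always declared by the caller; `suggest_cluster`
offers a compatibility heuristic but is never applied silently.
Population algebra: pA = (1+√(1−4q))/2 for q = pA·pB ≤ 0.25 (major
root).

## Synthetic data

The generators emulate the statistical structure the fitters assume:
mono-exponential decays and NOE pairs with fractional Gaussian noise
(default 2%, a stand-in — real per-residue noise is not reported in
this kind of study), constant-time CPMG intensities from the numerical
two-state model with independently-noised duplicates, and two-endpoint
single-pKa sigmoidal titration trajectories with missing/split-peak
status flags.  Default delay grids: R1 {0.01…1.2 s}, R2 {0.008…0.2 s},
8 points each.  Default CPMG design: T = 60 ms, νCPMG = 0, 50, 100(×2),
150, 200, 250, 300, 350, 400, 450, 500, 600, 750 Hz at 800.2 and
600.13 MHz.  Everything is a pure function of (truth, design, seed).

They deliberately do **not** emulate: lineshapes or peak overlap,
temperature or B1 imperfections, baseline or phasing artefacts,
assignment errors, or pKa heterogeneity beyond one sigmoid per residue.
Passing recovery tests therefore demonstrates correctness and
statistical efficiency of the estimators under the stated noise model,
not robustness to spectral-processing pathologies.

## Benchmark problem sizes

The recovery benchmarks use the study's own designs: 10-residue
clusters × 2 fields × 13 non-reference νCPMG points for the global
dispersion fits; 44 rigid residues for tensor recovery; a 47-residue
composition (28 M1 with S̄² = 0.90, 8 M3, 4 M4, 7 M5 termini) for
model-selection recovery; Monte Carlo at n_iter = 200 in the
acceptance suite and 500 by default elsewhere.  Δω truths span 1–4 ppm
across cluster members.  These sizes keep the full suite in the
minutes range while matching the reported experiment.

## Titration

Composite shift change Δδ = √(ΔδH² + (w·ΔδN)²) with w = 0.2 — the
customary ¹⁵N down-weighting in amide CSP analysis; the weight is
configurable since published variants range from 0.1 to 0.25, and
results differ from any particular published bar plot by at most this
global convention.  Missing peaks are flagged and propagated, never
zero-filled.  Reverse-titration reversibility is supported as a
series-to-series comparison at a common pH, not as a fitted quantity.

## Numerical choices and degenerate inputs

* Nonlinear fits: `scipy.optimize.least_squares` (trust-region
  reflective) with explicit `x_scale` per parameter and a finite-
  difference step of 1e−6 — the default step sits below the forward
  model's numerical noise floor for τe (~1e−11 s) and stalls the
  optimizer short of the minimum (caught by the grid-search oracle
  test).
* Model-free parameter bounds: S² ∈ [0,1], τe ≤ 3 ns (6 ns for M5),
  Rex ≤ 50 s⁻¹; M5 is parameterized as (S²f, S²s, τe) so S² = S²f·S²s
  respects S² ≤ S²f by construction.  Bound-hugging solutions are
  flagged.
* CPMG fit bounds: kex ∈ [10, 3·10⁴] s⁻¹, pA·pB ∈ [0, 0.25],
  Δω ∈ [0, 12] ppm.
* Degenerate geometry (collinear atoms) is rejected in the inertia
  utility; a missing amide proton is reconstructed from backbone
  geometry (opposite the N→CA/N→C′ bisector).
* Identical duplicate intensities (no scatter) fall back to the
  configured error floor; a zero error is never silently used.

## Known limitations

* Single-field model-free data cannot separate Rex from CSA
  miscalibration; Rex values are conditional on the assumed constants.
* The staged selection inherits the α-level false-rejection rate of M1
  and, with only three observables, M4/M5 fit exactly — their selection
  rests entirely on the simpler models failing.
* CPMG fitting assumes equal intrinsic R2 in both states and in-phase
  magnetization throughout the constant-time period.
* The titration generator's single-pKa sigmoid is generator-only
  structure; the analysis code fits no pKa.
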