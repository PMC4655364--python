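# nmrelax

Backbone ¹⁵N spin-relaxation analysis for protein dynamics: relaxation-
rate fitting, Lipari–Szabo model-free analysis with anisotropic
rotational diffusion, two-state CPMG relaxation-dispersion global
fitting, and pH-titration chemical-shift-perturbation tracking — with
seeded synthetic-data generators so every stage can be validated end to
end.

## Who this is for

Solution-NMR spectroscopists characterizing protein backbone dynamics —
for example acid-stress chaperones such as HdeB, whose activation at
mildly acidic pH is coupled to µs–ms conformational exchange at the
dimer interface rather than to structural change.  The package takes
per-residue peak-intensity tables (relaxation delay series,
saturated/reference NOE pairs, constant-time CPMG series at two static
fields) and per-residue chemical shifts across a pH series, all as
tab-separated text, and turns them into motional parameters.

## The models

**ps–ns motion.**  ¹⁵N R₁, R₂ and the {¹H}-¹⁵N NOE are expressed
through the extended model-free spectral density

J(ω) = (2/5) Σⱼ Aⱼ [ S²τⱼ/(1+(ωτⱼ)²) + (S²f−S²)τ′ⱼ/(1+(ωτ′ⱼ)²) ],
  1/τ′ⱼ = 1/τⱼ + 1/τe,

with the Woessner three-term sum for an axially symmetric diffusion
tensor (τm, D∥/D⊥, axis) and per-residue models M1 (S²), M2 (S², τe),
M3 (S², Rex), M4 (S², τe, Rex), M5 (S², τe, S²f) selected by a staged
χ²/F-test protocol.  The tensor is estimated from R₂/R₁ ratios of a
rigid subset, with isotropic vs axial decided by F-test and an
iterative refinement on M1-assigned residues.  Parameter errors come
from Monte Carlo simulations.

**µs–ms motion.**  Constant-time CPMG profiles
R₂ᵉᶠᶠ(νCPMG) = −(1/T)·ln(I(νCPMG)/I₀) are fitted with a two-state
exchange model by numerical Bloch–McConnell propagation through the
echo train (no assumption about the exchange regime), per residue or
globally over a cluster sharing kex = k_AB + k_BA and the population
product p_A·p_B, with per-residue |Δω| (ppm, field-scaled) and
per-(residue, field) exchange-free R₂⁰.  The Carver–Richards closed
form is implemented as an independent cross-check.  Major populations
follow from p_A = (1+√(1−4·p_Ap_B))/2.

**Titration bookkeeping.**  Composite shift changes
Δδ = √(ΔδH² + (0.2·ΔδN)²) between pH points, with explicit
present/missing/multiple peak-status tracking (missing peaks are
flagged, never zero-filled).

## Worked example

Simulate a 10-residue dispersion cluster in the fast-exchange-onset
regime and refit it globally:

```python
import numpy as np
from nmrelax import (CpmgDesign, DiffusionTensor, ExchangeTruth,
                     GroundTruth, duplicate_noise_estimate,
                     fit_cluster_global, make_cpmg_dataset,
                     population_from_product, r2eff_profile)

design = CpmgDesign()            # 60 ms, 14 nu_CPMG values, 800.2/600.13 MHz
truth = GroundTruth(
    tensor=DiffusionTensor("isotropic", 10.8e-9),
    exchange=ExchangeTruth(
        k_ex=1822.0, p_A=population_from_product(0.026),
        delta_omega={r: 1.0 + 0.3 * r for r in range(1, 11)}),
    noise=0.02, seed=11)
tables = make_cpmg_dataset(truth, design)
frac = duplicate_noise_estimate(tables["cpmg"])
profiles = [r2eff_profile(tables["cpmg"], design, residue=r, field_mhz=f,
                          noise_frac=frac[f][1])
            for r in range(1, 11) for f in design.fields]
fit = fit_cluster_global(profiles)
print(f"k_ex  = {fit.k_ex:7.1f} s^-1   (truth 1822)")
print(f"pA*pB = {fit.pApB:.4f}        (truth 0.026)")
print(f"pA    = {100 * fit.p_A:.1f}%          (major state)")
print(f"chi2  = {fit.chi2:.0f} over {fit.n_points} points")
```

prints

```
k_ex  =  1823.7 s^-1   (truth 1822)
pA*pB = 0.0259        (truth 0.026)
pA    = 97.3%          (major state)
chi2  = 171 over 240 points
```

i.e. the global fit recovers the exchange rate within 0.1% and the
population product within 0.0001 at 2% intensity noise, with a reduced
χ² below one — the 97.3% major / 2.7% minor population split is the
kind of skewed two-state equilibrium that CPMG dispersion detects even
though the minor state is invisible in the spectrum.

A command-line interface mirrors the library
(`nmrelax simulate | rates | modelfree | cpmg | titrate`); run
`nmrelax --help` after installing, or start from a generated fixture:

```
nmrelax simulate --out-dir demo --seed 5
nmrelax rates --r1 demo/r1_decays.tsv --r2 demo/r2_decays.tsv \
        --noe demo/noe.tsv --ph 4.5 --out demo/rates.tsv
nmrelax modelfree --rates demo/rates.tsv \
        --orientations demo/orientations.yaml --n-iter 0 --out demo/mf.tsv
```

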