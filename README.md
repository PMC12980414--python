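# sbmsaxs

Hybrid SAXS/MD characterization of multidomain proteins, built around
the workflow used to decide whether a protein in solution is a compact
dimer or an elongated monomer: run structure-based-model (Gō-like)
Langevin dynamics from a native reference, compute a theoretical
scattering profile for every sampled conformation, score each against
the measured curve with a scale-optimized χ², and extract the
representative solution ensemble by a χ²-band + point-density rule in a
2-D conformational projection.  The same package implements the
surrounding shape and spectroscopy analyses: Guinier fits, P(r)/Dmax by
regularized indirect transform, ¹⁹F relaxation (R₁/R₂) exponential
fits, amide-I Voigt deconvolution with secondary-structure fractions,
and DLS second-order cumulant analysis with hydrodynamic-diameter
conversion.

## The models

**Structure-based potential.**  For a conformation Γ relative to the
native Γ₀:

    V(Γ − Γ₀) = Σ ε_r (r − r₀)² + Σ ε_θ (θ − θ₀)² + Σ ε_ξ (ξ − ξ₀)²
              + Σ_bb ε_φ,bb F_d(φ) + Σ_sc ε_φ,sc F_d(φ)
              + Σ_contacts ε_C [(σ_ij/r_ij)¹² − 2 (σ_ij/r_ij)⁶]
              + Σ_noncontacts ε_NC (σ_NC/r_ij)¹²

with F_d(φ) = [1 − cos(φ − φ₀)] + ½[1 − cos 3(φ − φ₀)].  Native values
r₀, θ₀, ξ₀, φ₀ and contact distances σ_ij are measured from the
reference structure; contacts come from a shadow map (line-of-sight
occlusion by intervening atom spheres).  Contacts bridging rigid
domains are excluded and linker dihedrals released, so inter-domain
arrangements are sampled freely.  Defaults: ε_r = 100 /Å², ε_θ = 20
/rad², ε_ξ = 10 /rad², ε_NC = 0.01, σ_NC = 2.5 Å; dynamics use BAOAB
Langevin steps of 0.0005 reduced time units (≈ 0.5 fs with one reduced
time unit mapped to ~1 ps), recording every 1,000 steps.

**Scattering.**  I(q) = Σᵢⱼ fᵢfⱼ sin(q rᵢⱼ)/(q rᵢⱼ) (Debye sum);
χ²(c) = (1/n) Σ [(I_exp − c·I_th)/σ]² minimized over the scale c in
closed form, so a model that fits within counting noise sits at χ² ≈ 1.

**Spectroscopy.**  I(t) = I₀(1 − 2e^(−R₁t)) and I(t) = I₀e^(−R₂t);
amide-I bands as unit-area Voigt profiles whose areas give
secondary-structure percentages; g₂(τ) = B + β e^(−2Γτ)(1 + μ₂τ²/2)²
with PDI = μ₂/Γ² and D_h from Γ = Dq² plus Stokes–Einstein.

Because no experimental data ship with the package, a first-class
synthetic-data module generates every input with planted ground truth:
self-avoiding toy multidomain chains (three pseudo-atoms per residue),
rigid dimers of the same chain, Poisson-count SAXS curves, decay
series, Voigt spectra and DLS autocorrelations.

## Worked example

```python
import sbmsaxs as sx
from sbmsaxs import synthetic as syn

# a 20-residue two-domain chain on a flexible linker, and its topology
s, domains, linker = syn.make_two_domain(8, 4, seed=1)
topo = sx.build_topology(s, linker_residues=linker, domain_map=domains)
print(len(topo.bonds), len(topo.contacts))          # 59 43

# synthetic "experimental" curve from the monomer; score both states
q = syn.default_q_grid()
exp = syn.synth_saxs(s, q, mean_counts=1e4, seed=3)
dimer = syn.make_dimer(s, seed=7)
print(sx.chi_square(exp, sx.debye_profile(s, q)).chi2)      # 1.06
print(sx.chi_square(exp, sx.debye_profile(dimer, q)).chi2)  # 258.5

# shape analysis
print(sx.guinier_fit(exp).rg)                       # 10.12 (Å)
print(sx.pr_from_curve(exp, dmax_guess=40.0).dmax)  # 33.2 (Å)

# DLS cumulant fit of a synthetic autocorrelation planted at 72.3 Å
tau, g2, sig, truth = syn.synth_dls(dh=72.3, pdi=0.05, seed=1)
fit = sx.fit_cumulants(tau, g2, sigma=sig)
print(fit.dh, fit.pdi)                              # 71.9 0.067
```

The monomer that generated the curve scores χ² ≈ 1 (a fit within
noise) while the dimer is rejected outright; the indirect-transform
Dmax ≈ 33 Å agrees with the chain's true maximum extent of 31.5 Å to
within the transform's resolution; the cumulant fit recovers the
planted hydrodynamic diameter within its standard error.

A command-line pipeline wraps the same stages
(`sbmsaxs synth | topology | simulate | saxs-fit | pr | guinier |
ensemble-select | relax-fit | ftir-fit | dls-fit | pipeline`), each
writing a JSON run manifest; `sbmsaxs show-config` prints every
default.

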