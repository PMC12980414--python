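# Methods

This note records the models implemented in `sbmsaxs`, the defaults and
why they were chosen, the numerical choices that affect results, what
the synthetic-data generators do and do not emulate, and known
limitations.

## Structure-based model

The potential is an all-heavy-atom Gō-type force field whose global
minimum is a chosen native structure.  Bonds, angles and planar
(improper) dihedrals are harmonic in the deviation from their native
values; proper dihedrals use the periodic restraint
F_d(φ) = [1 − cos(φ − φ₀)] + ½[1 − cos 3(φ − φ₀)], which is zero and
minimal at φ₀ and penalizes a trans/gauche flip by 3 energy units;
native contacts are 12-6 wells of depth ε_C centred exactly at the
native distance σ_ij; every other pair repels as ε_NC (σ_NC/r)¹².

Parameters (reduced energy units, kB = 1, uniform unit masses):

| parameter | default | unit | note |
|---|---|---|---|
| ε_r | 100 | /Å² | bond restraint |
| ε_θ | 20 | /rad² | angle restraint |
| ε_ξ | 10 | /rad² | planar/improper restraint |
| ε_φ,bb / ε_φ,sc | 1.0 / 0.5 | — | backbone vs side-chain torsions |
| ε_C | 1.0 | — | per native contact |
| ε_NC / σ_NC | 0.01 / 2.5 Å | — | excluded volume |

The ε_r, ε_θ, ε_ξ, ε_NC and σ_NC values are the conventional
structure-based-model settings; the torsion and contact weights are
exposed as configuration because the balance between dihedral and
contact stabilization is a modelling choice, and the 1.0/0.5
backbone/side-chain split follows common all-atom SBM practice.

**Topology construction.**  Covalent connectivity comes from a
heavy-atom distance rule (bond cutoff 1.9 Å); angles and torsions are
enumerated from the bond graph; one improper is placed at every atom
with exactly three neighbours, choosing among the equivalent
neighbour orderings the one with the largest native plane normals so
the torsion gradient stays well-conditioned.  A chain break (two
consecutive residues with no inter-residue bond) is an error, not a
warning, because a silently split chain invalidates every downstream
native measurement.

**Shadow contacts.**  An atom pair is a native contact when it is
within 6.0 Å, at least 3 residues apart in sequence, not an excluded
(bonded/1-3/1-4) pair, and not occluded: no third atom, modelled as a
1.0 Å sphere, intersects the segment joining the pair.  Cutoff,
radius and separation are the standard shadow-map conventions and are
arguments, not constants.  Two sampling-oriented modifications follow
the multidomain use case: contacts whose residues belong to two
different rigid domains of the user's domain map are excluded
(inter-domain arrangements must be decided by the data, not the
reference), and proper dihedrals touching linker residues carry no
restraint.  Atoms of residues not assigned to any domain (the linker)
likewise contribute no contacts.

**Dynamics.**  BAOAB splitting of Langevin dynamics; with friction 0
the O-step is the identity and the integrator reduces exactly to
velocity Verlet, which is how the NVE conservation checks run.  The
default friction 1.0 /rtu is a compromise between thermostat coupling
and diffusive sampling; dt = 0.0005 rtu.  Forces are evaluated by a
compiled (numba) scalar kernel that is required to agree with the
vectorized numpy reference implementation to ~1e-13 (asserted in the
test suite); without numba the integrator falls back to the numpy
path.  A coordinate guard (|x| > 10⁴ Å) and energy finiteness check
abort divergent runs with the step index.

## SAXS

**Debye calculator.**  I(q) = Σᵢⱼ fᵢfⱼ sinc(q rᵢⱼ) with per-element
constant form factors (electron counts) by default, an optional
four-Gaussian analytic q-dependence, and unit factors for oracle
tests.  No hydration layer or excluded-volume term is fitted; that is
the main fidelity gap versus solution-scattering predictors that
optimize a water shell, and it is deliberate — every number the
calculator produces is checkable against a literal double loop, which
the tests do at 1e-10 relative tolerance.

For scoring thousands of trajectory frames there is a radial-binning
variant: pair distances are histogrammed at 0.05 Å with linear
interpolation between neighbouring bins and the sinc kernel applied
per bin.  The approximation error is O((q·Δr)²) ≈ 1e-6 relative over
the instrument q range — far below counting noise — and the exact and
binned paths are compared in the tests.

**χ².**  The scale c minimizing Σ[(I_exp − c·I_th)/σ]² has a closed
form; χ² divides the minimum by the number of fitted points n (not
n − 1), matching the convention in which χ² ≈ 1 means "fits within
noise"; the divisor is switchable.  An optional q-window restricts the
fit (e.g. to the high-q region, extrapolating the scaled model to low
q to expose size/mass disagreement), and an optional constant
background offset can be co-fitted.  Theoretical curves are cubic-
spline interpolated onto the experimental grid; extrapolation is an
error.  Residual diagnostics report the mean and a Wald–Wolfowitz
sign-runs z-statistic, flagging systematic (one-signed) deviations
that a good ensemble fit should not show.

**Guinier.**  ln I vs q² on the largest low-q window satisfying
q·Rg ≤ 1.3 (globular convention), found self-consistently; the limit
is reported, not enforced, for elongated particles.  The sphere-oracle
check in the acceptance suite fits with a 0.9 limit because the
Guinier expansion itself overestimates a sphere's Rg by ~1.8% already
at qRg = 1.3 — a property of the approximation, not of the fit.

**P(r).**  From coordinates: a form-factor-weighted histogram of pair
distances; Dmax is the exact maximum distance and Rg² = ⟨r²⟩/2 under
P(r).  From a measured curve: P(r) on a grid over [0, dmax_guess] with
pinned zero endpoints, solved as non-negative least squares with a
second-difference smoothness penalty; the penalty weight is chosen by
a deterministic L-curve corner criterion (maximum curvature over a
fixed 21-point logarithmic scan), so the transform has no random
state.  The refined Dmax is where the recovered P(r) last exceeds 1%
of its peak.

**Averaging.**  Repeat measurements are combined per q-point by
inverse-variance weighting with σ = (Σσᵢ⁻²)^(−1/2).

## Projection and ensemble selection

Frames are described by a seeded subsample of intramolecular pairwise
distances (rotation/translation invariant by construction); frame
dissimilarity is the RMS difference of these vectors.  The planar
embedding is SMACOF stress majorization — monotone non-increasing raw
stress per iteration, seeded Gaussian initialization, normalized
Kruskal stress-1 reported — cross-checked against scikit-learn's
SMACOF on a planted instance.

Selection follows a two-stage rule: (1) keep frames with χ² in a band,
default [0.9, 1.1], endpoints inclusive; (2) estimate the 2-D density
of the member points with a Gaussian KDE (Scott's-rule bandwidth,
overridable), take the connected region above 50% of the peak density
that contains the global peak, and return the k = 5 members nearest
the peak (ties broken by lower χ², then lower frame index).  The 50%
contour makes an inherently visual "densest cluster" rule explicit and
configurable; all density maxima are reported so secondary clusters
are visible rather than silently discarded.  If the band is empty the
selector raises with advice to widen it; if k exceeds the cluster, the
whole cluster is returned with a warning.

## Spectroscopy fits

All fitters are weighted nonlinear least squares (scipy `curve_fit`)
with deterministic, derivative-free initialization (log-linear prefits
for rates, plateau/tail heuristics for amplitudes and baselines).

*Relaxation.*  I(t) = I₀(1 − 2e^(−R₁t)) and I₀e^(−R₂t).  When a
spectrum SNR is given, σ_I = max|I|/SNR is used as an absolute
per-point uncertainty, making the reported standard errors absolute
rather than residual-scaled; the Monte-Carlo calibration tests require
empirical-SD/reported-SE within [0.7, 1.3].

*Amide I.*  The 1,600–1,700 cm⁻¹ band is fitted as a sum of Voigt
components (real Faddeeva profile via `scipy.special.voigt_profile`).
Each component's **area is itself a fit parameter** (the profile is
unit-area), so area uncertainties come directly from the covariance
matrix, with no numerical integration.  Centers start from the
canonical assignment positions (≈1682 β-turn, 1670 α-helix, 1649
disordered, 1637/1622 β-sheet) and may move at most ±8 cm⁻¹ — the same
window used to assign a fitted center to its class (nearest center on
overlap; outside every window is an error).  Secondary-structure
percentages are area fractions with the two β-sheet bands pooled.  An
optional Fourier self-deconvolution pre-filter (Lorentzian narrowing)
is provided but off by default: its bandwidth/narrowing parameters are
sample-dependent and no defaults generalize.

*DLS.*  g₂(τ) = B + β e^(−2Γτ)(1 + μ₂τ²/2)², weighted by the caller's
per-point σ (the generator supplies a Poisson-count model), μ₂
constrained non-negative so PDI = μ₂/Γ² ≥ 0.  D_h follows from
Γ = Dq², q = 4πn sin(θ/2)/λ and Stokes–Einstein, with a 90° detector,
633 nm laser, n = 1.33, 293 K and η = 1.002 mPa·s as overridable
instrument defaults.  Γ and D_h uncertainties propagate first-order
from the covariance; note D_h ∝ 1/Γ makes the relation between the
two involutive, which the tests exploit as a round-trip check.

## Synthetic data: what it emulates, what it does not

Toy chains use three pseudo-atoms per residue (N, CA backbone + CB
side chain, 1.5 Å bonds) so that every term of the potential —
including side-chain torsions and impropers — is exercised without
residue templates.  Backbones grow as self-avoiding walks (2.5 Å
non-bonded clearance) with the 1-3 distance held in [2.0, 2.9] Å,
i.e. bend angles in ≈[84°, 150°]: never clashing and never
near-linear, where angle/torsion gradients degenerate.  Two-domain
chains confine the walk to two spherical regions joined by an
extended, +x-biased linker; dimers are a rigid 180°-rotated copy
brought to a target interface gap by bisection.

SAXS curves are Poisson counts on the Debye profile, scaled to a peak
of `mean_counts` (default 10⁴); the reported σ is the counting-noise
level √λ of the underlying rate — the value a reduction pipeline
approaches by averaging repeated exposures — rather than √counts of a
single realization, which would bias χ² upward by ~2/λ.  The default
q grid spans 0.013–0.26 Å⁻¹ in 1,001 points, a typical azimuthal
integration binning; with n points the sampling spread of χ² is
√(2/n) ≈ 0.045, small enough that the [0.9, 1.1] selection band is a
statement about conformations rather than about noise realizations.

Planted ensembles mix jittered copies of the native (mode 0, 0.1 Å
per-atom jitter) with a 1.35× isotropically swollen decoy (mode 1,
0.25 Å jitter), with labels returned for scoring.  The decoy is a
caricature of an expanded state: it separates cleanly in both χ² and
feature space, so passing the recovery tests shows the selection
machinery is correct, *not* that the method can resolve subtle
conformational differences in real data.  Likewise the toy chains
have no sequence, no secondary structure and no realistic form-factor
contrast, and the noise models contain no inter-point correlations,
buffer-subtraction artefacts or beam-smearing.

## Problem sizes

The test suite and acceptance script run desk-scale versions of the
workflow: 10⁵–1.5×10⁵-step simulations with 1,000-step recording
(cadence preserved), 1,000-frame planted ensembles over 50–100
repetitions, 100-seed calibration loops, and 200-replicate Monte-Carlo
error calibrations.  These sizes give comfortable statistical margins
for every property checked while keeping a full run in minutes on one
core.

## Known limitations

- No hydration-shell or excluded-volume scattering term; absolute-scale
  comparison to real measured curves will show systematic deviations
  at high q.
- The shadow map treats all blockers as equal spheres; no per-element
  radii and no radius shrinking for overlapping atoms.
- The simulator is single-temperature Langevin only — no replica
  exchange; equilibration at low temperatures relies on the released
  linker dihedrals keeping inter-domain motion diffusive.
- The indirect transform's Dmax refinement depends on the 1%-of-peak
  support rule; very flat P(r) tails can shift it by a few bins.
- Secondary-structure assignment implements only the amide-I
  band-center map; no side-chain correction or band-narrowing
  validation.
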