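# Methods

## Physical model

The observable modelled throughout is the spinning-sideband intensity
pattern of an isolated spin-1/2 with chemical shift anisotropy under
magic-angle spinning — the carbonyl ¹³C case in collagen. Dipolar and J
couplings, cross-polarization dynamics, relaxation during acquisition and
finite-pulse effects are all outside the model: for well-resolved carbonyl
sideband *intensities* they perturb the envelope little compared with the
CSA itself, and they are what dedicated spin-dynamics packages exist for.

### Frequency under MAS

With the shift tensor expressed in the rotor-fixed frame as a symmetric
matrix A (the isotropic part removed), the laboratory-frame resonance
offset of a crystallite is b(t)ᵀ A b(t) · ν_L, where
b(t) = (sin θ_m cos ω_r t, sin θ_m sin ω_r t, cos θ_m) is the field
direction in the rotor frame and θ_m = arccos(1/√3). Expanding gives a
constant term that vanishes identically at the magic angle plus two rotor
harmonics with complex coefficients

    A₁ = 2 sin θ_m cos θ_m (A₁₃ − i A₂₃),
    A₂ = sin²θ_m ((A₁₁ − A₂₂)/2 − i A₁₂).

The accumulated anisotropic phase Φ(t) integrates these analytically, so
the only discretization in the engine is the FFT sampling of exp(iΦ) over
one rotor period. Sideband intensities are I_N = |F_N|², which is exactly
the uniform average over the initial rotor phase; by Parseval
Σ_N I_N = (1/n)Σ_k |exp(iΦ(t_k))|² = 1 to machine precision, so intensity
conservation is structural, not a numerical accident.

### Frame chain

All rotations are active ZYZ: PAS →(pas_orientation)→ molecular frame
→(grid α, β, γ)→ rotor frame →(magic-angle tilt, spinning)→ lab. Because
rotor-phase averaging is exact, results are independent of a global
rotation about the rotor axis (grid α only matters through relative
orientations, and for a single tensor not at all). Positive sideband index
means higher frequency.

### Independent oracle

`fid_dft_sidebands` deliberately avoids the analytic phase integral: it
evaluates the instantaneous frequency by explicit rotation of b(t),
integrates the phase by trapezoid over 128 rotor periods at 512 steps per
period, and reads intensities from DFT bins at multiples of the rotor
frequency. Agreement with the single-period engine is at the 1e-5 level,
limited by the oracle's trapezoid error, and both are compared in the
tests — the oracle is never used as the implementation.

## Orientation distribution for aligned samples

Partial uniaxial alignment is modelled by uniform-by-area sampling on the
prolate spheroid (a, a, c) followed by radial projection onto the unit
sphere. Sampling uses rejection against the exact surface-area element
(acceptance probability √(cos²θ + (c/a)² sin²θ)/(c/a)); projection is
radial normalization — the simplest geometric reading of "projected onto a
sphere". All points carry equal weight: alignment is encoded purely in
point density. The third Euler angle γ is drawn uniformly because only the
axis direction is constrained; for the sideband engine the choice is
irrelevant for a single tensor (exact rotor-phase averaging) and tested to
be so. A stratified `quasi_uniform` mode (inverse-CDF over the polar
coordinate) is available for low-variance sweeps.

The analytic cross-check `order_parameter_quadrature` integrates
P₂(u_z(θ)) against the same area element by Gauss–Legendre quadrature;
the sampled ⟨P₂⟩ agrees within Monte-Carlo error (~0.005 at n = 10⁴).
Oblate (c/a < 1) and biaxial (a ≠ b) distributions are not modelled.

## Tensor conventions and calibration

Raw shielding matrices are symmetrized before diagonalization; the
antisymmetric part does not contribute to the observable lineshape at this
level and its norm is logged when it exceeds 1 ppm. The shielding→shift
calibration line (default δ = −0.9760 σ + 175.7662) is applied **per
principal component** by default: this is the only reading under which the
calibrated tensor remains internally consistent (the anisotropy scales by
|slope| and flips sign with the negative slope). An `isotropic_only` mode
is exposed for the alternative reading, where only σ_iso is calibrated and
shift-scale deviations are the negated shielding-scale deviations.

Degenerate (isotropic) tensors get η = 0 and an explicit flag so
downstream code stays total. Haeberlen assignment ties (equal minor
deviations) are broken deterministically toward the larger η.

## Spectrometer defaults

| parameter | default | meaning |
|---|---|---|
| `larmor_MHz` | 150.9 | ¹³C at 14.1 T; converts ppm to Hz |
| `mas_rate_Hz` | 2200 | slow-MAS regime where carbonyl CSAs give rich sideband manifolds |
| `n_time_points` | 128 | FFT samples per rotor period; doubling changes no I_N by > 1e-6 |
| `n_sidebands_max` | 16 | reporting window; tail intensity beyond it must stay < 1e-4 or an error is raised |

## Sweeps

`strain_sweep` reuses one orientation grid (default c/a = 10, 800 points)
for every strain level so that tensor changes are the only variable;
`alignment_sweep` regenerates the grid per c/a from one seed. Ratios are
reported relative to the 0 %-strain or c/a = 1 condition after
normalizing each composite pattern on its centerband, for |N| ≤ 6 by
default (the visible manifold for carbonyl CSAs at 2.2 kHz / 14.1 T).
Per-sideband Monte-Carlo standard errors (orientation-sampling sd / √n)
accompany the ratios. The qualitative contrast between the two mechanisms
is reported as a diagnostic (`monotone_fraction`) rather than asserted as
an invariant, because it depends on the tensor table supplied.

## CSA fitting

The fit minimizes simulated-vs-observed sideband intensities over
(ζ, η, intensity), η constrained to [0, 1]; the forward model is the
package's own engine (uniform-powder Gauss–Legendre quadrature with
n_beta = 64, n_alpha = 8, or a fixed crystallite orientation). A
deterministic multi-start over ζ ∈ ±{20, 50, 80, 110} ppm × η ∈
{0.05, 0.5, 0.95} is ranked by the residual at the analytically optimal
amplitude (amplitude enters linearly), and the three best starts are
polished with bounded least squares. The sign of ζ is identifiable from
the envelope asymmetry whenever |κ| is appreciable; fits with
|ζ| < 1e-3 ppm are flagged degenerate in η. Uncertainties are linearized
standard errors from (JᵀJ)⁻¹ at the optimum. Full-lineshape mode
additionally fits δ_iso and a Lorentzian linewidth against a
(ppm, intensity) spectrum. Joint fitting of alignment (c/a) with CSA from
a single pattern is deliberately not offered — it is degenerate without
prior knowledge.

## Synthetic data: what it emulates, and what it does not

`make_strain_tensor_table` emulates the statistical structure of per-strain
quantum-chemistry tensor tables for Gly/Pro/Hyp carbonyls: baseline
parameters plus a linear strain response plus optional seeded noise, at
strain levels 0, 1.4, 3.4, 8.6, 13.1, 17 % (forces 0–500 pN). The baseline
values (δ_iso ≈ 170 ppm, ζ ≈ −75 ppm, η ≈ 0.6) are plausible
literature-scale stand-ins for peptide C′ sites — **synthetic, not the
output of any particular calculation**. The default response makes Gly
δ_iso the dominant mover, matching the qualitative behaviour of strained
triple helices; the linear form is the simplest model consistent with
monotone trends.

Default PAS orientations place the Haeberlen unique axis perpendicular to
the molecular long axis (β_pas = 90°) — the peptide-plane normal is
roughly perpendicular to the helix axis — with small per-residue in-plane
angles (γ_pas = 0°, 10°, 20°) representing differing C′ geometries. With
this geometry the composite alignment response is smooth and monotone per
sideband, the qualitative signature that distinguishes alignment from
strain.

What the generator does **not** emulate: site-to-site heterogeneity within
a residue type (~1000 distinct carbonyls in a real collagen molecule),
non-carbonyl spectral regions, conformational dynamics, and experimental
artifacts beyond additive white noise (sd = max(signal)/SNR). Passing
tests therefore demonstrate correctness of the machinery and
recoverability under the stated noise model, not agreement with any
experimental tendon dataset.

## Numerical choices and problem sizes

Orientation grids default to 800 points with ellipsoid axes (10, 1, 1);
sweeps in the tests and the acceptance script use 800–5000 points, which
puts per-sideband Monte-Carlo standard errors near 0.5 % of the
centerband. The fit-recovery study uses 20 replicates at SNR 50. The
conservation and oracle-equivalence checks run 200 and 20 random cases
respectively. These sizes make the full pipeline reproducible in about a
minute on one CPU while keeping every statistical tolerance comfortably
resolvable.

## Known limitations

- Single-spin CSA only; no multi-spin couplings or CP dynamics.
- Prolate, axially symmetric alignment model only.
- The per-component calibration choice is a documented interpretation;
  both it and the isotropic-only alternative are exposed.
- The strain sweep is exercised on synthetic tensor tables; quantitative
  per-strain ratio values are therefore illustrative, not predictions for
  real collagen.
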