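# orimas

Simulation and analysis of magic-angle-spinning (MAS) spinning-sideband
patterns for **partially oriented samples**, built around the collagen /
tendon use case: interpreting how slow-MAS ¹³C carbonyl sideband
intensities respond to molecular strain versus molecular alignment.

## Who this is for

Solid-state NMR spectroscopists and structural-biology modellers who study
ordered biological tissues (tendon, bone, cartilage) or other uniaxially
aligned materials, and need to go from computed or fitted chemical-shift
tensors to the sideband patterns a partially aligned sample produces in the
rotor — and back, by fitting CSA parameters to observed patterns.

## The model

A spin-1/2 nucleus with chemical shift anisotropy (CSA) described in the
Haeberlen convention by the isotropic shift δ_iso, anisotropy
ζ = δ_zz − δ_iso and asymmetry η = (δ_yy − δ_xx)/ζ, with principal
components ordered |δ_zz − δ_iso| ≥ |δ_xx − δ_iso| ≥ |δ_yy − δ_iso|.
Under MAS at rate ω_r with the rotor at the magic angle
θ_m = arccos(1/√3), the anisotropic frequency of a crystallite is a
two-harmonic Fourier series in the rotor phase; the accumulated phase
Φ(t) is periodic, so exp(iΦ) expands in Fourier coefficients F_N and the
sideband intensity at order N is I_N = |F_N|². This performs the rotor-phase
average exactly and conserves ΣI_N = 1 by Parseval.

Partial alignment of molecules with the rotor axis is modelled by sampling
points uniformly by area on a prolate ellipsoid with axes (a, a, c) — c
along the rotor axis — and projecting them onto the unit sphere; the aspect
ratio c/a sets the degree of alignment (c/a = 1 is a uniform powder),
quantified by the order parameter ⟨P₂⟩ = ⟨(3cos²β − 1)/2⟩. Shielding
tensors from quantum chemistry are converted to the shift scale with an
affine calibration (δ = −0.9760 σ + 175.7662 by default).

Composite collagen patterns sum the Gly, Pro and Hyp carbonyl
contributions (1:1:1 by default), and two sweeps separate the two candidate
causes of sideband changes in strained tissue: tensor changes with
molecular strain at fixed alignment (c/a = 10), and alignment changes at
fixed tensors.

## Worked example

```sh
python examples/03_sideband_patterns.py
```

prints, for a carbonyl-like tensor (δ_iso = 172 ppm, ζ = −75 ppm, η = 0.5)
at 2.2 kHz MAS and 14.1 T (150.9 MHz ¹³C):

```
tensor: delta_iso=172.0 ppm, zeta=-75.0 ppm, eta=0.50
sideband spacing: 14.58 ppm (2200 Hz / 150.9 MHz)

   N  crystallite       powder  aligned c/a=10
  -3       0.1170       0.0957          0.0443
  -2       0.0417       0.1177          0.0813
  -1       0.0136       0.0422          0.1508
   0       0.1050       0.1507          0.3483
   1       0.0374       0.1600          0.1791
   2       0.3763       0.1957          0.1107
   3       0.1363       0.1079          0.0401
```

(abridged to |N| ≤ 3; run the script for the full table). Each column is a sideband
intensity distribution over order N: a single crystallite orientation, the
uniform powder, and a partially aligned ensemble at c/a = 10. All columns
sum to 1 — MAS redistributes intensity among sidebands without losing it.
`examples/04_strain_and_alignment_sweeps.py` prints the two sweep tables
and the force→stress conversions (10 pN on a 1.5 nm triple helix ≈ 5.7
MPa), and `examples/05_csa_fitting.py` recovers (ζ, η) from a noisy
pattern: at SNR 50 it reports ζ = −74.8 ± 0.6 ppm against a ground truth
of −75 ppm.

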