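"""Recover CSA parameters from a noisy slow-MAS sideband pattern.

Simulates a uniform-powder pattern for a known tensor, adds noise at
SNR 50, fits it, and compares recovered vs true parameters.
"""

from orimas import (
    SpectrometerConfig,
    fit_csa,
    haeberlen_parameters,
    make_noisy_pattern,
    powder_pattern_quadrature,
)

cfg = SpectrometerConfig()
true = haeberlen_parameters([228.25, 190.75, 97.0])  # zeta=-75, eta=0.5
obs = powder_pattern_quadrature(true, cfg, n_beta=64, n_alpha=8)

clean = fit_csa(obs, cfg)
print("noiseless round trip:")
print(f"  zeta {clean.params.zeta:+8.3f} ppm (true {true.zeta:+.1f}), "
      f"eta {clean.params.eta:.4f} (true {true.eta:.2f}), "
      f"residual {clean.residual_norm:.2e}")

noisy = make_noisy_pattern(obs, snr=50.0, seed=1)
fit = fit_csa(noisy, cfg)
print("SNR 50 pattern:")
print(f"  zeta {fit.params.zeta:+8.3f} +- {fit.uncertainties['zeta']:.3f} ppm")
print(f"  eta  {fit.params.eta:8.4f} +- {fit.uncertainties['eta']:.4f}")
print(f"  intensity {fit.intensity:.4f}, starts tried {fit.n_starts_tried}")
# The fit minimizes simulated-vs-observed sideband intensities over
# (zeta, eta, intensity) with a deterministic multi-start; the quoted
# uncertainties are linearized standard errors from the residual curvature.
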