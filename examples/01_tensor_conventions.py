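"""Convert a raw shielding tensor to chemical-shift conventions.

Builds a carbonyl-like shielding matrix, diagonalizes it, applies the
shielding->shift calibration line, and prints the Haeberlen and IUPAC
parameters.
"""

import numpy as np

from orimas import ShieldingTensor, shielding_tensor_to_params, shielding_to_shift

# a backbone C'-like shielding tensor (ppm, shielding scale), slightly
# rotated away from its principal axes
from orimas.orientations import euler_zyz_to_matrix

pas = np.diag([-65.0, 10.0, 75.0]) + 5.0
R = euler_zyz_to_matrix(0.3, 0.9, 0.1)
tensor = ShieldingTensor("C1", "Gly", R @ pas @ R.T)

params = shielding_tensor_to_params(tensor)
print(f"sigma_iso = {np.trace(tensor.matrix) / 3:8.3f} ppm (shielding)")
print(f"delta_iso = {params.delta_iso:8.3f} ppm (shift, calibrated)")
print(f"zeta      = {params.zeta:8.3f} ppm   eta = {params.eta:5.3f}")
print(f"span      = {params.span_omega:8.3f} ppm   skew = {params.skew_kappa:5.3f}")
print(f"check: delta(sigma=0) = {shielding_to_shift(0.0):.4f} ppm (intercept)")
# delta_iso is the centerband position; zeta/eta set the sideband envelope
# at slow MAS; span/skew express the same tensor in the IUPAC convention.
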