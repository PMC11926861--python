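"""MAS spinning-sideband simulation for an isolated spin-1/2 with CSA.

Under magic-angle spinning the instantaneous chemical-shift frequency of a
crystallite is the isotropic shift plus two rotor harmonics,

    nu(t) - nu_iso = Re[A1 exp(i w_r t)] + Re[A2 exp(2 i w_r t)],

with complex coefficients determined by the shift tensor expressed in the
rotor-fixed frame (the rotor axis makes the magic angle
theta_m = arccos(1/sqrt 3) with the field, so the time-average of the
anisotropic part vanishes).  The accumulated anisotropic phase Phi(t) is
periodic with the rotor period, so exp(i Phi(t)) expands in Fourier
coefficients F_N, and the sideband intensity at order N is I_N = |F_N|^2.
This form performs the rotor-phase (initial-phase) average exactly and, by
Parseval, conserves total intensity: sum_N I_N = 1.

Frame chain (all rotations active ZYZ):
PAS --(pas_orientation)--> molecular frame --(grid alpha, beta, gamma)-->
rotor frame --(magic-angle tilt + rotor spinning)--> lab frame.
Positive sideband index = higher frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .orientations import OrientationSet, euler_zyz_to_matrices, euler_zyz_to_matrix
from .tensors import ShiftTensorParams

#: magic angle: rotor axis to static field
THETA_MAGIC = float(np.arccos(1.0 / np.sqrt(3.0)))

#: default 13C Larmor frequency at 14.1 T
DEFAULT_LARMOR_MHZ = 150.9


@dataclass(frozen=True)
class SpectrometerConfig:
    """Field / spinning / discretization settings.

    ``larmor_MHz`` converts ppm to Hz (ppm * MHz = Hz).  ``n_time_points``
    samples one rotor period for the Fourier-coefficient evaluation; it must
    be a power of two >= 32 and bounds the representable sideband order at
    ``n_time_points // 2``.
    """

    larmor_MHz: float = DEFAULT_LARMOR_MHZ
    mas_rate_Hz: float = 2200.0
    n_sidebands_max: int = 16
    n_time_points: int = 128

    def __post_init__(self) -> None:
        if self.mas_rate_Hz <= 0 or self.larmor_MHz <= 0:
            raise ValueError("mas_rate_Hz and larmor_MHz must be positive")
        n = self.n_time_points
        if n < 32 or (n & (n - 1)) != 0:
            raise ValueError("n_time_points must be a power of 2 >= 32")
        if self.n_sidebands_max >= self.n_time_points // 2:
            raise ValueError("n_sidebands_max must be < n_time_points / 2")

    @property
    def sideband_spacing_ppm(self) -> float:
        return self.mas_rate_Hz / self.larmor_MHz


@dataclass(frozen=True)
class SidebandPattern:
    """Sideband intensities I_N over integer orders N.

    ``indices`` run from ``-n_sidebands_max`` to ``+n_sidebands_max``;
    intensities are non-negative and sum to (at most) 1, the small remainder
    being intensity beyond the reported window.
    """

    indices: np.ndarray
    intensities: np.ndarray
    delta_iso: float
    config: SpectrometerConfig
    per_orientation_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        inten = np.asarray(self.intensities, dtype=float)
        if idx.shape != inten.shape:
            raise ValueError("indices and intensities must align")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "intensities", inten)

    def intensity(self, n: int) -> float:
        """I_N for sideband order n (0 outside the stored window)."""
        hit = np.nonzero(self.indices == n)[0]
        return float(self.intensities[hit[0]]) if hit.size else 0.0

    def total(self) -> float:
        return float(self.intensities.sum())

    def as_dict(self) -> dict:
        return {int(n): float(i) for n, i in zip(self.indices, self.intensities)}


# ---------------------------------------------------------------------------
# core: rotor-frame tensor -> harmonic coefficients -> |F_N|^2
# ---------------------------------------------------------------------------

def _harmonic_coefficients(A_rotor: np.ndarray):
    """Complex rotor harmonics (A1, A2) in ppm from rotor-frame tensor(s).

    ``A_rotor`` has shape (..., 3, 3) (symmetric).  With the field direction
    in the rotor frame b(t) = (s cos p, s sin p, c), s = sin theta_m,
    c = cos theta_m, the lab zz component b^T A b expands as
    d_iso + Re[A1 e^{ip}] + Re[A2 e^{2ip}].
    """
    s, c = np.sin(THETA_MAGIC), np.cos(THETA_MAGIC)
    A1 = 2.0 * s * c * (A_rotor[..., 0, 2] - 1j * A_rotor[..., 1, 2])
    A2 = s * s * (
        0.5 * (A_rotor[..., 0, 0] - A_rotor[..., 1, 1])
        - 1j * A_rotor[..., 0, 1]
    )
    return A1, A2


def _sideband_intensities_from_harmonics(A1, A2, config: SpectrometerConfig):
    """|F_N|^2 for each case, via exact phase integration + FFT.

    A1, A2: complex arrays of shape (...,) in ppm.  Returns an array of
    shape (..., n_time_points) of intensities ordered by FFT frequency
    (np.fft.fftfreq convention: index 0 = centerband).
    """
    A1 = np.asarray(A1, dtype=complex)
    A2 = np.asarray(A2, dtype=complex)
    n = config.n_time_points
    w_r = 2.0 * np.pi * config.mas_rate_Hz
    nuL = config.larmor_MHz  # Hz per ppm
    t = np.arange(n) / (n * config.mas_rate_Hz)  # one rotor period
    phase_t = np.exp(1j * w_r * t)  # e^{i w_r t_k}

    # Phi(t) = 2 pi nuL Re[ A1 (e^{iwt}-1)/(i w) + A2 (e^{2iwt}-1)/(2 i w) ]
    term1 = (phase_t - 1.0)[..., :] * (A1[..., None] / (1j * w_r))
    term2 = (phase_t**2 - 1.0)[..., :] * (A2[..., None] / (2j * w_r))
    phi = 2.0 * np.pi * nuL * np.real(term1 + term2)
    g = np.exp(1j * phi)
    F = np.fft.fft(g, axis=-1) / n
    return np.abs(F) ** 2


def _window(intensity_fft: np.ndarray, config: SpectrometerConfig,
            check_convergence: bool = True, tail_tol: float = 1e-4):
    """Extract the +-n_sidebands_max window from FFT-ordered intensities."""
    nmax = config.n_sidebands_max
    idx = np.arange(-nmax, nmax + 1)
    win = intensity_fft[..., idx]  # FFT wrap-around indexing
    if check_convergence:
        tail = intensity_fft.sum(axis=-1) - win.sum(axis=-1)
        if np.max(tail) > tail_tol:
            raise ValueError(
                f"sideband window +-{nmax} not converged: "
                f"tail intensity {np.max(tail):.2e} > {tail_tol:.0e}; "
                f"increase n_sidebands_max"
            )
    return idx, win


def _pas_to_rotor_tensor(params: ShiftTensorParams, R_mol_to_rotor: np.ndarray):
    """Anisotropic shift tensor in the rotor frame (iso part removed)."""
    pas = np.diag(params.principal_shifts() - params.delta_iso)
    R_pas = euler_zyz_to_matrix(*params.pas_orientation)
    R = R_mol_to_rotor @ R_pas
    return R @ pas @ R.T


def crystallite_sidebands(
    params: ShiftTensorParams,
    alpha: float,
    beta: float,
    config: SpectrometerConfig,
    gamma: float = 0.0,
) -> SidebandPattern:
    """Sideband pattern of a single crystallite orientation.

    ``alpha, beta, gamma`` are the ZYZ Euler angles (radians) carrying the
    molecular frame into the rotor frame.  Rotor-phase averaging is exact,
    so intensities do not depend on the initial rotor position.
    """
    R = euler_zyz_to_matrix(alpha, beta, gamma)
    A_rotor = _pas_to_rotor_tensor(params, R)
    A1, A2 = _harmonic_coefficients(A_rotor)
    inten = _sideband_intensities_from_harmonics(A1, A2, config)
    idx, win = _window(inten, config)
    return SidebandPattern(
        indices=idx, intensities=win, delta_iso=params.delta_iso, config=config
    )


def ensemble_pattern(
    tensors,
    orientations: OrientationSet,
    config: SpectrometerConfig,
    tensor_weights=None,
    keep_orientation_stats: bool = False,
) -> SidebandPattern:
    """Orientation- and site-averaged sideband pattern.

    For each orientation the tensor's PAS->molecular rotation composes with
    the grid angles; per-orientation intensities are averaged with the set's
    weights, and multiple tensors (e.g. Gly/Pro/Hyp carbonyls) combine with
    ``tensor_weights`` (uniform by default).  ``keep_orientation_stats``
    records the per-orientation standard deviation of each sideband, from
    which a Monte-Carlo standard error of the ensemble mean follows as
    sd / sqrt(n).
    """
    if isinstance(tensors, ShiftTensorParams):
        tensors = [tensors]
    tensors = list(tensors)
    if not tensors or len(orientations) == 0:
        raise ValueError("need at least one tensor and one orientation")
    tw = (
        np.full(len(tensors), 1.0 / len(tensors))
        if tensor_weights is None
        else np.asarray(tensor_weights, dtype=float)
    )
    if tw.shape != (len(tensors),) or np.any(tw < 0) or tw.sum() == 0:
        raise ValueError("tensor_weights must be non-negative, one per tensor")
    tw = tw / tw.sum()

    R_grid = euler_zyz_to_matrices(
        orientations.angles[:, 0], orientations.angles[:, 1],
        orientations.angles[:, 2],
    )

    w = orientations.weights
    idx = np.arange(-config.n_sidebands_max, config.n_sidebands_max + 1)
    mean = np.zeros(idx.size)
    var_accum = np.zeros(idx.size)
    delta_iso = float(np.dot(tw, [p.delta_iso for p in tensors]))
    for p, wt in zip(tensors, tw):
        pas = np.diag(p.principal_shifts() - p.delta_iso)
        R_pas = euler_zyz_to_matrix(*p.pas_orientation)
        R = R_grid @ R_pas  # (n, 3, 3)
        A_rotor = R @ pas @ np.swapaxes(R, -1, -2)
        A1, A2 = _harmonic_coefficients(A_rotor)
        inten = _sideband_intensities_from_harmonics(A1, A2, config)  # (n, nt)
        _, win = _window(inten, config)  # (n, 2*nmax+1)
        m = w @ win
        mean += wt * m
        if keep_orientation_stats:
            var_accum += wt * (w @ (win - m) ** 2)
    sd = np.sqrt(var_accum) if keep_orientation_stats else None
    return SidebandPattern(
        indices=idx, intensities=mean, delta_iso=delta_iso, config=config,
        per_orientation_sd=sd,
    )


# ---------------------------------------------------------------------------
# independent oracle: brute-force long-FID propagation + DFT
# ---------------------------------------------------------------------------

def fid_dft_sidebands(
    params: ShiftTensorParams,
    alpha: float,
    beta: float,
    config: SpectrometerConfig,
    gamma: float = 0.0,
    n_periods: int = 128,
    steps_per_period: int = 512,
) -> SidebandPattern:
    """Brute-force reference: numerically integrate the FID phase over many
    rotor periods at fine time steps and read sideband intensities from a
    discrete Fourier transform.

    Independent of the single-period Fourier-coefficient route: the
    instantaneous frequency is evaluated by explicitly rotating the field
    direction in the rotor frame, the phase accumulates by trapezoidal
    integration, and intensities come from DFT bins at multiples of the
    rotor frequency.
    """
    R = euler_zyz_to_matrix(alpha, beta, gamma)
    A_rotor = _pas_to_rotor_tensor(params, R)
    ntot = n_periods * steps_per_period
    t = np.arange(ntot) / (steps_per_period * config.mas_rate_Hz)
    p = 2.0 * np.pi * config.mas_rate_Hz * t
    s, c = np.sin(THETA_MAGIC), np.cos(THETA_MAGIC)
    b = np.column_stack([s * np.cos(p), s * np.sin(p), np.full_like(p, c)])
    freq_ppm = np.einsum("ti,ij,tj->t", b, A_rotor, b)
    freq_hz = freq_ppm * config.larmor_MHz
    dt = 1.0 / (steps_per_period * config.mas_rate_Hz)
    phase = np.concatenate(
        [[0.0], np.cumsum((freq_hz[1:] + freq_hz[:-1]) / 2.0) * dt]
    )
    fid = np.exp(2j * np.pi * phase)
    spec = np.fft.fft(fid) / ntot
    nmax = config.n_sidebands_max
    idx = np.arange(-nmax, nmax + 1)
    inten = np.abs(spec[(idx * n_periods) % ntot]) ** 2
    return SidebandPattern(
        indices=idx, intensities=inten, delta_iso=params.delta_iso,
        config=config,
    )


def powder_pattern_quadrature(
    params: ShiftTensorParams,
    config: SpectrometerConfig,
    n_beta: int = 256,
    n_alpha: int = 1,
) -> SidebandPattern:
    """Uniform-powder pattern by Gauss-Legendre quadrature over cos(beta).

    For axially symmetric tensors one beta sweep suffices (``n_alpha=1``);
    for eta > 0 an alpha grid is added.  Serves as the dense deterministic
    reference for Monte-Carlo ensembles at c/a = 1, and as the forward model
    for powder-pattern fits.
    """
    x, wq = np.polynomial.legendre.leggauss(n_beta)
    betas = np.arccos(x)
    alphas = (
        np.array([0.0]) if n_alpha == 1
        else np.linspace(0, 2 * np.pi, n_alpha, endpoint=False)
    )
    pas = np.diag(params.principal_shifts() - params.delta_iso)
    R_pas = euler_zyz_to_matrix(*params.pas_orientation)
    idx = np.arange(-config.n_sidebands_max, config.n_sidebands_max + 1)
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    R = euler_zyz_to_matrices(A.ravel(), B.ravel(), 0.0) @ R_pas
    A_rotor = R @ pas @ np.swapaxes(R, -1, -2)
    A1, A2 = _harmonic_coefficients(A_rotor)
    inten = _sideband_intensities_from_harmonics(A1, A2, config)
    _, win = _window(inten, config)
    w_full = np.tile(wq / wq.sum() / len(alphas), len(alphas))
    acc = w_full @ win
    return SidebandPattern(
        indices=idx, intensities=acc, delta_iso=params.delta_iso, config=config
    )


# ---------------------------------------------------------------------------
# 1D spectrum rendering
# ---------------------------------------------------------------------------

def render_spectrum(
    pattern: SidebandPattern,
    axis_ppm: np.ndarray,
    linewidth_ppm: float = 1.0,
    lineshape: str = "lorentzian",
) -> np.ndarray:
    """Render a sideband pattern onto a ppm axis.

    One line per sideband at ``delta_iso + N * spacing`` with area
    proportional to I_N; ``linewidth_ppm`` is the FWHM.  ``linewidth_ppm=0``
    places each sideband's intensity on the nearest axis point (stick mode).
    Sidebands outside the axis range are dropped with a warning.
    """
    axis = np.asarray(axis_ppm, dtype=float)
    d = np.diff(axis)
    if axis.ndim != 1 or axis.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be strictly monotone")
    if linewidth_ppm < 0:
        raise ValueError("linewidth must be non-negative")
    lo, hi = min(axis[0], axis[-1]), max(axis[0], axis[-1])
    spacing = pattern.config.sideband_spacing_ppm
    out = np.zeros_like(axis)
    dropped = 0
    for n, inten in zip(pattern.indices, pattern.intensities):
        center = pattern.delta_iso + n * spacing
        if center < lo or center > hi:
            if inten > 1e-12:
                dropped += 1
            continue
        if linewidth_ppm == 0:
            out[np.argmin(np.abs(axis - center))] += inten
        elif lineshape == "lorentzian":
            hwhm = linewidth_ppm / 2.0
            out += inten * (hwhm / np.pi) / ((axis - center) ** 2 + hwhm**2)
        elif lineshape == "gaussian":
            sd = linewidth_ppm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            out += inten * np.exp(-0.5 * ((axis - center) / sd) ** 2) / (
                sd * np.sqrt(2.0 * np.pi)
            )
        else:
            raise ValueError(f"unknown lineshape {lineshape!r}")
    if dropped:
        import warnings

        warnings.warn(
            f"{dropped} sideband(s) fall outside the ppm axis; spectrum "
            "truncated", stacklevel=2,
        )
    return out


def write_pattern(path, pattern: SidebandPattern) -> None:
    """Export as delimited text: columns (sideband_index, intensity)."""
    import pandas as pd

    df = pd.DataFrame(
        {"sideband_index": pattern.indices, "intensity": pattern.intensities}
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# delta_iso={pattern.delta_iso} "
            f"mas_rate_Hz={pattern.config.mas_rate_Hz} "
            f"larmor_MHz={pattern.config.larmor_MHz}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_pattern(path) -> SidebandPattern:
    import io as _io

    import pandas as pd

    meta = {}
    body = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh.read().splitlines():
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = float(v)
            elif line.strip():
                body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t")
    indices = df["sideband_index"].to_numpy(dtype=int)
    config = SpectrometerConfig(
        larmor_MHz=meta.get("larmor_MHz", DEFAULT_LARMOR_MHZ),
        mas_rate_Hz=meta.get("mas_rate_Hz", 2200.0),
        n_sidebands_max=int(np.max(np.abs(indices))),
        n_time_points=max(
            128, 1 << int(np.ceil(np.log2(2 * np.max(np.abs(indices)) + 2)))
        ),
    )
    return SidebandPattern(
        indices=indices,
        intensities=df["intensity"].to_numpy(dtype=float),
        delta_iso=meta.get("delta_iso", 0.0),
        config=config,
    )
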