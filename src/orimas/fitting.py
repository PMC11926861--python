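"""Least-squares recovery of Haeberlen CSA parameters from slow-MAS
sideband patterns or rendered 1D spectra.

The default mode fits integrated sideband intensities: the forward model is
the package's own sideband engine (uniform-powder quadrature, or a single
crystallite orientation), scaled by an overall intensity, and the residual
is minimized over (zeta, eta, intensity) with eta constrained to [0, 1].
Because a single pattern is symmetric under (zeta, eta) -> tensor
relabelings only at eta = 1, the sign of zeta is identifiable from the
envelope asymmetry whenever the skew is appreciable; a deterministic
multi-start over a coarse (zeta, eta) grid avoids local minima either way.

Full-lineshape mode additionally fits the isotropic shift and a Lorentzian
linewidth against a (ppm, intensity) spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .sidebands import (
    SidebandPattern,
    SpectrometerConfig,
    crystallite_sidebands,
    powder_pattern_quadrature,
    render_spectrum,
)
from .tensors import ShiftTensorParams, haeberlen_parameters

#: deterministic multi-start grid
_ZETA_STARTS = (-110.0, -80.0, -50.0, -20.0, 20.0, 50.0, 80.0, 110.0)
_ETA_STARTS = (0.05, 0.5, 0.95)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a CSA fit."""

    params: ShiftTensorParams
    intensity: float
    linewidth_ppm: float
    residual_norm: float
    uncertainties: dict
    converged: bool
    n_starts_tried: int
    objective_trace: tuple = ()

    @property
    def degenerate(self) -> bool:
        return self.params.degenerate


def _forward_pattern(zeta, eta, config, assume_uniform_orientation,
                     orientation, n_beta):
    p = haeberlen_parameters([
        -zeta * (1 + eta) / 2.0, -zeta * (1 - eta) / 2.0, zeta,
    ]) if abs(zeta) > 1e-12 else haeberlen_parameters([0.0, 0.0, 0.0])
    if assume_uniform_orientation:
        n_alpha = 1 if eta < 1e-9 else 8
        return powder_pattern_quadrature(p, config, n_beta=n_beta,
                                         n_alpha=n_alpha)
    al, be = orientation
    return crystallite_sidebands(p, al, be, config)


def fit_csa(
    observed,
    config: SpectrometerConfig,
    assume_uniform_orientation: bool = True,
    init: tuple | None = None,
    orientation: tuple = (0.0, 0.0),
    fit_lineshape: bool = False,
    axis_ppm: np.ndarray | None = None,
    n_beta: int = 64,
) -> FitResult:
    """Fit (zeta, eta, intensity[, delta_iso, linewidth]) to observed data.

    Parameters
    ----------
    observed : SidebandPattern or ndarray
        Sideband intensities (default mode), or a 1D spectrum on
        ``axis_ppm`` when ``fit_lineshape`` is True.
    config : SpectrometerConfig
        Known MAS rate and field (not fitted).
    assume_uniform_orientation : bool
        Model the pattern as a uniform powder (quadrature average); when
        False, a single crystallite at ``orientation`` (alpha, beta).
    init : optional (zeta, eta)
        Starting point; when omitted a deterministic multi-start grid over
        zeta in +-{20, 50, 80, 110} ppm x eta in {0.05, 0.5, 0.95} is used.

    Notes
    -----
    A pattern needs at least four resolvable sidebands (counting the
    centerband) for the three intensity-mode parameters to be identifiable.
    Uncertainties are linearized standard errors from the residual Jacobian
    at the optimum.
    """
    if fit_lineshape:
        return _fit_lineshape(observed, axis_ppm, config,
                              assume_uniform_orientation, orientation,
                              init, n_beta)
    if not isinstance(observed, SidebandPattern):
        raise TypeError("intensity-mode fitting expects a SidebandPattern")
    y = observed.intensities
    n_resolved = int(np.sum(y > 1e-6 * max(y.max(), 1e-300)))
    if n_resolved < 4:
        raise ValueError(
            f"only {n_resolved} resolvable sidebands; need >= 4 to identify "
            "(zeta, eta, intensity)"
        )

    cfg = SpectrometerConfig(
        larmor_MHz=config.larmor_MHz, mas_rate_Hz=config.mas_rate_Hz,
        n_sidebands_max=int(np.max(np.abs(observed.indices))),
        n_time_points=config.n_time_points,
    )

    def residuals(theta):
        zeta, eta, amp = theta
        model = _forward_pattern(zeta, eta, cfg, assume_uniform_orientation,
                                 orientation, n_beta)
        return amp * model.intensities - y

    if init is not None:
        starts = [(init[0], init[1])]
    else:
        # rank the coarse grid by residual with the analytically optimal
        # amplitude (amp enters linearly), then polish only the best starts
        grid = [(z, e) for z in _ZETA_STARTS for e in _ETA_STARTS]
        scored = []
        for z0, e0 in grid:
            m = _forward_pattern(z0, e0, cfg, assume_uniform_orientation,
                                 orientation, n_beta).intensities
            amp = max(float(m @ y) / float(m @ m), 0.0)
            scored.append((float(np.linalg.norm(amp * m - y)), z0, e0))
        scored.sort()
        starts = [(z, e) for _, z, e in scored[:3]]
    best = None
    trace = []
    for z0, e0 in starts:
        amp0 = max(y.sum(), 1e-12)
        try:
            sol = least_squares(
                residuals, x0=[z0, e0, amp0],
                bounds=([-np.inf, 0.0, 0.0], [np.inf, 1.0, np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        resid_here = float(np.linalg.norm(sol.fun))
        if best is None or resid_here < np.linalg.norm(best.fun) - 1e-15:
            best = sol
            trace.append(resid_here)  # accepted-improvement trace
    if best is None:
        raise RuntimeError("no fit start converged")
    zeta, eta, amp = best.x
    resid = float(np.linalg.norm(best.fun))
    unc = _linearized_uncertainties(best, ("zeta", "eta", "intensity"))

    params = haeberlen_parameters(
        np.array([-zeta * (1 + eta) / 2, -zeta * (1 - eta) / 2, zeta])
        + observed.delta_iso
    )
    if abs(zeta) < 1e-3 and not params.degenerate:
        # anisotropy indistinguishable from zero: eta is unidentifiable
        params = ShiftTensorParams(
            delta_iso=params.delta_iso, zeta=params.zeta, eta=0.0,
            span_omega=params.span_omega, skew_kappa=params.skew_kappa,
            pas_orientation=params.pas_orientation, degenerate=True,
        )
    converged = bool(best.success) and resid < 10 * np.linalg.norm(y)
    return FitResult(
        params=params, intensity=float(amp), linewidth_ppm=0.0,
        residual_norm=resid, uncertainties=unc, converged=converged,
        n_starts_tried=len(starts), objective_trace=tuple(trace),
    )


def _fit_lineshape(y, axis_ppm, config, assume_uniform_orientation,
                   orientation, init, n_beta):
    """Full-lineshape mode: fit (zeta, eta, amp, delta_iso, linewidth)."""
    y = np.asarray(y, dtype=float)
    axis = np.asarray(axis_ppm, dtype=float)
    if axis is None or axis.shape != y.shape:
        raise ValueError("lineshape mode needs matching axis_ppm and spectrum")
    diso0 = float(axis[np.argmax(y)])

    def residuals(theta):
        zeta, eta, amp, diso, lw = theta
        pat = _forward_pattern(zeta, eta, config, assume_uniform_orientation,
                               orientation, n_beta)
        pat = SidebandPattern(pat.indices, pat.intensities, diso, config)
        return amp * render_spectrum(pat, axis, linewidth_ppm=lw) - y

    starts = (
        [init] if init is not None
        else [(z, e) for z in _ZETA_STARTS for e in _ETA_STARTS]
    )
    dppm = abs(axis[1] - axis[0])
    amp0 = max(float(np.trapezoid(np.abs(y), dx=dppm)), 1e-12)
    best = None
    for z0, e0 in starts:
        try:
            sol = least_squares(
                residuals, x0=[z0, e0, amp0, diso0, 2.0],
                bounds=([-np.inf, 0.0, 0.0, axis.min(), 10 * dppm],
                        [np.inf, 1.0, np.inf, axis.max(), np.inf]),
                xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        if best is None or np.linalg.norm(sol.fun) < np.linalg.norm(best.fun):
            best = sol
    if best is None:
        raise RuntimeError("no lineshape fit start converged")
    zeta, eta, amp, diso, lw = best.x
    unc = _linearized_uncertainties(
        best, ("zeta", "eta", "intensity", "delta_iso", "linewidth_ppm")
    )
    params = haeberlen_parameters(
        np.array([-zeta * (1 + eta) / 2, -zeta * (1 - eta) / 2, zeta]) + diso
    )
    return FitResult(
        params=params, intensity=float(amp), linewidth_ppm=float(lw),
        residual_norm=float(np.linalg.norm(best.fun)), uncertainties=unc,
        converged=bool(best.success), n_starts_tried=len(starts),
    )


def _linearized_uncertainties(sol, names) -> dict:
    """Standard errors from the curvature (J^T J)^-1 at the optimum."""
    J = sol.jac
    m, p = J.shape
    dof = max(m - p, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se.tolist()))
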