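"""Chemical-shielding / chemical-shift tensor processing.

Raw nuclear shielding tensors (e.g. from quantum-chemistry output) are
symmetrized, diagonalized and converted to the chemical-shift scale with an
affine calibration line, then parameterized in the Haeberlen convention
(``delta_iso``, anisotropy ``zeta``, asymmetry ``eta``) and the IUPAC
(Herzfeld--Berger) convention (span ``Omega``, skew ``kappa``).

Conventions
-----------
Haeberlen ordering of principal shifts:
``|d_zz - d_iso| >= |d_xx - d_iso| >= |d_yy - d_iso|`` with
``zeta = d_zz - d_iso`` and ``eta = (d_yy - d_xx) / zeta`` (so eta in [0, 1]).
IUPAC ordering ``d_11 >= d_22 >= d_33`` gives ``Omega = d_11 - d_33`` and
``kappa = 3 (d_22 - d_iso) / Omega``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .orientations import rotation_matrix_to_euler_zyz

logger = logging.getLogger(__name__)

RESIDUE_VOCAB = frozenset({"Gly", "Pro", "Hyp", "other"})

#: Default shielding->shift calibration, obtained by regressing computed
#: isotropic shieldings against known collagen shifts.
DEFAULT_CALIBRATION_SLOPE = -0.9760
DEFAULT_CALIBRATION_INTERCEPT = 175.7662


@dataclass(frozen=True)
class ShiftCalibration:
    """Affine map from shielding sigma (ppm) to chemical shift delta (ppm)."""

    slope: float = DEFAULT_CALIBRATION_SLOPE
    intercept: float = DEFAULT_CALIBRATION_INTERCEPT

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")

    def __call__(self, sigma):
        return self.slope * np.asarray(sigma, dtype=float) + self.intercept

    def inverse(self, delta):
        return (np.asarray(delta, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class ShieldingTensor:
    """Raw 3x3 shielding matrix (ppm) for one nucleus.

    The matrix need not be symmetric; only the symmetric part contributes to
    the observable lineshape at this level of theory and is used downstream.
    """

    site_id: str
    residue: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError(f"non-finite shielding matrix for site {self.site_id!r}")
        if self.residue not in RESIDUE_VOCAB:
            raise ValueError(
                f"residue {self.residue!r} not in {sorted(RESIDUE_VOCAB)}"
            )
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class ShiftTensorParams:
    """Chemical-shift tensor in Haeberlen + IUPAC parameterizations.

    Parameters
    ----------
    delta_iso : float
        Isotropic chemical shift (ppm).
    zeta : float
        Haeberlen anisotropy ``d_zz - d_iso`` (ppm, signed).
    eta : float
        Asymmetry in [0, 1].
    span_omega, skew_kappa : float
        IUPAC span (ppm, >= 0) and skew (in [-1, 1]).
    pas_orientation : tuple of float
        ZYZ Euler angles (radians) rotating the principal axis system into
        the molecular frame.
    degenerate : bool
        True when zeta == 0 (isotropic tensor); eta is then defined as 0.
    """

    delta_iso: float
    zeta: float
    eta: float
    span_omega: float = 0.0
    skew_kappa: float = 0.0
    pas_orientation: tuple = (0.0, 0.0, 0.0)
    degenerate: bool = False
    site_id: str = ""
    residue: str = "other"

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.eta <= 1 + 1e-12):
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        if self.span_omega < -1e-12:
            raise ValueError("span must be non-negative")

    def principal_shifts(self) -> np.ndarray:
        """Principal values (d_xx, d_yy, d_zz) in the Haeberlen assignment."""
        d_zz = self.delta_iso + self.zeta
        d_xx = self.delta_iso - self.zeta * (1.0 + self.eta) / 2.0
        d_yy = self.delta_iso - self.zeta * (1.0 - self.eta) / 2.0
        return np.array([d_xx, d_yy, d_zz])

    def pas_tensor(self) -> np.ndarray:
        """Diagonal shift tensor in its principal axis system."""
        return np.diag(self.principal_shifts())


def diagonalize_shielding(tensor: ShieldingTensor, antisym_warn_ppm: float = 1.0):
    """Diagonalize the symmetric part of a raw shielding matrix.

    Returns
    -------
    principal : ndarray, shape (3,)
        Principal shielding values, descending.
    euler_zyz : tuple
        ZYZ Euler angles (radians) of the PAS in the input frame.
    degenerate : bool
        True if all three principal values coincide (orientation arbitrary).

    Notes
    -----
    The antisymmetric part of the matrix does not contribute to the
    observable MAS lineshape to first order and is discarded; if its norm
    exceeds ``antisym_warn_ppm`` this is logged.
    """
    m = tensor.matrix
    sym = 0.5 * (m + m.T)
    anti = 0.5 * (m - m.T)
    anti_norm = float(np.linalg.norm(anti))
    if anti_norm > antisym_warn_ppm:
        logger.info(
            "site %s: antisymmetric shielding norm %.3f ppm discarded",
            tensor.site_id, anti_norm,
        )
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.linalg.det(evecs) < 0:  # keep a proper rotation
        evecs[:, -1] *= -1
    degenerate = bool(np.allclose(evals, evals[0], atol=1e-9))
    euler = (0.0, 0.0, 0.0) if degenerate else rotation_matrix_to_euler_zyz(evecs)
    return evals, euler, degenerate


def shielding_to_shift(sigma, calibration: ShiftCalibration | None = None):
    """Apply the affine shielding->shift calibration (element-wise)."""
    if calibration is None:
        calibration = ShiftCalibration()
    return calibration(sigma)


def haeberlen_parameters(
    principal_shifts,
    pas_orientation: tuple = (0.0, 0.0, 0.0),
    site_id: str = "",
    residue: str = "other",
    tol: float = 1e-12,
) -> ShiftTensorParams:
    """Parameterize three principal chemical shifts in both conventions.

    An isotropic tensor (all deviations zero) is flagged degenerate with
    ``eta = 0``.  When the two minor deviations tie exactly, the assignment
    with the larger eta is kept.
    """
    d = np.asarray(principal_shifts, dtype=float)
    if d.shape != (3,) or not np.all(np.isfinite(d)):
        raise ValueError("principal shifts must be three finite values")
    d_iso = float(d.mean())
    dev = d - d_iso

    # IUPAC: d_11 >= d_22 >= d_33
    d_sorted = np.sort(d)[::-1]
    span = float(d_sorted[0] - d_sorted[2])
    kappa = 0.0 if span < tol else float(3.0 * (d_sorted[1] - d_iso) / span)

    abs_dev = np.abs(dev)
    if abs_dev.max() < tol:
        return ShiftTensorParams(
            delta_iso=d_iso, zeta=0.0, eta=0.0, span_omega=span,
            skew_kappa=kappa, pas_orientation=tuple(pas_orientation),
            degenerate=True, site_id=site_id, residue=residue,
        )
    # zz carries the largest deviation; of the remaining two, xx the larger.
    # Enumerate candidate assignments, keep a valid one maximizing eta
    # (deterministic tie-break toward eta = 1).
    best = None
    for i_zz in range(3):
        rest = [j for j in range(3) if j != i_zz]
        for i_xx, i_yy in (rest, rest[::-1]):
            if not (
                abs_dev[i_zz] >= abs_dev[i_xx] - tol
                and abs_dev[i_xx] >= abs_dev[i_yy] - tol
            ):
                continue
            zeta = float(dev[i_zz])
            eta = float((d[i_yy] - d[i_xx]) / zeta)
            if eta < -tol or eta > 1 + tol:
                continue
            eta = min(max(eta, 0.0), 1.0)
            if best is None or eta > best[1]:
                best = (zeta, eta)
    zeta, eta = best
    return ShiftTensorParams(
        delta_iso=d_iso, zeta=zeta, eta=eta, span_omega=span,
        skew_kappa=kappa, pas_orientation=tuple(pas_orientation),
        degenerate=False, site_id=site_id, residue=residue,
    )


def shielding_tensor_to_params(
    tensor: ShieldingTensor,
    calibration: ShiftCalibration | None = None,
    calibrate_mode: str = "per_component",
) -> ShiftTensorParams:
    """Full route: raw shielding matrix -> calibrated ShiftTensorParams.

    ``calibrate_mode='per_component'`` applies the calibration line to every
    principal shielding value (anisotropy scales by |slope| and flips sign
    because the slope is negative); ``'isotropic_only'`` calibrates only the
    isotropic shift and negates the shielding anisotropy (delta-scale
    deviations are minus sigma-scale deviations).
    """
    if calibration is None:
        calibration = ShiftCalibration()
    principal_sigma, euler, degenerate = diagonalize_shielding(tensor)
    if calibrate_mode == "per_component":
        principal_delta = calibration(principal_sigma)
    elif calibrate_mode == "isotropic_only":
        sigma_iso = principal_sigma.mean()
        delta_iso = float(calibration(sigma_iso))
        principal_delta = delta_iso - (principal_sigma - sigma_iso)
    else:
        raise ValueError(f"unknown calibrate_mode {calibrate_mode!r}")
    params = haeberlen_parameters(
        principal_delta, pas_orientation=euler,
        site_id=tensor.site_id, residue=tensor.residue,
    )
    if degenerate and not params.degenerate:
        params = ShiftTensorParams(
            **{**params.__dict__, "degenerate": True}
        )
    return params


# ---------------------------------------------------------------------------
# Tensor-table IO
#
# Delimited text (comma or tab, auto-detected), one nucleus per row, header
# mandatory. Either principal-value columns (site_id, residue, s11, s22, s33)
# or full-matrix columns (site_id, residue, m11, m12, m13, m21, ..., m33);
# optional strain_pct / force_pN columns. Lines starting with '#' are
# metadata; '# scale=shielding' marks sigma-scale values needing calibration.
# ---------------------------------------------------------------------------

_MATRIX_COLS = [f"m{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
_PRINCIPAL_COLS = ["s11", "s22", "s33"]


class TensorTableError(ValueError):
    """Raised for schema violations in tensor tables, naming the row."""


def read_tensor_table(
    path,
    calibration: ShiftCalibration | None = None,
    calibrate_mode: str = "per_component",
) -> list[ShiftTensorParams]:
    """Read a tensor table into a list of :class:`ShiftTensorParams`.

    Values are interpreted on the chemical-shift scale unless the header
    carries ``scale=shielding``, in which case the calibration is applied.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    header_meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            for tokenpair in line[1:].replace(",", " ").split():
                if "=" in tokenpair:
                    k, v = tokenpair.split("=", 1)
                    header_meta[k.strip()] = v.strip()
            continue
        if line.strip():
            body_lines.append(line)
    if not body_lines:
        warnings.warn(f"empty tensor table: {path}", stacklevel=2)
        return []
    sep = "\t" if "\t" in body_lines[0] else ","
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep=sep)
    df.columns = [c.strip() for c in df.columns]

    shielding_scale = header_meta.get("scale", "shift") == "shielding"
    if calibration is None:
        calibration = ShiftCalibration()

    required = {"site_id", "residue"}
    if not required.issubset(df.columns):
        raise TensorTableError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    has_matrix = set(_MATRIX_COLS).issubset(df.columns)
    has_principal = set(_PRINCIPAL_COLS).issubset(df.columns)
    if not (has_matrix or has_principal):
        raise TensorTableError(
            f"{path}: need either principal columns {_PRINCIPAL_COLS} "
            f"or matrix columns m11..m33"
        )
    value_cols = _MATRIX_COLS if has_matrix else _PRINCIPAL_COLS

    out: list[ShiftTensorParams] = []
    for irow, row in df.iterrows():
        vals = row[value_cols]
        try:
            vals = vals.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise TensorTableError(
                f"{path} row {irow}: non-numeric tensor value ({exc})"
            ) from None
        if not np.all(np.isfinite(vals)):
            raise TensorTableError(f"{path} row {irow}: non-finite tensor value")
        residue = str(row["residue"]).strip()
        site_id = str(row["site_id"]).strip()
        if residue not in RESIDUE_VOCAB:
            raise TensorTableError(
                f"{path} row {irow}: unknown residue {residue!r}"
            )
        if has_matrix:
            tensor = ShieldingTensor(site_id, residue, vals.reshape(3, 3))
            if not shielding_scale:
                # shift-scale matrix: treat values as already calibrated
                ident = ShiftCalibration(slope=1.0, intercept=0.0)
                params = shielding_tensor_to_params(
                    tensor, calibration=ident, calibrate_mode="per_component"
                )
            else:
                params = shielding_tensor_to_params(
                    tensor, calibration=calibration, calibrate_mode=calibrate_mode
                )
        else:
            principal = vals
            if shielding_scale:
                if calibrate_mode == "per_component":
                    principal = calibration(principal)
                else:
                    sigma_iso = principal.mean()
                    principal = float(calibration(sigma_iso)) - (principal - sigma_iso)
            pas = (0.0, 0.0, 0.0)
            pas_cols = ("pas_alpha_deg", "pas_beta_deg", "pas_gamma_deg")
            if set(pas_cols).issubset(df.columns):
                pas = tuple(np.radians(float(row[c])) for c in pas_cols)
            params = haeberlen_parameters(
                principal, pas_orientation=pas, site_id=site_id,
                residue=residue,
            )
        extra = {}
        for col in ("strain_pct", "force_pN"):
            if col in df.columns:
                extra[col] = float(row[col])
        if extra:
            object.__setattr__(params, "_table_meta", extra)
        out.append(params)
    return out


def write_tensor_table(path, records, meta: dict | None = None) -> None:
    """Write ShiftTensorParams records as a principal-value tensor table."""
    rows = []
    for p in records:
        d = p.principal_shifts()
        row = {
            "site_id": p.site_id,
            "residue": p.residue,
            "s11": d[0],
            "s22": d[1],
            "s33": d[2],
            "pas_alpha_deg": np.degrees(p.pas_orientation[0]),
            "pas_beta_deg": np.degrees(p.pas_orientation[1]),
            "pas_gamma_deg": np.degrees(p.pas_orientation[2]),
        }
        tm = getattr(p, "_table_meta", None)
        if tm:
            row.update(tm)
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        items = dict(meta or {})
        items.setdefault("scale", "shift")
        fh.write("# " + " ".join(f"{k}={v}" for k, v in items.items()) + "\n")
        df.to_csv(fh, sep="\t", index=False)
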