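"""Synthetic inputs for the whole pipeline.

Generates per-strain chemical-shift tensor tables with the statistical
structure of QM/MM carbonyl output for a collagen-like (Gly-Pro-Hyp)n
triple helix, noisy slow-MAS patterns/spectra at a stated signal-to-noise
ratio, and schema-conformant fixture files — so every stage is testable
without downloading anything.

The baseline carbonyl parameters (delta_iso ~ 170 ppm, zeta ~ -75 ppm,
eta ~ 0.6) are plausible literature-scale stand-ins for peptide backbone
C' sites, NOT values from any specific quantum-chemistry run.  The strain
response is linear in molecular strain, the simplest model consistent with
the observation that strain predominantly moves Gly carbonyl isotropic
shifts while anisotropies change little.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .analysis import StrainPoint
from .sidebands import SidebandPattern, SpectrometerConfig, render_spectrum
from .tensors import ShiftTensorParams, write_tensor_table

#: force (pN) -> molecular tensile strain (%) levels of the strained
#: triple-helix trajectory the tensor tables emulate
DEFAULT_FORCE_STRAIN = (
    (0.0, 0.0),
    (10.0, 1.4),
    (50.0, 3.4),
    (100.0, 8.6),
    (250.0, 13.1),
    (500.0, 17.0),
)

#: approximate amino-acid composition of collagen type I
DEFAULT_RESIDUE_COMPOSITION = {
    "Gly": 0.33, "Pro": 0.21, "Hyp": 0.21, "Ala": 0.10, "Arg": 0.05,
    "Glu": 0.045, "Ser": 0.04, "Lys/Hyl": 0.035,
}

#: synthetic baseline carbonyl tensors (delta_iso ppm, zeta ppm, eta).
#: The Haeberlen unique axis of a peptide C' tensor lies perpendicular to
#: the sp2 peptide plane; with the plane roughly parallel to the helix
#: axis this puts beta_pas ~ 90 deg, with residue-dependent in-plane
#: angles gamma_pas.
DEFAULT_BASELINES = {
    "Gly": (169.5, -74.0, 0.60),
    "Pro": (172.0, -76.0, 0.58),
    "Hyp": (171.0, -78.0, 0.62),
}

#: default PAS -> molecular-frame ZYZ Euler angles (radians) per residue
DEFAULT_PAS_ORIENTATIONS = {
    "Gly": (0.0, np.pi / 2, 0.0),
    "Pro": (0.0, np.pi / 2, np.pi / 18),
    "Hyp": (0.0, np.pi / 2, np.pi / 9),
}

#: per-% -strain linear responses (d delta_iso, d zeta, d eta per % strain);
#: Gly delta_iso is the dominant mover by construction
DEFAULT_STRAIN_RESPONSE = {
    "Gly": (-0.20, 0.08, 0.002),
    "Pro": (-0.05, 0.10, 0.001),
    "Hyp": (0.04, -0.06, 0.001),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a per-strain tensor table."""

    strain_levels: tuple = tuple(s for _, s in DEFAULT_FORCE_STRAIN)
    forces_pN: tuple = tuple(f for f, _ in DEFAULT_FORCE_STRAIN)
    residues: tuple = ("Gly", "Pro", "Hyp")
    baseline_params: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    strain_response: dict = field(
        default_factory=lambda: dict(DEFAULT_STRAIN_RESPONSE)
    )
    pas_orientations: dict = field(
        default_factory=lambda: dict(DEFAULT_PAS_ORIENTATIONS)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.strain_levels, dtype=float)
        if np.any(s < 0) or np.any(np.diff(s) < 0):
            raise ValueError("strain levels must be non-negative and sorted")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for r in self.residues:
            if r not in self.strain_response or r not in self.baseline_params:
                raise ValueError(f"no baseline/response for residue {r!r}")


def _params_from_triplet(diso, zeta, eta, residue, site_id,
                         pas=(0.0, 0.0, 0.0),
                         strain=None, force=None) -> ShiftTensorParams:
    eta = float(np.clip(eta, 0.0, 1.0))
    principal = np.array([
        diso - zeta * (1 + eta) / 2.0,
        diso - zeta * (1 - eta) / 2.0,
        diso + zeta,
    ])
    from .tensors import haeberlen_parameters

    p = haeberlen_parameters(principal, pas_orientation=tuple(pas),
                             site_id=site_id, residue=residue)
    if strain is not None or force is not None:
        object.__setattr__(
            p, "_table_meta",
            {"strain_pct": float(strain or 0), "force_pN": float(force or 0)},
        )
    return p


def make_strain_tensor_table(spec: SyntheticSpec) -> list[StrainPoint]:
    """Per-residue tensors at each strain level: baseline + linear response
    + seeded Gaussian noise on (delta_iso, zeta)."""
    rng = np.random.default_rng(spec.seed)
    points = []
    forces = list(spec.forces_pN) + [0.0] * max(
        0, len(spec.strain_levels) - len(spec.forces_pN)
    )
    for strain, force in zip(spec.strain_levels, forces):
        tensors = []
        for res in spec.residues:
            d0, z0, e0 = spec.baseline_params[res]
            dd, dz, de = spec.strain_response[res]
            noise = rng.normal(0.0, spec.noise_sd, 2) if spec.noise_sd > 0 else (0, 0)
            tensors.append(_params_from_triplet(
                d0 + dd * strain + noise[0],
                z0 + dz * strain + noise[1],
                e0 + de * strain,
                res, f"{res}_C_{strain:g}pct",
                pas=spec.pas_orientations.get(res, (0.0, 0.0, 0.0)),
                strain=strain, force=force,
            ))
        points.append(StrainPoint(force_pN=force, strain_pct=strain,
                                  tensors=tensors))
    return points


def strain_points_to_records(points) -> list[ShiftTensorParams]:
    return [t for sp in points for t in sp.tensors]


def make_noisy_pattern(pattern: SidebandPattern, snr: float,
                       seed: int = 0) -> SidebandPattern:
    """Additive white noise on sideband intensities, sd = max(I)/snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    sd = float(pattern.intensities.max()) / snr
    noisy = pattern.intensities + rng.normal(0.0, sd, pattern.intensities.shape)
    return SidebandPattern(
        indices=pattern.indices, intensities=noisy,
        delta_iso=pattern.delta_iso, config=pattern.config,
    )


def make_noisy_spectrum(
    pattern: SidebandPattern,
    axis_ppm: np.ndarray,
    snr: float,
    linewidth_ppm: float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Rendered spectrum plus seeded white noise, sd = max(signal)/snr.

    ``snr = inf`` returns the noiseless render.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = render_spectrum(pattern, axis_ppm, linewidth_ppm=linewidth_ppm)
    if not np.isfinite(snr):
        return clean
    rng = np.random.default_rng(seed)
    sd = float(clean.max()) / snr
    return clean + rng.normal(0.0, sd, clean.shape)


def make_fixture_files(out_dir, seed: int = 0) -> dict:
    """Write one schema-conformant example of every file the readers accept.

    Returns a dict of file paths: a per-strain tensor table, an orientation
    grid, a sideband pattern and a rendered spectrum.
    """
    from .orientations import (
        DistributionSpec, sample_ellipsoid_projected, write_orientation_set,
    )
    from .sidebands import ensemble_pattern, write_pattern

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    spec = SyntheticSpec(seed=seed)
    points = make_strain_tensor_table(spec)
    paths["tensor_table"] = os.path.join(out_dir, "strain_tensors.tsv")
    write_tensor_table(paths["tensor_table"], strain_points_to_records(points),
                       meta={"seed": seed})

    oset = sample_ellipsoid_projected(
        DistributionSpec(n_points=800, c_over_a=10.0, seed=seed)
    )
    paths["grid"] = os.path.join(out_dir, "grid.tsv")
    write_orientation_set(paths["grid"], oset)

    config = SpectrometerConfig()
    pattern = ensemble_pattern(points[0].tensors, oset, config)
    paths["pattern"] = os.path.join(out_dir, "pattern.tsv")
    write_pattern(paths["pattern"], pattern)

    span = (config.n_sidebands_max + 1) * config.sideband_spacing_ppm
    axis = np.linspace(pattern.delta_iso - span, pattern.delta_iso + span, 2048)
    spec_y = make_noisy_spectrum(pattern, axis, snr=50.0, seed=seed)
    paths["spectrum"] = os.path.join(out_dir, "spectrum.tsv")
    np.savetxt(
        paths["spectrum"], np.column_stack([axis, spec_y]), delimiter="\t",
        header="ppm\tintensity", comments="",
    )
    return paths
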