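"""Molecular orientation distributions for uniform and partially aligned samples.

A partially aligned sample (e.g. collagen fibrils packed along the rotor
axis) is modeled by distributing points uniformly by surface area on a
prolate spheroid with axes ``(a, a, c)`` — the long axis ``c`` along the
rotor axis — and projecting each point radially onto the unit sphere.  The
ratio ``c/a`` sets the degree of alignment: ``c/a = 1`` is the uniform
(powder) distribution, ``c/a >> 1`` concentrates directions near the rotor
axis.  Each projected direction is converted to ZYZ Euler angles
``(alpha, beta, gamma)`` relating the molecular frame to the rotor frame.

All angles are stored in radians; grid files use degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# ZYZ Euler-angle helpers (active rotations: v_new = R @ v_old)
# ---------------------------------------------------------------------------

def euler_zyz_to_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active rotation matrix R = Rz(alpha) @ Ry(beta) @ Rz(gamma)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    return np.array([
        [ca * cb * cg - sa * sg, -ca * cb * sg - sa * cg, ca * sb],
        [sa * cb * cg + ca * sg, -sa * cb * sg + ca * cg, sa * sb],
        [-sb * cg, sb * sg, cb],
    ])


def euler_zyz_to_matrices(alpha, beta, gamma) -> np.ndarray:
    """Vectorized :func:`euler_zyz_to_matrix`: inputs broadcast, output
    shape (..., 3, 3)."""
    alpha, beta, gamma = np.broadcast_arrays(
        np.asarray(alpha, float), np.asarray(beta, float),
        np.asarray(gamma, float),
    )
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    R = np.empty(alpha.shape + (3, 3))
    R[..., 0, 0] = ca * cb * cg - sa * sg
    R[..., 0, 1] = -ca * cb * sg - sa * cg
    R[..., 0, 2] = ca * sb
    R[..., 1, 0] = sa * cb * cg + ca * sg
    R[..., 1, 1] = -sa * cb * sg + ca * cg
    R[..., 1, 2] = sa * sb
    R[..., 2, 0] = -sb * cg
    R[..., 2, 1] = sb * sg
    R[..., 2, 2] = cb
    return R


def rotation_matrix_to_euler_zyz(R: np.ndarray) -> tuple:
    """Inverse of :func:`euler_zyz_to_matrix` (beta in [0, pi])."""
    beta = float(np.arccos(np.clip(R[2, 2], -1.0, 1.0)))
    if abs(np.sin(beta)) < 1e-12:
        # gimbal-degenerate: only alpha + gamma (beta=0) or alpha - gamma
        # (beta=pi) is determined; put it all in alpha
        alpha = float(np.arctan2(R[1, 0], R[0, 0]))
        if R[2, 2] < 0:
            alpha = -alpha
        gamma = 0.0
    else:
        alpha = float(np.arctan2(R[1, 2], R[0, 2]))
        gamma = float(np.arctan2(R[2, 1], -R[2, 0]))
    return (alpha % (2 * np.pi), beta, gamma % (2 * np.pi))


def vector_to_euler_zyz(v) -> tuple:
    """Euler angles (alpha, beta, 0) such that Rzyz(alpha, beta, 0) @ z = v.

    ``beta = arccos(v_z)``, ``alpha = atan2(v_y, v_x)`` mapped to [0, 2pi);
    at the poles alpha is arbitrary and returned as 0.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("zero vector has no direction")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"vector must be unit length, |v| = {norm}")
    v = v / norm
    beta = float(np.arccos(np.clip(v[2], -1.0, 1.0)))
    if abs(v[0]) < 1e-15 and abs(v[1]) < 1e-15:
        alpha = 0.0
    else:
        alpha = float(np.arctan2(v[1], v[0])) % (2 * np.pi)
    return (alpha, beta, 0.0)


# ---------------------------------------------------------------------------
# Distribution spec and orientation sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """Parameters of an ellipsoid-projection orientation distribution.

    ``c_over_a >= 1`` (prolate; the long axis lies along the rotor axis).
    The default grid size of 800 points matches the custom alignment grid
    used for the tendon simulations; the default aspect ratio 10 corresponds
    to ellipsoid axes (10, 1, 1).
    """

    n_points: int = 800
    c_over_a: float = 10.0
    seed: int = 0
    quasi_uniform: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.c_over_a < 1:
            raise ValueError("c_over_a must be >= 1 (oblate not modeled)")


@dataclass(frozen=True)
class OrientationSet:
    """Weighted list of ZYZ Euler angles (molecule -> rotor frame)."""

    angles: np.ndarray  # (n, 3) radians
    weights: np.ndarray  # (n,), non-negative, sums to 1
    spec: DistributionSpec | None = None

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.angles, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if a.shape[1] != 3 or a.shape[0] != w.shape[0]:
            raise ValueError("angles must be (n, 3) with matching weights")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.angles.shape[0]

    @property
    def beta(self) -> np.ndarray:
        return self.angles[:, 1]

    def directions(self) -> np.ndarray:
        """Unit vectors of the molecular long axis in the rotor frame."""
        al, be = self.angles[:, 0], self.angles[:, 1]
        return np.column_stack(
            [np.cos(al) * np.sin(be), np.sin(al) * np.sin(be), np.cos(be)]
        )


def _directions_to_set(dirs: np.ndarray, gamma: np.ndarray,
                       spec: DistributionSpec) -> OrientationSet:
    alpha = np.arctan2(dirs[:, 1], dirs[:, 0]) % (2 * np.pi)
    beta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    angles = np.column_stack([alpha, beta, gamma])
    n = dirs.shape[0]
    return OrientationSet(angles=angles, weights=np.full(n, 1.0 / n), spec=spec)


def sample_uniform_sphere(spec: DistributionSpec) -> OrientationSet:
    """Orientation set for a non-aligned sample: directions uniform on S^2."""
    rng = np.random.default_rng(spec.seed)
    z = rng.uniform(-1.0, 1.0, spec.n_points)
    phi = rng.uniform(0.0, 2 * np.pi, spec.n_points)
    s = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    gamma = rng.uniform(0.0, 2 * np.pi, spec.n_points)
    return _directions_to_set(dirs, gamma, spec)


def sample_ellipsoid_projected(spec: DistributionSpec) -> OrientationSet:
    """Orientation set for a partially aligned sample.

    Points are sampled uniformly with respect to surface area on the prolate
    spheroid ``(a, a, c)`` by rejection against the spheroid area element,
    then projected radially onto the unit sphere.  The third angle gamma
    (rotation about the molecular long axis) is drawn uniformly; sideband
    results are insensitive to it because rotor-phase averaging is exact.

    With ``quasi_uniform=True`` the polar coordinate is stratified (one point
    per equal-probability bin, jittered) for low-variance sweeps.
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.c_over_a  # work in units of a = 1
    n = spec.n_points

    if spec.c_over_a == 1.0 and not spec.quasi_uniform:
        return sample_uniform_sphere(spec)

    # Surface-area density over the spheroid polar angle theta
    # (point (sin t cos p, sin t sin p, (c/a) cos t) before projection):
    #   dA ∝ sin t * sqrt(cos^2 t + (c/a)^2 sin^2 t) dt dp
    def accept_prob(cos_t):
        sin2 = 1.0 - cos_t**2
        return np.sqrt(cos_t**2 + c**2 * sin2) / c  # max value 1 at equator

    if spec.quasi_uniform:
        # invert the CDF of the theta density on a stratified uniform grid
        grid = np.linspace(-1.0, 1.0, 200001)
        dens = np.sqrt(grid**2 + c**2 * (1.0 - grid**2))
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2)])
        cdf /= cdf[-1]
        u = (np.arange(n) + rng.uniform(0, 1, n)) / n
        cos_t = np.interp(u, cdf, grid)
    else:
        cos_t = np.empty(0)
        while cos_t.size < n:
            need = max(n - cos_t.size, 16)
            cand = rng.uniform(-1.0, 1.0, 2 * need)
            keep = rng.uniform(0.0, 1.0, cand.size) < accept_prob(cand)
            cos_t = np.concatenate([cos_t, cand[keep]])
        cos_t = cos_t[:n]

    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    # spheroid point, radially normalized (the projection onto the sphere)
    xyz = np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), c * cos_t]
    )
    dirs = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
    gamma = rng.uniform(0.0, 2 * np.pi, n)
    return _directions_to_set(dirs, gamma, spec)


def order_parameter(oset: OrientationSet) -> float:
    """Weighted mean of P2(cos beta) = (3 cos^2 beta - 1)/2.

    0 for a uniform distribution, 1 for perfect alignment with the rotor
    axis, -0.5 for directions confined to the rotor equator.
    """
    if len(oset) == 0:
        raise ValueError("empty orientation set")
    cb = np.cos(oset.beta)
    return float(np.sum(oset.weights * (3.0 * cb**2 - 1.0) / 2.0))


def order_parameter_quadrature(c_over_a: float, n_nodes: int = 2000) -> float:
    """Analytic-quadrature <P2> of the projected spheroid distribution.

    Integrates P2 of the projected direction against the spheroid
    surface-area element; the independent oracle for the sampled
    distribution.
    """
    if c_over_a < 1:
        raise ValueError("c_over_a must be >= 1")
    x, w = np.polynomial.legendre.leggauss(n_nodes)  # cos(theta) in [-1, 1]
    c = c_over_a
    sin2 = 1.0 - x**2
    dens = np.sqrt(x**2 + c**2 * sin2)
    uz = c * x / np.sqrt(sin2 + c**2 * x**2)
    p2 = (3.0 * uz**2 - 1.0) / 2.0
    return float(np.sum(w * dens * p2) / np.sum(w * dens))


# ---------------------------------------------------------------------------
# Grid file IO: columns (alpha_deg, beta_deg, gamma_deg, weight)
# ---------------------------------------------------------------------------

def write_orientation_set(path, oset: OrientationSet) -> None:
    df = pd.DataFrame({
        "alpha_deg": np.degrees(oset.angles[:, 0]),
        "beta_deg": np.degrees(oset.angles[:, 1]),
        "gamma_deg": np.degrees(oset.angles[:, 2]),
        "weight": oset.weights,
    })
    with open(path, "w", encoding="utf-8") as fh:
        if oset.spec is not None:
            fh.write(
                f"# n={oset.spec.n_points} c_over_a={oset.spec.c_over_a} "
                f"seed={oset.spec.seed}\n"
            )
        df.to_csv(fh, sep="\t", index=False)


def read_orientation_set(path) -> OrientationSet:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        elif line.strip():
            body.append(line)
    import io as _io
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t")
    angles = np.radians(df[["alpha_deg", "beta_deg", "gamma_deg"]].to_numpy())
    weights = df["weight"].to_numpy(dtype=float)
    weights = weights / weights.sum()
    spec = None
    if {"n", "c_over_a", "seed"} <= meta.keys():
        spec = DistributionSpec(
            n_points=int(meta["n"]), c_over_a=float(meta["c_over_a"]),
            seed=int(meta["seed"]),
        )
    return OrientationSet(angles=angles, weights=weights, spec=spec)
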