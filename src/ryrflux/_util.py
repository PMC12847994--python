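"""Shared numerical helpers: rotations, truncated counting laws, rounding."""

from __future__ import annotations

import decimal

import numpy as np
from scipy import optimize, stats


def rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def pose_matrix(azimuth_deg: float, tilt_deg: float, spin_deg: float) -> np.ndarray:
    """Rotation taking the canonical (axis = +z) frame into the world frame.

    Extrinsic z-y-z convention: spin about the structure's own axis, tilt away
    from +z, then azimuthal placement of the tilt direction.
    """
    return rot_z(azimuth_deg) @ rot_y(tilt_deg) @ rot_z(spin_deg)


def axis_from_angles(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit symmetry-axis vector with polar angle ``tilt`` and azimuth ``azimuth``."""
    t, a = np.deg2rad(tilt_deg), np.deg2rad(azimuth_deg)
    return np.array([np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t)])


def rotation_angle_deg(r: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix in degrees."""
    c = (np.trace(r) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition q -> p (proper rotation only).

    Returns (R, t, rmsd) such that p ~= q @ R.T + t.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = qc.T @ pc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = p.mean(axis=0) - r @ q.mean(axis=0)
    resid = pc - qc @ r.T
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return r, t, rmsd


def zt_poisson_lambda(conditional_mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given conditional mean (>= 1)."""
    m = float(conditional_mean)
    if m < 1.0:
        raise ValueError(f"conditional mean of a zero-truncated count must be >= 1, got {m}")
    if m == 1.0:
        return 0.0
    # E[X | X >= 1] = lam / (1 - exp(-lam)) is increasing in lam
    return float(optimize.brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - m, 1e-12, 50.0))


def sample_zt_poisson(rng: np.random.Generator, conditional_mean: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws with conditional mean >= 1 (inverse CDF)."""
    if size == 0:
        return np.zeros(0, dtype=int)
    lam = zt_poisson_lambda(conditional_mean)
    if lam == 0.0:
        return np.ones(size, dtype=int)
    kmax = max(20, int(lam + 12 * np.sqrt(lam) + 12))
    ks = np.arange(1, kmax + 1)
    cdf = (stats.poisson.cdf(ks, lam) - np.exp(-lam)) / (1.0 - np.exp(-lam))
    cdf[-1] = 1.0
    u = rng.random(size)
    return ks[np.searchsorted(cdf, u, side="left")]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Report-time rounding: half away from zero (so 4.125 -> 4.1 stays, 8.15 -> 8.2)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG derived from a base seed and an integer key path."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key)))
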