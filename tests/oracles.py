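"""Independent oracles used only by the tests.

Each oracle deliberately takes a different route from the library code it
checks: quaternion (Horn) superposition vs SVD Kabsch, exhaustive double
loops vs vectorized distance matrices, Monte-Carlo rejection sampling and
analytic sphere-cap formulas vs the deterministic point lattice.
"""

from __future__ import annotations

import numpy as np


def brute_force_min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Exhaustive double loop over all atom pairs."""
    best = np.inf
    for p in coords_a:
        for q in coords_b:
            d = float(np.sqrt(((p - q) ** 2).sum()))
            if d < best:
                best = d
    return best


def quaternion_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Horn's closed-form quaternion superposition of P onto Q.

    Returns (R, t, rmsd) with Q ≈ P @ R.T + t, proper rotation.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    S = Pc.T @ Qc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(K)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = cq - R @ cp
    rmsd = float(np.sqrt(((Q - (P @ R.T + t)) ** 2).sum() / len(P)))
    return R, t, rmsd


def monte_carlo_sasa(
    positions: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-atom SASA by rejection sampling of random sphere points."""
    positions = np.asarray(positions, float)
    expanded = np.asarray(radii, float) + probe
    areas = np.empty(len(positions))
    for i in range(len(positions)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = positions[i] + expanded[i] * v
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(positions)):
            if j == i:
                continue
            d2 = ((pts - positions[j]) ** 2).sum(axis=1)
            exposed &= d2 >= expanded[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def two_sphere_cap_sasa(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Analytic accessible areas of two intersecting expanded spheres.

    For centers a distance d apart (|r1 − r2| < d < r1 + r2), each sphere
    loses the spherical cap cut off by the radical plane: cap height on
    sphere 1 is h1 = r1 − (d² + r1² − r2²) / (2d), lost area 2π r1 h1.
    """
    h1 = r1 - (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    h2 = r2 - (d * d + r2 * r2 - r1 * r1) / (2.0 * d)
    a1 = 4.0 * np.pi * r1 * r1 - 2.0 * np.pi * r1 * h1
    a2 = 4.0 * np.pi * r2 * r2 - 2.0 * np.pi * r2 * h2
    return a1, a2


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def axis_angle(axis: np.ndarray, degrees: float) -> np.ndarray:
    """Rodrigues rotation matrix from axis and angle."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(degrees)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
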