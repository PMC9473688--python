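"""Pairwise porphyrin geometry.

The central statistic is the rotation angle θ between two porphyrin rings:
superpose ring A onto ring B by name-matched least-squares (Kabsch), take
the proper rotation R of that superposition, and set

    θ = arccos((tr(R) − 1) / 2),   θ ∈ [0°, 180°].

θ = 0° means the two rings are perfectly parallel (same in-plane
orientation), θ = 180° perfectly antiparallel (flipped).  Because the four
pyrrole rings A–D are chemically distinct, name-matched correspondence
breaks the 4-fold pseudo-symmetry of the porphyrin and θ is well defined.

Edge-to-edge (minimum ring) distance is the smallest of the 25 × 25
atom–atom distances between the two canonical cores, regardless of atom
type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import PorphyrinRing

MOTIFS = ("parallel", "T_shaped", "antiparallel", "intermediate")


@dataclass
class SuperpositionResult:
    """Rigid superposition of one coordinate set onto another."""

    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float  # Å
    n_pairs_used: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class HemePair:
    """A contact pair of porphyrin rings with its geometry."""

    ring_a: PorphyrinRing
    ring_b: PorphyrinRing
    min_distance: float  # Å
    rotation: np.ndarray  # (3, 3), maps ring_a coords toward ring_b
    translation: np.ndarray
    theta: float  # degrees in [0, 180]
    plane_angle: float  # degrees in [0, 180], between ring normals
    motif: str


def min_ring_distance(a: PorphyrinRing, b: PorphyrinRing) -> float:
    """Minimum atom–atom distance between two porphyrin cores, in Å."""
    if a.heme_id == b.heme_id:
        raise ValueError(f"self-pair {a.heme_id} is meaningless")
    return float(cdist(a.ring_coords, b.ring_coords).min())


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation R and translation t with Q ≈ P·Rᵀ + t."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) point set: rotation is not determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    residuals = Q - (P @ R.T + t)
    rmsd = float(np.sqrt((residuals**2).sum() / len(P)))
    return R, t, rmsd


def superpose_rings(a: PorphyrinRing, b: PorphyrinRing) -> SuperpositionResult:
    """Superpose ring a onto ring b by canonical-name correspondence.

    Proper rotation only (no reflection).  Returns the rotation R, the
    translation t and the post-fit RMSD over all 25 atom pairs.
    """
    R, t, rmsd = _kabsch(a.ring_coords, b.ring_coords)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs_used=25)


def rotation_angle(R: np.ndarray, *, tol: float = 1e-6) -> float:
    """Angle θ (degrees, in [0, 180]) of a proper rotation matrix.

    θ = arccos(clamp((tr(R) − 1)/2, −1, 1)).  Evaluated as
    atan2(‖R − Rᵀ‖_F / (2√2), (tr(R) − 1)/2) — identical on [0°, 180°]
    but numerically stable where arccos loses precision near 0° and 180°.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("R must be 3x3")
    if not np.allclose(R @ R.T, np.eye(3), atol=tol) or not np.isclose(
        np.linalg.det(R), 1.0, atol=tol
    ):
        raise ValueError("R is not a proper rotation (orthonormal, det +1)")
    c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    s = np.linalg.norm(R - R.T) / (2.0 * np.sqrt(2.0))  # = sin θ for a rotation
    return float(np.degrees(np.arctan2(s, c)))


def plane_angle(a: PorphyrinRing, b: PorphyrinRing) -> float:
    """Angle between the two ring-plane normals, degrees in [0, 180]."""
    c = np.clip(np.dot(a.plane_normal, b.plane_normal), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def classify_motif(theta: float, plane_angle_deg: float | None = None) -> str:
    """Discretize a pair's orientation into a packing motif.

    parallel for θ < 40°, antiparallel for θ > 140°, T-shaped when the
    inter-plane angle lies in [60°, 120°], otherwise intermediate.  When no
    plane angle is supplied θ itself is used for the T-shaped window (exact
    for rotations about an in-plane axis).
    """
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta {theta} outside [0, 180]")
    if theta < 40.0:
        return "parallel"
    if theta > 140.0:
        return "antiparallel"
    pa = theta if plane_angle_deg is None else plane_angle_deg
    if 60.0 <= pa <= 120.0:
        return "T_shaped"
    return "intermediate"


def make_pair_geometry(a: PorphyrinRing, b: PorphyrinRing) -> HemePair:
    """Populate the full geometry record for one ring pair."""
    sup = superpose_rings(a, b)
    theta = rotation_angle(sup.rotation)
    pa = plane_angle(a, b)
    return HemePair(
        ring_a=a,
        ring_b=b,
        min_distance=min_ring_distance(a, b),
        rotation=sup.rotation,
        translation=sup.translation,
        theta=theta,
        plane_angle=pa,
        motif=classify_motif(theta, pa),
    )


def contact_pairs(rings: list[PorphyrinRing], cutoff: float = 6.0) -> list[HemePair]:
    """All unordered ring pairs with minimum distance ≤ ``cutoff`` Å.

    Pairs are ordered by (chain, residue_seq) of both members so output is
    deterministic.
    """
    ordered = sorted(rings, key=lambda r: (r.heme_id[0], r.heme_id[1]))
    pairs: list[HemePair] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if min_ring_distance(a, b) <= cutoff:
                pairs.append(make_pair_geometry(a, b))
    return pairs


def pruned_superposition(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    prune_factor: float = 2.0,
    min_pairs: int = 4,
) -> SuperpositionResult:
    """Best-subset rigid superposition by iterative outlier pruning.

    Superpose, drop correspondences whose residual exceeds
    ``prune_factor × rmsd``, re-superpose; stop when no pair is dropped or
    fewer than ``min_pairs`` would remain.  Reports the final rmsd and the
    number of surviving pairs.  Used for whole-model comparisons where only
    a conserved core aligns well.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matching N x 3 arrays")
    if len(A) < min_pairs:
        raise ValueError(f"need at least {min_pairs} correspondences, got {len(A)}")

    keep = np.arange(len(A))
    while True:
        R, t, rmsd = _kabsch(A[keep], B[keep])
        residuals = np.linalg.norm(B[keep] - (A[keep] @ R.T + t), axis=1)
        # an essentially exact fit has nothing left to prune
        mask = residuals <= max(prune_factor * rmsd, 1e-8)
        if mask.all() or mask.sum() < min_pairs:
            return SuperpositionResult(
                rotation=R, translation=t, rmsd=rmsd, n_pairs_used=len(keep)
            )
        keep = keep[mask]
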