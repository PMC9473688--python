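"""Synthetic multiheme structures with exact, recorded ground truth.

Everything downstream — pair geometry, chain topology, helical expansion,
the survey pipeline — is validated against structures built here, whose
designed parameters (rotation angle, minimum ring distance, chain/branch
topology, rise/twist) are exact by construction and attached to each
Structure's ``metadata``.

The idealized porphyrin is a planar, 4-fold-symmetrized 25-atom core: Fe
at the origin, pyrrole nitrogens 2.00 Å along ±x/±y, pyrrole carbons and
methine bridges at idealized in-plane positions with chemically sensible
1.35–1.44 Å bonds.  Synthetic hemes carry only the 25 ring atoms — no
vinyl or propionate substituents — which is sufficient for every geometry
module; SASA fixtures with analytic answers are built directly from small
atom clusters in the tests instead.

Default dimensions follow the filament architecture the package targets:
eight hemes per subunit, seven of them in a closely packed chain at 4.0 Å
edge-to-edge spacing with alternating parallel/antiparallel orientations,
one pendant branch heme at 4.6 Å from chain heme 5, a 4.5 Å antiparallel
inter-subunit contact, and a left-handed twist of −158.2° per subunit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .helical_model import HelicalParams, expand_filament
from .porphyrin_geometry import min_ring_distance
from .structure_io import PorphyrinRing, Structure, rings_to_structure

#: Half-extent of the idealized ring along a pyrrole direction (max |x|).
_RING_HALF_SPAN = 4.19
DEFAULT_SEED = 20220905


def _ideal_ring_coords() -> np.ndarray:
    """Canonical-order coordinates of the idealized planar porphyrin."""
    # pyrrole A in its local (+x) frame: N, C1 (alpha), C2, C3 (beta), C4 (alpha)
    n = np.array([2.00, 0.00])
    c1 = np.array([2.81, -1.13])
    c2 = np.array([4.19, -0.71])
    c3 = np.array([4.19, 0.71])
    c4 = np.array([2.81, 1.13])

    def rot(p: np.ndarray, quarter_turns: int) -> np.ndarray:
        t = quarter_turns * math.pi / 2.0
        c, s = math.cos(t), math.sin(t)
        return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1]])

    coords = [np.zeros(2)]  # FE
    coords += [rot(n, k) for k in range(4)]  # NA NB NC ND
    for k in range(4):  # C1A..C4A, C1B..C4B, C1C..C4C, C1D..C4D
        coords += [rot(c, k) for c in (c1, c2, c3, c4)]
    ch = np.array([2.42, -2.42])  # CHA bridges pyrroles D and A
    coords += [rot(ch, k) for k in range(4)]  # CHA CHB CHC CHD
    xy = np.array(coords)
    return np.column_stack([xy, np.zeros(len(xy))])


def ideal_porphyrin(
    heme_id: tuple[str, int, str] = ("A", 1, "HEC")
) -> PorphyrinRing:
    """An idealized planar porphyrin ring in the z = 0 plane, Fe at origin."""
    return PorphyrinRing(heme_id=heme_id, ring_coords=_ideal_ring_coords())


def _axis_angle_matrix(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / norm
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


@dataclass
class PairSpec:
    """Design of a two-heme fixture: rotation angle plus placement offsets.

    When ``target_min_distance`` is set, the normal offset is solved by
    root finding so the achieved minimum ring distance equals the target.
    """

    theta: float = 0.0  # degrees in [0, 180]
    rotation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    normal_offset: float = 4.0  # Å along +z
    lateral_offset: float = 0.0  # Å along +x
    target_min_distance: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError(f"theta {self.theta} outside [0, 180]")
        if self.normal_offset < 0 or self.lateral_offset < 0:
            raise ValueError("offsets must be non-negative")


def make_pair(spec: PairSpec) -> Structure:
    """Two hemes: an ideal ring and a rotated, translated copy.

    Ring B is the ideal ring rotated by ``theta`` about ``rotation_axis``
    (through the Fe), then translated ``normal_offset``·ẑ +
    ``lateral_offset``·x̂.  Ground truth (theta, achieved minimum distance)
    is recorded in ``Structure.metadata['truth']``.
    """
    ring_a = ideal_porphyrin(("A", 1, "HEC"))
    R = _axis_angle_matrix(np.array(spec.rotation_axis), spec.theta)
    base = ring_a.ring_coords @ R.T

    def placed(dz: float) -> PorphyrinRing:
        return PorphyrinRing(
            heme_id=("A", 2, "HEC"),
            ring_coords=base + np.array([spec.lateral_offset, 0.0, dz]),
        )

    if spec.target_min_distance is None:
        dz = spec.normal_offset
    else:
        target = spec.target_min_distance
        if target <= 0:
            raise ValueError("target_min_distance must be positive")
        hi = target + 2.0 * _RING_HALF_SPAN + 2.0

        def gap(d: float) -> float:
            return min_ring_distance(ring_a, placed(d)) - target

        if gap(0.0) > 0.0:
            # already farther apart than the target at zero normal offset
            # (large lateral offset): solve laterally instead
            raise ValueError(
                "target_min_distance unsatisfiable along the normal; "
                "reduce lateral_offset"
            )
        dz = brentq(gap, 0.0, hi, xtol=1e-12, rtol=8.9e-16)

    ring_b = placed(dz)
    structure = rings_to_structure([ring_a, ring_b], identifier="synthetic_pair")
    structure.metadata["truth"] = {
        "theta": spec.theta,
        "rotation_axis": list(np.asarray(spec.rotation_axis, dtype=float)),
        "min_distance": min_ring_distance(ring_a, ring_b),
        "normal_offset": float(dz),
        "lateral_offset": spec.lateral_offset,
    }
    return structure


@dataclass
class FilamentSpec:
    """Design of a toy multiheme filament under exact screw symmetry.

    ``hemes_per_subunit`` counts every heme of the asymmetric unit,
    pendants included; the chain therefore holds
    ``hemes_per_subunit − len(branch_positions)`` rings.  One subunit is a
    stack of chain rings along z at ``chain_spacing`` Å (ring planes
    perpendicular to the axis, orientation alternating 0°/180° about x so
    consecutive pairs are antiparallel), plus pendant branch rings attached
    in-plane at given 0-based chain positions and edge-to-edge gaps.  The
    default emulates an octaheme filament subunit: seven chain hemes plus
    one pendant at 4.6 Å from chain heme 5.

    The helical rise is derived so the terminal hemes of adjacent subunits
    meet at ``interface_pair_distance``; pass ``rise`` explicitly to
    override (the chain spacing is then re-derived, and may break chain
    contact if the result exceeds the contact cutoff).
    """

    n_subunits: int = 3
    hemes_per_subunit: int = 8  # total per subunit, pendants included
    chain_spacing: float = 4.0  # Å edge-to-edge between consecutive rings
    interface_pair_distance: float = 4.5  # Å across the subunit interface
    twist: float = -158.2  # degrees per subunit
    rise: float | None = None  # Å per subunit; derived when None
    branch_positions: tuple[tuple[int, float], ...] = ((4, 4.6),)  # (chain index, gap Å)
    orientation_pattern: tuple[float, ...] = (0.0, 180.0)  # deg about x, cycled

    def __post_init__(self) -> None:
        if self.n_subunits < 1 or self.n_chain_hemes < 1:
            raise ValueError(
                "need at least one subunit and one chain heme "
                "(hemes_per_subunit counts pendants too; adjust branch_positions)"
            )
        if self.chain_spacing <= 0 or self.interface_pair_distance <= 0:
            raise ValueError("spacings must be positive")
        for pos, gap in self.branch_positions:
            if not 0 <= pos < self.n_chain_hemes:
                raise ValueError(f"branch position {pos} outside the {self.n_chain_hemes}-heme chain")
            if gap <= 0:
                raise ValueError("branch gap must be positive")

    @property
    def n_chain_hemes(self) -> int:
        return self.hemes_per_subunit - len(self.branch_positions)

    @property
    def derived_rise(self) -> float:
        if self.rise is not None:
            return self.rise
        return (self.n_chain_hemes - 1) * self.chain_spacing + self.interface_pair_distance

    @property
    def derived_spacing(self) -> float:
        if self.rise is None or self.n_chain_hemes == 1:
            return self.chain_spacing
        return (self.rise - self.interface_pair_distance) / (self.n_chain_hemes - 1)


def make_subunit(spec: FilamentSpec, chain_id: str = "A") -> Structure:
    """One asymmetric unit of the toy filament, chain stacked along z."""
    s = spec.derived_spacing
    rings: list[PorphyrinRing] = []
    seq = 0
    for i in range(spec.n_chain_hemes):
        seq += 1
        flip = spec.orientation_pattern[i % len(spec.orientation_pattern)]
        R = _axis_angle_matrix(np.array([1.0, 0.0, 0.0]), flip)
        coords = _ideal_ring_coords() @ R.T + np.array([0.0, 0.0, i * s])
        rings.append(PorphyrinRing((chain_id, seq, "HEC"), coords))
    branch_ids = []
    for pos, gap in spec.branch_positions:
        seq += 1
        offset = gap + 2.0 * _RING_HALF_SPAN  # in-plane placement is exact
        coords = _ideal_ring_coords() + np.array([offset, 0.0, pos * s])
        rings.append(PorphyrinRing((chain_id, seq, "HEC"), coords))
        branch_ids.append({"branch_seq": seq, "attachment_seq": pos + 1, "gap": gap})

    structure = rings_to_structure(rings, identifier="synthetic_subunit")
    structure.metadata["truth"] = {
        "hemes_per_subunit": spec.hemes_per_subunit,
        "chain_hemes_per_subunit": spec.n_chain_hemes,
        "chain_spacing": s,
        "branches": branch_ids,
    }
    return structure


def make_filament(spec: FilamentSpec) -> Structure:
    """Toy filament: the subunit replicated by the rise/twist screw.

    The designed inter-subunit contact is exact: consecutive chain rings
    and the interface pair are related by pure translations along the ring
    normal, so the achieved minimum ring distances equal ``chain_spacing``
    and ``interface_pair_distance`` by construction.  Ground truth (chain
    path length, branch list, rise, twist) is attached as metadata.
    """
    subunit = make_subunit(spec)
    params = HelicalParams(rise=spec.derived_rise, twist=spec.twist)
    filament = expand_filament(subunit, params, spec.n_subunits)

    pos = filament.coords()
    if len(pos) > 1:
        from scipy.spatial import cKDTree

        if len(cKDTree(pos).query_pairs(1.0)) > 0:
            raise ValueError("designed filament has atom collisions closer than 1 Å")

    m = spec.n_chain_hemes
    filament.metadata["truth"] = {
        **subunit.metadata["truth"],
        "n_subunits": spec.n_subunits,
        "rise": params.rise,
        "twist": params.twist,
        "interface_pair_distance": spec.interface_pair_distance,
        "main_chain_length": m * spec.n_subunits,
        "n_branches": len(spec.branch_positions) * spec.n_subunits,
    }
    filament.identifier = "synthetic_filament"
    return filament


def write_truth_json(structure: Structure, path: str | Path) -> None:
    """Ground-truth sidecar for a generated structure."""
    Path(path).write_text(json.dumps(structure.metadata.get("truth", {}), indent=2) + "\n")
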