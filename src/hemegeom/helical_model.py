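"""Helical-symmetry arithmetic for filaments.

A helical polymer with rise Δz (Å per subunit) and twist Δφ (degrees per
subunit, signed by hand) relates subunit i+1 to subunit i by a screw
operation about the z axis.  The 1-start helical pitch is

    pitch = rise × 360 / |twist|,

and a filament's averaged power spectrum shows a meridional layer line at
1/rise and a near-equatorial layer line at 1/pitch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, Structure

CLASH_DISTANCE = 1.0  # Å


@dataclass(frozen=True)
class HelicalParams:
    """Rise (Å/subunit) and signed twist (deg/subunit) about the z axis."""

    rise: float
    twist: float

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise ValueError(f"rise must be positive, got {self.rise}")
        if not 0 < abs(self.twist) <= 180:
            raise ValueError(f"|twist| must be in (0, 180], got {self.twist}")


@dataclass(frozen=True)
class LayerLinePrediction:
    """Predicted layer-line positions in reciprocal Å."""

    meridional_position: float  # 1/Å, = 1/rise
    one_start_position: float  # 1/Å, = 1/pitch
    pitch: float  # Å


def pitch(params: HelicalParams) -> float:
    """1-start helical pitch in Å: rise × 360 / |twist|."""
    return params.rise * 360.0 / abs(params.twist)


def layer_lines(params: HelicalParams) -> LayerLinePrediction:
    """Meridional (1/rise) and 1-start (1/pitch) layer-line positions."""
    p = pitch(params)
    return LayerLinePrediction(
        meridional_position=1.0 / params.rise,
        one_start_position=1.0 / p,
        pitch=p,
    )


def _rz(degrees: float) -> np.ndarray:
    t = np.radians(degrees)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def expand_filament(
    asym_unit: Structure,
    params: HelicalParams,
    n_copies: int,
    center_index: int = 0,
) -> Structure:
    """Expand an asymmetric unit into a filament by the screw operation.

    Copy j (j running over a window of ``n_copies`` indices positioned so
    that ``center_index`` maps to copy 0) is rotated by j·twist about z and
    translated by j·rise along z.  Chain ids gain the copy index as a
    suffix.  Inter-copy atom clashes closer than 1 Å raise a warning, not
    an error.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if not asym_unit.atoms:
        raise ValueError("asymmetric unit is empty")

    atoms: list[AtomRecord] = []
    copy_of: list[int] = []
    for j in range(-center_index, n_copies - center_index):
        R = _rz(j * params.twist)
        shift = np.array([0.0, 0.0, j * params.rise])
        for a in asym_unit.atoms:
            atoms.append(
                AtomRecord(
                    atom_name=a.atom_name,
                    element=a.element,
                    position=R @ a.position + shift,
                    residue_name=a.residue_name,
                    residue_seq=a.residue_seq,
                    chain_id=a.chain_id if n_copies == 1 else f"{a.chain_id}{j}",
                    altloc=a.altloc,
                    occupancy=a.occupancy,
                )
            )
            copy_of.append(j)

    out = Structure(
        identifier=f"{asym_unit.identifier}_x{n_copies}",
        atoms=atoms,
        metadata={**asym_unit.metadata, "helical": {"rise": params.rise, "twist": params.twist, "n_copies": n_copies}},
    )
    if n_copies > 1:
        pos = out.coords()
        copy_arr = np.asarray(copy_of)
        pairs = cKDTree(pos).query_pairs(CLASH_DISTANCE, output_type="ndarray")
        if len(pairs) and (copy_arr[pairs[:, 0]] != copy_arr[pairs[:, 1]]).any():
            warnings.warn(
                f"{out.identifier}: inter-copy atom contacts closer than "
                f"{CLASH_DISTANCE} Å — check rise/twist",
                stacklevel=2,
            )
    return out


def align_principal_axis(structure: Structure) -> Structure:
    """Rotate a structure so its longest principal axis lies along z.

    Deposited filament models follow the z-axis convention already and are
    used as-is; this helper is for arbitrary inputs.  The centroid moves to
    the origin.
    """
    if not structure.atoms:
        raise ValueError("empty structure")
    pos = structure.coords()
    centered = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    new = [
        AtomRecord(
            atom_name=a.atom_name,
            element=a.element,
            position=R @ (a.position - pos.mean(axis=0)),
            residue_name=a.residue_name,
            residue_seq=a.residue_seq,
            chain_id=a.chain_id,
            altloc=a.altloc,
            occupancy=a.occupancy,
        )
        for a in structure.atoms
    ]
    return Structure(identifier=structure.identifier, atoms=new, metadata=dict(structure.metadata))
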