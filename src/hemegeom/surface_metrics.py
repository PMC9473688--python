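"""Solvent-accessible surface area and interface burial, from first principles.

The Shrake–Rupley construction: place a deterministic golden-spiral lattice
of test points on each atom's solvent-expanded sphere (van der Waals radius
plus probe radius, probe 1.4 Å by default) and count the points not buried
inside any neighbouring expanded sphere.  The accessible area of an atom is
the surviving-point fraction times the full expanded-sphere area.

Per-heme areas sum over *all* atoms of the heme residue (ring plus vinyl
and propionate substituents when present), since reported heme exposures
are whole-ligand quantities; a ring-only sum is available via
``ring_atoms_only``.  Buried interface area between two subunit selections
is the PISA-style per-side average (SASA_A + SASA_B − SASA_AB) / 2 by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import CANONICAL_RING_ATOMS, HEME_RESIDUE_NAMES, Structure

#: Van der Waals radii in Å by element; unknown elements fall back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "FE": 1.80}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform lattice of n points on the unit sphere."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SASAResult:
    """Per-atom and per-heme solvent-accessible areas with provenance."""

    atom_keys: list[tuple[str, int, str]]  # (chain_id, residue_seq, atom_name)
    per_atom_area: np.ndarray  # Å², aligned with atom_keys
    per_heme_area: dict[tuple[str, int, str], float]  # heme_id -> Å²
    probe_radius: float
    n_sphere_points: int
    context: str

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())

    def atom_area(self, chain_id: str, residue_seq: int, atom_name: str) -> float:
        idx = self.atom_keys.index((chain_id, residue_seq, atom_name))
        return float(self.per_atom_area[idx])


@dataclass
class InterfaceArea:
    """Buried area between two chain selections of one structure."""

    subunit_a: tuple[str, ...]
    subunit_b: tuple[str, ...]
    buried_area: float  # Å²
    per_side: bool  # True: (ΔA)/2 convention; False: total buried area


def shrake_rupley(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_POINTS,
    ring_atoms_only: bool = False,
) -> SASAResult:
    """Shrake–Rupley SASA of every atom in the structure.

    Deterministic: the test-point lattice is a fixed golden spiral.  Heme
    residues additionally get a per-heme sum over all their atoms (or only
    the 25 canonical ring atoms when ``ring_atoms_only``).
    """
    atoms = structure.atoms
    if not atoms:
        raise ValueError("cannot compute SASA of an empty structure")
    pos = structure.coords()
    radii = np.array([vdw_radius(a.element) for a in atoms])
    expanded = radii + probe_radius
    sphere = golden_spiral_points(n_sphere_points)

    tree = cKDTree(pos)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = pos[i] + expanded[i] * sphere
        neighbours = [j for j in tree.query_ball_point(pos[i], max_reach) if j != i]
        if neighbours:
            nb = np.asarray(neighbours)
            # buried: point inside any neighbour's expanded sphere
            d2 = ((pts[:, None, :] - pos[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2

    ring_set = set(CANONICAL_RING_ATOMS)
    per_heme: dict[tuple[str, int, str], float] = {}
    for a, area in zip(atoms, areas):
        if a.residue_name in HEME_RESIDUE_NAMES:
            if ring_atoms_only and a.atom_name not in ring_set:
                continue
            key = (a.chain_id, a.residue_seq, a.residue_name)
            per_heme[key] = per_heme.get(key, 0.0) + float(area)

    return SASAResult(
        atom_keys=[(a.chain_id, a.residue_seq, a.atom_name) for a in atoms],
        per_atom_area=areas,
        per_heme_area=per_heme,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        context=",".join(structure.chains),
    )


def heme_sasa(
    structure: Structure,
    heme_id: tuple[str, int, str] | tuple[str, int],
    context_chains: list[str] | None = None,
    probe_radius: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_POINTS,
) -> float:
    """Solvent-exposed area (Å²) of one heme within a chosen context.

    All atoms of ``context_chains`` (default: the whole structure) occlude;
    the returned area sums over all atoms of the named heme.  The heme's
    own chain must be part of the context.
    """
    context = structure if context_chains is None else structure.select_chains(context_chains)
    result = shrake_rupley(context, probe_radius, n_sphere_points)
    matches = [
        hid
        for hid in result.per_heme_area
        if hid[0] == heme_id[0] and hid[1] == heme_id[1]
    ]
    if not matches:
        raise ValueError(f"heme {heme_id} not found in context {context.chains}")
    return result.per_heme_area[matches[0]]


def buried_interface_area(
    structure: Structure,
    chains_a: list[str],
    chains_b: list[str],
    probe_radius: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_POINTS,
    per_side: bool = True,
) -> InterfaceArea:
    """Buried area between two disjoint chain selections.

    (SASA(A alone) + SASA(B alone) − SASA(A ∪ B)) / 2 by default; set
    ``per_side=False`` for the undivided total.
    """
    set_a, set_b = set(chains_a), set(chains_b)
    if not set_a or not set_b:
        raise ValueError("both selections must be non-empty")
    if set_a & set_b:
        raise ValueError(f"selections overlap: {sorted(set_a & set_b)}")
    part_a = structure.select_chains(set_a)
    part_b = structure.select_chains(set_b)
    if not part_a.atoms or not part_b.atoms:
        raise ValueError("a selection matched no atoms")
    both = structure.select_chains(set_a | set_b)
    sasa_a = shrake_rupley(part_a, probe_radius, n_sphere_points).total_area
    sasa_b = shrake_rupley(part_b, probe_radius, n_sphere_points).total_area
    sasa_ab = shrake_rupley(both, probe_radius, n_sphere_points).total_area
    buried = sasa_a + sasa_b - sasa_ab
    if per_side:
        buried /= 2.0
    return InterfaceArea(
        subunit_a=tuple(sorted(set_a)),
        subunit_b=tuple(sorted(set_b)),
        buried_area=max(buried, 0.0),
        per_side=per_side,
    )


def per_heme_table(result: SASAResult, structure_id: str) -> "list[dict]":
    """Rows for the per-heme SASA TSV export."""
    return [
        {
            "structure_id": structure_id,
            "chain": hid[0],
            "residue_seq": hid[1],
            "area_A2": round(area, 2),
            "context": result.context,
        }
        for hid, area in sorted(result.per_heme_area.items())
    ]
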