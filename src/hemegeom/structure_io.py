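"""Reading and writing structures and extracting porphyrin rings.

PDB and mmCIF parsing is delegated to :mod:`gemmi`; this module converts
parsed models into the package's flat atom-record representation, applies
the alternate-conformer and hydrogen rules, and pulls out the canonical
25-atom porphyrin core of every complete HEC/HEM residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical porphyrin-core atom order: the iron, the four pyrrole nitrogens,
#: the sixteen pyrrole carbons and the four methine bridge carbons.  Vinyl and
#: propionate substituents are deliberately excluded.
CANONICAL_RING_ATOMS: tuple[str, ...] = (
    "FE",
    "NA", "NB", "NC", "ND",
    "C1A", "C2A", "C3A", "C4A",
    "C1B", "C2B", "C3B", "C4B",
    "C1C", "C2C", "C3C", "C4C",
    "C1D", "C2D", "C3D", "C4D",
    "CHA", "CHB", "CHC", "CHD",
)

HEME_RESIDUE_NAMES = frozenset({"HEC", "HEM"})


@dataclass
class AtomRecord:
    """One non-hydrogen atom of a structure."""

    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    residue_name: str
    residue_seq: int
    chain_id: str
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Structure:
    """An ordered collection of atoms with an identifier.

    ``metadata`` carries generator ground truth for synthetic structures and
    is otherwise empty.
    """

    identifier: str
    atoms: list[AtomRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return tuple(seen)

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in self.atoms])

    def select_chains(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = set(chain_ids)
        return Structure(
            identifier=self.identifier,
            atoms=[a for a in self.atoms if a.chain_id in wanted],
            metadata=dict(self.metadata),
        )

    def validate_unique(self) -> None:
        keys = {(a.chain_id, a.residue_seq, a.atom_name, a.altloc) for a in self.atoms}
        if len(keys) != len(self.atoms):
            raise ValueError(f"{self.identifier}: duplicate (chain, seq, atom, altloc) records")


@dataclass
class PorphyrinRing:
    """The canonical 25-atom porphyrin core of one heme.

    ``ring_coords`` rows follow :data:`CANONICAL_RING_ATOMS` exactly, so atom
    correspondence between two rings is positional.  ``plane_normal`` is the
    unit normal of the least-squares plane through the 24 non-iron atoms,
    oriented along (NA→C1A) × (NA→C1B).
    """

    heme_id: tuple[str, int, str]  # (chain_id, residue_seq, residue_name)
    ring_coords: np.ndarray  # (25, 3) Å

    def __post_init__(self) -> None:
        self.ring_coords = np.asarray(self.ring_coords, dtype=float)
        if self.ring_coords.shape != (25, 3):
            raise ValueError("ring_coords must be 25 x 3")
        if self.heme_id[2] not in HEME_RESIDUE_NAMES:
            raise ValueError(f"unsupported heme residue name {self.heme_id[2]!r}")

    @property
    def fe_position(self) -> np.ndarray:
        return self.ring_coords[0]

    @property
    def plane_normal(self) -> np.ndarray:
        pts = self.ring_coords[1:]  # non-Fe atoms define the plane
        centered = pts - pts.mean(axis=0)
        # smallest right-singular vector = least-squares plane normal
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        n = vt[-1]
        na, c1a, c1b = self.ring_coords[1], self.ring_coords[5], self.ring_coords[9]
        reference = np.cross(c1a - na, c1b - na)
        if np.dot(n, reference) < 0:
            n = -n
        return n / np.linalg.norm(n)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PorphyrinRing":
        return PorphyrinRing(
            heme_id=self.heme_id,
            ring_coords=self.ring_coords @ np.asarray(rotation).T + np.asarray(translation),
        )


def _resolve_format(path: Path, format: str) -> str:
    if format != "auto":
        if format not in ("pdb", "mmcif"):
            raise ValueError(f"unknown structure format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format explicitly")


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Hydrogens (and deuteriums) are dropped.  For alternate conformers of the
    same atom the highest-occupancy copy is kept, ties resolved toward
    altloc ``A``.  Only the first model of a multi-model file is read.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]

    records: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            best: dict[str, AtomRecord] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                altloc = atom.altloc if atom.altloc not in ("\x00",) else ""
                rec = AtomRecord(
                    atom_name=atom.name.strip(),
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    residue_name=residue.name.strip(),
                    residue_seq=residue.seqid.num,
                    chain_id=chain.name,
                    altloc=altloc,
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                )
                prev = best.get(rec.atom_name)
                if prev is None or _prefer(rec, prev):
                    best[rec.atom_name] = rec
            records.extend(best.values())

    structure = Structure(identifier=path.stem, atoms=records)
    structure.validate_unique()
    return structure


def _prefer(new: AtomRecord, old: AtomRecord) -> bool:
    """Alternate-conformer rule: highest occupancy, ties toward altloc 'A'."""
    if new.occupancy != old.occupancy:
        return new.occupancy > old.occupancy
    return (new.altloc or "~") < (old.altloc or "~")


def extract_hemes(structure: Structure) -> list[PorphyrinRing]:
    """Extract one :class:`PorphyrinRing` per complete HEC/HEM residue.

    Residues missing any of the 25 canonical core atoms are skipped with a
    logged warning — geometry statistics must not mix measured and imputed
    atoms.  Returns an empty list when the structure has no hemes.
    """
    by_residue: dict[tuple[str, int, str], dict[str, np.ndarray]] = {}
    for a in structure.atoms:
        if a.residue_name in HEME_RESIDUE_NAMES:
            key = (a.chain_id, a.residue_seq, a.residue_name)
            by_residue.setdefault(key, {})[a.atom_name] = a.position

    rings: list[PorphyrinRing] = []
    for key in by_residue:
        atom_map = by_residue[key]
        missing = [name for name in CANONICAL_RING_ATOMS if name not in atom_map]
        if missing:
            logger.warning(
                "%s: heme %s missing ring atoms %s; skipped", structure.identifier, key, missing
            )
            continue
        coords = np.array([atom_map[name] for name in CANONICAL_RING_ATOMS])
        rings.append(PorphyrinRing(heme_id=key, ring_coords=coords))
    return rings


def _chain_letter_map(chain_ids: Sequence[str]) -> dict[str, str]:
    """Deterministic remap of arbitrary chain ids to single PDB characters."""
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    if all(len(c) == 1 for c in chain_ids):
        return {c: c for c in chain_ids}
    if len(chain_ids) > len(alphabet):
        raise ValueError(f"cannot map {len(chain_ids)} chains onto single PDB characters")
    mapping = {c: alphabet[i] for i, c in enumerate(chain_ids)}
    logger.warning("multi-character chain ids remapped for PDB output: %s", mapping)
    return mapping


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as PDB, HETATM for heme residues, ATOM otherwise.

    Coordinates are written at the PDB format's 3-decimal precision, so a
    read/write round trip reproduces them to 1e-3 Å.  Multi-character chain
    ids (from filament expansion) are remapped to single characters.
    """
    if not structure.atoms:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    chain_map = _chain_letter_map(structure.chains)

    lines = []
    serial = 0
    for a in structure.atoms:
        serial += 1
        record = "HETATM" if a.residue_name in HEME_RESIDUE_NAMES else "ATOM  "
        name = a.atom_name
        # PDB atom-name column rule: names of atoms with 1-letter element
        # symbols start in column 14
        if len(a.element) == 1 and len(name) < 4:
            name = " " + name
        x, y, z = a.position
        lines.append(
            f"{record}{min(serial, 99999):>5d} {name:<4s}{(a.altloc or ' '):1s}"
            f"{a.residue_name:>3s} {chain_map[a.chain_id]:1s}{a.residue_seq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element[:2]:>2s}"
        )
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc


def rings_to_structure(
    rings: Sequence[PorphyrinRing], identifier: str = "synthetic"
) -> Structure:
    """Pack porphyrin rings into a Structure of HETATM-style records."""
    atoms: list[AtomRecord] = []
    for ring in rings:
        chain_id, seq, resname = ring.heme_id
        for name, pos in zip(CANONICAL_RING_ATOMS, ring.ring_coords):
            element = "Fe" if name == "FE" else name[0]
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    element=element,
                    position=pos,
                    residue_name=resname,
                    residue_seq=seq,
                    chain_id=chain_id,
                )
            )
    return Structure(identifier=identifier, atoms=atoms)
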