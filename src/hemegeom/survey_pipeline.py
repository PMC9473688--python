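"""Batch heme-pair survey over a corpus of structure files.

Reproduces the distance–angle survey of heme packing: every HEC/HEM pair
within an edge-to-edge cutoff (6 Å by default) contributes one row with
its minimum ring distance, rotation angle θ and motif.  Pairs are strictly
intra-structure; multi-model files contribute their first model only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .porphyrin_geometry import contact_pairs
from .structure_io import Structure, extract_hemes, read_structure

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = [
    "structure_id",
    "chain_a",
    "seq_a",
    "ligand_a",
    "chain_b",
    "seq_b",
    "ligand_b",
    "min_distance_A",
    "theta_deg",
    "plane_angle_deg",
    "motif",
]


def survey_structure(structure: Structure, cutoff: float = 6.0) -> pd.DataFrame:
    """Contact-pair rows for a single in-memory structure."""
    rings = extract_hemes(structure)
    rows = []
    for p in contact_pairs(rings, cutoff=cutoff):
        a, b = p.ring_a.heme_id, p.ring_b.heme_id
        rows.append(
            {
                "structure_id": structure.identifier,
                "chain_a": a[0],
                "seq_a": a[1],
                "ligand_a": a[2],
                "chain_b": b[0],
                "seq_b": b[1],
                "ligand_b": b[2],
                "min_distance_A": p.min_distance,
                "theta_deg": p.theta,
                "plane_angle_deg": p.plane_angle,
                "motif": p.motif,
            }
        )
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def survey(paths: Sequence[str | Path], cutoff: float = 6.0) -> pd.DataFrame:
    """Concatenated pair survey over many structure files.

    Unreadable files are logged and skipped; if every file fails, raises.
    Row order is deterministic: input file order, then (chain, seq) within
    each structure.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no input files")
    frames = []
    n_ok = 0
    for path in paths:
        try:
            structure = read_structure(path)
        except (ValueError, OSError) as exc:
            logger.warning("skipping unreadable file %s: %s", path, exc)
            continue
        n_ok += 1
        frames.append(survey_structure(structure, cutoff=cutoff))
    if n_ok == 0:
        raise ValueError(f"none of the {len(paths)} input files could be read")
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SURVEY_COLUMNS)


def angle_histogram(
    rows: pd.DataFrame, bin_width: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of rotation angles over [0°, 180°].

    Returns ``(counts, bin_edges)`` with bins ``[k·w, (k+1)·w)``; the
    counts sum to the number of rows.
    """
    if len(rows) == 0:
        raise ValueError("no survey rows to histogram")
    if not 0 < bin_width <= 180:
        raise ValueError("bin width must be in (0, 180]")
    n_bins = int(np.ceil(180.0 / bin_width))
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(rows["theta_deg"].to_numpy(), bins=edges)
    return counts, edges


def rare_pair_flags(
    rows: pd.DataFrame,
    theta_low: float = 50.0,
    theta_high: float = 90.0,
    distance_max: float = 5.0,
) -> pd.DataFrame:
    """Flag close pairs in the normally sparse 50–90° rotation-angle band.

    Pairs with θ in [theta_low, theta_high] usually sit at 6 Å or larger
    edge-to-edge separations; ones closer than ``distance_max`` are the
    structurally unusual cases worth inspection.
    """
    mask = (
        rows["theta_deg"].between(theta_low, theta_high)
        & (rows["min_distance_A"] < distance_max)
    )
    return rows[mask].reset_index(drop=True)


def write_survey_tsv(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False, float_format="%.4f")


def plot_survey(rows: pd.DataFrame, scatter_path: str | Path, hist_path: str | Path | None = None,
                bin_width: float = 10.0) -> None:
    """Distance–angle scatter (and optional θ histogram) as image files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(rows["theta_deg"], rows["min_distance_A"], s=12, alpha=0.7)
    ax.set_xlabel("rotation angle θ (deg)")
    ax.set_ylabel("minimum ring distance (Å)")
    ax.set_xlim(0, 180)
    fig.tight_layout()
    fig.savefig(scatter_path, dpi=150)
    plt.close(fig)

    if hist_path is not None:
        counts, edges = angle_histogram(rows, bin_width=bin_width)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(edges[:-1], counts, width=bin_width, align="edge", edgecolor="k")
        ax.set_xlabel("rotation angle θ (deg)")
        ax.set_ylabel("pairs")
        fig.tight_layout()
        fig.savefig(hist_path, dpi=150)
        plt.close(fig)
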