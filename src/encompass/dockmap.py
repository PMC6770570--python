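"""Docked-pose ensembles: top-score selection and contact-probability maps.

A pose set is a rigid receptor plus N rigid placements of a ligand
conformer, each with one scalar score (larger = more native-like).  Contact
probability of a residue is the fraction of poses in which its minimal
heavy-atom distance to the partner satisfies the cutoff rule (strict
``< 4 Å`` by default, the conventional contact definition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, EmptySelectionError
from .structio import (
    ConformerEnsemble,
    SegmentSpec,
    Structure,
    read_pdb,
    read_score_table,
    select_atoms,
)

__all__ = [
    "PoseSet",
    "ContactParams",
    "ContactProfile",
    "top_fraction_count",
    "select_top_fraction",
    "ligand_contact_profile",
    "receptor_contact_profile",
    "read_pose_set",
]


@dataclass
class PoseSet:
    """Fixed receptor + N scored rigid ligand placements."""

    receptor: Structure
    ligand_topology: Structure
    ligand_coordinates: np.ndarray  # (N, n_atoms, 3)
    scores: np.ndarray  # (N,)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ligand_coordinates = np.asarray(self.ligand_coordinates, float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.ligand_coordinates.ndim != 3:
            raise ConfigurationError("ligand_coordinates must be (N, atoms, 3)")
        n = self.n_poses
        if n < 1:
            raise ConfigurationError("a pose set needs at least one pose")
        if self.ligand_coordinates.shape[1] != len(self.ligand_topology):
            raise ConfigurationError("pose atom count != ligand topology")
        if self.scores.shape != (n,):
            raise ConfigurationError("one score per pose required")
        if not np.all(np.isfinite(self.scores)):
            raise ConfigurationError("scores must be finite")
        if not self.labels:
            self.labels = [str(i + 1) for i in range(n)]
        if len(self.labels) != n:
            raise ConfigurationError("one label per pose required")

    @property
    def n_poses(self) -> int:
        return self.ligand_coordinates.shape[0]

    def pose_ligand(self, i: int) -> Structure:
        return self.ligand_topology.with_coords(self.ligand_coordinates[i])

    def subset(self, indices: Sequence[int]) -> "PoseSet":
        idx = np.asarray(indices, dtype=int)
        return PoseSet(
            receptor=self.receptor,
            ligand_topology=self.ligand_topology,
            ligand_coordinates=self.ligand_coordinates[idx],
            scores=self.scores[idx],
            labels=[self.labels[i] for i in idx],
        )


@dataclass(frozen=True)
class ContactParams:
    """Contact definition: cutoff in Å, atom set, strictness of the
    inequality, and whether HETATM partners count."""

    cutoff: float = 4.0
    atom_set: Literal["heavy", "all"] = "heavy"
    strict: bool = True
    include_hetero: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def in_contact(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances)
        return d < self.cutoff if self.strict else d <= self.cutoff


@dataclass
class ContactProfile:
    """Per-residue contact probabilities over a pose (or frame) ensemble."""

    residue_labels: list[tuple[str, int, str]]  # (chain, number, name)
    probabilities: np.ndarray
    n_poses: int
    params: ContactParams

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        counts = p * self.n_poses
        if np.max(np.abs(counts - np.round(counts))) > 1e-9:
            raise ValueError("each probability × n_poses must be integral")
        self.probabilities = p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [c for c, _, _ in self.residue_labels],
            "residue_number": [r for _, r, _ in self.residue_labels],
            "residue_name": [n for _, _, n in self.residue_labels],
            "probability": self.probabilities,
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6f")

    def for_chain(self, chain_id: str) -> "ContactProfile":
        keep = [i for i, (c, _, _) in enumerate(self.residue_labels)
                if c == chain_id]
        return ContactProfile(
            [self.residue_labels[i] for i in keep],
            self.probabilities[keep], self.n_poses, self.params,
        )


def top_fraction_count(n: int, fraction: float) -> int:
    """Number of poses retained by a top-``fraction`` selection: the
    ceiling of ``fraction × n`` (with a guard against float fuzz on exact
    products)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be positive")
    return int(math.ceil(fraction * n - 1e-9))


def select_top_fraction(p: PoseSet, fraction: float) -> PoseSet:
    """The ceiling(fraction × N) highest-scoring poses, ordered by
    descending score; score ties at the boundary break by pose index."""
    k = top_fraction_count(p.n_poses, fraction)
    order = np.argsort(-p.scores, kind="stable")
    return p.subset(order[:k])


def _residue_groups(
    s: Structure, atom_set: str, include_hetero: bool
) -> tuple[list[tuple[str, int, str]], list[np.ndarray]]:
    """Residues (file order) and their atom indices under the atom set."""
    mask = np.ones(len(s), dtype=bool)
    if not include_hetero:
        mask &= ~s.is_hetero
    if atom_set == "heavy":
        mask &= ~s.is_hydrogen
    labels: list[tuple[str, int, str]] = []
    groups: list[np.ndarray] = []
    seen: dict[tuple[str, int], int] = {}
    idx = np.where(mask)[0]
    for i in idx:
        key = (str(s.chain_ids[i]), int(s.residue_numbers[i]))
        if key not in seen:
            seen[key] = len(labels)
            labels.append((key[0], key[1], str(s.residue_names[i])))
            groups.append([])
        groups[seen[key]].append(i)
    return labels, [np.asarray(g) for g in groups]


def _partner_atom_indices(
    s: Structure, c: ContactParams
) -> np.ndarray:
    mask = np.ones(len(s), dtype=bool)
    if not c.include_hetero:
        mask &= ~s.is_hetero
    if c.atom_set == "heavy":
        mask &= ~s.is_hydrogen
    idx = np.where(mask)[0]
    if idx.size == 0:
        raise EmptySelectionError("contact partner selection is empty")
    return idx


def min_residue_distances(
    groups: list[np.ndarray],
    coords: np.ndarray,
    partner_coords: np.ndarray,
) -> np.ndarray:
    """Per residue group, the minimal atom–atom distance to the partner."""
    flat = np.concatenate(groups)
    d = cdist(coords[flat], partner_coords)
    mins = np.minimum.reduceat(
        d.min(axis=1), np.cumsum([0] + [len(g) for g in groups[:-1]])
    )
    return mins


def ligand_contact_profile(p: PoseSet, c: ContactParams | None = None
                           ) -> ContactProfile:
    """Per ligand residue, the fraction of poses whose minimal atom–atom
    distance to any receptor atom satisfies the contact rule."""
    c = c or ContactParams()
    labels, groups = _residue_groups(p.ligand_topology, c.atom_set,
                                     c.include_hetero)
    if not labels:
        raise EmptySelectionError("ligand has no selectable residues")
    rec_idx = _partner_atom_indices(p.receptor, c)
    rec_coords = p.receptor.coords[rec_idx]
    counts = np.zeros(len(labels), dtype=int)
    for m in range(p.n_poses):
        mins = min_residue_distances(groups, p.ligand_coordinates[m],
                                     rec_coords)
        counts += c.in_contact(mins)
    return ContactProfile(labels, counts / p.n_poses, p.n_poses, c)


def receptor_contact_profile(
    p: PoseSet,
    segments: Sequence[SegmentSpec],
    c: ContactParams | None = None,
) -> ContactProfile:
    """Per receptor residue (all chains, file order), the fraction of poses
    in which any atom of any listed ligand segment is within the cutoff.

    An empty segment list yields an all-zero profile.  Use
    :meth:`ContactProfile.for_chain` to split a two-chain receptor into the
    per-chain layout.
    """
    c = c or ContactParams()
    labels, groups = _residue_groups(p.receptor, c.atom_set, c.include_hetero)
    if not labels:
        raise EmptySelectionError("receptor has no selectable residues")
    counts = np.zeros(len(labels), dtype=int)
    if segments:
        seg_idx = np.unique(np.concatenate([
            select_atoms(p.ligand_topology, seg,
                         atom_set="heavy" if c.atom_set == "heavy" else "all")
            for seg in segments
        ]))
        for m in range(p.n_poses):
            mins = min_residue_distances(
                groups, p.receptor.coords, p.ligand_coordinates[m][seg_idx]
            )
            counts += c.in_contact(mins)
    return ContactProfile(labels, counts / p.n_poses, p.n_poses, c)


def read_pose_set(
    receptor_path: str | Path,
    ligand_poses_path: str | Path,
    scores_path: str | Path,
) -> PoseSet:
    """Assemble a pose set from a single-model receptor PDB, a multi-model
    ligand-pose PDB, and a 2-column (label, score) sidecar table."""
    receptor = read_pdb(receptor_path, model_policy="first")
    poses = read_pdb(ligand_poses_path, model_policy="all")
    if isinstance(poses, Structure):  # pragma: no cover - policy guarantees
        poses = ConformerEnsemble(poses, poses.coords[None])
    table = read_score_table(scores_path)
    missing = [lab for lab in poses.labels if lab not in table.index]
    if missing:
        raise ConfigurationError(
            f"score table lacks entries for pose label(s) {missing[:5]}"
        )
    scores = table.loc[poses.labels].to_numpy()
    return PoseSet(
        receptor=receptor,
        ligand_topology=poses.topology,
        ligand_coordinates=poses.coordinates,
        scores=scores,
        labels=list(poses.labels),
    )
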