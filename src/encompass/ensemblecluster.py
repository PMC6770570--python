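"""gromos-style conformational clustering and ensemble descriptors.

The clustering is the iterative neighbour-count scheme used for MD
ensembles: under an RMSD cutoff, the conformer with the most neighbours
seeds a cluster, its whole neighbourhood is removed, and the process
repeats.  Descriptors (radius-of-gyration distribution, per-residue helix
propensity) check that a representative subset still looks like the full
ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geomcore import (
    assign_helix,
    atomic_masses,
    backbone_dihedrals,
    radius_of_gyration,
    rmsd_no_fit,
    superpose,
)
from .structio import ConformerEnsemble, SegmentSpec, select_atoms, write_pdb

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "select_top_clusters",
    "ensemble_descriptors",
    "cluster_table",
    "write_representatives",
]


@dataclass(frozen=True)
class ClusterParams:
    """Cutoff in Å (5.0 Å = 0.5 nm is the conventional coarse cutoff for
    disordered ensembles), atom set for the RMSD, and whether each pair is
    superposed before the RMSD."""

    cutoff: float = 5.0
    atom_set: Literal["CA", "mainchain"] = "mainchain"
    fit_before_rmsd: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ClusterResult:
    """Clusters in formation order; each with its neighbour-count center."""

    clusters: list[list[int]]
    representatives: list[int]
    n_conformers: int
    coverage: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        sizes = np.array([len(c) for c in self.clusters], dtype=float)
        if int(sizes.sum()) != self.n_conformers:
            raise ValueError("clusters must partition the ensemble")
        for rep, members in zip(self.representatives, self.clusters):
            if rep not in members:
                raise ValueError("representative outside its cluster")
        self.coverage = np.cumsum(sizes) / self.n_conformers

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters])


def _full_chain_segment(e: ConformerEnsemble) -> list[SegmentSpec]:
    segs = []
    for chain in np.unique(e.topology.chain_ids):
        mask = e.topology.chain_ids == chain
        res = e.topology.residue_numbers[mask]
        segs.append(
            SegmentSpec(f"chain {chain}", str(chain),
                        int(res.min()), int(res.max()))
        )
    return segs


def _selection_indices(e: ConformerEnsemble, atom_set: str) -> np.ndarray:
    idx = [select_atoms(e.topology, seg, atom_set=atom_set)
           for seg in _full_chain_segment(e)]
    return np.sort(np.concatenate(idx))


def pairwise_rmsd_matrix(
    e: ConformerEnsemble, p: ClusterParams
) -> np.ndarray:
    """Symmetric M×M matrix of (optionally superposed) RMSD over the
    selected atom set, Å."""
    idx = _selection_indices(e, p.atom_set)
    coords = e.coordinates[:, idx, :]
    M = e.n_conformers
    mat = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            if p.fit_before_rmsd:
                _, r = superpose(coords[i], coords[j])
            else:
                r = rmsd_no_fit(coords[i], coords[j])
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Iterative neighbour-count clustering under an RMSD cutoff.

    A conformer is its own neighbour and neighbourhood membership uses a
    strict ``< cutoff``; neighbour-count ties go to the lowest conformer
    index, which makes the procedure deterministic.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConfigurationError("matrix must be square")
    if np.max(np.abs(mat - mat.T)) > 1e-6:
        raise ConfigurationError("matrix must be symmetric (tolerance 1e-6)")
    if np.max(np.abs(np.diag(mat))) > 1e-9:
        raise ConfigurationError("matrix diagonal must be zero")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    M = mat.shape[0]
    neighbour = mat < cutoff  # includes the diagonal (self-neighbour)
    unassigned = np.ones(M, dtype=bool)
    clusters: list[list[int]] = []
    representatives: list[int] = []
    while np.any(unassigned):
        counts = (neighbour & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        rep = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(neighbour[rep] & unassigned)[0]
        clusters.append([int(m) for m in members])
        representatives.append(rep)
        unassigned[members] = False
    return ClusterResult(clusters, representatives, M)


def select_top_clusters(
    r: ClusterResult, coverage_target: float
) -> list[int]:
    """Representatives of the shortest cluster prefix (formation order)
    whose cumulative population reaches ``coverage_target``."""
    if not 0 < coverage_target <= 1:
        raise ValueError("coverage_target must be in (0, 1]")
    n_keep = int(np.searchsorted(r.coverage, coverage_target - 1e-12) + 1)
    n_keep = min(n_keep, len(r.clusters))
    return r.representatives[:n_keep]


def ensemble_descriptors(
    e: ConformerEnsemble,
    rg_atom_set: Literal["heavy", "CA"] = "heavy",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-conformer radius of gyration and per-residue helix propensity.

    Rg is mass-weighted over heavy atoms by default (unweighted over CA
    atoms with ``rg_atom_set="CA"``).  Helix propensity is the fraction of
    conformers in which the dihedral-rule assignment marks the residue
    helical.
    """
    idx = _selection_indices(e, rg_atom_set if rg_atom_set == "CA" else "heavy")
    if rg_atom_set == "CA":
        masses = None
    else:
        masses = atomic_masses(e.topology.subset(idx))
    rg = np.array([
        radius_of_gyration(e.coordinates[m, idx, :], masses)
        for m in range(e.n_conformers)
    ])

    chains = np.unique(e.topology.chain_ids)
    frames = []
    for chain in chains:
        counts = None
        res_ids = None
        for m in range(e.n_conformers):
            conf = e.conformer(m)
            res_ids, phi, psi = backbone_dihedrals(conf, chain_id=str(chain))
            helical = assign_helix(np.column_stack([phi, psi]))
            counts = helical.astype(int) if counts is None else counts + helical
        frames.append(pd.DataFrame({
            "chain": str(chain),
            "residue_number": res_ids,
            "helix_propensity": counts / e.n_conformers,
        }))
    propensity = pd.concat(frames, ignore_index=True)
    return rg, propensity


def cluster_table(r: ClusterResult, labels: list[str] | None = None
                  ) -> pd.DataFrame:
    """One row per conformer: label, cluster id (formation order), flag."""
    M = r.n_conformers
    if labels is None:
        labels = [str(i + 1) for i in range(M)]
    cluster_id = np.empty(M, dtype=int)
    is_rep = np.zeros(M, dtype=bool)
    for cid, (members, rep) in enumerate(zip(r.clusters, r.representatives)):
        cluster_id[members] = cid
        is_rep[rep] = True
    return pd.DataFrame({
        "conformer": labels,
        "cluster": cluster_id,
        "is_representative": is_rep,
    })


def write_representatives(
    e: ConformerEnsemble, r: ClusterResult, path: str | Path,
    coverage_target: float = 1.0,
) -> list[int]:
    """Export cluster representatives (up to a coverage target) as a
    multi-model PDB; returns the exported conformer indices."""
    reps = select_top_clusters(r, coverage_target)
    sub = ConformerEnsemble(
        topology=e.topology,
        coordinates=e.coordinates[reps],
        labels=[e.labels[i] for i in reps],
    )
    write_pdb(sub, path)
    return reps
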