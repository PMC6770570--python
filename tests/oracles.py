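"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: straightforward
loops, exhaustive enumeration, and grid search.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def grid_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray,
                        coarse_deg: float = 4.0) -> float:
    """Minimum RMSD over proper rotations by Euler-angle grid search.

    Centroids are matched analytically; the rotation is searched on a
    coarse grid and refined on a 1° grid around the coarse optimum, so the
    final resolution is 1°.
    """
    X = mobile - mobile.mean(axis=0)
    Y = reference - reference.mean(axis=0)

    def best_on(grids):
        a, b, c = np.meshgrid(*grids, indexing="ij")
        angles = np.column_stack([a.ravel(), b.ravel(), c.ravel()])
        mats = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        rotated = np.einsum("rij,nj->rni", mats, X)
        rmsds = np.sqrt(((rotated - Y) ** 2).sum(axis=2).mean(axis=1))
        k = int(np.argmin(rmsds))
        return angles[k], float(rmsds[k])

    step = coarse_deg
    coarse = best_on([
        np.arange(0.0, 360.0, step),
        np.arange(0.0, 180.0 + step, step),
        np.arange(0.0, 360.0, step),
    ])
    center = coarse[0]
    fine = best_on([
        center[0] + np.arange(-step, step + 1.0, 1.0),
        center[1] + np.arange(-step, step + 1.0, 1.0),
        center[2] + np.arange(-step, step + 1.0, 1.0),
    ])
    return min(coarse[1], fine[1])


def brute_gromos(matrix: np.ndarray, cutoff: float):
    """Reference neighbour-count clustering by explicit loops."""
    m = np.asarray(matrix)
    remaining = list(range(m.shape[0]))
    clusters, reps = [], []
    while remaining:
        counts = {}
        for i in remaining:
            counts[i] = sum(1 for j in remaining if m[i, j] < cutoff)
        best = max(counts.values())
        rep = min(i for i in remaining if counts[i] == best)
        members = [j for j in remaining if m[rep, j] < cutoff]
        clusters.append(members)
        reps.append(rep)
        remaining = [i for i in remaining if i not in members]
    return clusters, reps


def min_distance_loop(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    best = np.inf
    for p in coords_a:
        for q in coords_b:
            best = min(best, float(np.linalg.norm(p - q)))
    return best


def ligand_profile_oracle(pose_set, cutoff: float) -> np.ndarray:
    """Per ligand residue contact probability by exhaustive pairwise
    distances (heavy atoms, strict < cutoff, HETATM excluded)."""
    lig = pose_set.ligand_topology
    rec = pose_set.receptor
    rec_mask = ~rec.is_hydrogen & ~rec.is_hetero
    rec_coords = rec.coords[rec_mask]
    keys = []
    for c, r in zip(lig.chain_ids, lig.residue_numbers):
        if (c, r) not in keys:
            keys.append((c, r))
    counts = np.zeros(len(keys))
    lig_mask = ~lig.is_hydrogen & ~lig.is_hetero
    for m in range(pose_set.n_poses):
        coords = pose_set.ligand_coordinates[m]
        for k, (c, r) in enumerate(keys):
            sel = (lig.chain_ids == c) & (lig.residue_numbers == r) & lig_mask
            if min_distance_loop(coords[sel], rec_coords) < cutoff:
                counts[k] += 1
    return counts / pose_set.n_poses


def hotspot_count_oracle(receptor, seg_coords: np.ndarray,
                         hotspot_residues, cutoff: float) -> int:
    n = 0
    for chain, rid in hotspot_residues:
        sel = ((receptor.chain_ids == chain)
               & (receptor.residue_numbers == rid)
               & ~receptor.is_hydrogen)
        if min_distance_loop(receptor.coords[sel], seg_coords) < cutoff:
            n += 1
    return n


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=rng).as_matrix()
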