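"""Productive encounter-complex identification.

A pose is productive when its recognition segment (i) touches at least a
minimum number of receptor hot-spot residues (the residues the reference
crystal helix contacts) and (ii) lies with its helix principal axis within
a threshold angle of the crystallographic orientation — the orientation
matters because an antiparallel placement cannot evolve into the native
complex.  Segment RMSD against the reference complex is reported after a
receptor-only fit, so it measures the segment's placement, not its internal
geometry alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dockmap import PoseSet
from .errors import ConfigurationError
from .geomcore import (
    OrientedAxis,
    RigidTransform,
    axis_angle,
    rmsd_no_fit,
    segment_axis,
    superpose,
)
from .structio import SegmentSpec, Structure, select_atoms

__all__ = [
    "HotspotSet",
    "ProductiveCriteria",
    "ProductiveReport",
    "count_hotspot_contacts",
    "filter_productive",
    "rank_by_segment_rmsd",
    "receptor_fit_transform",
]


@dataclass(frozen=True)
class HotspotSet:
    """Receptor hot-spot residues with the contact rule applied to them."""

    residues: tuple[tuple[str, int], ...]  # (chain_id, residue_number)
    min_count: int = 6
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(
            (str(c), int(r)) for c, r in self.residues
        ))
        if self.min_count > len(self.residues):
            raise ConfigurationError(
                "min_count exceeds the number of hot-spot residues"
            )
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ProductiveCriteria:
    """One recognition segment, the hot-spot rule, and the reference
    orientation/complex the segment is compared against."""

    segment: SegmentSpec
    hotspots: HotspotSet
    max_axis_angle: float = 30.0
    reference_axis: OrientedAxis | None = None
    reference_complex: Structure | None = None
    reference_segment: SegmentSpec | None = None

    def __post_init__(self) -> None:
        if not 0 < self.max_axis_angle <= 180:
            raise ValueError("max_axis_angle must be in (0, 180]")

    def resolve_reference_axis(self) -> OrientedAxis:
        if self.reference_axis is not None:
            return self.reference_axis
        if self.reference_complex is None or self.reference_segment is None:
            raise ConfigurationError(
                "need reference_axis, or reference_complex plus "
                "reference_segment to derive it"
            )
        idx = select_atoms(self.reference_complex, self.reference_segment,
                           atom_set="CA")
        return segment_axis(self.reference_complex.coords[idx])


@dataclass
class ProductiveReport:
    """Per-pose hot-spot count, axis angle, segment RMSD and pass flag."""

    table: pd.DataFrame
    criteria: ProductiveCriteria

    @property
    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passes"]]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _hotspot_atom_groups(
    receptor: Structure, h: HotspotSet
) -> list[np.ndarray]:
    heavy = ~receptor.is_hydrogen
    groups = []
    for chain, resnum in h.residues:
        mask = (
            (receptor.chain_ids == chain)
            & (receptor.residue_numbers == resnum)
            & heavy & ~receptor.is_hetero
        )
        idx = np.where(mask)[0]
        if idx.size == 0:
            raise ConfigurationError(
                f"hot-spot residue {chain}:{resnum} not found on receptor"
            )
        groups.append(idx)
    return groups


def count_hotspot_contacts(
    receptor: Structure,
    ligand_topology: Structure,
    ligand_coords: np.ndarray,
    segment: SegmentSpec,
    h: HotspotSet,
) -> int:
    """Number of hot-spot residues whose minimal heavy-atom distance to any
    atom of the ligand segment is below the cutoff."""
    seg_idx = select_atoms(ligand_topology, segment, atom_set="heavy")
    seg_coords = np.asarray(ligand_coords)[seg_idx]
    count = 0
    for idx in _hotspot_atom_groups(receptor, h):
        if cdist(receptor.coords[idx], seg_coords).min() < h.cutoff:
            count += 1
    return count


def receptor_fit_transform(
    pose_receptor: Structure, reference: Structure
) -> tuple[RigidTransform, float, int]:
    """Superpose the pose receptor onto the reference over shared CA atoms.

    Shared means same (chain_id, residue_number) carrying a CA atom on both
    sides; returns (transform, rmsd, n_shared).
    """
    def ca_map(s: Structure) -> dict[tuple[str, int], np.ndarray]:
        mask = (s.atom_names == "CA") & ~s.is_hetero
        return {
            (str(c), int(r)): xyz
            for c, r, xyz in zip(
                s.chain_ids[mask], s.residue_numbers[mask], s.coords[mask]
            )
        }

    mob = ca_map(pose_receptor)
    ref = ca_map(reference)
    shared = sorted(set(mob) & set(ref))
    if len(shared) < 3:
        raise ConfigurationError(
            "fewer than 3 shared CA atoms between pose receptor and reference"
        )
    X = np.array([mob[k] for k in shared])
    Y = np.array([ref[k] for k in shared])
    transform, rmsd = superpose(X, Y)
    return transform, rmsd, len(shared)


def filter_productive(p: PoseSet, c: ProductiveCriteria) -> ProductiveReport:
    """Evaluate every pose against the productive-complex criteria.

    Pass rule: ``hotspot_count >= min_count`` and
    ``axis_angle < max_axis_angle`` (both strict per the contact and angle
    conventions).  Segment RMSD is computed by superposing the pose
    receptor onto the reference receptor (shared CA), applying that
    transform to the ligand, then RMSD without refit over the segment CA
    atoms against the reference segment — reported for ranking, not part of
    the pass rule.
    """
    ref_axis = c.resolve_reference_axis()
    seg_ca = select_atoms(p.ligand_topology, c.segment, atom_set="CA")

    if c.reference_complex is not None:
        transform, _, _ = receptor_fit_transform(p.receptor,
                                                 c.reference_complex)
    else:
        transform = RigidTransform.identity()
    ref_seg_coords = None
    if c.reference_complex is not None and c.reference_segment is not None:
        ref_idx = select_atoms(c.reference_complex, c.reference_segment,
                               atom_set="CA")
        if len(ref_idx) == len(seg_ca):
            ref_seg_coords = c.reference_complex.coords[ref_idx]

    rows = []
    for m in range(p.n_poses):
        coords = p.ligand_coordinates[m]
        n_hot = count_hotspot_contacts(
            p.receptor, p.ligand_topology, coords, c.segment, c.hotspots
        )
        fitted_seg = transform.apply(coords[seg_ca])
        angle = axis_angle(segment_axis(fitted_seg), ref_axis)
        seg_rmsd = (
            rmsd_no_fit(fitted_seg, ref_seg_coords)
            if ref_seg_coords is not None else np.nan
        )
        rows.append((p.labels[m], n_hot, angle, seg_rmsd))
    table = pd.DataFrame(
        rows, columns=["label", "hotspot_count", "axis_angle_deg",
                       "segment_rmsd"]
    )
    table["passes"] = (
        (table["hotspot_count"] >= c.hotspots.min_count)
        & (table["axis_angle_deg"] < c.max_axis_angle)
    )
    return ProductiveReport(table, c)


def rank_by_segment_rmsd(r: ProductiveReport, k: int) -> list[str]:
    """Labels of the k passing poses with smallest segment RMSD, ascending
    (ties by pose order); returns all passing, with a warning, if fewer
    than k pass."""
    if k < 1:
        raise ValueError("k must be >= 1")
    passing = r.passing
    if len(passing) < k:
        warnings.warn(
            f"only {len(passing)} passing pose(s) available for k={k}",
            stacklevel=2,
        )
        k = len(passing)
    ranked = passing.sort_values("segment_rmsd", kind="stable")
    return list(ranked["label"].iloc[:k])
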