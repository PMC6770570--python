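"""Deterministic, seeded generators for every input class the pipeline
consumes, with planted ground truth for parameter-recovery tests.

The generators emulate the study conditions of an IDP-recognition
analysis: a flexible ~60-residue chain with two transient helical segments
(the tandem-motif layout), a rigid CA-only toy receptor with a planted
groove of hot-spot residues mimicking a recognition cleft at fixture
scale, scored pose sets in which a known subset is productive, and
bound/unbound trajectories whose segment–receptor minimal distance follows
a first-order autoregressive process of known relaxation time.

Every generator is a pure function of its :class:`SynthSpec`: random
streams are derived per component from the seed, so repeated calls are
bit-identical and changing one spec field perturbs only its component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import biotite.structure as bst
from scipy.spatial.distance import cdist

from .dockmap import PoseSet
from .errors import GenerationError
from .geomcore import axis_angle, segment_axis
from .prodfilter import HotspotSet, ProductiveCriteria, count_hotspot_contacts
from .structio import ConformerEnsemble, SegmentSpec, Structure, select_atoms
from .trajanal import Trajectory

__all__ = [
    "SynthSpec",
    "make_ideal_helix",
    "build_backbone",
    "make_conformer_ensemble",
    "make_pose_set",
    "make_complex_trajectory",
    "SyntheticEnsemble",
    "SyntheticPoseSet",
    "SyntheticTrajectory",
]

# ideal backbone internal coordinates (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0

# random-coil dihedral basins (φ, ψ): β, polyproline-II and extended —
# all outside the helix-assignment window even with ±15° jitter
_COIL_BASINS = np.array([(-120.0, 130.0), (-75.0, 145.0), (-140.0, 155.0)])

_STREAMS = {"coil": 0, "helix": 1, "pose": 2, "score": 3, "noise": 4,
            "traj": 5, "receptor": 6}


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the synthetic generators.

    Defaults model the analysis scale: a 60-residue construct with helical
    segments 9–18 and 37–46, a ~100-residue toy receptor with 9 hot spots,
    200 scored poses of which 10% are productive (axis jitter well inside
    the 30° orientation filter), and trajectories sampled every 20 ps with
    a 100-frame distance relaxation time.
    """

    seed: int = 0
    n_residues: int = 60
    helix_segments: tuple[tuple[int, int], ...] = ((9, 18), (37, 46))
    receptor_size: int = 100
    groove_residues: tuple[int, ...] | None = None
    n_poses: int = 200
    productive_fraction: float = 0.1
    axis_jitter: float = 20.0
    trajectory_length: int = 2000
    ou_relaxation: float = 100.0
    n_conformers: int = 200
    helix_probability: float = 0.4
    traj_noise_amplitude: float = 3.0
    dt_ps: float = 20.0

    def __post_init__(self) -> None:
        for name in ("n_residues", "receptor_size", "n_poses",
                     "trajectory_length", "n_conformers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("productive_fraction", "helix_probability"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ou_relaxation <= 0 or self.dt_ps <= 0:
            raise ValueError("ou_relaxation and dt_ps must be positive")
        if self.axis_jitter <= 0 or self.axis_jitter >= 30:
            raise ValueError(
                "axis_jitter must be in (0, 30) so planted productive poses "
                "stay inside the orientation filter"
            )
        for a, b in self.helix_segments:
            if not 1 <= a <= b <= self.n_residues:
                raise ValueError(f"helix segment {a}-{b} outside the chain")

    @property
    def hotspot_residues(self) -> tuple[int, ...]:
        if self.groove_residues is not None:
            return tuple(self.groove_residues)
        return tuple(range(1, 10))

    def rng(self, component: str) -> np.random.Generator:
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(_STREAMS[component],)
        )
        return np.random.default_rng(ss)


@dataclass
class SyntheticEnsemble:
    ensemble: ConformerEnsemble
    #: (M, n_segments) — which helix segments are helical in each conformer
    segment_helical: np.ndarray


@dataclass
class SyntheticPoseSet:
    pose_set: PoseSet
    productive_mask: np.ndarray
    hotspots: HotspotSet
    criteria: ProductiveCriteria
    recognition_segment: SegmentSpec
    reference_complex: Structure


@dataclass
class SyntheticTrajectory:
    trajectory: Trajectory
    bound: np.ndarray  # per-frame ground-truth bound flag
    distance_series: np.ndarray  # planted AR(1) series, Å
    ligand_segment: SegmentSpec
    receptor_chain: str
    hotspots: HotspotSet


# ---------------------------------------------------------------------------
# backbone construction


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a–b–c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: Sequence[float],
    psi: Sequence[float],
    chain_id: str = "A",
    first_residue: int = 1,
    res_name: str = "ALA",
) -> Structure:
    """N/CA/C/O backbone from per-residue (φ, ψ) with ideal bond geometry
    and trans peptide bonds.  φ of the first residue is geometrically
    unused; ψ of the last residue only orients its carbonyl oxygen."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = phi.size
    if n < 2 or psi.size != n:
        raise ValueError("need matching phi/psi arrays of length >= 2")
    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    O = np.empty((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n - 1):
        N[i + 1] = _nerf(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psi[i])
        CA[i + 1] = _nerf(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0)
        C[i + 1] = _nerf(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C,
                         phi[i + 1])
    for i in range(n):
        O[i] = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0)

    n_atoms = 4 * n
    arr = bst.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    names = ("N", "CA", "C", "O")
    elements = ("N", "C", "C", "O")
    per_res = (N, CA, C, O)
    for i in range(n):
        for j in range(4):
            k = 4 * i + j
            coords[k] = per_res[j][i]
            arr.atom_name[k] = names[j]
            arr.element[k] = elements[j]
            arr.res_id[k] = first_residue + i
            arr.res_name[k] = res_name
            arr.chain_id[k] = chain_id
    arr.coord = coords
    arr.hetero[:] = False
    arr.ins_code[:] = ""
    return Structure(arr, validate=False)


def make_ideal_helix(n: int, chain_id: str = "A",
                     first_residue: int = 1) -> Structure:
    """Canonical α-helix backbone (φ, ψ) = (−57°, −47°): ~1.5 Å rise and
    ~100° twist per residue at ~2.3 Å CA radius."""
    if n < 4:
        raise ValueError("an ideal helix needs at least 4 residues")
    return build_backbone(
        np.full(n, _HELIX_PHI), np.full(n, _HELIX_PSI),
        chain_id=chain_id, first_residue=first_residue,
    )


def _ca_self_avoiding(structure: Structure, min_dist: float = 3.0) -> bool:
    ca = structure.coords[structure.atom_names == "CA"]
    if ca.shape[0] < 4:
        return True
    d = cdist(ca, ca)
    n = d.shape[0]
    i, j = np.triu_indices(n, k=3)
    return bool(d[i, j].min() > min_dist)


def _sample_dihedrals(
    spec: SynthSpec,
    helical_segments: Sequence[tuple[int, int]],
    rng_coil: np.random.Generator,
    rng_noise: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = spec.n_residues
    basin = rng_coil.integers(0, len(_COIL_BASINS), size=n)
    jitter = rng_coil.uniform(-15.0, 15.0, size=(n, 2))
    phi = _COIL_BASINS[basin, 0] + jitter[:, 0]
    psi = _COIL_BASINS[basin, 1] + jitter[:, 1]
    for a, b in helical_segments:
        m = slice(a - 1, b)
        k = b - a + 1
        phi[m] = _HELIX_PHI + np.clip(rng_noise.normal(0, 3, k), -9, 9)
        psi[m] = _HELIX_PSI + np.clip(rng_noise.normal(0, 3, k), -9, 9)
    return phi, psi


def _build_chain(
    spec: SynthSpec,
    helical_segments: Sequence[tuple[int, int]],
    rng_coil: np.random.Generator,
    rng_noise: np.random.Generator,
    max_tries: int = 60,
) -> Structure:
    for _ in range(max_tries):
        phi, psi = _sample_dihedrals(spec, helical_segments, rng_coil,
                                     rng_noise)
        s = build_backbone(phi, psi)
        if _ca_self_avoiding(s):
            return s
    raise GenerationError(
        f"self-avoiding chain generation failed after {max_tries} tries"
    )


def make_conformer_ensemble(s: SynthSpec) -> SyntheticEnsemble:
    """Ensemble of self-avoiding coil conformers in which each helix
    segment is helical in a seeded ~``helix_probability`` fraction of
    conformers; the per-conformer flags are the planted ground truth for
    the helix-propensity descriptor."""
    rng_helix = s.rng("helix")
    rng_coil = s.rng("coil")
    rng_noise = s.rng("noise")
    n_seg = len(s.helix_segments)
    flags = rng_helix.random((s.n_conformers, n_seg)) < s.helix_probability
    coords = []
    topology: Structure | None = None
    for m in range(s.n_conformers):
        segs = [seg for seg, on in zip(s.helix_segments, flags[m]) if on]
        conf = _build_chain(s, segs, rng_coil, rng_noise)
        if topology is None:
            topology = conf
        coords.append(conf.coords)
    ensemble = ConformerEnsemble(
        topology=topology,
        coordinates=np.stack(coords),
        labels=[f"conf{m + 1:04d}" for m in range(s.n_conformers)],
    )
    return SyntheticEnsemble(ensemble, flags)


# ---------------------------------------------------------------------------
# toy receptor + poses


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _ca_only_structure(coords: np.ndarray, res_ids: Sequence[int],
                       chain_id: str) -> Structure:
    n = coords.shape[0]
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=float)
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    arr.res_name[:] = "GLY"
    arr.chain_id[:] = chain_id
    arr.res_id[:] = np.asarray(res_ids, dtype=int)
    arr.hetero[:] = False
    arr.ins_code[:] = ""
    return Structure(arr, validate=False)


@dataclass
class _ReferenceGeometry:
    ligand: Structure
    receptor: Structure
    complex: Structure
    segment: SegmentSpec
    hotspots: HotspotSet
    groove_direction: np.ndarray  # unit vector, ligand -> receptor side
    segment_centroid: np.ndarray


def _reference_geometry(s: SynthSpec) -> _ReferenceGeometry:
    """Ligand in its reference (bound) placement plus a receptor built
    around it: hot-spot pseudo-residues 3.5 Å off the recognition segment
    along the groove direction, filler residues on a shell behind them."""
    rng_pose = s.rng("pose")
    rng_rec = s.rng("receptor")
    ligand = _build_chain(s, list(s.helix_segments), rng_pose, rng_pose)
    a, b = s.helix_segments[0]
    segment = SegmentSpec(f"{a}-{b}", "A", a, b)
    ca_idx = select_atoms(ligand, segment, atom_set="CA")
    seg_axis = segment_axis(ligand.coords[ca_idx])
    centroid = seg_axis.origin
    ref_dir = seg_axis.direction
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, ref_dir)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    groove = np.cross(ref_dir, helper)
    groove /= np.linalg.norm(groove)

    # anchor hot spots to the segment's interior residues only, so that
    # covalently adjacent flanking residues sit measurably farther from
    # the groove than the planted segment itself
    interior = SegmentSpec(segment.label, segment.chain_id,
                           segment.first_residue + 1,
                           segment.last_residue - 1)
    heavy_idx = select_atoms(ligand, interior, atom_set="heavy")
    seg_coords = ligand.coords[heavy_idx]
    proj = seg_coords @ ref_dir
    order = np.argsort(proj)
    hotspot_ids = s.hotspot_residues
    n_hot = len(hotspot_ids)
    anchors = seg_coords[order[np.linspace(0, len(order) - 1, n_hot,
                                           dtype=int)]]
    hotspot_pos = anchors + groove[None, :] * 3.5

    n_fill = s.receptor_size - n_hot
    if n_fill < 0:
        raise GenerationError("receptor_size smaller than the hot-spot list")
    shell_center = centroid + groove * 12.0
    fillers = []
    lig_coords = ligand.coords
    tries = 0
    while len(fillers) < n_fill:
        tries += 1
        if tries > 200 * max(n_fill, 1):
            raise GenerationError("receptor shell placement failed")
        u = rng_rec.normal(size=3)
        u /= np.linalg.norm(u)
        pos = shell_center + u * rng_rec.uniform(12.0, 20.0)
        if cdist(pos[None], lig_coords).min() < 6.0:
            continue
        if cdist(pos[None], hotspot_pos).min() < 4.5:
            continue
        if fillers and cdist(pos[None], np.array(fillers)).min() < 3.0:
            continue
        fillers.append(pos)
    rec_coords = np.vstack([hotspot_pos] + ([np.array(fillers)]
                                            if fillers else []))
    filler_ids = [i for i in range(1, s.receptor_size + n_hot + 1)
                  if i not in set(hotspot_ids)][:n_fill]
    rec_ids = list(hotspot_ids) + filler_ids
    receptor = _ca_only_structure(rec_coords, rec_ids, chain_id="R")
    complex_ = Structure(receptor.atom_array + ligand.atom_array,
                         validate=False)
    hotspots = HotspotSet(
        residues=tuple(("R", rid) for rid in hotspot_ids),
        min_count=6, cutoff=4.0,
    )
    return _ReferenceGeometry(ligand, receptor, complex_, segment,
                              hotspots, groove, centroid)


def _transform_coords(coords: np.ndarray, R: np.ndarray, pivot: np.ndarray,
                      shift: np.ndarray) -> np.ndarray:
    return (coords - pivot) @ R.T + pivot + shift


def make_pose_set(s: SynthSpec) -> SyntheticPoseSet:
    """Scored pose set around the toy receptor with an exactly planted
    productive subset.

    Productive poses perturb the reference placement by a rotation within
    ``axis_jitter`` and a sub-Å translation, verified to keep ≥ 6 hot-spot
    contacts and an axis angle well under 30°; non-productive poses are
    either remote surface placements (verified ≤ 3 hot-spot contacts) or
    antiparallel groove placements (axis angle ≥ 90°).  Scores rank
    productive poses high on average, with overlap.
    """
    geo = _reference_geometry(s)
    rng_pose = s.rng("pose")
    rng_score = s.rng("score")
    n = s.n_poses
    n_prod = int(round(s.productive_fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng_pose.permutation(n)[:n_prod]] = True

    ref_coords = geo.ligand.coords
    seg_ca = select_atoms(geo.ligand, geo.segment, atom_set="CA")
    ref_axis = segment_axis(ref_coords[seg_ca])
    pivot = geo.segment_centroid
    max_rot = 0.8 * s.axis_jitter

    def productive_pose() -> np.ndarray:
        for _ in range(200):
            u = rng_pose.normal(size=3)
            u /= np.linalg.norm(u)
            R = _rotation_about(u, rng_pose.uniform(0.0, max_rot))
            shift = rng_pose.normal(0.0, 0.3, size=3)
            coords = _transform_coords(ref_coords, R, pivot, shift)
            angle = axis_angle(segment_axis(coords[seg_ca]), ref_axis)
            if angle >= min(s.axis_jitter, 25.0):
                continue
            n_hot = count_hotspot_contacts(
                geo.receptor, geo.ligand, coords, geo.segment, geo.hotspots
            )
            if n_hot >= geo.hotspots.min_count:
                return coords
        raise GenerationError("productive pose placement failed")

    def remote_pose() -> np.ndarray:
        for _ in range(200):
            u = rng_pose.normal(size=3)
            u /= np.linalg.norm(u)
            R = _rotation_about(u, rng_pose.uniform(0.0, 180.0))
            v = rng_pose.normal(size=3)
            v /= np.linalg.norm(v)
            shift = v * rng_pose.uniform(15.0, 30.0)
            coords = _transform_coords(ref_coords, R, pivot, shift)
            n_hot = count_hotspot_contacts(
                geo.receptor, geo.ligand, coords, geo.segment, geo.hotspots
            )
            if n_hot <= 3:
                return coords
        raise GenerationError("remote pose placement failed")

    def antiparallel_pose() -> np.ndarray:
        for _ in range(200):
            R0 = _rotation_about(geo.groove_direction, 180.0)
            u = rng_pose.normal(size=3)
            u /= np.linalg.norm(u)
            R = _rotation_about(u, rng_pose.uniform(0.0, 5.0)) @ R0
            shift = rng_pose.normal(0.0, 0.3, size=3)
            coords = _transform_coords(ref_coords, R, pivot, shift)
            angle = axis_angle(segment_axis(coords[seg_ca]), ref_axis)
            if angle >= 90.0:
                return coords
        raise GenerationError("antiparallel pose placement failed")

    coords_list = []
    for i in range(n):
        if mask[i]:
            coords_list.append(productive_pose())
        elif rng_pose.random() < 0.3:
            coords_list.append(antiparallel_pose())
        else:
            coords_list.append(remote_pose())

    scores = np.where(
        mask,
        rng_score.normal(5.0, 1.0, size=n),
        rng_score.normal(0.0, 1.5, size=n),
    )
    pose_set = PoseSet(
        receptor=geo.receptor,
        ligand_topology=geo.ligand,
        ligand_coordinates=np.stack(coords_list),
        scores=scores,
        labels=[f"pose{i + 1:04d}" for i in range(n)],
    )
    criteria = ProductiveCriteria(
        segment=geo.segment,
        hotspots=geo.hotspots,
        max_axis_angle=30.0,
        reference_axis=ref_axis,
        reference_complex=geo.complex,
        reference_segment=geo.segment,
    )
    return SyntheticPoseSet(
        pose_set=pose_set,
        productive_mask=mask,
        hotspots=geo.hotspots,
        criteria=criteria,
        recognition_segment=geo.segment,
        reference_complex=geo.complex,
    )


def make_distance_series(s: SynthSpec, n_frames: int | None = None,
                         mean: float = 0.0) -> np.ndarray:
    """Planted first-order autoregressive (discretized Ornstein–Uhlenbeck)
    series: relaxation ``ou_relaxation`` frames, stationary standard
    deviation ``traj_noise_amplitude``.  Standalone so long series can be
    generated without materialising trajectory frames."""
    rng = s.rng("traj")
    T = n_frames if n_frames is not None else s.trajectory_length
    tau = s.ou_relaxation
    phi = np.exp(-1.0 / tau)
    x = np.empty(T)
    x[0] = rng.normal(0.0, 1.0)
    innov = rng.normal(0.0, 1.0, size=T - 1)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + np.sqrt(1 - phi**2) * innov[t - 1]
    return mean + x * s.traj_noise_amplitude


def make_complex_trajectory(s: SynthSpec) -> SyntheticTrajectory:
    """Bound/unbound trajectory of the toy complex.

    The receptor is static; the ligand translates rigidly along the groove
    normal so that the recognition segment's distance to the receptor
    follows a first-order autoregressive (discretized Ornstein–Uhlenbeck)
    process with relaxation ``ou_relaxation`` frames and stationary
    amplitude ``traj_noise_amplitude`` Å.  The planted AR series and
    per-frame bound labels (realized minimal distance < 4 Å) are returned
    as ground truth.
    """
    geo = _reference_geometry(s)
    T = s.trajectory_length
    seg_heavy = select_atoms(geo.ligand, geo.segment, atom_set="heavy")
    rec_heavy = ~geo.receptor.is_hydrogen
    d0 = float(cdist(geo.ligand.coords[seg_heavy],
                     geo.receptor.coords[rec_heavy]).min())
    distance = make_distance_series(s, n_frames=T, mean=d0)

    n_rec = len(geo.receptor)
    topo = geo.complex
    frames = np.empty((T, len(topo), 3))
    offsets = np.maximum(distance - d0, 0.0)
    bound = np.empty(T, dtype=bool)
    away = -geo.groove_direction
    for t in range(T):
        frames[t, :n_rec] = geo.receptor.coords
        lig = geo.ligand.coords + away * offsets[t]
        frames[t, n_rec:] = lig
        bound[t] = cdist(lig[seg_heavy],
                         geo.receptor.coords[rec_heavy]).min() < 4.0
    traj = Trajectory(topology=topo, frames=frames, dt=s.dt_ps)
    return SyntheticTrajectory(
        trajectory=traj,
        bound=bound,
        distance_series=distance,
        ligand_segment=geo.segment,
        receptor_chain="R",
        hotspots=geo.hotspots,
    )
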