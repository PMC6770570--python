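"""Rigid-body geometry primitives.

Superposition is least-squares (Kabsch, SVD with reflection correction so
chirality is preserved), segment axes are dominant principal directions
oriented N-terminus → C-terminus, and helix assignment is a documented
backbone-dihedral stand-in for a full secondary-structure program.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import biotite.structure as bst

from .errors import DegenerateGeometryError
from .structio import Structure

__all__ = [
    "RigidTransform",
    "OrientedAxis",
    "superpose",
    "rmsd_no_fit",
    "segment_axis",
    "axis_angle",
    "radius_of_gyration",
    "backbone_dihedrals",
    "assign_helix",
    "atomic_masses",
]

#: Standard atomic masses (u) for mass-weighted radii of gyration.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
}
_DEFAULT_MASS = 12.011

#: Provisional helix window (degrees) and minimum run length approximating
#: secondary-structure assignment on canonical geometry.
HELIX_PHI_RANGE = (-100.0, -30.0)
HELIX_PSI_RANGE = (-67.0, -7.0)
HELIX_MIN_RUN = 4


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: ``x -> R x + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class OrientedAxis:
    """A unit direction with an origin; sign fixed N-terminus → C-terminus."""

    direction: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")

    def negate(self) -> "OrientedAxis":
        return OrientedAxis(-np.asarray(self.direction), self.origin)


def _as_points(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be (n, 3), got {x.shape}")
    return x


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper-rotation transform attaining the global minimum RMSD
    and that RMSD (Å).  Reflections are rejected by construction, so
    chirality is preserved.
    """
    X = _as_points(mobile, "mobile")
    Y = _as_points(reference, "reference")
    if X.shape != Y.shape:
        raise ValueError(f"point counts differ: {X.shape[0]} vs {Y.shape[0]}")
    n = X.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs >= 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cm = w @ X
    cr = w @ Y
    Xc = X - cm
    Yc = Y - cr
    for pts, name in ((Xc, "mobile"), (Yc, "reference")):
        sv = np.linalg.svd(pts * np.sqrt(w)[:, None], compute_uv=False)
        if sv[1] < 1e-8 * max(1.0, sv[0]):
            raise DegenerateGeometryError(
                f"{name} points are collinear or coincident"
            )

    C = (Xc * w[:, None]).T @ Yc
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    diff = transform.apply(X) - Y
    rmsd = float(np.sqrt(np.sum(w * np.sum(diff**2, axis=1))))
    return transform, rmsd


def rmsd_no_fit(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two coordinate sets without any superposition."""
    A = _as_points(a, "a")
    B = _as_points(b, "b")
    if A.shape != B.shape:
        raise ValueError(f"point counts differ: {A.shape[0]} vs {B.shape[0]}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def segment_axis(ca_coords: np.ndarray) -> OrientedAxis:
    """Principal axis of an ordered CA trace, oriented N → C.

    The direction is the dominant singular direction of the centered
    coordinates; its sign is flipped if needed so that it points from the
    first toward the last residue.  The paper-style angle filter needs this
    orientation: a pure inertia axis could not distinguish a helix bound
    parallel to the reference from one bound antiparallel.
    """
    X = _as_points(ca_coords, "ca_coords")
    if X.shape[0] < 4:
        raise DegenerateGeometryError("segment axis needs >= 4 points")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[0] < 1e-8:
        raise DegenerateGeometryError("all points coincident")
    direction = Vt[0]
    if np.dot(direction, X[-1] - X[0]) < 0:
        direction = -direction
    return OrientedAxis(direction / np.linalg.norm(direction), centroid)


def axis_angle(a: OrientedAxis, b: OrientedAxis) -> float:
    """Angle between oriented axes in degrees, in [0, 180].

    Deliberately not folded to [0, 90]: an antiparallel placement must read
    ~180° so orientation filters can reject it.  Computed as
    atan2(|u×v|, u·v), which stays accurate near 0° and 180° where the
    arccos form loses precision.
    """
    u = np.asarray(a.direction, dtype=float)
    v = np.asarray(b.direction, dtype=float)
    return float(np.degrees(
        np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))
    ))


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """(Mass-weighted) root-mean-square distance from the centroid, Å."""
    X = _as_points(coords, "coords")
    if X.shape[0] < 1:
        raise ValueError("need at least one point")
    if masses is None:
        w = np.ones(X.shape[0])
    else:
        w = np.asarray(masses, dtype=float)
        if w.shape != (X.shape[0],):
            raise ValueError("one mass per point required")
        if np.any(w <= 0):
            raise ValueError("masses must be positive")
    w = w / w.sum()
    centroid = w @ X
    return float(np.sqrt(np.sum(w * np.sum((X - centroid) ** 2, axis=1))))


def atomic_masses(s: Structure) -> np.ndarray:
    """Per-atom standard masses from the element field."""
    elems = np.char.upper(np.char.strip(s.elements))
    return np.array([ATOMIC_MASSES.get(e, _DEFAULT_MASS) for e in elems])


def backbone_dihedrals(
    s: Structure, chain_id: str | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue (φ, ψ) in degrees for one chain.

    Follows the IUPAC convention φ = C(i−1)–N(i)–CA(i)–C(i),
    ψ = N(i)–CA(i)–C(i)–N(i+1).  Residues missing a neighbour (termini,
    chain breaks in author numbering, missing backbone atoms) get NaN.
    Returns (residue_numbers, phi, psi).
    """
    arr = s.atom_array
    mask = ~arr.hetero
    if chain_id is not None:
        mask &= arr.chain_id == chain_id
    res_ids = np.unique(arr.res_id[mask])
    pos: dict[tuple[int, str], np.ndarray] = {}
    for name in ("N", "CA", "C"):
        sel = mask & (arr.atom_name == name)
        for rid, xyz in zip(arr.res_id[sel], arr.coord[sel]):
            pos[(int(rid), name)] = xyz

    phi = np.full(len(res_ids), np.nan)
    psi = np.full(len(res_ids), np.nan)
    for k, rid in enumerate(res_ids):
        rid = int(rid)
        n, ca, c = pos.get((rid, "N")), pos.get((rid, "CA")), pos.get((rid, "C"))
        if n is None or ca is None or c is None:
            continue
        c_prev = pos.get((rid - 1, "C"))
        if c_prev is not None:
            phi[k] = np.degrees(bst.dihedral(c_prev, n, ca, c))
        n_next = pos.get((rid + 1, "N"))
        if n_next is not None:
            psi[k] = np.degrees(bst.dihedral(n, ca, c, n_next))
    return res_ids, phi, psi


def assign_helix(
    phi_psi: Sequence[tuple[float, float]] | np.ndarray,
    phi_range: tuple[float, float] = HELIX_PHI_RANGE,
    psi_range: tuple[float, float] = HELIX_PSI_RANGE,
    min_run: int = HELIX_MIN_RUN,
) -> np.ndarray:
    """Boolean helix assignment from per-residue (φ, ψ) pairs in degrees.

    A residue is provisionally helical iff φ and ψ both fall in the helical
    window; the final assignment keeps only runs of ``min_run`` or more
    consecutive provisional residues.  Missing dihedrals (NaN) are
    non-helical.
    """
    pp = np.asarray(phi_psi, dtype=float)
    if pp.ndim != 2 or pp.shape[1] != 2:
        raise ValueError("phi_psi must be (n, 2)")
    phi, psi = pp[:, 0], pp[:, 1]
    with np.errstate(invalid="ignore"):
        provisional = (
            (phi >= phi_range[0]) & (phi <= phi_range[1])
            & (psi >= psi_range[0]) & (psi <= psi_range[1])
        )
    provisional &= np.isfinite(phi) & np.isfinite(psi)
    helical = np.zeros(len(provisional), dtype=bool)
    i = 0
    n = len(provisional)
    while i < n:
        if provisional[i]:
            j = i
            while j < n and provisional[j]:
                j += 1
            if j - i >= min_run:
                helical[i:j] = True
            i = j
        else:
            i += 1
    return helical
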