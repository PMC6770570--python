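"""PDB input/output and the atom/residue/chain data model.

The in-memory container wraps a :class:`biotite.structure.AtomArray`; all
other modules address atoms through :func:`select_atoms` and
:class:`SegmentSpec`, so residue numbering stays in the construct's own
author numbering throughout (full-protein offsets are metadata only and are
never applied silently).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite import InvalidFileError
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EmptySelectionError,
    ParseError,
    TopologyMismatchError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "ConformerEnsemble",
    "SegmentSpec",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "read_score_table",
    "write_score_table",
]

AtomSet = Literal["CA", "mainchain", "heavy", "all"]

_MAINCHAIN = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomRecord:
    """One atom, in author numbering and Å coordinates."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom serial {self.serial}")


def _is_hydrogen(element: np.ndarray, atom_name: np.ndarray) -> np.ndarray:
    """Hydrogen flag from the element field, falling back to the atom name.

    PDB names like ``1HB`` put the element letter after a digit, so the
    fallback strips leading digits before looking at the first character.
    """
    elem = np.char.upper(np.char.strip(element))
    is_h = (elem == "H") | (elem == "D")
    blank = elem == ""
    if np.any(blank):
        stripped = np.array(
            [re.sub(r"^\d+", "", n.strip()) for n in atom_name[blank]]
        )
        first = np.array([s[:1].upper() for s in stripped])
        is_h[np.where(blank)[0]] = first == "H"
    return is_h


class Structure:
    """A single structural model: an ordered collection of atoms.

    Iteration order is stable and equal to file order.  After altloc
    resolution, ``(chain_id, residue_number, ins_code, atom_name)`` is
    unique within the model.
    """

    def __init__(self, atom_array: bst.AtomArray, model_id: int = 1,
                 validate: bool = True):
        if "occupancy" not in atom_array.get_annotation_categories():
            atom_array.set_annotation(
                "occupancy", np.ones(atom_array.array_length())
            )
        self.atom_array = atom_array
        self.model_id = int(model_id)
        if validate:
            self._check_unique()

    def _check_unique(self) -> None:
        keys = list(
            zip(
                self.atom_array.chain_id,
                self.atom_array.res_id,
                self.atom_array.ins_code,
                self.atom_array.atom_name,
            )
        )
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise TopologyMismatchError(
                f"duplicate atom after altloc resolution: chain {dup[0]!r} "
                f"residue {dup[1]}{dup[2]} atom {dup[3]!r}"
            )

    # -- vectorised views -------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates in Å."""
        return self.atom_array.coord

    @property
    def chain_ids(self) -> np.ndarray:
        return self.atom_array.chain_id

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.atom_array.res_id

    @property
    def residue_names(self) -> np.ndarray:
        return self.atom_array.res_name

    @property
    def atom_names(self) -> np.ndarray:
        return self.atom_array.atom_name

    @property
    def elements(self) -> np.ndarray:
        return self.atom_array.element

    @property
    def is_hetero(self) -> np.ndarray:
        return self.atom_array.hetero

    @property
    def is_hydrogen(self) -> np.ndarray:
        return _is_hydrogen(self.elements, self.atom_names)

    def __len__(self) -> int:
        return self.atom_array.array_length()

    def atoms(self) -> Iterator[AtomRecord]:
        a = self.atom_array
        for i in range(len(self)):
            yield AtomRecord(
                serial=i + 1,
                atom_name=str(a.atom_name[i]),
                element=str(a.element[i]),
                residue_name=str(a.res_name[i]),
                residue_number=int(a.res_id[i]),
                chain_id=str(a.chain_id[i]),
                position=a.coord[i].copy(),
                occupancy=float(a.occupancy[i]),
            )

    def subset(self, indices: np.ndarray) -> "Structure":
        return Structure(self.atom_array[np.asarray(indices)],
                         model_id=self.model_id, validate=False)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        arr = self.atom_array.copy()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != arr.coord.shape:
            raise TopologyMismatchError(
                f"coordinate shape {coords.shape} does not match "
                f"topology shape {arr.coord.shape}"
            )
        arr.coord = coords
        return Structure(arr, model_id=self.model_id, validate=False)

    def copy(self) -> "Structure":
        return Structure(self.atom_array.copy(), self.model_id, validate=False)


@dataclass
class ConformerEnsemble:
    """Shared topology plus M coordinate sets (Å)."""

    topology: Structure
    coordinates: np.ndarray  # (M, n_atoms, 3)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TopologyMismatchError(
                f"coordinates must be (M, n_atoms, 3), got "
                f"{self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != len(self.topology):
            raise TopologyMismatchError(
                f"{self.coordinates.shape[1]} coordinates per conformer but "
                f"topology has {len(self.topology)} atoms"
            )
        if self.n_conformers < 1:
            raise TopologyMismatchError("ensemble needs at least 1 conformer")
        if not self.labels:
            self.labels = [str(i + 1) for i in range(self.n_conformers)]
        if len(self.labels) != self.n_conformers:
            raise TopologyMismatchError("one label per conformer required")

    @property
    def n_conformers(self) -> int:
        return self.coordinates.shape[0]

    def conformer(self, i: int) -> Structure:
        return self.topology.with_coords(self.coordinates[i])


_SEGMENT_RE = re.compile(
    r"^(?:(?P<chain>[A-Za-z0-9]):)?(?P<first>\d+)"
    r"(?:-(?P<last>\d+)|[A-Z]+(?P<last2>\d+))$"
)


@dataclass(frozen=True)
class SegmentSpec:
    """A named inclusive residue range on one chain (author numbering)."""

    label: str
    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError(
                f"segment {self.label!r}: first_residue > last_residue"
            )

    @classmethod
    def from_string(cls, text: str, chain_id: str = "A") -> "SegmentSpec":
        """Parse ``"9-18"``, ``"A:9-18"`` or sequence-tagged ``"22LKKV25"``."""
        m = _SEGMENT_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse segment spec {text!r}")
        chain = m.group("chain") or chain_id
        first = int(m.group("first"))
        last = int(m.group("last") or m.group("last2"))
        return cls(label=text.strip(), chain_id=chain,
                   first_residue=first, last_residue=last)

    def residue_numbers(self) -> range:
        return range(self.first_residue, self.last_residue + 1)


def select_atoms(
    s: Structure,
    segment: SegmentSpec,
    atom_set: AtomSet = "heavy",
    include_hetero: bool = False,
) -> np.ndarray:
    """Indices (file order) of the segment's atoms for the given atom set.

    ``mainchain`` is N/CA/C/O; ``heavy`` is every non-hydrogen atom.
    Residues carrying an insertion code are excluded from ranges (with a
    warning), since author ranges address insertion-free numbering.
    """
    mask = (
        (s.chain_ids == segment.chain_id)
        & (s.residue_numbers >= segment.first_residue)
        & (s.residue_numbers <= segment.last_residue)
    )
    inscoded = mask & (np.char.strip(s.atom_array.ins_code) != "")
    if np.any(inscoded):
        warnings.warn(
            f"segment {segment.label!r}: excluding "
            f"{len(set(s.residue_numbers[inscoded]))} insertion-coded "
            "residue(s) from the range",
            stacklevel=2,
        )
        mask &= ~inscoded
    if not include_hetero:
        mask &= ~s.is_hetero
    if atom_set == "CA":
        mask &= s.atom_names == "CA"
    elif atom_set == "mainchain":
        mask &= np.isin(s.atom_names, _MAINCHAIN)
    elif atom_set == "heavy":
        mask &= ~s.is_hydrogen
    elif atom_set != "all":
        raise ValueError(f"unknown atom_set {atom_set!r}")
    indices = np.where(mask)[0]
    if indices.size == 0:
        raise EmptySelectionError(
            f"segment {segment.label!r} (chain {segment.chain_id!r}, residues "
            f"{segment.first_residue}-{segment.last_residue}, "
            f"atom_set={atom_set}) selects no atoms"
        )
    return indices


def _diagnose_parse_failure(path: Path) -> str | None:
    """Locate a malformed fixed-width coordinate field, for error reporting."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    f = line[lo:hi].strip()
                    try:
                        float(f) if f else None
                    except ValueError:
                        return (
                            f"line {lineno}: malformed coordinate field "
                            f"{f!r} in columns {lo + 1}-{hi}"
                        )
    return None


def read_pdb(
    path: str | Path,
    model_policy: Literal["first", "all"] = "first",
) -> Structure | ConformerEnsemble:
    """Read a PDB file into a :class:`Structure` or, for ``model_policy="all"``,
    a :class:`ConformerEnsemble` (one conformer per MODEL block).

    Altlocs are resolved to the highest-occupancy location (ties: first
    occurrence).  Hydrogens are retained; selections flag them out.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(path)
    except Exception as exc:  # biotite raises plain ValueError subclasses
        detail = _diagnose_parse_failure(path)
        raise ParseError(detail or f"{path}: {exc}") from exc

    try:
        if model_policy == "first":
            arr = pdb.get_structure(
                model=1, altloc="occupancy", extra_fields=["occupancy"]
            )
            return Structure(arr, model_id=1)
        if model_policy != "all":
            raise ValueError(f"unknown model_policy {model_policy!r}")
        stack = pdb.get_structure(altloc="occupancy",
                                  extra_fields=["occupancy"])
    except InvalidFileError as exc:
        if "model" in str(exc).lower():
            raise TopologyMismatchError(
                f"{path}: models differ in atom count ({exc})"
            ) from exc
        detail = _diagnose_parse_failure(path)
        raise ParseError(detail or f"{path}: {exc}") from exc
    except ValueError as exc:
        detail = _diagnose_parse_failure(path)
        if detail is not None:
            raise ParseError(detail) from exc
        raise
    if stack.array_length() == 0:
        raise ParseError(f"{path}: no ATOM records")
    topo = Structure(stack[0], model_id=1)
    return ConformerEnsemble(
        topology=topo,
        coordinates=stack.coord.copy(),
        labels=[str(i + 1) for i in range(stack.stack_depth())],
    )


def write_pdb(obj: Structure | ConformerEnsemble, path: str | Path) -> None:
    """Write a single-model (Structure) or multi-model (ensemble) PDB file."""
    pdb = PDBFile()
    if isinstance(obj, Structure):
        pdb.set_structure(obj.atom_array)
    else:
        stack = bst.stack(
            [obj.topology.with_coords(c).atom_array for c in obj.coordinates]
        )
        pdb.set_structure(stack)
    pdb.write(str(path))


def read_score_table(path: str | Path) -> pd.Series:
    """Read a 2-column (pose label, score) delimited sidecar table."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["label", "score"], dtype={"label": str})
    if df["score"].isna().any() or not np.all(np.isfinite(df["score"])):
        raise ParseError(f"{path}: non-numeric or non-finite score values")
    return pd.Series(df["score"].values, index=df["label"].values,
                     name="score")


def write_score_table(scores: pd.Series | Sequence[float],
                      path: str | Path,
                      labels: Sequence[str] | None = None) -> None:
    if not isinstance(scores, pd.Series):
        if labels is None:
            labels = [str(i + 1) for i in range(len(scores))]
        scores = pd.Series(list(scores), index=list(labels))
    with open(path, "w") as fh:
        for label, score in scores.items():
            fh.write(f"{label}\t{score:.6f}\n")
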