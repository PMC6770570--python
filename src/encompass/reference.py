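"""Accession-based reference checks against deposited crystal structures.

The dimeric reference complex (PDB 3M3N) carries two actin chains whose
fold should superpose closely onto the monomeric reference actin (PDB
2VCP); the shared-residue CA RMSD of each 3M3N chain onto the 2VCP actin
is the deterministic sanity check for the superposition machinery.  The
coordinate files are not bundled: point these functions at local copies,
or use :func:`fetch_entries` on a machine with RCSB access.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .prodfilter import receptor_fit_transform
from .structio import Structure, read_pdb

__all__ = ["chain_ca_rmsd", "actin_chain_rmsd_report", "fetch_entries"]


def _single_chain(s: Structure, chain_id: str) -> Structure:
    idx = np.where((s.chain_ids == chain_id) & ~s.is_hetero)[0]
    if idx.size == 0:
        raise ValueError(f"chain {chain_id!r} not found")
    return s.subset(idx)


def _largest_chain_id(s: Structure) -> str:
    chains, counts = np.unique(s.chain_ids[~s.is_hetero], return_counts=True)
    return str(chains[np.argmax(counts)])


def chain_ca_rmsd(
    mobile: Structure,
    reference: Structure,
    mobile_chain: str,
    reference_chain: str,
    exclude_termini: int = 0,
) -> tuple[float, int]:
    """CA RMSD of one chain onto another over shared residue numbers.

    Both chains are relabelled to a common chain id so the shared set is
    the intersection of author residue numbers carrying CA atoms;
    ``exclude_termini`` trims that many residues from each end of the
    shared set (the deposited termini are often flexible).  Returns
    (rmsd_Å, n_shared_residues).
    """
    mob = _single_chain(mobile, mobile_chain).copy()
    ref = _single_chain(reference, reference_chain).copy()
    mob.atom_array.chain_id[:] = "X"
    ref.atom_array.chain_id[:] = "X"
    if exclude_termini:
        shared = sorted(
            set(mob.residue_numbers[mob.atom_names == "CA"])
            & set(ref.residue_numbers[ref.atom_names == "CA"])
        )
        keep = shared[exclude_termini:-exclude_termini or None]
        for s in (mob, ref):
            idx = np.where(np.isin(s.residue_numbers, keep))[0]
            s.atom_array = s.atom_array[idx]
    _, rmsd, n_shared = receptor_fit_transform(mob, ref)
    return rmsd, n_shared


def actin_chain_rmsd_report(
    path_2vcp: str | Path,
    path_3m3n: str | Path,
    reference_chain: str | None = None,
    mobile_chains: tuple[str, str] = ("A", "B"),
    exclude_termini: int = 0,
) -> pd.DataFrame:
    """Shared-residue CA RMSD of each 3M3N actin chain onto the 2VCP actin.

    The 2VCP actin chain defaults to the largest chain in the file (the
    actin; the co-crystallized peptide chain is much shorter).
    """
    ref = read_pdb(path_2vcp, model_policy="first")
    mob = read_pdb(path_3m3n, model_policy="first")
    ref_chain = reference_chain or _largest_chain_id(ref)
    rows = []
    for chain in mobile_chains:
        rmsd, n = chain_ca_rmsd(mob, ref, chain, ref_chain,
                                exclude_termini=exclude_termini)
        rows.append({"mobile_chain": chain, "reference_chain": ref_chain,
                     "ca_rmsd": rmsd, "n_shared_residues": n})
    return pd.DataFrame(rows)


def fetch_entries(directory: str | Path,
                  pdb_ids: tuple[str, ...] = ("2VCP", "3M3N")) -> list[Path]:
    """Download the reference entries from RCSB (requires network)."""
    from biotite.database.rcsb import fetch

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [Path(fetch(pdb_id, "pdb", str(directory)))
            for pdb_id in pdb_ids]
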