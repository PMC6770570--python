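"""Trajectory analyses: receptor-fit RMSD traces, minimal-distance traces,
transient contact probabilities, and autocorrelation relaxation times.

Frames are assumed equally spaced; the time step is user-supplied (PDB
frames carry no time).  The relaxation time of a distance series is the
integral of its normalized autocorrelation up to the first non-positive
value — a parameter-free estimator that equals the time constant for an
exponentially decaying ACF — with a single-exponential least-squares fit
offered for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist
from statsmodels.tsa.stattools import acf as _sm_acf

from .dockmap import ContactParams, ContactProfile, _residue_groups, \
    min_residue_distances
from .errors import ConfigurationError, DegenerateSeriesError
from .geomcore import rmsd_no_fit, superpose
from .structio import SegmentSpec, Structure, select_atoms

__all__ = [
    "Trajectory",
    "ACFResult",
    "receptor_fit_rmsd_series",
    "min_distance_series",
    "transient_contact_profile",
    "acf_relaxation",
]


@dataclass
class Trajectory:
    """Shared topology plus T equally spaced frames; dt in ps."""

    topology: Structure
    frames: np.ndarray  # (T, n_atoms, 3)
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ConfigurationError("frames must be (T, n_atoms, 3)")
        if self.frames.shape[0] < 2:
            raise ConfigurationError("a trajectory needs at least 2 frames")
        if self.frames.shape[1] != len(self.topology):
            raise ConfigurationError("frame atom count != topology")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class ACFResult:
    """Normalized autocorrelation and the derived relaxation time (ps)."""

    lags: np.ndarray
    acf: np.ndarray
    relaxation_time: float
    method: Literal["integral", "exponential_fit"]

    def __post_init__(self) -> None:
        if abs(self.acf[0] - 1.0) > 1e-12:
            raise ValueError("acf must be normalized (acf[0] = 1)")
        if not self.relaxation_time > 0:
            raise ValueError("relaxation_time must be positive")


def receptor_fit_rmsd_series(
    t: Trajectory,
    reference: Structure,
    fit_segment: SegmentSpec,
    report_segments: Sequence[SegmentSpec],
) -> pd.DataFrame:
    """Per-frame segment RMSD after fitting each frame on the reference.

    Each frame is superposed onto the reference over the fit segment's CA
    atoms (e.g. the receptor); each report segment's CA RMSD is then taken
    without refit, so reported values measure motion relative to the
    reference frame of the receptor.
    """
    fit_idx_t = select_atoms(t.topology, fit_segment, atom_set="CA")
    fit_idx_r = select_atoms(reference, fit_segment, atom_set="CA")
    if len(fit_idx_t) != len(fit_idx_r):
        raise ConfigurationError(
            f"fit segment {fit_segment.label!r} resolves to different atom "
            "counts on trajectory and reference"
        )
    rep_idx = []
    for seg in report_segments:
        it = select_atoms(t.topology, seg, atom_set="CA")
        ir = select_atoms(reference, seg, atom_set="CA")
        if len(it) != len(ir):
            raise ConfigurationError(
                f"report segment {seg.label!r} resolves to different atom "
                "counts on trajectory and reference"
            )
        rep_idx.append((seg.label, it, ir))

    data: dict[str, np.ndarray] = {"time_ps": t.times}
    series = {label: np.empty(t.n_frames) for label, _, _ in rep_idx}
    ref_fit = reference.coords[fit_idx_r]
    for f in range(t.n_frames):
        transform, _ = superpose(t.frames[f][fit_idx_t], ref_fit)
        for label, it, ir in rep_idx:
            series[label][f] = rmsd_no_fit(
                transform.apply(t.frames[f][it]), reference.coords[ir]
            )
    data.update(series)
    return pd.DataFrame(data)


def min_distance_series(
    t: Trajectory,
    group_a: SegmentSpec,
    group_b: SegmentSpec,
    heavy_only: bool = True,
) -> np.ndarray:
    """Per frame, the minimal atom–atom distance between two disjoint
    atom groups (Å)."""
    atom_set = "heavy" if heavy_only else "all"
    ia = select_atoms(t.topology, group_a, atom_set=atom_set)
    ib = select_atoms(t.topology, group_b, atom_set=atom_set)
    if np.intersect1d(ia, ib).size > 0:
        raise ConfigurationError(
            f"groups {group_a.label!r} and {group_b.label!r} overlap"
        )
    out = np.empty(t.n_frames)
    for f in range(t.n_frames):
        out[f] = cdist(t.frames[f][ia], t.frames[f][ib]).min()
    return out


def transient_contact_profile(
    t: Trajectory,
    ligand_segment: SegmentSpec,
    receptor_chain: str,
    c: ContactParams | None = None,
) -> ContactProfile:
    """Per receptor residue of one chain, the fraction of frames in which
    the ligand segment is in contact with it."""
    c = c or ContactParams()
    seg_idx = select_atoms(
        t.topology, ligand_segment,
        atom_set="heavy" if c.atom_set == "heavy" else "all",
    )
    labels, groups = _residue_groups(t.topology, c.atom_set, c.include_hetero)
    keep = [i for i, (chain, _, _) in enumerate(labels)
            if chain == receptor_chain]
    if not keep:
        raise ConfigurationError(
            f"receptor chain {receptor_chain!r} has no residues"
        )
    labels = [labels[i] for i in keep]
    groups = [groups[i] for i in keep]
    counts = np.zeros(len(labels), dtype=int)
    for f in range(t.n_frames):
        mins = min_residue_distances(groups, t.frames[f],
                                     t.frames[f][seg_idx])
        counts += c.in_contact(mins)
    return ContactProfile(labels, counts / t.n_frames, t.n_frames, c)


def acf_relaxation(
    series: np.ndarray,
    dt: float,
    method: Literal["integral", "exponential_fit"] = "integral",
) -> ACFResult:
    """Normalized autocorrelation of a mean-centered series and its
    relaxation time.

    ``integral``: dt × sum of the ACF from lag 0 up to (not including) the
    first non-positive value.  ``exponential_fit``: least-squares fit of
    ``exp(−τ/τ_r)`` over the same lag range.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise DegenerateSeriesError("series must be 1-D with >= 10 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.var(x) == 0:
        raise DegenerateSeriesError("series has zero variance")
    nlags = x.size - 1
    acf = _sm_acf(x, nlags=nlags, fft=True, adjusted=False)
    nonpos = np.where(acf <= 0)[0]
    m = int(nonpos[0]) if nonpos.size else acf.size
    lags = np.arange(acf.size) * dt
    if method == "integral":
        tau = float(dt * acf[:m].sum())
    elif method == "exponential_fit":
        tau0 = max(dt * acf[:m].sum(), dt)
        (tau,), _ = curve_fit(
            lambda l, t_r: np.exp(-l / t_r),
            lags[:m], acf[:m], p0=[tau0],
            bounds=(1e-12, np.inf), maxfev=10000,
        )
        tau = float(tau)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ACFResult(lags=lags, acf=acf, relaxation_time=tau, method=method)
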