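"""Trajectory metrics: RMSD traces, minimal distances, transient contacts,
autocorrelation relaxation times."""

import numpy as np
import pytest

from encompass.errors import ConfigurationError, DegenerateSeriesError
from encompass.geomcore import rmsd_no_fit, superpose
from encompass.structio import SegmentSpec, select_atoms
from encompass.synthgen import (
    SynthSpec,
    make_complex_trajectory,
    make_distance_series,
)
from encompass.trajanal import (
    Trajectory,
    acf_relaxation,
    min_distance_series,
    receptor_fit_rmsd_series,
    transient_contact_profile,
)

from .oracles import min_distance_loop, random_rotation
from .test_dockmap import ca_structure


def _receptor_segment(topology):
    res = topology.residue_numbers[topology.chain_ids == "R"]
    return SegmentSpec("receptor", "R", int(res.min()), int(res.max()))


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self, short_trajectory):
        topo = short_trajectory.trajectory.topology
        frames = np.repeat(topo.coords[None], 5, axis=0)
        t = Trajectory(topo, frames, dt=20.0)
        series = receptor_fit_rmsd_series(
            t, topo, _receptor_segment(topo),
            [short_trajectory.ligand_segment],
        )
        np.testing.assert_allclose(
            series[short_trajectory.ligand_segment.label], 0.0, atol=1e-9
        )

    def test_per_frame_rigid_motion_removed(self, short_trajectory, rng):
        topo = short_trajectory.trajectory.topology
        frames = np.empty((6, len(topo), 3))
        for f in range(6):
            R = random_rotation(rng)
            frames[f] = topo.coords @ R.T + rng.normal(scale=10.0, size=3)
        t = Trajectory(topo, frames, dt=20.0)
        series = receptor_fit_rmsd_series(
            t, topo, _receptor_segment(topo),
            [short_trajectory.ligand_segment],
        )
        np.testing.assert_allclose(
            series[short_trajectory.ligand_segment.label], 0.0, atol=1e-9
        )

    def test_matches_per_frame_oracle(self, short_trajectory):
        synth = short_trajectory
        t = synth.trajectory
        reference = t.topology.with_coords(t.frames[0])
        fit_seg = _receptor_segment(t.topology)
        series = receptor_fit_rmsd_series(t, reference, fit_seg,
                                          [synth.ligand_segment])
        fit_idx = select_atoms(t.topology, fit_seg, atom_set="CA")
        rep_idx = select_atoms(t.topology, synth.ligand_segment,
                               atom_set="CA")
        for f in range(0, t.n_frames, 17):
            transform, _ = superpose(t.frames[f][fit_idx],
                                     reference.coords[fit_idx])
            expected = rmsd_no_fit(transform.apply(t.frames[f][rep_idx]),
                                   reference.coords[rep_idx])
            assert series[synth.ligand_segment.label][f] == pytest.approx(
                expected, abs=1e-9
            )

    def test_global_rigid_motion_invariance(self, short_trajectory, rng):
        synth = short_trajectory
        t = synth.trajectory
        reference = t.topology.with_coords(t.frames[0])
        fit_seg = _receptor_segment(t.topology)
        base = receptor_fit_rmsd_series(t, reference, fit_seg,
                                        [synth.ligand_segment])
        R = random_rotation(rng)
        shift = rng.normal(scale=15.0, size=3)
        moved = Trajectory(t.topology, t.frames @ R.T + shift, dt=t.dt)
        series = receptor_fit_rmsd_series(moved, reference, fit_seg,
                                          [synth.ligand_segment])
        np.testing.assert_allclose(
            series[synth.ligand_segment.label],
            base[synth.ligand_segment.label], atol=1e-9,
        )


class TestMinDistance:
    def test_constant_separation(self):
        topo = ca_structure(
            [[0.0, 0.0, 0.0], [7.0, 0.0, 0.0]], res_ids=[1, 2]
        )
        frames = np.repeat(topo.coords[None], 4, axis=0)
        t = Trajectory(topo, frames, dt=1.0)
        d = min_distance_series(t, SegmentSpec("a", "A", 1, 1),
                                SegmentSpec("b", "A", 2, 2))
        np.testing.assert_allclose(d, 7.0)

    def test_overlapping_groups_rejected(self, short_trajectory):
        t = short_trajectory.trajectory
        seg = short_trajectory.ligand_segment
        with pytest.raises(ConfigurationError):
            min_distance_series(t, seg, seg)

    def test_matches_pair_oracle(self, short_trajectory):
        synth = short_trajectory
        t = synth.trajectory
        rec_seg = _receptor_segment(t.topology)
        d = min_distance_series(t, synth.ligand_segment, rec_seg)
        ia = select_atoms(t.topology, synth.ligand_segment, atom_set="heavy")
        ib = select_atoms(t.topology, rec_seg, atom_set="heavy")
        for f in range(0, t.n_frames, 23):
            expected = min_distance_loop(t.frames[f][ia], t.frames[f][ib])
            assert d[f] == pytest.approx(expected, abs=1e-12)


class TestTransientContacts:
    def test_all_bound_trajectory_groove_is_one(self):
        synth = make_complex_trajectory(
            SynthSpec(seed=2, trajectory_length=30,
                      traj_noise_amplitude=0.0)
        )
        assert synth.bound.all()
        prof = transient_contact_profile(
            synth.trajectory, synth.ligand_segment, synth.receptor_chain
        )
        frame = prof.to_frame()
        hotspot_ids = {rid for _, rid in synth.hotspots.residues}
        groove = frame[frame.residue_number.isin(hotspot_ids)]
        assert (groove.probability == 1.0).all()

    def test_detached_trajectory_all_zero(self, short_trajectory):
        t = short_trajectory.trajectory
        n_rec = int(np.sum(t.topology.chain_ids == "R"))
        frames = t.frames[:10].copy()
        frames[:, n_rec:] += 500.0  # push the ligand far away
        detached = Trajectory(t.topology, frames, dt=t.dt)
        prof = transient_contact_profile(
            detached, short_trajectory.ligand_segment,
            short_trajectory.receptor_chain,
        )
        assert (prof.probabilities == 0.0).all()

    def test_half_bound_alternation(self, short_trajectory):
        t = short_trajectory.trajectory
        n_rec = int(np.sum(t.topology.chain_ids == "R"))
        bound = t.topology.coords
        frames = np.repeat(bound[None], 10, axis=0)
        frames[1::2, n_rec:] += 500.0
        alt = Trajectory(t.topology, frames, dt=t.dt)
        prof = transient_contact_profile(
            alt, short_trajectory.ligand_segment,
            short_trajectory.receptor_chain,
        )
        frame = prof.to_frame()
        hotspot_ids = {rid for _, rid in short_trajectory.hotspots.residues}
        groove = frame[frame.residue_number.isin(hotspot_ids)]
        assert (groove.probability == 0.5).all()

    def test_concatenation_weighted_average(self, short_trajectory):
        synth = short_trajectory
        t = synth.trajectory
        a = Trajectory(t.topology, t.frames[:30], dt=t.dt)
        b = Trajectory(t.topology, t.frames[30:], dt=t.dt)
        pa = transient_contact_profile(a, synth.ligand_segment, "R")
        pb = transient_contact_profile(b, synth.ligand_segment, "R")
        full = transient_contact_profile(t, synth.ligand_segment, "R")
        weighted = (pa.probabilities * a.n_frames
                    + pb.probabilities * b.n_frames) / t.n_frames
        np.testing.assert_allclose(full.probabilities, weighted, atol=1e-12)


class TestAcfRelaxation:
    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            acf_relaxation(np.ones(100), dt=1.0)

    def test_normalization_and_affine_invariance(self, rng):
        x = rng.normal(size=500).cumsum()
        res = acf_relaxation(x, dt=2.0)
        assert res.acf[0] == pytest.approx(1.0, abs=1e-12)
        scaled = acf_relaxation(3.5 * x - 40.0, dt=2.0)
        np.testing.assert_allclose(res.acf, scaled.acf, atol=1e-9)
        assert res.relaxation_time == pytest.approx(scaled.relaxation_time,
                                                    rel=1e-9)

    def test_white_noise_relaxes_within_two_frames(self, rng):
        x = rng.normal(size=10_000)
        res = acf_relaxation(x, dt=1.0)
        assert res.relaxation_time <= 2.0

    def test_ar1_recovery_fixed_seed(self):
        x = make_distance_series(SynthSpec(seed=4, ou_relaxation=100.0),
                                 n_frames=100_000)
        res = acf_relaxation(x, dt=1.0)
        assert res.relaxation_time == pytest.approx(100.0, rel=0.2)

    def test_exponential_fit_agrees_roughly(self):
        x = make_distance_series(SynthSpec(seed=4, ou_relaxation=100.0),
                                 n_frames=100_000)
        integral = acf_relaxation(x, dt=1.0, method="integral")
        expfit = acf_relaxation(x, dt=1.0, method="exponential_fit")
        assert expfit.relaxation_time == pytest.approx(
            integral.relaxation_time, rel=0.3
        )

    def test_dt_scales_time_units(self):
        x = make_distance_series(SynthSpec(seed=6, ou_relaxation=50.0),
                                 n_frames=20_000)
        tau1 = acf_relaxation(x, dt=1.0).relaxation_time
        tau20 = acf_relaxation(x, dt=20.0).relaxation_time
        assert tau20 == pytest.approx(20.0 * tau1, rel=1e-9)
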