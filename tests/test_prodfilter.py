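"""Productive encounter-complex filtering."""

import dataclasses

import numpy as np
import pytest

from encompass.dockmap import PoseSet
from encompass.prodfilter import (
    HotspotSet,
    count_hotspot_contacts,
    filter_productive,
    rank_by_segment_rmsd,
)
from encompass.structio import SegmentSpec, Structure
from encompass.synthgen import SynthSpec, make_pose_set

from .oracles import hotspot_count_oracle, random_rotation
from .test_dockmap import ca_structure


class TestHotspotCounting:
    def test_exactly_six_of_nine(self):
        # 9 single-atom hot-spot residues along x; segment atoms sit 3.5 Å
        # directly above the first 6 (neighbours are 5.3 Å away)
        rec_coords = [[4.0 * i, 0.0, 0.0] for i in range(9)]
        receptor = ca_structure(rec_coords, chain="R")
        lig_coords = [[4.0 * i, 3.5, 0.0] for i in range(6)]
        ligand = ca_structure(lig_coords)
        h = HotspotSet([("R", i + 1) for i in range(9)], min_count=6)
        seg = SegmentSpec("1-6", "A", 1, 6)
        n = count_hotspot_contacts(receptor, ligand, ligand.coords, seg, h)
        assert n == 6

    def test_remote_segment_zero(self):
        receptor = ca_structure([[0.0, 0.0, 0.0]], chain="R")
        ligand = ca_structure([[50.0, 0.0, 0.0], [54.0, 0.0, 0.0]])
        h = HotspotSet([("R", 1)], min_count=1)
        seg = SegmentSpec("1-2", "A", 1, 2)
        assert count_hotspot_contacts(receptor, ligand, ligand.coords,
                                      seg, h) == 0

    def test_matches_distance_oracle(self, small_pose_data):
        synth = small_pose_data
        p = synth.pose_set
        seg_idx = np.where(
            (p.ligand_topology.chain_ids == "A")
            & (p.ligand_topology.residue_numbers
               >= synth.recognition_segment.first_residue)
            & (p.ligand_topology.residue_numbers
               <= synth.recognition_segment.last_residue)
        )[0]
        for m in range(0, p.n_poses, 5):
            ours = count_hotspot_contacts(
                p.receptor, p.ligand_topology, p.ligand_coordinates[m],
                synth.recognition_segment, synth.hotspots,
            )
            expected = hotspot_count_oracle(
                p.receptor, p.ligand_coordinates[m][seg_idx],
                synth.hotspots.residues, synth.hotspots.cutoff,
            )
            assert ours == expected

    def test_min_count_cannot_exceed_hotspots(self):
        with pytest.raises(Exception):
            HotspotSet([("R", 1), ("R", 2)], min_count=3)


class TestFilterProductive:
    def test_reference_pose_passes_perfectly(self, small_pose_data):
        synth = small_pose_data
        ref_pose = PoseSet(
            receptor=synth.pose_set.receptor,
            ligand_topology=synth.pose_set.ligand_topology,
            ligand_coordinates=synth.pose_set.ligand_topology.coords[None],
            scores=np.array([1.0]),
        )
        report = filter_productive(ref_pose, synth.criteria)
        row = report.table.iloc[0]
        assert row.hotspot_count == len(synth.hotspots.residues)
        assert row.axis_angle_deg == pytest.approx(0.0, abs=1e-6)
        assert row.segment_rmsd == pytest.approx(0.0, abs=1e-6)
        assert row.passes

    def test_antiparallel_pose_fails_on_angle(self, small_pose_data):
        synth = small_pose_data
        report = filter_productive(synth.pose_set, synth.criteria)
        anti = report.table[report.table.axis_angle_deg > 90.0]
        assert len(anti) > 0
        assert not anti.passes.any()

    def test_recovers_planted_mask_exactly(self, small_pose_data):
        synth = small_pose_data
        report = filter_productive(synth.pose_set, synth.criteria)
        np.testing.assert_array_equal(report.table.passes.values,
                                      synth.productive_mask)

    def test_rigid_motion_of_whole_complex_invariant(self, small_pose_data,
                                                     rng):
        """Moving receptor + reference ligand together leaves angle and
        segment RMSD at zero: the receptor fit removes the motion."""
        synth = small_pose_data
        base = synth.pose_set
        for _ in range(3):
            R = random_rotation(rng)
            t = rng.normal(scale=20.0, size=3)
            moved_receptor = Structure(
                base.receptor.atom_array.copy(), validate=False
            )
            moved_receptor.atom_array.coord = base.receptor.coords @ R.T + t
            moved_ligand = base.ligand_topology.coords @ R.T + t
            p = PoseSet(
                receptor=moved_receptor,
                ligand_topology=base.ligand_topology,
                ligand_coordinates=moved_ligand[None],
                scores=np.array([1.0]),
            )
            report = filter_productive(p, synth.criteria)
            row = report.table.iloc[0]
            assert row.axis_angle_deg == pytest.approx(0.0, abs=1e-6)
            assert row.segment_rmsd == pytest.approx(0.0, abs=1e-6)
            assert row.passes

    @pytest.mark.parametrize("angles", [(10.0, 30.0, 60.0)])
    def test_monotone_in_angle_threshold(self, small_pose_data, angles):
        synth = small_pose_data
        sizes = []
        for angle in angles:
            criteria = dataclasses.replace(synth.criteria,
                                           max_axis_angle=angle)
            report = filter_productive(synth.pose_set, criteria)
            sizes.append(int(report.table.passes.sum()))
        assert sizes == sorted(sizes)

    def test_monotone_in_min_count(self, small_pose_data):
        synth = small_pose_data
        sizes = []
        for min_count in (9, 6, 3, 1):
            criteria = dataclasses.replace(
                synth.criteria,
                hotspots=dataclasses.replace(synth.hotspots,
                                             min_count=min_count),
            )
            report = filter_productive(synth.pose_set, criteria)
            sizes.append(int(report.table.passes.sum()))
        assert sizes == sorted(sizes)

    def test_brute_force_equivalence_on_small_set(self, small_pose_data):
        """Pass decisions equal an explicit per-pose evaluation."""
        synth = small_pose_data
        p = synth.pose_set
        report = filter_productive(p, synth.criteria)
        for m in range(p.n_poses):
            n_hot = count_hotspot_contacts(
                p.receptor, p.ligand_topology, p.ligand_coordinates[m],
                synth.recognition_segment, synth.hotspots,
            )
            row = report.table.iloc[m]
            expected = (n_hot >= synth.hotspots.min_count
                        and row.axis_angle_deg < synth.criteria.max_axis_angle)
            assert bool(row.passes) == expected


class TestRanking:
    def _report_with_rmsds(self, small_pose_data):
        synth = small_pose_data
        return filter_productive(synth.pose_set, synth.criteria)

    def test_lowest_rmsd_first(self, small_pose_data):
        report = self._report_with_rmsds(small_pose_data)
        top = rank_by_segment_rmsd(report, 1)
        passing = report.passing
        best = passing.loc[passing.segment_rmsd.idxmin(), "label"]
        assert top == [best]

    def test_matches_sort_oracle(self, small_pose_data):
        report = self._report_with_rmsds(small_pose_data)
        k = 5
        ranked = rank_by_segment_rmsd(report, k)
        passing = report.passing
        expected = list(
            passing.sort_values("segment_rmsd", kind="stable").label.iloc[:k]
        )
        assert ranked == expected

    def test_k_larger_than_passing_warns(self, small_pose_data):
        report = self._report_with_rmsds(small_pose_data)
        n_pass = len(report.passing)
        with pytest.warns(UserWarning):
            ranked = rank_by_segment_rmsd(report, n_pass + 10)
        assert len(ranked) == n_pass


def test_zero_productive_fraction_passes_nothing():
    synth = make_pose_set(
        SynthSpec(seed=21, n_poses=30, productive_fraction=0.0)
    )
    report = filter_productive(synth.pose_set, synth.criteria)
    assert not report.table.passes.any()
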