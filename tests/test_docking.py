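"""Pose RMSD, leader clustering (vs brute-force oracle), geometric filtering,
ΔG selection and the mean−SD nomination threshold."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petscreen.docking import (
    FilterRules,
    Pose,
    ScreenRecord,
    cluster_poses,
    delta_delta_g,
    nominate_candidates,
    pose_filter,
    pose_rmsd,
    poses_from_pdb,
    poses_from_tsv,
    poses_to_pdb,
    poses_to_tsv,
    select_delta_g,
    selection_threshold,
)
from petscreen.synthetic import gen_pose_set, gen_receptor


def leader_cluster_oracle(poses, tol):
    """Independent replay of the leader rule (kept dumb on purpose)."""
    order = sorted(poses, key=lambda p: (p.energy, p.pose_id))
    reps, assignment = [], {}
    for p in order:
        placed = False
        for rep in reps:
            d = np.sqrt(np.mean(np.sum((p.coords - rep.coords) ** 2, axis=1)))
            if d <= tol:
                assignment[p.pose_id] = rep.pose_id
                placed = True
                break
        if not placed:
            reps.append(p)
            assignment[p.pose_id] = p.pose_id
    return assignment


def _pose(pid, coords, energy=-7.0, label="WT"):
    return Pose(pose_id=pid, coords=np.asarray(coords, float), energy=energy,
                variant_label=label)


class TestPoseRMSD:
    def test_identical_poses(self, rng):
        c = rng.normal(size=(6, 3))
        assert pose_rmsd(_pose(0, c), _pose(1, c)) == 0.0

    def test_rigid_translation(self, rng):
        c = rng.normal(size=(6, 3))
        shifted = c + np.array([3.0, 0.0, 0.0])
        assert pose_rmsd(_pose(0, c), _pose(1, shifted)) == pytest.approx(3.0)

    def test_matches_direct_formula(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        direct = np.sqrt(np.sum((a - b) ** 2) / 5)
        assert pose_rmsd(_pose(0, a), _pose(1, b)) == pytest.approx(
            direct, abs=1e-10
        )

    def test_mismatched_atom_counts(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            pose_rmsd(_pose(0, rng.normal(size=(5, 3))),
                      _pose(1, rng.normal(size=(6, 3))))


class TestClusterPoses:
    def test_copies_form_one_cluster(self, rng):
        c = rng.normal(size=(8, 3))
        poses = [_pose(i, c, energy=-7 + 0.1 * i) for i in range(10)]
        clusters = cluster_poses(poses)
        assert len(clusters) == 1
        assert clusters[0].size == 10
        assert clusters[0].representative == 0  # lowest energy

    def test_distant_poses_are_singletons(self, rng):
        c = rng.normal(size=(8, 3))
        poses = [_pose(i, c + 10 * i, energy=-6.0 - i) for i in range(3)]
        clusters = cluster_poses(poses, rmsd_tol=2.0)
        assert [cl.size for cl in clusters] == [1, 1, 1]
        # ordered by representative energy
        energies = [cl.representative_energy for cl in clusters]
        assert energies == sorted(energies)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        poses = [
            _pose(i, rng.uniform(0, 4, size=(5, 3)),
                  energy=float(rng.uniform(-9, -4)))
            for i in range(n)
        ]
        tol = float(rng.uniform(0.5, 3.0))
        clusters = cluster_poses(poses, rmsd_tol=tol)
        oracle = leader_cluster_oracle(poses, tol)
        ours = {
            pid: cl.representative for cl in clusters for pid in cl.members
        }
        assert ours == oracle

    def test_partition_and_tolerance_invariants(self, rng):
        poses, _, _ = gen_pose_set(3, 0.8, 24, seed=5)
        clusters = cluster_poses(poses, rmsd_tol=2.0)
        members = [pid for cl in clusters for pid in cl.members]
        assert sorted(members) == list(range(24))  # partition
        by_id = {p.pose_id: p for p in poses}
        for cl in clusters:
            rep = by_id[cl.representative]
            assert all(
                by_id[m].energy >= rep.energy for m in cl.members
            )
            assert all(
                pose_rmsd(by_id[m], rep) <= 2.0 for m in cl.members
            )

    def test_empty_input(self):
        assert cluster_poses([]) == []


class TestPoseFilter:
    @pytest.fixture
    def receptor(self):
        return gen_receptor(catalytic_xyz=(0.0, 0.0, 0.0))

    @pytest.fixture
    def rules(self):
        return FilterRules(subsites={"I": [87, 119], "II": [238, 280]})

    def _pose_at(self, xyz, n=4):
        # a tight blob of ligand atoms at xyz
        offsets = np.array(
            [[0, 0, 0], [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5]], float
        )[:n]
        return _pose(0, np.asarray(xyz, float) + offsets)

    def test_accept_inside_cutoffs(self, receptor, rules):
        # 3.9 A from OG; spans toward both subsites via generous contact cutoff
        pose = _pose(
            0,
            np.array([[3.9, 0, 0], [5.0, 0, 0], [0, 0, 3.0], [0, 0, 5.5]]),
        )
        ok, reasons = pose_filter(pose, receptor, rules)
        assert ok and reasons == []

    def test_reject_catalytic_distance(self, receptor, rules):
        pose = _pose(0, np.array([[4.1, 0, 0], [6.0, 0, 0],
                                  [0, 0, 4.5], [0, 0, 6.0]]))
        ok, reasons = pose_filter(pose, receptor, rules)
        assert not ok and "catalytic_distance" in reasons

    def test_reject_single_subsite_occupancy(self, receptor, rules):
        # near OG and subsite I, but nowhere near subsite II (z-arm)
        pose = self._pose_at((3.5, 0, 0))
        ok, reasons = pose_filter(pose, receptor, rules)
        assert not ok and reasons == ["subsite_II"]

    def test_missing_catalytic_atom(self, receptor, rules):
        bad = receptor[receptor["name"] != "OG"]
        with pytest.raises(KeyError, match="catalytic"):
            pose_filter(self._pose_at((0, 0, 0)), bad, rules)


class TestSelectDeltaG:
    def test_lowest_energy_representative_wins(self, rng):
        c = rng.normal(size=(5, 3))
        poses = [_pose(0, c, -7.1), _pose(1, c, -6.8)]
        rec = select_delta_g(poses)
        assert rec.delta_g == -7.1 and rec.accepted_pose == 0

    def test_min_over_accepted_clusters(self, rng):
        c = rng.normal(size=(5, 3))
        poses = [_pose(0, c, -7.0), _pose(1, c + 10, -7.5)]
        rec = select_delta_g(poses)
        assert rec.delta_g == -7.5
        assert rec.n_accepted_clusters == 2

    def test_global_minimum_failing_filter_skipped(self):
        receptor = gen_receptor()
        rules = FilterRules(subsites={"I": [87, 119], "II": [238, 280]})
        good = np.array([[3.5, 0, 0], [5.5, 0, 0], [0, 0, 3.0], [0, 0, 5.5]])
        bad = good + np.array([20.0, 0, 0])  # far from OG and subsites
        poses = [_pose(0, bad, -9.0), _pose(1, good, -7.2)]
        rec = select_delta_g(poses, receptor=receptor, rules=rules)
        assert rec.delta_g == -7.2 and rec.accepted_pose == 1

    def test_no_accepted_cluster_flags_record(self):
        receptor = gen_receptor()
        rules = FilterRules(subsites={"I": [87, 119], "II": [238, 280]})
        far = np.full((4, 3), 50.0)
        rec = select_delta_g([_pose(0, far, -8.0)], receptor=receptor,
                             rules=rules)
        assert rec.delta_g is None and rec.reject_reasons

    def test_input_order_invariance(self, rng):
        poses, _, _ = gen_pose_set(3, 0.5, 15, seed=3)
        rec_a = select_delta_g(poses)
        rec_b = select_delta_g(list(reversed(poses)))
        assert rec_a.delta_g == rec_b.delta_g
        assert rec_a.accepted_pose == rec_b.accepted_pose


class TestThresholdAndNomination:
    def test_constant_values(self):
        t = selection_threshold([1.0, 1.0, 1.0])
        assert (t.mean, t.sd, t.cutoff) == (1.0, 0.0, 1.0)

    def test_two_values_closed_form(self):
        t = selection_threshold([0.0, 2.0])
        assert t.mean == pytest.approx(1.0)
        assert t.sd == pytest.approx(np.sqrt(2.0))
        assert t.cutoff == pytest.approx(1.0 - np.sqrt(2.0))

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.normal(size=42)
        t = selection_threshold(vals)
        mean = sum(vals) / 42
        sd = np.sqrt(sum((v - mean) ** 2 for v in vals) / 41)
        assert t.mean == pytest.approx(mean, abs=1e-12)
        assert t.sd == pytest.approx(sd, abs=1e-12)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            selection_threshold([1.0])

    def test_strictly_below_cutoff(self):
        recs = [
            ScreenRecord("A1B", delta_delta_g=-1.0),
            ScreenRecord("C2D", delta_delta_g=0.5),
            ScreenRecord("E3F", delta_delta_g=0.0),
        ]
        t = selection_threshold([0.0, 0.0, 0.0])  # cutoff 0
        hits = nominate_candidates(recs, t)
        assert [r.variant_label for r in hits] == ["A1B"]

    def test_delta_delta_g_arithmetic(self):
        assert delta_delta_g(-7.2, -7.2) == 0.0
        assert delta_delta_g(-8.0, -7.0) == -1.0
        assert delta_delta_g(None, -7.0) is None

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=30),
        st.floats(-3, 3),
    )
    @settings(deadline=None, max_examples=100)
    def test_shift_invariance_of_nomination(self, ddgs, shift):
        from hypothesis import assume

        t0 = selection_threshold(ddgs)
        # exclude floating-point boundary ties with the cutoff
        assume(all(abs(v - t0.cutoff) > 1e-6 for v in ddgs))
        recs = [
            ScreenRecord(f"S{i + 1}A", delta_delta_g=v)
            for i, v in enumerate(ddgs)
        ]
        shifted = [
            ScreenRecord(f"S{i + 1}A", delta_delta_g=v + shift)
            for i, v in enumerate(ddgs)
        ]
        base = nominate_candidates(recs, selection_threshold(ddgs))
        moved = nominate_candidates(
            shifted, selection_threshold([v + shift for v in ddgs])
        )
        assert [r.variant_label for r in base] == [
            r.variant_label for r in moved
        ]


class TestPoseIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        poses, _, _ = gen_pose_set(2, 0.5, 6, seed=9, variant_label="S238C")
        path = tmp_path / "poses.tsv"
        poses_to_tsv(poses, path)
        back = poses_from_tsv(path)
        assert len(back) == 6
        for a, b in zip(poses, back):
            assert a.pose_id == b.pose_id
            assert a.energy == pytest.approx(b.energy)
            assert a.variant_label == b.variant_label
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)

    def test_pdb_roundtrip_energy_remarks(self, tmp_path):
        poses, _, _ = gen_pose_set(2, 0.5, 4, seed=11)
        path = tmp_path / "poses.pdb"
        poses_to_pdb(poses, path)
        back = poses_from_pdb(path)
        assert [p.pose_id for p in back] == [p.pose_id for p in poses]
        for a, b in zip(poses, back):
            assert b.energy == pytest.approx(a.energy, abs=1e-4)
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-3)
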