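"""Snapshot selection, Shrake-Rupley SASA, apolar model, binding-energy
bookkeeping and per-residue decomposition deltas."""

import itertools

import numpy as np
import pandas as pd
import pytest

from petscreen.mmpbsa import (
    APOLAR_CONST,
    APOLAR_GAMMA,
    TERMS,
    EnergyFrame,
    apolar_energy,
    binding_energy,
    frames_from_tsv,
    frames_to_tsv,
    load_radii_table,
    load_reference_binding_table,
    mean_residue_profile,
    per_residue_delta,
    select_snapshots,
    shrake_rupley,
    summarize,
)
from petscreen.synthetic import gen_energy_frames


class TestSelectSnapshots:
    def test_every_second_frame(self):
        idx = select_snapshots(2000, n_select=500)
        assert len(idx) == 500
        assert idx[0] == 1000 and idx[-1] == 1998
        assert set(np.diff(idx)) == {2}

    def test_window_equal_to_selection_identity(self):
        idx = select_snapshots(1000, n_select=500)
        np.testing.assert_array_equal(idx, np.arange(500, 1000))

    def test_small_window_takes_all_with_warning(self):
        with pytest.warns(UserWarning, match="taking all"):
            idx = select_snapshots(100, n_select=500)
        np.testing.assert_array_equal(idx, np.arange(50, 100))

    def test_spacing_uniform_over_small_grid(self):
        # exhaustive: gaps of the selection never differ by more than 1
        for n_frames, n_select in itertools.product(
            range(20, 200, 13), [5, 9, 17, 50]
        ):
            idx = select_snapshots(n_frames, n_select=n_select)
            assert len(idx) == min(n_select, n_frames - n_frames // 2)
            assert idx[0] >= n_frames // 2 and idx[-1] <= n_frames - 1
            assert np.all(np.diff(idx) > 0)
            gaps = np.diff(idx)
            if len(gaps):
                assert gaps.max() - gaps.min() <= 1

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            select_snapshots(100, n_select=10, window=(60, 60))


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        per = shrake_rupley(np.zeros((1, 3)), np.array([1.9]), probe=1.4)
        exact = 4 * np.pi * (1.9 + 1.4) ** 2
        assert per[0] == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        per = shrake_rupley(coords, radii)
        exact = 4 * np.pi * ((1.7 + 1.4) ** 2 + (1.52 + 1.4) ** 2)
        assert per.sum() == pytest.approx(exact, rel=0.01)

    def test_overlapping_pair_vs_numerical_oracle(self):
        # two-sphere SASA has a closed form via spherical caps; evaluate it
        # by fine 1-D quadrature over the polar angle as an independent check
        r1, r2, d, probe = 1.7, 1.52, 2.2, 1.4
        R1, R2 = r1 + probe, r2 + probe

        def accessible_area(Ra, Rb, dist):
            theta = np.linspace(0, np.pi, 200_001)
            ring = 2 * np.pi * Ra**2 * np.sin(theta)
            # point on sphere a at polar angle theta from the a->b axis
            px = Ra * np.cos(theta)
            py = Ra * np.sin(theta)
            outside = (px - dist) ** 2 + py**2 >= Rb**2
            return np.trapezoid(ring * outside, theta)

        oracle = accessible_area(R1, R2, d) + accessible_area(R2, R1, d)
        per = shrake_rupley(
            np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([r1, r2])
        )
        assert per.sum() == pytest.approx(oracle, rel=0.02)

    def test_monotone_decrease_on_approach(self):
        radii = np.array([1.7, 1.7])
        totals = []
        for d in [6.5, 4.0, 2.5, 1.0, 0.2]:
            per = shrake_rupley(
                np.array([[0.0, 0, 0], [d, 0, 0]]), radii
            )
            totals.append(per.sum())
        assert all(a >= b - 1e-6 for a, b in zip(totals, totals[1:]))

    def test_agrees_with_independent_library_implementation(self, rng):
        pytest.importorskip("biotite")
        import biotite.structure as struc

        n = 20
        coords = rng.uniform(0, 8, size=(n, 3))
        radii = np.full(n, 1.7)
        ours = shrake_rupley(coords, radii, probe=1.4, n_sphere_points=960)
        arr = struc.AtomArray(n)
        arr.coord = coords
        arr.atom_name = np.array(["C"] * n, dtype="U6")
        arr.res_id = np.arange(1, n + 1)
        arr.res_name = np.array(["UNK"] * n, dtype="U5")
        arr.chain_id = np.array(["A"] * n, dtype="U4")
        arr.element = np.array(["C"] * n, dtype="U2")
        theirs = struc.sasa(
            arr, probe_radius=1.4, point_number=1000,
            vdw_radii=np.full(n, 1.7),
        )
        assert ours.sum() == pytest.approx(theirs.sum(), rel=0.02)

    def test_missing_radius_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley(np.zeros((1, 3)), np.array([-1.0]))

    def test_radii_table_has_common_elements(self):
        table = load_radii_table()
        assert {"C", "N", "O", "S", "H"} <= set(table)


class TestApolarEnergy:
    def test_zero_sasa_gives_constant(self):
        assert apolar_energy(0.0) == pytest.approx(3.84982)

    def test_hundred_square_angstroms(self):
        assert apolar_energy(100.0) == pytest.approx(6.11760, abs=1e-5)

    def test_linearity_in_sasa(self):
        s = 237.5
        assert apolar_energy(2 * s) - apolar_energy(s) == pytest.approx(
            APOLAR_GAMMA * s
        )

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            apolar_energy(-1.0)


def _frame(idx, deltas, per_residue=None):
    protein = {"vdw": -900.0, "electrostatic": -4200.0, "polar": 1500.0,
               "apolar": 110.0}
    ligand = {"vdw": -40.0, "electrostatic": -120.0, "polar": 90.0,
              "apolar": 12.0}
    complex_ = {t: protein[t] + ligand[t] + deltas[t] for t in TERMS}
    return EnergyFrame(
        frame_index=idx,
        terms={"complex": complex_, "protein": protein, "ligand": ligand},
        per_residue=per_residue,
    )


class TestBindingEnergy:
    def test_zero_when_complex_equals_sum(self):
        f = _frame(0, {t: 0.0 for t in TERMS})
        be = binding_energy(f)
        assert all(be[t] == 0.0 for t in TERMS) and be["total"] == 0.0

    def test_planted_deltas(self):
        f = _frame(0, {"vdw": -10.0, "electrostatic": -5.0, "polar": 7.0,
                       "apolar": -2.0})
        be = binding_energy(f)
        assert be["total"] == pytest.approx(-10.0)

    def test_generated_frames_match_summation_oracle(self):
        frames = gen_energy_frames(
            {"vdw": -160.0, "electrostatic": -32.0, "polar": 94.0,
             "apolar": -20.0},
            {t: 5.0 for t in TERMS},
            n=20, seed=4,
        )
        for f in frames:
            be = binding_energy(f)
            oracle = sum(
                f.terms["complex"][t]
                - f.terms["protein"][t]
                - f.terms["ligand"][t]
                for t in TERMS
            )
            assert be["total"] == pytest.approx(oracle, abs=1e-12)

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            EnergyFrame(
                frame_index=0,
                terms={"complex": {t: 0.0 for t in TERMS},
                       "ligand": {t: 0.0 for t in TERMS}},
            )


class TestSummarize:
    def test_constant_frames(self):
        deltas = {"vdw": -160.0, "electrostatic": -32.0, "polar": 94.0,
                  "apolar": -20.0}
        frames = [_frame(i, deltas) for i in range(5)]
        s = summarize(frames)
        assert s.total_mean == pytest.approx(-118.0)
        assert s.total_sd == 0.0
        assert s.term_mean["vdw"] == pytest.approx(-160.0)

    def test_total_mean_equals_sum_of_term_means(self, rng):
        frames = gen_energy_frames(
            {"vdw": -150.0, "electrostatic": -30.0, "polar": 90.0,
             "apolar": -20.0},
            {t: 10.0 for t in TERMS},
            n=50, seed=2,
        )
        s = summarize(frames)
        assert s.total_mean == pytest.approx(
            sum(s.term_mean.values()), abs=1e-9
        )

    def test_reference_row_terms_sum_to_total(self):
        # published per-term means must reproduce the printed totals
        ref = load_reference_binding_table()
        row = ref[(ref["variant"] == "Q119F") & (ref["replica"] == "r0")]
        total = float(
            row[["vdw_mean", "electrostatic_mean", "polar_mean",
                 "apolar_mean"]].sum(axis=1).iloc[0]
        )
        assert total == float(row["total_mean"].iloc[0]) == -118.0

    def test_gaussian_frames_recover_parameterized_total(self):
        ref = load_reference_binding_table()
        row = ref[(ref["variant"] == "WT") & (ref["replica"] == "r0")].iloc[0]
        means = {t: float(row[f"{t}_mean"]) for t in TERMS}
        sds = {t: float(row[f"{t}_sd"]) for t in TERMS}
        frames = gen_energy_frames(means, sds, n=500, seed=8)
        s = summarize(frames)
        param_total = sum(means.values())
        tol = 3 * np.sqrt(sum(v**2 for v in sds.values())) / np.sqrt(500)
        assert abs(s.total_mean - param_total) < tol

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            summarize([_frame(0, {t: 0.0 for t in TERMS})])


class TestPerResidueDelta:
    def test_identical_profiles_give_zero(self):
        deltas = {t: -10.0 for t in TERMS}
        prof = {1: -20.0, 2: 0.0, 3: -20.0}
        var = [_frame(i, deltas, dict(prof)) for i in range(3)]
        wt = [[_frame(i, deltas, dict(prof)) for i in range(3)]] * 2
        d = per_residue_delta(var, wt)
        assert np.allclose(d.values, 0.0)

    def test_hand_built_three_residue_case(self):
        deltas = {t: 0.0 for t in TERMS}
        var = [_frame(0, deltas, {1: -2.0, 2: 0.0, 3: 1.0})] * 2
        wt_rep = [_frame(0, deltas, {1: -1.0, 2: 0.0, 3: 1.0})] * 2
        d = per_residue_delta(var, [wt_rep, wt_rep])
        assert list(d.values) == [-1.0, 0.0, 0.0]

    def test_residue_mismatch_names_offenders(self):
        deltas = {t: 0.0 for t in TERMS}
        var = [_frame(0, deltas, {1: 0.0, 2: 0.0})] * 2
        wt = [[_frame(0, deltas, {1: 0.0, 3: 0.0})] * 2]
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            per_residue_delta(var, wt)

    def test_decomposition_sums_to_total_per_frame(self):
        frames = gen_energy_frames(
            {"vdw": -150.0, "electrostatic": -30.0, "polar": 90.0,
             "apolar": -20.0},
            {t: 8.0 for t in TERMS},
            n=10, seed=5, residues=range(1, 31),
        )
        for f in frames:
            assert sum(f.per_residue.values()) == pytest.approx(
                binding_energy(f)["total"], abs=1e-9
            )


def test_energy_frame_tsv_roundtrip(tmp_path):
    frames = gen_energy_frames(
        {"vdw": -150.0, "electrostatic": -30.0, "polar": 90.0,
         "apolar": -20.0},
        {t: 8.0 for t in TERMS},
        n=5, seed=6, residues=[1, 2, 3],
    )
    fpath, rpath = tmp_path / "e.tsv", tmp_path / "r.tsv"
    frames_to_tsv(frames, fpath, residue_path=rpath)
    back = frames_from_tsv(fpath, residue_path=rpath)
    assert len(back) == 5
    for a, b in zip(frames, back):
        assert binding_energy(a)["total"] == pytest.approx(
            binding_energy(b)["total"], abs=1e-9
        )
        assert a.per_residue.keys() == b.per_residue.keys()
    profile = mean_residue_profile(back)
    assert len(profile) == 3
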