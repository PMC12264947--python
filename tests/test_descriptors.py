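"""Descriptor oracles: brute-force equivalence, closed forms, invariances."""

import numpy as np
import pytest

import ensembledecomp as ed
from ensembledecomp.errors import (
    DegenerateInputError,
    MissingHydrogenError,
    ParameterError,
    SelectionError,
)
from conftest import make_toy_ensemble


def random_rigid_motion(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(scale=10.0, size=3)


class TestRadiusOfGyration:
    def test_two_equal_mass_atoms_at_unit_offsets(self):
        ens = make_toy_ensemble([[[-1, 0, 0], [1, 0, 0]]], atom_names=["N", "N"])
        assert ed.radius_of_gyration(ens).values == pytest.approx([1.0])

    def test_single_atom_is_zero(self):
        ens = make_toy_ensemble([[[3.0, 4.0, 5.0]]], atom_names=["C"])
        assert ed.radius_of_gyration(ens).values == pytest.approx([0.0])

    @pytest.mark.parametrize("mass_weighted", [True, False])
    def test_matches_double_loop_evaluation(self, rng, mass_weighted):
        coords = rng.normal(scale=4.0, size=(3, 50, 3))
        ens = make_toy_ensemble(coords)
        got = ed.radius_of_gyration(ens, mass_weighted=mass_weighted).values
        w = ens.masses if mass_weighted else np.ones(50)
        for f in range(3):
            centroid = (coords[f] * w[:, None]).sum(0) / w.sum()
            expected = np.sqrt(
                sum(w[i] * np.dot(coords[f, i] - centroid, coords[f, i] - centroid)
                    for i in range(50)) / w.sum()
            )
            assert abs(got[f] - expected) < 1e-10

    def test_zero_weights_rejected(self):
        ens = make_toy_ensemble(np.zeros((1, 2, 3)))
        ens.masses = np.zeros(2)
        with pytest.raises(DegenerateInputError):
            ed.radius_of_gyration(ens)


class TestEndToEnd:
    def test_same_atom_gives_zero(self):
        ens = make_toy_ensemble(np.zeros((2, 1, 3)), atom_names=["N"])
        d = ed.end_to_end_distance(ens, (1, "N"), (1, "N"))
        assert d.values == pytest.approx([0.0, 0.0])

    def test_three_four_five(self):
        ens = make_toy_ensemble(
            [[[0, 0, 0], [3, 4, 0]]], residue_index=[1, 2], atom_names=["N", "C"]
        )
        assert ed.end_to_end_distance(ens).values == pytest.approx([5.0])

    def test_ambiguous_selector_raises(self):
        ens = make_toy_ensemble(np.zeros((1, 2, 3)), residue_index=[1, 1],
                                atom_names=["N", "N"])
        with pytest.raises(SelectionError):
            ed.end_to_end_distance(ens, (1, "N"), (1, "N"))

    def test_extended_chain_is_rodlike(self):
        spec = ed.GeneratorSpec(n_residues=38, n_frames=50, compactness=0.0, seed=5)
        ens, _ = ed.gen_backbone_ensemble(spec)
        rg = ed.radius_of_gyration(ens).values
        ree = ed.end_to_end_distance(ens).values
        assert np.all(ree > rg * np.sqrt(3))


class TestPolymerShape:
    def test_equal_series_give_one(self):
        s = ed.ScalarSeries("Rg", np.array([2.0, 3.0]), "Å")
        t = ed.ScalarSeries("Ree", np.array([2.0, 3.0]), "Å")
        assert ed.polymer_shape(s, t).values == pytest.approx([1.0, 1.0])

    def test_uniform_rod_approaches_twelve(self):
        # n collinear equally spaced points: P_S = 12(n-1)/(n+1) -> 12
        n = 2001
        coords = np.zeros((1, n, 3))
        coords[0, :, 0] = np.arange(n)
        ens = make_toy_ensemble(coords, residue_index=np.r_[1, np.full(n - 2, 2), 3],
                                atom_names=["N"] + ["C"] * (n - 2) + ["C"])
        rg = ed.radius_of_gyration(ens, mass_weighted=False)
        ree = ed.end_to_end_distance(ens, (1, "N"), (3, "C"))
        ps = ed.polymer_shape(rg, ree).values[0]
        assert ps == pytest.approx(12.0 * (n - 1) / (n + 1), rel=1e-10)
        assert ps == pytest.approx(12.0, rel=2e-3)

    def test_elementwise_hand_computation(self, rng):
        rgv = rng.uniform(5, 15, 5)
        reev = rng.uniform(5, 40, 5)
        ps = ed.polymer_shape(ed.ScalarSeries("Rg", rgv, "Å"),
                              ed.ScalarSeries("Ree", reev, "Å")).values
        np.testing.assert_allclose(ps, reev**2 / rgv**2, rtol=1e-12)

    def test_zero_rg_names_frame(self):
        rg = ed.ScalarSeries("Rg", np.array([1.0, 0.0]), "Å")
        ree = ed.ScalarSeries("Ree", np.array([1.0, 1.0]), "Å")
        with pytest.raises(DegenerateInputError, match="1"):
            ed.polymer_shape(rg, ree)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        ens = make_toy_ensemble([[[0.0, 0.0, 0.0]]], atom_names=["C"])
        ens.radii = np.array([1.6])
        total, per_res = ed.sasa_shrake_rupley(ens, probe_radius=1.4)
        expected = 4 * np.pi * 3.0**2
        assert total.values[0] == pytest.approx(expected, rel=0.01)
        assert per_res[0, 0] == pytest.approx(expected, rel=0.01)

    def test_coincident_atoms_fully_buried(self):
        ens = make_toy_ensemble([[[0.0, 0, 0], [0.0, 0, 0]]], atom_names=["C", "C"])
        total, _ = ed.sasa_shrake_rupley(ens)
        assert total.values[0] == 0.0

    def test_against_independent_fine_grid_integration(self, rng):
        coords = rng.normal(scale=2.5, size=(1, 20, 3))
        ens = make_toy_ensemble(coords)
        total, _ = ed.sasa_shrake_rupley(ens, n_sphere_points=960)
        # independent Monte Carlo surface integration, 10^4 points/atom
        radii = ens.radii + 1.4
        mc = 0.0
        for a in range(20):
            pts = rng.normal(size=(10_000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[0, a] + radii[a] * pts
            buried = np.zeros(len(pts), dtype=bool)
            for b in range(20):
                if b == a:
                    continue
                buried |= np.linalg.norm(pts - coords[0, b], axis=1) < radii[b]
            mc += (~buried).mean() * 4 * np.pi * radii[a] ** 2
        assert total.values[0] == pytest.approx(mc, rel=0.02)

    def test_sasa_decreases_as_atoms_approach(self):
        totals = []
        for d in (6.0, 4.0, 3.0, 2.0, 1.0, 0.0):
            ens = make_toy_ensemble([[[0, 0, 0], [d, 0, 0]]], atom_names=["C", "C"])
            totals.append(ed.sasa_shrake_rupley(ens, n_sphere_points=480)[0].values[0])
        assert np.all(np.diff(totals) <= 1e-9)


class TestKabsch:
    def test_identical_frames(self, rng):
        X = rng.normal(size=(10, 3))
        R, t, rmsd = ed.kabsch_superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed(self, rng):
        X = rng.normal(size=(12, 3))
        Q, t = random_rigid_motion(rng)
        _, _, rmsd = ed.kabsch_superpose(X, X @ Q.T + t)
        assert rmsd < 1e-10

    def test_optimal_among_random_rotations(self, rng):
        X = rng.normal(size=(15, 3))
        Y = X + rng.normal(scale=0.5, size=(15, 3))
        _, _, best = ed.kabsch_superpose(X, Y)
        Yc = Y - Y.mean(0)
        Xc = X - X.mean(0)
        for _ in range(100):
            Q, _ = random_rigid_motion(rng)
            rmsd = np.sqrt(np.mean(np.sum((Yc @ Q.T - Xc) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_collinear_subset_rejected(self):
        X = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateInputError):
            ed.kabsch_superpose(X, X + 1.0)


class TestRmsf:
    def test_identical_frames_zero(self, small_ensemble):
        ens, _ = small_ensemble
        frozen = make_toy_ensemble(
            np.repeat(ens.coords[:1], 5, axis=0), ens.residue_index, ens.atom_names
        )
        prof = ed.rmsf(frozen)
        assert np.abs(prof.values).max() < 1e-10

    def test_single_frame_rejected(self, small_ensemble):
        ens, _ = small_ensemble
        with pytest.raises(ParameterError):
            ed.rmsf(ens.subset_frames(np.array([0])))

    def test_planted_jitter_recovers_sigma_sqrt3(self, rng):
        # 3 fixed backbone-named residues anchor the fit; residue 4's O jitters
        base = np.array(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0], [2, 2, 2.0]]
        )
        sigma = 0.4
        coords = np.repeat(base[None], 2000, axis=0)
        coords[:, 3, :] += rng.normal(scale=sigma, size=(2000, 3))
        ens = make_toy_ensemble(coords, residue_index=[1, 2, 3, 4],
                                atom_names=["N", "CA", "C", "O"])
        prof = ed.rmsf(ens)
        assert prof.values[3] == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_invariant_under_per_frame_rigid_motion(self, small_ensemble, rng):
        ens, _ = small_ensemble
        moved = ens.coords.copy()
        for f in range(ens.n_frames):
            Q, t = random_rigid_motion(rng)
            moved[f] = moved[f] @ Q.T + t
        ens2 = make_toy_ensemble(moved, ens.residue_index, ens.atom_names)
        np.testing.assert_allclose(
            ed.rmsf(ens).values, ed.rmsf(ens2).values, atol=1e-6
        )


class TestContactMaps:
    def test_min_distance_diagonal_and_symmetry(self, small_ensemble):
        ens, _ = small_ensemble
        m = ed.min_distance_map(ens).matrix
        assert np.all(np.diag(m) == 0)
        np.testing.assert_array_equal(m, m.T)

    def test_min_distance_matches_brute_force(self, rng):
        coords = rng.normal(scale=5.0, size=(9, 6, 3))
        ens = make_toy_ensemble(coords, residue_index=[1, 1, 2, 2, 3, 3])
        m = ed.min_distance_map(ens).matrix
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                ai = np.flatnonzero(ens.residue_index == i + 1)
                aj = np.flatnonzero(ens.residue_index == j + 1)
                brute = min(
                    np.linalg.norm(coords[f, a] - coords[f, b])
                    for f in range(9) for a in ai for b in aj
                )
                assert m[i, j] == pytest.approx(brute, abs=1e-10)

    def test_normalized_map_in_unit_range(self, small_ensemble):
        ens, _ = small_ensemble
        m = ed.min_distance_map(ens, normalize=True).matrix
        assert m.max() == pytest.approx(1.0)
        assert m.min() >= 0.0

    def test_rigid_motion_invariance(self, small_ensemble, rng):
        ens, _ = small_ensemble
        moved = ens.coords.copy()
        for f in range(ens.n_frames):
            Q, t = random_rigid_motion(rng)
            moved[f] = moved[f] @ Q.T + t
        ens2 = make_toy_ensemble(moved, ens.residue_index, ens.atom_names)
        np.testing.assert_allclose(
            ed.min_distance_map(ens).matrix, ed.min_distance_map(ens2).matrix,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            ed.radius_of_gyration(ens).values, ed.radius_of_gyration(ens2).values,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            ed.end_to_end_distance(ens).values, ed.end_to_end_distance(ens2).values,
            atol=1e-8,
        )


class TestMeanMinPairDistance:
    def test_three_frame_hand_computation(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = [2.0, 3.0, 4.0]
        ens = make_toy_ensemble(coords, residue_index=[1, 2])
        assert ed.mean_min_pair_distance(ens, (1, 2)) == pytest.approx(3.0)

    def test_identical_frames_equal_single_frame(self, small_ensemble):
        ens, _ = small_ensemble
        one = ed.mean_min_pair_distance(ens, (1, 8), frames=np.array([2]))
        rep = make_toy_ensemble(np.repeat(ens.coords[2:3], 4, axis=0),
                                ens.residue_index, ens.atom_names)
        assert ed.mean_min_pair_distance(rep, (1, 8)) == pytest.approx(one)

    def test_self_pair_rejected(self, small_ensemble):
        ens, _ = small_ensemble
        with pytest.raises(SelectionError):
            ed.mean_min_pair_distance(ens, (3, 3))

    def test_mean_at_least_global_minimum(self, small_ensemble):
        ens, _ = small_ensemble
        m = ed.min_distance_map(ens).matrix
        for pair in [(1, 5), (2, 7), (3, 8)]:
            assert ed.mean_min_pair_distance(ens, pair) >= m[pair[0] - 1, pair[1] - 1] - 1e-12


class TestHbondContactMap:
    @staticmethod
    def _toy(d_da, angle_deg):
        """Donor N–H in residue 1, acceptor O in residue 2 at distance
        d_da from N and H–N–O angle angle_deg."""
        a = np.deg2rad(angle_deg)
        coords = np.array(
            [[[0, 0, 0], [1.01, 0, 0],
              [d_da * np.cos(a), d_da * np.sin(a), 0.0]]]
        )
        return make_toy_ensemble(coords, residue_index=[1, 1, 2],
                                 atom_names=["N", "H", "O"])

    def test_geometry_inside_cutoffs_counted(self):
        m = ed.hbond_contact_map(self._toy(2.9, 10.0)).matrix
        assert m[0, 1] == pytest.approx(1.0)
        assert m.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("d,ang", [(3.6, 10.0), (2.9, 40.0)])
    def test_cutoff_failures_not_counted(self, d, ang):
        assert ed.hbond_contact_map(self._toy(d, ang)).matrix.sum() == 0.0

    def test_helix_gives_i_to_i_minus_4_band(self):
        spec = ed.GeneratorSpec(n_residues=12, n_frames=3, compactness=1.0,
                                seed=1, helix_span=(1, 12), helix_jitter_deg=1.0)
        ens, _ = ed.gen_backbone_ensemble(spec)
        m = ed.hbond_contact_map(ens).matrix
        band = sum(m[i, i - 4] for i in range(4, 12))
        assert band > 0
        assert band == pytest.approx(m.sum())  # only the helical band

    def test_missing_hydrogens_rejected(self):
        ens = make_toy_ensemble(np.zeros((1, 2, 3)), residue_index=[1, 2],
                                atom_names=["N", "O"])
        with pytest.raises(MissingHydrogenError):
            ed.hbond_contact_map(ens)
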