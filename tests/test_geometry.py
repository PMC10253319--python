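"""Superposition, RMSD conventions, essential-dynamics PCA and SASA."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from allosom.geometry import (
    DegenerateFitError,
    delta_sasa,
    pca_modes,
    rmsd,
    rmsd_series,
    shrake_rupley_sasa,
    superpose,
)
from allosom.structure import AtomSet, resolve_selection
from allosom.synthetic import ShiftSpec, domain_shift_ensemble

from conftest import make_ensemble, make_structure


def brute_force_min_rmsd(mobile, reference, n_starts=12, seed=0):
    """Independent rigid-fit oracle: numerical minimization over rotation
    vectors and translations from multiple random starts."""
    rng = np.random.default_rng(seed)

    def cost(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = mobile @ R.T + params[3:]
        return rmsd(moved, reference)

    best = np.inf
    for _ in range(n_starts):
        x0 = np.concatenate([rng.normal(0, 2, 3), rng.normal(0, 5, 3)])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(8, 3))
        transform, value = superpose(pts, pts)
        assert value == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_fully_recovered(self, rng):
        pts = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([5.0, 0.0, 0.0])
        _, value = superpose(moved, pts)
        assert value < 1e-8

    def test_matches_brute_force_minimum(self, rng):
        reference = rng.normal(size=(4, 3)) * 3
        mobile = reference.copy()
        mobile[2] += np.array([2.0, 0.0, 0.0])  # one point displaced 2 Å
        mobile = mobile @ Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix().T
        mobile += np.array([1.0, -2.0, 3.0])
        _, value = superpose(mobile, reference)
        oracle = brute_force_min_rmsd(mobile, reference)
        assert value == pytest.approx(oracle, abs=1e-5)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateFitError):
            superpose(line, line)
        two = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        with pytest.raises(DegenerateFitError):
            superpose(two, two)

    def test_forward_backward_composition_is_identity(self, rng):
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        t_ab, _ = superpose(a, b)
        t_ba, _ = superpose(b, a)
        composed_rot = t_ba.rotation @ t_ab.rotation
        np.testing.assert_allclose(composed_rot, np.eye(3), atol=1e-6)
        roundtrip = t_ba.apply(t_ab.apply(a))
        np.testing.assert_allclose(roundtrip, a, atol=1e-6)


class TestRmsdSeries:
    def test_static_ensemble_gives_zeros(self):
        structure = make_structure(8)
        ensemble = make_ensemble(structure, np.zeros((5, 8, 3)))
        sel = AtomSet(np.arange(8))
        series = rmsd_series(ensemble, structure.coords, sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)

    def test_shifted_calc_set_passes_through_fit(self):
        # fit set static, disjoint calc set rigidly translated by 3 Å
        structure = make_structure(10)
        disp = np.zeros((6, 10, 3))
        disp[:, 7:, 0] = 3.0
        ensemble = make_ensemble(structure, disp)
        fit_set = AtomSet(np.arange(7))
        calc_set = AtomSet(np.arange(7, 10))
        series = rmsd_series(ensemble, structure.coords, fit_set, calc_set)
        np.testing.assert_allclose(series.values, 3.0, atol=1e-8)

    def test_planted_rotation_orders_conditions(self):
        apo, holo, dmap = domain_shift_ensemble(ShiftSpec(frames=80, seed=11))
        fit = resolve_selection(apo.structure, dmap, "scaffold & name CA")
        calc = resolve_selection(apo.structure, dmap, "mobile & name CA")
        med_apo = np.median(rmsd_series(apo, apo.coords[0], fit, calc).values)
        med_holo = np.median(rmsd_series(holo, holo.coords[0], fit, calc).values)
        assert med_apo > med_holo

    def test_invariant_under_global_rigid_transform(self, rng):
        structure = make_structure(9)
        disp = rng.normal(0, 0.5, size=(6, 9, 3))
        ensemble = make_ensemble(structure, disp)
        sel = AtomSet(np.arange(9))
        base = rmsd_series(ensemble, structure.coords, sel).values
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = make_ensemble(
            structure, (structure.coords + disp) @ R.T + 7.0 - structure.coords
        )
        transformed = rmsd_series(moved, structure.coords, sel).values
        np.testing.assert_allclose(transformed, base, atol=1e-6)


class TestPca:
    def test_rank_one_motion_recovered_exactly(self, rng):
        structure = make_structure(6)
        disp = np.zeros((60, 6, 3))
        disp[:, 0, 0] = rng.normal(0, 1.5, size=60)
        ensemble = make_ensemble(structure, disp)
        result = pca_modes([ensemble], AtomSet(np.arange(6)), n_modes=3, fit=False)
        planted_var = np.var(disp[:, 0, 0])
        assert result.eigenvalues[0] == pytest.approx(planted_var, rel=1e-8)
        assert result.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        # eigenvector localized on the moving coordinate
        assert abs(result.eigenvectors[0][0]) == pytest.approx(1.0, abs=1e-8)

    def test_eigenvalues_match_explicit_covariance(self, rng):
        structure = make_structure(3)
        disp = rng.normal(0, 0.8, size=(50, 3, 3))
        ensemble = make_ensemble(structure, disp)
        result = pca_modes([ensemble], AtomSet(np.arange(3)), n_modes=9, fit=False)
        # brute-force oracle: accumulate the 9x9 covariance frame by frame
        flat = (structure.coords + disp).reshape(50, -1)
        mean = flat.mean(axis=0)
        cov = np.zeros((9, 9))
        for f in range(50):
            d = flat[f] - mean
            for i in range(9):
                for j in range(9):
                    cov[i, j] += d[i] * d[j]
        cov /= 50
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(result.eigenvalues, expected, atol=1e-10)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        structure = make_structure(4)
        disp = rng.normal(0, 0.6, size=(40, 4, 3))
        ensemble = make_ensemble(structure, disp)
        result = pca_modes([ensemble], AtomSet(np.arange(4)), n_modes=12, fit=False)
        assert result.eigenvalues.sum() == pytest.approx(result.total_variance, rel=1e-6)

    def test_planted_shift_separates_condition_projections(self):
        apo, holo, dmap = domain_shift_ensemble(ShiftSpec(frames=120, seed=5))
        sel = resolve_selection(apo.structure, dmap, "name CA")
        result = pca_modes([apo, holo], sel, n_modes=1)
        proj = {s.condition: s.values for s in result.projections if s.name == "pc1"}
        lo_a, hi_a = np.percentile(proj["apo-like"], [25, 75])
        lo_h, hi_h = np.percentile(proj["holo-like"], [25, 75])
        assert hi_a < lo_h or hi_h < lo_a  # non-overlapping interquartile ranges

    def test_too_many_modes_rejected(self, rng):
        structure = make_structure(3)
        ensemble = make_ensemble(structure, rng.normal(size=(10, 3, 3)))
        with pytest.raises(ValueError):
            pca_modes([ensemble], AtomSet(np.arange(3)), n_modes=10)


class TestSasa:
    def test_isolated_sphere_matches_closed_form(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]), probe=1.4, n_points=960)
        exact = 4 * np.pi * 3.1**2
        assert area[0] == pytest.approx(exact, rel=0.005)

    def test_distant_spheres_are_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        areas = shrake_rupley_sasa(coords, radii, 1.4, 960)
        for i, r in enumerate(radii):
            assert areas[i] == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=0.005)

    def test_two_sphere_overlap_matches_cap_formula(self):
        # equal expanded radii R, centers d apart: accessible area per sphere
        # is 4πR² − 2πR(R − d/2) = 2πR(R + d/2)
        d = 2.0
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = np.array([1.7, 1.7])
        areas = shrake_rupley_sasa(coords, radii, 1.4, 2000)
        R = 1.7 + 1.4
        exact = 2 * np.pi * R * (R + d / 2)
        assert areas[0] == pytest.approx(exact, rel=0.01)
        assert areas[1] == pytest.approx(exact, rel=0.01)

    def test_agrees_with_independent_implementation(self, rng):
        import biotite.structure as struc

        coords = rng.normal(0, 3, size=(12, 3))
        radii = np.full(12, 1.7)
        mine = shrake_rupley_sasa(coords, radii, 1.4, 2000)
        arr = struc.AtomArray(12)
        arr.coord = coords
        arr.element = np.full(12, "C")
        arr.atom_name = np.full(12, "C")
        arr.res_id = np.arange(1, 13)
        arr.res_name = np.full(12, "UNK")
        arr.chain_id = np.full(12, "A")
        theirs = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=2000)
        np.testing.assert_allclose(mine, theirs, rtol=0.03)

    def test_adding_an_atom_never_increases_area(self, rng):
        coords = rng.normal(0, 2.5, size=(8, 3))
        radii = np.full(8, 1.6)
        base = shrake_rupley_sasa(coords, radii, 1.4, 960)
        extra = np.vstack([coords, rng.normal(0, 2.5, size=(1, 3))])
        with_extra = shrake_rupley_sasa(extra, np.append(radii, 1.6), 1.4, 960)
        assert np.all(with_extra[:8] <= base + 1e-9)

    def test_coincident_atoms_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError):
            shrake_rupley_sasa(coords, np.array([1.7, 1.7]), 1.4, 960)


class TestDeltaSasa:
    def _structure(self, coords):
        n = len(coords)
        s = make_structure(n)
        return type(s)(
            atom_names=s.atom_names, elements=s.elements, chain_ids=s.chain_ids,
            res_ids=s.res_ids, res_names=s.res_names, coords=np.asarray(coords, float),
            radii=np.full(n, 1.7),
        )

    def test_distant_partner_buries_nothing(self):
        coords = np.vstack([np.eye(3) * 2.0, np.eye(3) * 2.0 + 50.0])
        s = self._structure(coords)
        value = delta_sasa(s, coords, AtomSet(np.arange(3)), AtomSet(np.arange(3, 6)))
        assert value == pytest.approx(0.0, abs=1e-6)

    def test_equals_two_independent_sasa_runs(self):
        coords = np.array(
            [[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0],
             [1.5, 3.0, 0], [4.5, 3.0, 0], [3.0, -3.0, 0]]
        )
        s = self._structure(coords)
        region = AtomSet(np.arange(3))
        partner = AtomSet(np.arange(3, 6))
        value = delta_sasa(s, coords, region, partner)
        alone = shrake_rupley_sasa(coords[:3], s.radii[:3], 1.4, 960)
        complexed = shrake_rupley_sasa(coords, s.radii, 1.4, 960)
        expected = alone.sum() - complexed[:3].sum()
        assert value == pytest.approx(expected, abs=1e-9)
        assert value > 0  # contacting partner buries surface

    def test_symmetric_toy_is_symmetric(self):
        # mirror-symmetric arrangement: swapping roles gives the same burial
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [9.0, 0, 0], [6.0, 0, 0]])
        s = self._structure(coords)
        left = AtomSet(np.array([0, 1]))
        right = AtomSet(np.array([2, 3]))
        # equal up to the (non-mirror-symmetric) sphere-point sampling noise
        assert delta_sasa(s, coords, left, right) == pytest.approx(
            delta_sasa(s, coords, right, left), rel=0.05
        )

    def test_overlapping_sets_rejected(self):
        coords = np.eye(4, 3) * 3
        s = self._structure(coords)
        with pytest.raises(ValueError):
            delta_sasa(s, coords, AtomSet(np.array([0, 1])), AtomSet(np.array([1, 2])))
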