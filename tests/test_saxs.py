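import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confswitch import saxs, synth


class TestGuinier:
    def test_exact_gaussian_form(self):
        q = np.linspace(0.002, 0.05, 200)
        inten = 100.0 * np.exp(-(q**2) * 50.0**2 / 3.0)
        fit = saxs.guinier_fit(saxs.SAXSCurve(q, inten, 0.01 * inten))
        assert fit.rg == pytest.approx(50.0, rel=1e-6)
        assert fit.i0 == pytest.approx(100.0, rel=1e-6)

    def test_analytic_sphere_within_one_percent(self, sphere_curve):
        fit = saxs.guinier_fit(sphere_curve)
        assert fit.rg == pytest.approx(40.0 * np.sqrt(3.0 / 5.0), rel=0.01)

    def test_increasing_intensity_raises(self):
        q = np.linspace(0.01, 0.1, 50)
        inten = 1.0 + q
        with pytest.raises(saxs.NoGuinierRegionError):
            saxs.guinier_fit(saxs.SAXSCurve(q, inten, 0.01 * inten))

    def test_window_respects_qrg_limit(self, sphere_curve_wide):
        fit = saxs.guinier_fit(sphere_curve_wide)
        assert fit.qmax_rg <= 1.3 + 1e-9


class TestPofR:
    def test_sphere_matches_closed_form(self, sphere_curve_wide):
        radius = 40.0
        pr = saxs.pofr_transform(sphere_curve_wide, 2 * radius, alpha=1.0)
        x = pr.r / radius
        p_true = pr.r**2 * (1.0 - 0.75 * x + x**3 / 16.0)
        p_true[pr.r > 2 * radius] = 0.0
        p_true = p_true / p_true.max()
        p_est = pr.p / pr.p.max()
        assert np.abs(p_true - p_est).max() < 0.02

    def test_back_transform_chi(self, sphere_curve_wide):
        pr = saxs.pofr_transform(sphere_curve_wide, 80.0, alpha=1.0)
        assert pr.back_chi <= 1.5

    def test_real_space_rg(self, sphere_curve_wide):
        pr = saxs.pofr_transform(sphere_curve_wide, 80.0, alpha=1.0)
        assert pr.rg == pytest.approx(40.0 * np.sqrt(3.0 / 5.0), rel=0.01)

    def test_constraints(self, sphere_curve_wide):
        pr = saxs.pofr_transform(sphere_curve_wide, 80.0, alpha=1.0)
        assert pr.p[0] == 0.0 and pr.p[-1] == 0.0
        assert (pr.p >= 0).all()

    def test_alpha_zero_rejected(self, sphere_curve_wide):
        with pytest.raises(ValueError, match="alpha"):
            saxs.pofr_transform(sphere_curve_wide, 80.0, alpha=0.0)

    def test_integral_proportional_to_i0(self, sphere_curve_wide):
        pr = saxs.pofr_transform(sphere_curve_wide, 80.0, alpha=1.0)
        dr = pr.r[1] - pr.r[0]
        # the sin(qr)/(qr) kernel tends to 1 at q=0, so the back-transformed
        # I(0) equals the P(r) integral
        i0_back = pr.p.sum() * dr
        fit = saxs.guinier_fit(sphere_curve_wide)
        assert i0_back == pytest.approx(fit.i0, rel=0.01)


class TestEstimateDmax:
    def test_sphere_dmax(self, sphere_curve_wide):
        d = saxs.estimate_dmax(sphere_curve_wide, (40.0, 160.0, 25))
        assert d == pytest.approx(80.0, rel=0.10)

    def test_dumbbell_two_points(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        q = np.linspace(0.005, 0.25, 150)
        c = saxs.debye_scatter(coords, q)
        d = saxs.estimate_dmax(c, (60.0, 160.0, 21))
        assert d == pytest.approx(100.0, abs=6.0)

    def test_pure_noise_errors(self):
        rng = np.random.default_rng(0)
        q = np.linspace(0.01, 0.3, 80)
        inten = rng.normal(0.0, 1.0, 80)
        c = saxs.SAXSCurve(q, inten, np.full(80, 1.0))
        with pytest.raises((saxs.UnboundedDmaxError, ValueError)):
            saxs.estimate_dmax(c, (20.0, 100.0, 9))


class TestDebye:
    def test_single_bead_flat(self):
        c = saxs.debye_scatter(np.zeros((1, 3)), np.linspace(0.01, 0.3, 20))
        assert np.allclose(c.intensity, 1.0)

    def test_two_beads_closed_form(self):
        d = 25.0
        q = np.linspace(0.01, 0.3, 50)
        c = saxs.debye_scatter(np.array([[0.0, 0, 0], [d, 0, 0]]), q)
        expected = 2.0 + 2.0 * np.sin(q * d) / (q * d)
        np.testing.assert_allclose(c.intensity, expected, rtol=1e-12)

    def test_i0_equals_squared_total(self):
        coords = np.random.default_rng(0).normal(0, 10, (30, 3))
        f = np.random.default_rng(1).uniform(0.5, 2.0, 30)
        c = saxs.debye_scatter(coords, np.array([1e-6]), form_factors=f)
        assert c.intensity[0] == pytest.approx(f.sum() ** 2, rel=1e-6)

    def test_invariant_under_rigid_transform(self):
        coords = np.random.default_rng(2).normal(0, 15, (25, 3))
        q = np.linspace(0.01, 0.25, 40)
        c1 = saxs.debye_scatter(coords, q)
        rot = Rotation.from_rotvec([0.3, 1.0, -0.6]).as_matrix()
        c2 = saxs.debye_scatter(coords @ rot.T + np.array([4.0, 5.0, -6.0]), q)
        np.testing.assert_allclose(c2.intensity, c1.intensity, rtol=1e-9)

    def test_guinier_of_debye_matches_coordinate_rg(self):
        coords = np.random.default_rng(3).normal(0, 12, (60, 3))
        rg = saxs.coordinate_rg(coords)
        q = np.linspace(0.001, 0.8 / rg, 80)
        fit = saxs.guinier_fit(saxs.debye_scatter(coords, q))
        assert fit.rg == pytest.approx(rg, rel=0.01)


class TestChiFit:
    def test_identical_curves(self, sphere_curve_wide):
        chi, scale = saxs.chi_fit(sphere_curve_wide, sphere_curve_wide)
        assert chi == pytest.approx(0.0, abs=1e-9)
        assert scale == pytest.approx(1.0)

    def test_scale_invariance(self, sphere_curve_wide):
        c = sphere_curve_wide
        doubled = saxs.SAXSCurve(c.q, 2.0 * c.intensity, c.sigma)
        chi, scale = saxs.chi_fit(c, doubled)
        assert chi == pytest.approx(0.0, abs=1e-9)
        assert scale == pytest.approx(2.0)

    def test_hand_built_three_point_case(self):
        # data (10, 20, 30), model (1, 2, 4), sigma (1, 2, 1):
        # c = (10*1/1 + 20*2/4 + 30*4/1) / (1/1 + 4/4 + 16/1) = 140/18
        model = saxs.SAXSCurve([0.1, 0.2, 0.3], [1.0, 2.0, 4.0], [1, 1, 1])
        data = saxs.SAXSCurve([0.1, 0.2, 0.3], [10.0, 20.0, 30.0], [1.0, 2.0, 1.0])
        chi, scale = saxs.chi_fit(model, data)
        c = 140.0 / 18.0
        resid = np.array([10 - c, (20 - 2 * c) / 2, 30 - 4 * c])
        expected = np.sqrt((resid**2).sum() / 2)
        assert scale == pytest.approx(c)
        assert chi == pytest.approx(expected)

    def test_too_few_points(self):
        c = saxs.SAXSCurve([0.1, 0.2], [1.0, 2.0], [0.1, 0.1])
        one = saxs.SAXSCurve([0.1], [1.0], [0.1])
        with pytest.raises(ValueError):
            saxs.chi_fit(c, one)


class TestAssembleC4:
    def test_four_copies(self):
        protomer = synth.make_compact_protomer(20, seed=0)
        chains = saxs.assemble_c4(protomer, np.array([0.0, 0, 0, 15.0]))
        assert len(chains) == 4
        assert all(len(c) == len(protomer) for c in chains)

    def test_exact_symmetry(self):
        protomer = synth.make_compact_protomer(20, seed=0)
        chains = saxs.assemble_c4(protomer, np.array([0.2, -0.1, 0.4, 15.0]))
        rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        for i in range(4):
            rotated = chains[i].coords @ rz.T
            np.testing.assert_allclose(
                rotated, chains[(i + 1) % 4].coords, atol=1e-9
            )

    def test_single_point_adjacent_distance(self):
        m = _point_pair_model(rho_dummy=True)
        chains = saxs.assemble_c4(m, np.array([0.0, 0, 0, 10.0]))
        d = np.linalg.norm(chains[0].coords[0] - chains[1].coords[0])
        assert d == pytest.approx(10.0 * np.sqrt(2.0), rel=1e-9)


class TestRigidBodyFit:
    def test_round_trip_recovery(self, tetramer_fit):
        _, _, restraints, fit = tetramer_fit
        assert fit.chi <= 1.5
        assert all(d <= 35.0 for d in fit.restraint_distances.values())

    def test_seeded_reproducibility(self, tetramer_fit):
        protomer, data, restraints, fit = tetramer_fit
        fit2 = saxs.rigid_body_fit(protomer, data, restraints, seed=3, steps=300)
        np.testing.assert_array_equal(fit.pose, fit2.pose)
        assert fit.chi == fit2.chi

    def test_penalty_monotone_in_violation(self, tetramer_fit):
        protomer, data, restraints, fit = tetramer_fit
        obj_ok, chi_ok, _, dists = saxs.tetramer_objective(
            protomer, fit.pose, data, restraints
        )
        far_pose = fit.pose.copy()
        far_pose[3] += 10.0  # push protomers apart: restraints violated more
        obj_far, chi_far, _, dists_far = saxs.tetramer_objective(
            protomer, far_pose, data, restraints
        )
        pen_ok = sum(max(0, d - 35.0) ** 2 for d in dists.values())
        pen_far = sum(max(0, d - 35.0) ** 2 for d in dists_far.values())
        assert pen_far > pen_ok
        assert obj_far - chi_far**2 >= obj_ok - chi_ok**2

    def test_default_restraints_are_paper_configuration(self):
        spec = saxs.RestraintSpec()
        assert spec.residues == (157, 173, 305)
        assert spec.upper_bound == 35.0


class TestRefineRestrained:
    def test_distances_approach_target(self, tetramer_fit):
        _, _, restraints, fit = tetramer_fit
        before = fit.restraint_distances
        refined = saxs.refine_restrained(fit, restraints)
        for res, d in refined.restraint_distances.items():
            assert abs(d - 30.0) <= abs(before[res] - 30.0) + 1e-9

    def test_already_at_target_unchanged(self):
        protomer = synth.make_compact_protomer(20, seed=2)
        spec = saxs.RestraintSpec(residues=(int(protomer.res_ids[5]),))
        # find a rho whose homotypic distance is 30 for this residue
        import scipy.optimize

        def dist_at(rho):
            chains = saxs.assemble_c4(protomer, np.array([0.0, 0, 0, rho]))
            idx = 5
            return float(
                np.linalg.norm(chains[0].coords[idx] - chains[1].coords[idx])
            )

        rho30 = scipy.optimize.brentq(lambda r: dist_at(r) - 30.0, 1.0, 60.0)
        t = saxs.TetramerModel(
            protomer=protomer,
            pose=np.array([0.0, 0, 0, rho30]),
            chains=saxs.assemble_c4(protomer, np.array([0.0, 0, 0, rho30])),
        )
        refined = saxs.refine_restrained(t, spec)
        assert refined.restraint_distances[spec.residues[0]] == pytest.approx(
            30.0, abs=0.1
        )

    def test_symmetry_preserved(self, tetramer_fit):
        _, _, restraints, fit = tetramer_fit
        refined = saxs.refine_restrained(fit, restraints)
        rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        np.testing.assert_allclose(
            refined.chains[0].coords @ rz.T, refined.chains[1].coords, atol=1e-9
        )


class TestCurveIO:
    def test_round_trip(self, tmp_path, sphere_curve_wide):
        p = tmp_path / "curve.dat"
        saxs.write_curve(sphere_curve_wide, p, header="test curve")
        back = saxs.read_curve(p)
        np.testing.assert_allclose(back.q, sphere_curve_wide.q, rtol=1e-5)
        np.testing.assert_allclose(
            back.intensity, sphere_curve_wide.intensity, rtol=1e-5
        )

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            saxs.SAXSCurve([0.2, 0.1], [1.0, 1.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            saxs.SAXSCurve([0.1, 0.2], [1.0, 1.0], [0.1, -0.1])


def _point_pair_model(rho_dummy=False):
    from confswitch.struct_io import CalphaModel

    # single-point protomer is not a valid CalphaModel (N >= 2); use two
    # coincident points at the origin so the posed position is exactly rho
    coords = np.zeros((2, 3))
    return CalphaModel(
        coords,
        np.array(["A", "A"], dtype=object),
        np.array([1, 2]),
        np.array(["x", "x"], dtype=object),
    )
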