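"""Element kinematics, Mooney-Rivlin plane stress and field summaries."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, strategies as st

import sws4d as s
from sws4d.errors import ConfigurationError
from sws4d.strain_stress import classify_peak_location, grid_deformation_gradients

from conftest import cylinder_grid


def unit_quad():
    return np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)


class TestDeformationGradient:
    def test_identity(self):
        F = s.element_deformation_gradient(unit_quad(), unit_quad())
        assert np.allclose(F, np.eye(2), atol=1e-14)

    def test_pure_circumferential_stretch(self):
        ref = unit_quad()
        deformed = ref * np.array([1.1, 1.0, 1.0])  # x is the circumferential axis
        F = s.element_deformation_gradient(ref, deformed)
        assert np.allclose(F, np.diag([1.1, 1.0]), atol=1e-12)

    def test_least_squares_optimality(self):
        # F must beat any perturbed linear map on the 4-edge residual
        rng = np.random.default_rng(7)
        ref = unit_quad() + 0.05 * rng.normal(size=(4, 3)) * np.array([1, 1, 0])
        deformed = ref @ np.array([[1.08, 0.03, 0], [0.02, 0.97, 0], [0, 0, 1.0]]).T
        deformed += 0.02 * rng.normal(size=(4, 3)) * np.array([1, 1, 0])
        F = s.element_deformation_gradient(ref, deformed)

        from sws4d.strain_stress import _element_edges_2d

        e_ref = _element_edges_2d(ref[None])[0]
        e_def = _element_edges_2d(deformed[None])[0]

        def residual(M):
            return np.sum((M @ e_ref - e_def) ** 2)

        base = residual(F)
        for _ in range(50):
            assert residual(F + 0.01 * rng.normal(size=(2, 2))) >= base - 1e-12

    def test_rigid_motion_of_both_configurations_is_invisible(self):
        rng = np.random.default_rng(1)
        ref = cylinder_grid(L=5, C=12)
        deformed = ref * np.array([1.07, 1.07, 1.01]) + 0.01 * rng.normal(size=ref.shape)
        F0 = grid_deformation_gradients(ref, deformed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = 0.7
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
        F1 = grid_deformation_gradients(ref @ R.T + 5.0, deformed @ R.T + 5.0)
        l0 = s.principal_stretches(F0)
        l1 = s.principal_stretches(F1)
        for a, b in zip(l0, l1):
            assert np.max(np.abs(a - b) / a) < 1e-9


class TestPrincipalStretches:
    def test_identity(self):
        assert s.principal_stretches(np.eye(2)) == pytest.approx((1.0, 1.0, 1.0))

    def test_diagonal_incompressibility(self):
        l1, l2, l3 = s.principal_stretches(np.diag([1.1, 1.0]))
        assert (l1, l2) == pytest.approx((1.1, 1.0))
        assert l3 == pytest.approx(1.0 / 1.1, abs=1e-12)

    def test_simple_shear_matches_svd_oracle(self):
        F = np.array([[1.0, 0.2], [0.0, 1.0]])
        l1, l2, l3 = s.principal_stretches(F)
        sv = np.linalg.svd(F, compute_uv=False)
        assert l1 == pytest.approx(sv[0], abs=1e-12)
        assert l2 == pytest.approx(sv[1], abs=1e-12)
        assert l1 == pytest.approx(1.10499, abs=1e-5)
        assert l2 == pytest.approx(0.90499, abs=1e-5)
        assert l3 == pytest.approx(1.0, abs=1e-12)

    @given(
        st.floats(0.7, 1.4), st.floats(0.7, 1.4),
        st.floats(-0.3, 0.3), st.floats(-0.3, 0.3),
    )
    def test_incompressibility_exact(self, a, d, b, c):
        F = np.array([[a, b], [c, d]])
        if np.linalg.det(F) <= 0.05:
            return
        l1, l2, l3 = s.principal_stretches(F)
        assert abs(l1 * l2 * l3 - 1.0) < 1e-12
        assert l1 >= l2 > 0


class TestMooneyRivlin:
    def test_reference_state_stress_free(self, materials):
        for mat in materials.values():
            assert s.mooney_rivlin_cauchy((1.0, 1.0, 1.0), mat) == pytest.approx((0.0, 0.0))

    def test_equibiaxial_matches_symbolic_oracle(self, materials):
        # independent derivation: eliminate the plane-stress multiplier from W
        # symbolically and differentiate
        l1s, l2s, c1s, c2s = sp.symbols("l1 l2 c1 c2", positive=True)
        l3s = 1 / (l1s * l2s)
        I1 = l1s**2 + l2s**2 + l3s**2
        I2 = (l1s * l2s) ** 2 + (l1s * l3s) ** 2 + (l2s * l3s) ** 2
        W = c1s * (I1 - 3) + c2s * (I2 - 3)
        sigma1 = sp.simplify(l1s * sp.diff(W, l1s))
        mat = materials["normal"]
        lam = 1.1
        expected = float(sigma1.subs({l1s: lam, l2s: lam, c1s: mat.c1, c2s: mat.c2}))
        got1, got2 = s.mooney_rivlin_cauchy((lam, lam, 1.0 / lam**2), mat)
        assert got1 == pytest.approx(expected, rel=1e-12)
        assert got1 == pytest.approx(got2)

    def test_uniaxial_recovers_classical_formula(self, materials):
        from scipy.optimize import brentq

        mat = materials["normal"]
        lam1 = 1.2

        def sigma2(lam2):
            return s.mooney_rivlin_cauchy((lam1, lam2, 1.0 / (lam1 * lam2)), mat)[1]

        lam2 = brentq(sigma2, 0.5, 1.0, xtol=1e-14)
        s1 = s.mooney_rivlin_cauchy((lam1, lam2, 1.0 / (lam1 * lam2)), mat)[0]
        classical = 2.0 * (lam1**2 - 1.0 / lam1) * (mat.c1 + mat.c2 / lam1)
        assert s1 == pytest.approx(classical, rel=1e-10)
        assert lam2 == pytest.approx(1.0 / np.sqrt(lam1), rel=1e-6)  # near neo-Hookean

    def test_constitutive_consistency_numeric_differentiation(self, materials):
        # σk = λk ∂Ŵ/∂λk with the multiplier eliminated, by central differences
        mat = materials["fibrous"]
        h = 1e-6
        grid = np.linspace(0.8, 1.4, 13)
        worst = 0.0
        for lam1 in grid:
            for lam2 in grid:
                s1, s2 = s.mooney_rivlin_cauchy((lam1, lam2, 1 / (lam1 * lam2)), mat)
                d1 = (
                    s.strain_energy_density(lam1 + h, lam2, mat)
                    - s.strain_energy_density(lam1 - h, lam2, mat)
                ) / (2 * h)
                d2 = (
                    s.strain_energy_density(lam1, lam2 + h, mat)
                    - s.strain_energy_density(lam1, lam2 - h, mat)
                ) / (2 * h)
                ref = max(abs(s1), abs(s2), 1.0)
                worst = max(worst, abs(lam1 * d1 - s1) / ref, abs(lam2 * d2 - s2) / ref)
        assert worst < 1e-6


class TestVonMises:
    @pytest.mark.parametrize(
        "s1,s2,expected", [(0.0, 0.0, 0.0), (100.0, 0.0, 100.0), (60.0, 60.0, 60.0)]
    )
    def test_plane_stress_values(self, s1, s2, expected):
        assert s.von_mises(s1, s2) == pytest.approx(expected)


class TestStrainSeries:
    def test_null_motion_zero_strain_both_modes(self):
        g = cylinder_grid()
        for mode in ("cumulative", "incremental"):
            for sf in s.compute_strain_series([g, g.copy(), g.copy()], mode=mode):
                assert np.allclose(sf.max_principal_strain, 0.0, atol=1e-14)

    def test_single_step_inflation(self):
        g = cylinder_grid()
        g2 = g * np.array([1.12, 1.12, 1.0])
        (sf,) = s.compute_strain_series([g, g2])
        assert np.allclose(sf.max_principal_strain, 0.12, atol=1e-12)

    def test_two_half_steps_compose_multiplicatively(self):
        g = cylinder_grid()
        grids = [g, g * np.array([1.06, 1.06, 1.0]), g * np.array([1.06**2, 1.06**2, 1.0])]
        cum = s.compute_strain_series(grids, mode="cumulative")
        inc = s.compute_strain_series(grids, mode="incremental")
        assert np.allclose(cum[1].max_principal_strain, 1.06 * 1.06 - 1.0, atol=1e-12)
        assert np.allclose(inc[1].max_principal_strain, 0.06, atol=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            s.compute_strain_series([cylinder_grid()], mode="total")


def _uniform_profile(n_rings, stenotic_span=None):
    ds = np.zeros(n_rings)
    if stenotic_span is not None:
        ds[stenotic_span] = 50.0
    ref = np.full(n_rings, 3.0)
    labels = np.where(ds > 20.0, "stenotic", "normal")
    return s.StenosisProfile(
        percent_ds=ds, reference_diameter=ref, labels=labels,
        arclength=np.linspace(0.0, n_rings - 1.0, n_rings),
    )


class TestStressSeries:
    def test_zero_strain_zero_stress(self, materials):
        g = cylinder_grid()
        strains = s.compute_strain_series([g, g.copy()])
        profile = _uniform_profile(g.shape[0])
        (st_f,) = s.compute_stress_series(strains, profile, {"normal": materials["normal"]})
        assert np.allclose(st_f.von_mises, 0.0, atol=1e-12)

    def test_uniform_inflation_homogeneous_material_constant_stress(self, materials):
        g = cylinder_grid()
        strains = s.compute_strain_series([g, g * np.array([1.1, 1.1, 1.0])])
        (st_f,) = s.compute_stress_series(
            strains, _uniform_profile(g.shape[0]), {"normal": materials["normal"]}
        )
        assert np.ptp(st_f.von_mises) < 1e-9 * st_f.von_mises.mean()

    def test_stiffer_lesion_scales_stress_by_constant_ratio(self, materials):
        g = cylinder_grid(L=11)
        strains = s.compute_strain_series([g, g * np.array([1.1, 1.1, 1.0])])
        profile = _uniform_profile(11, stenotic_span=slice(4, 7))
        (st_f,) = s.compute_stress_series(
            strains, profile, {"normal": materials["normal"], "fibrous": materials["fibrous"]},
            lesion_class="fibrous",
        )
        lesion = st_f.material_map == "fibrous"
        ratio = st_f.von_mises[lesion].mean() / st_f.von_mises[~lesion].mean()
        # fibrous constants are exactly 2x normal; stress is linear in (C1, C2)
        assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_missing_material_class_rejected(self, materials):
        g = cylinder_grid(L=11)
        strains = s.compute_strain_series([g, g * np.array([1.1, 1.1, 1.0])])
        profile = _uniform_profile(11, stenotic_span=slice(4, 7))
        with pytest.raises(ConfigurationError):
            s.compute_stress_series(
                strains, profile, {"normal": materials["normal"]}, lesion_class="calcified"
            )


class TestPulseAndSummary:
    def _stress_pair(self, materials):
        g = cylinder_grid(L=21, C=12, length=20.0)
        grids = [g, g * np.array([1.05, 1.05, 1.0]), g * np.array([1.12, 1.12, 1.0])]
        strains = s.compute_strain_series(grids)
        profile = _uniform_profile(21)
        return s.compute_stress_series(strains, profile, {"normal": materials["normal"]})

    def test_identical_fields_zero_pulse(self, materials):
        st1, _ = self._stress_pair(materials)
        res = s.pulse_stress(st1, st1)
        assert np.allclose(res.values, 0.0)

    def test_constant_offset_pulse(self, materials):
        st1, st2 = self._stress_pair(materials)
        shifted = s.StressField(
            principal_cauchy=st1.principal_cauchy,
            von_mises=st1.von_mises + 10.0,
            material_map=st1.material_map,
            frame_index=2,
            element_arclength=st1.element_arclength,
        )
        res = s.pulse_stress(shifted, st1)
        assert np.allclose(res.values, 10.0)
        assert 0.0 <= res.argmax_arclength_mm <= 20.0

    def test_no_lesion_summary_is_normal_class(self, materials):
        g = cylinder_grid(L=21, C=12, length=20.0)
        grids = [g, g * np.array([1.1, 1.1, 1.0])]
        strains = s.compute_strain_series(grids)
        profile = _uniform_profile(21)
        stresses = s.compute_stress_series(strains, profile, {"normal": materials["normal"]})
        summ = s.summarize_fields(strains, stresses, profile)
        assert summ.peak_location_class == "normal"
        assert set(summ.strain_by_class) == {"normal"}

    def test_peak_classifier_partitions_lesion(self, stenotic_vessel):
        profile = s.compute_stenosis_profile(stenotic_vessel.lumen)
        throat = profile.throat_index
        classes = [classify_peak_location(profile, r) for r in range(len(profile.percent_ds) - 1)]
        assert classes[throat] == "throat"
        sten_rows = [i for i, c in enumerate(classes) if c != "normal"]
        assert classes[min(sten_rows)] == "proximal_shoulder"
        assert classes[max(sten_rows)] == "distal_shoulder"
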