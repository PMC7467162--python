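"""Debye profiles, q grids, condition model and offset fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waxshelix import helix_forge as hf
from waxshelix import scattering as sc


class TestQGrid:
    def test_default_grid_has_191_points(self):
        grid = sc.make_qgrid()
        assert len(grid) == 191
        assert grid.values[0] == 0.0
        assert grid.values[-1] == pytest.approx(0.950)
        assert np.allclose(np.diff(grid.values), 0.005)

    def test_small_inclusive_grid(self):
        assert np.allclose(sc.make_qgrid(0, 1, 0.5).values, [0, 0.5, 1.0])

    def test_non_divisible_range_errors(self):
        with pytest.raises(sc.ScatteringError, match="divisible"):
            sc.make_qgrid(0, 1, 0.3)

    @given(st.integers(min_value=1, max_value=400))
    @settings(deadline=None, max_examples=30)
    def test_point_count_matches_fencepost(self, n):
        spacing = 0.005
        grid = sc.make_qgrid(0.0, n * spacing, spacing)
        assert len(grid) == n + 1

    def test_decreasing_grid_rejected(self):
        with pytest.raises(sc.ScatteringError, match="increasing"):
            sc.QGrid(np.array([0.0, 0.2, 0.1]))


def _single_bead_model(electrons=10.0):
    m = hf.canonical_aform()
    return m, electrons


class TestDebyeProfile:
    def test_single_bead_closed_form(self):
        """One bead: I(q) = f(q)^2; at q = 0 exactly electrons^2."""
        m = hf.canonical_aform()
        solo = hf.DuplexModel(
            conformation_id="solo", sequence=m.sequence,
            strand=m.strand, residue=m.residue, bead_kind=m.bead_kind,
            coords=np.zeros_like(m.coords), electrons=m.electrons,
        )  # all beads at one point == a single scatterer of summed f
        qg = sc.make_qgrid(0.0, 0.9, 0.1)
        prof = sc.debye_profile(solo, qg, bead_width=2.0)
        f = solo.total_electrons * np.exp(-((qg.values * 2.0) ** 2) / 2)
        assert np.allclose(prof.intensity, f**2, rtol=1e-12)
        assert prof.intensity[0] == pytest.approx(solo.total_electrons**2)

    def test_two_point_beads_interference(self):
        """Two point scatterers at distance d: f1^2 + f2^2 + 2 f1 f2 sinc(qd)."""
        m = hf.canonical_aform()
        coords = np.zeros_like(m.coords)
        half = m.n_beads // 2
        coords[half:, 2] = 10.0
        pair = hf.replace_coords(m, coords)
        e1 = pair.electrons[:half].sum()
        e2 = pair.electrons[half:].sum()
        qg = sc.make_qgrid(0.0, 0.9, 0.05)
        prof = sc.debye_profile(pair, qg, bead_width=0.0)
        q = qg.values
        with np.errstate(invalid="ignore"):
            sinc = np.where(q == 0, 1.0, np.sin(q * 10.0) / (q * 10.0))
        expected = e1**2 + e2**2 + 2 * e1 * e2 * sinc
        assert np.allclose(prof.intensity, expected, rtol=1e-10)

    def test_full_duplex_matches_brute_force_double_sum(self, tiny_ensemble):
        """Independent O(N^2) double-loop oracle, rel. tol. 1e-8, all 191 q."""
        m = tiny_ensemble[0]
        qg = sc.make_qgrid()
        prof = sc.debye_profile(m, qg)
        q = qg.values
        oracle = np.zeros_like(q)
        for i in range(m.n_beads):
            for j in range(m.n_beads):
                dij = np.linalg.norm(m.coords[i] - m.coords[j])
                x = q * dij
                with np.errstate(invalid="ignore"):
                    s = np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1, x))
                oracle += m.electrons[i] * m.electrons[j] * s
        oracle *= np.exp(-((q * sc.DEFAULT_BEAD_WIDTH) ** 2))
        assert np.allclose(prof.intensity, oracle, rtol=1e-8)

    def test_strictly_positive_on_default_grid(self, tiny_ensemble):
        for m in tiny_ensemble:
            assert sc.debye_profile(m).intensity.min() > 0


class TestConditions:
    def test_nine_documented_conditions(self):
        assert len(sc.DEFAULT_CONDITIONS) == 9
        kcl = sorted(c.concentration_mM for c in sc.DEFAULT_CONDITIONS
                     if c.salt == "KCl")
        mg = sorted(c.concentration_mM for c in sc.DEFAULT_CONDITIONS
                    if c.salt == "MgCl2")
        assert kcl == [30, 50, 100, 200, 500]
        assert mg == [0.25, 0.50, 1.00, 5.00]

    def test_identity_condition_is_identity(self, tiny_ensemble):
        prof = sc.debye_profile(tiny_ensemble[0])
        null = sc.SolutionCondition("KCl", 1.0, contrast_epsilon=0.0,
                                    offset_b=0.0)
        out = sc.apply_condition(prof, null)
        assert np.array_equal(out.intensity, prof.intensity)

    def test_one_conformation_yields_nine_profiles(self, tiny_ensemble):
        prof = sc.debye_profile(tiny_ensemble[0])
        outs = [sc.apply_condition(prof, c) for c in sc.DEFAULT_CONDITIONS]
        assert len({o.condition for o in outs}) == 9

    def test_unknown_condition_name_rejected(self):
        with pytest.raises(sc.ScatteringError, match="unknown condition"):
            sc.condition_by_name("NaCl_100mM")
        with pytest.raises(sc.ScatteringError, match="unknown salt"):
            sc.SolutionCondition("NaCl", 100, 0.0, 0.0)

    def test_fitted_offsets_below_ten_percent_of_tail_intensity(self):
        """Condition-to-condition |c| stays under 10% of I(q_max)."""
        models = hf.sample_ensemble(20, seed=17)
        for m in models:
            base = sc.debye_profile(m)
            profs = [sc.apply_condition(base, c) for c in sc.DEFAULT_CONDITIONS]
            ref = profs[0]
            for p in profs[1:]:
                c = sc.fit_offset_c(ref, p)
                assert abs(c) <= 0.10 * ref.intensity[-1]


class TestPropagateError:
    def test_default_rule_is_identity(self):
        sigma = np.array([0.0, 1.0, 2.5])
        assert np.array_equal(sc.propagate_error(sigma), sigma)

    def test_negative_sigma_rejected(self):
        with pytest.raises(sc.ScatteringError, match="non-negative"):
            sc.propagate_error(np.array([-1.0]))

    def test_plugged_rule_changes_weights_not_minimizer_form(self):
        """With any plugged rule the closed form still matches a grid search."""
        rng = np.random.default_rng(0)
        qg = sc.make_qgrid(0, 0.5, 0.05)
        theory = sc.ScatteringProfile(qg, np.full(len(qg), 100.0))
        sigma = rng.uniform(0.5, 3.0, len(qg))
        exp = sc.ScatteringProfile(
            qg, 100.0 + rng.normal(0, 1, len(qg)), sigma=sigma
        )
        rule = lambda s, snr: 2.0 * s + 0.1
        c_hat = sc.fit_offset_c(theory, exp, rule=rule)
        # brute-force 1-D grid search of the weighted residual sum
        w = 1.0 / sc.propagate_error(sigma, rule=rule) ** 2
        cs = np.linspace(c_hat - 1, c_hat + 1, 200001)
        resid = exp.intensity - theory.intensity
        loss = ((resid[None, :] - cs[:, None]) ** 2 * w[None, :]).sum(axis=1)
        assert c_hat == pytest.approx(cs[np.argmin(loss)], abs=1e-4)


class TestFitOffset:
    def test_identical_profiles_give_zero(self):
        qg = sc.make_qgrid(0, 0.5, 0.05)
        p = sc.ScatteringProfile(qg, np.linspace(10, 1, len(qg)))
        assert sc.fit_offset_c(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_recovered_exactly(self):
        qg = sc.make_qgrid(0, 0.5, 0.05)
        theory = sc.ScatteringProfile(qg, np.linspace(10, 1, len(qg)))
        exp = sc.ScatteringProfile(
            qg, theory.intensity + 3.25, sigma=np.ones(len(qg))
        )
        assert sc.fit_offset_c(theory, exp) == pytest.approx(3.25, abs=1e-12)

    def test_heteroscedastic_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        qg = sc.make_qgrid(0, 0.5, 0.025)
        theory = sc.ScatteringProfile(qg, rng.uniform(5, 50, len(qg)))
        exp = sc.ScatteringProfile(
            qg, theory.intensity + rng.normal(2.0, 1.0, len(qg)),
            sigma=rng.uniform(0.2, 5.0, len(qg)),
        )
        c_hat = sc.fit_offset_c(theory, exp)
        w = 1.0 / exp.sigma**2
        resid = exp.intensity - theory.intensity
        cs = np.linspace(c_hat - 0.5, c_hat + 0.5, 1_000_001)
        loss = ((resid[None, :] - cs[:, None]) ** 2 * w[None, :]).sum(axis=1)
        assert c_hat == pytest.approx(cs[np.argmin(loss)], abs=1e-6)

    @given(st.floats(min_value=-50, max_value=50))
    @settings(deadline=None, max_examples=25)
    def test_translation_equivariance(self, k):
        qg = sc.make_qgrid(0, 0.3, 0.05)
        theory = sc.ScatteringProfile(qg, np.linspace(20, 2, len(qg)))
        exp_i = np.linspace(21, 2.5, len(qg))
        sigma = np.linspace(0.5, 1.5, len(qg))
        c0 = sc.fit_offset_c(theory, sc.ScatteringProfile(qg, exp_i, sigma=sigma))
        ck = sc.fit_offset_c(
            theory, sc.ScatteringProfile(qg, exp_i + k, sigma=sigma)
        )
        assert ck == pytest.approx(c0 + k, abs=1e-9 * max(1, abs(k)))

    def test_corrected_residual_never_exceeds_uncorrected(self, tiny_ensemble):
        base = sc.debye_profile(tiny_ensemble[0], sc.make_qgrid(0, 0.5, 0.05))
        pert = sc.apply_condition(base, sc.DEFAULT_CONDITIONS[4])
        pert.sigma = np.full(len(pert.qgrid), 1.0)
        c = sc.fit_offset_c(base, pert)
        before = np.sum((pert.intensity - base.intensity) ** 2)
        after = np.sum((pert.intensity - base.intensity - c) ** 2)
        assert after <= before

    def test_mismatched_grids_rejected(self):
        a = sc.ScatteringProfile(sc.make_qgrid(0, 0.5, 0.05),
                                 np.ones(11))
        b = sc.ScatteringProfile(sc.make_qgrid(0, 0.5, 0.1), np.ones(6))
        with pytest.raises(sc.ScatteringError, match="matching q grids"):
            sc.fit_offset_c(a, b)
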