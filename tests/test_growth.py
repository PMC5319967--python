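"""Strain-driven growth law: stimuli, increments, kinematics, trajectories."""

import numpy as np
import pytest

from fetallv.geometry import lv_metrics, wall_volume
from fetallv.growth import (
    GrowthParams,
    NormativeTrajectory,
    apply_growth,
    growth_increment,
    growth_stimuli,
    simulate_growth,
)
from fetallv.mechanics import inflate

NQ = 180  # quadrature points of the reference topology


@pytest.fixture(scope="module")
def gparams():
    return GrowthParams(s_f50=0.08, s_t50=0.12).with_rate_scale(0.08)


class TestStimuli:
    def test_strains_at_setpoints_give_zero(self, ed_state):
        E = ed_state.E_fiber
        p = GrowthParams(
            s_f50=0.1, s_t50=0.1,
            e_f_set=0.0, e_t_set=0.0, transverse_stimulus="cc",
        )
        s_f, s_t = growth_stimuli(ed_state, p)
        # setting the setpoints to the observed strains zeroes the stimuli
        p2 = GrowthParams(s_f50=0.1, s_t50=0.1, transverse_stimulus="cc")
        sf0, st0 = growth_stimuli(ed_state, p2)
        np.testing.assert_allclose(sf0 - E[:, 0, 0], 0.0, atol=1e-14)

    def test_fiber_stimulus_is_strain_minus_setpoint(self, ed_state):
        p = GrowthParams(s_f50=0.1, s_t50=0.1, e_f_set=0.05)
        s_f, _ = growth_stimuli(ed_state, p)
        np.testing.assert_allclose(s_f, ed_state.E_fiber[:, 0, 0] - 0.05, atol=1e-14)

    def test_transverse_principal_matches_eigen_oracle(self, ed_state):
        """The closed-form maximal principal strain of the cross-fiber block
        equals the eigenvalue-solver result to 1e-12."""
        p = GrowthParams(s_f50=0.1, s_t50=0.1)
        _, s_t = growth_stimuli(ed_state, p)
        E = ed_state.E_fiber
        blocks = E[:, 1:, 1:]
        oracle = np.linalg.eigvalsh(blocks)[:, -1]
        np.testing.assert_allclose(s_t, oracle, atol=1e-12)

    def test_known_2x2_block(self):
        blk = np.array([[0.1, 0.02], [0.02, 0.05]])
        lam = np.linalg.eigvalsh(blk)[-1]
        closed = 0.075 + np.sqrt(0.025**2 + 0.02**2)
        assert lam == pytest.approx(closed, abs=1e-15)


class TestIncrement:
    def test_dead_band_is_identity(self, gparams):
        dff, dfc, dfr = growth_increment(
            (np.array([-0.01, 0.0]), np.array([0.0, -0.2])), gparams
        )
        np.testing.assert_array_equal(dff, 1.0)
        np.testing.assert_array_equal(dfc, 1.0)
        np.testing.assert_array_equal(dfr, 1.0)

    def test_half_activation_value(self, gparams):
        s = np.array([gparams.s_f50])
        dff, _, _ = growth_increment((s, np.array([-1.0])), gparams)
        expected = 1.0 + gparams.growth_dt * gparams.f_ff_max / 2.0
        assert dff[0] == pytest.approx(expected, rel=1e-12)

    def test_saturation_limit(self, gparams):
        dff, _, _ = growth_increment((np.array([100.0]), np.array([-1.0])), gparams)
        assert dff[0] == pytest.approx(1.0 + gparams.growth_dt * gparams.f_ff_max, rel=1e-9)

    def test_transverse_isotropy(self, gparams, rng):
        s_t = rng.uniform(0, 0.3, 8)
        _, dfc, dfr = growth_increment((np.full(8, -1.0), s_t), gparams)
        np.testing.assert_array_equal(dfc, dfr)

    def test_limits_clamp(self):
        p = GrowthParams(s_f50=0.0, s_t50=0.0, limit_max=1.05).with_rate_scale(0.5)
        dff, _, _ = growth_increment((np.array([10.0]), np.array([-1.0])), p)
        assert dff[0] == 1.05

    def test_uncalibrated_halfpoints_rejected(self, ed_state):
        with pytest.raises(ValueError):
            growth_increment((np.zeros(2), np.zeros(2)), GrowthParams())


class TestApplyGrowth:
    def test_identity_update_leaves_mesh_unchanged(self, ref_mesh, soft_material):
        g, diag = apply_growth(ref_mesh, (np.ones(NQ),) * 3, soft_material)
        np.testing.assert_array_equal(g.dofs, ref_mesh.dofs)
        assert diag["wall_ratio"] == 1.0

    def test_uniform_similarity_growth(self, ref_mesh, soft_material):
        s = 1.04
        g, diag = apply_growth(
            ref_mesh, (np.full(NQ, s),) * 3, soft_material
        )
        m0, m1 = lv_metrics(ref_mesh), lv_metrics(g)
        assert m1.wall_volume == pytest.approx(s**3 * m0.wall_volume, rel=0.01)
        assert m1.long_axis == pytest.approx(s * m0.long_axis, rel=0.01)
        assert m1.short_axis == pytest.approx(s * m0.short_axis, rel=0.01)

    def test_fiber_only_growth_widens_more_than_lengthens(
        self, ref_mesh, soft_material
    ):
        """Fiber growth (predominantly circumferential) grows the short axis
        more than the long axis, and wall volume tracks det(Fg) within 1%."""
        g, diag = apply_growth(
            ref_mesh, (np.full(NQ, 1.06), np.ones(NQ), np.ones(NQ)), soft_material
        )
        m0, m1 = lv_metrics(ref_mesh), lv_metrics(g)
        sa_gain = m1.short_axis / m0.short_axis
        la_gain = m1.long_axis / m0.long_axis
        assert sa_gain > la_gain
        assert diag["wall_ratio"] == pytest.approx(diag["det_integral_ratio"], rel=0.01)

    def test_wall_volume_equals_det_integral(self, ed_state, ref_mesh, soft_material, gparams):
        inc = growth_increment(growth_stimuli(ed_state, gparams), gparams)
        g, diag = apply_growth(ref_mesh, inc, soft_material)
        assert diag["wall_ratio"] == pytest.approx(diag["det_integral_ratio"], rel=0.01)

    def test_forward_then_reverse_step_returns_wall_volume(
        self, ed_state, ref_mesh, soft_material, gparams
    ):
        dff, dfc, dfr = growth_increment(growth_stimuli(ed_state, gparams), gparams)
        fwd, _ = apply_growth(ref_mesh, (dff, dfc, dfr), soft_material)
        back, _ = apply_growth(fwd, (1 / dff, 1 / dfc, 1 / dfr), soft_material)
        assert wall_volume(back) == pytest.approx(wall_volume(ref_mesh), rel=0.01)


class TestSimulateGrowth:
    def test_zero_rates_give_flat_trajectory(self, ref_mesh, soft_material):
        p = GrowthParams(s_f50=0.08, s_t50=0.12).with_rate_scale(0.0)
        traj = simulate_growth(ref_mesh, soft_material, p, 0.75, 22, 25)
        v = traj.data["cavity_volume"]
        assert v.max() - v.min() < 0.005 * v.iloc[0]

    def test_forward_growth_increases_volume_weekly(
        self, ref_mesh, soft_material, gparams
    ):
        traj = simulate_growth(ref_mesh, soft_material, gparams, 0.75, 22, 25)
        v = traj.data["cavity_volume"].to_numpy()
        assert np.all(np.diff(v) > 0)
        assert list(traj.data["age"]) == [22.0, 23.0, 24.0, 25.0]

    def test_reverse_growth_shrinks_toward_unloaded(
        self, ref_mesh, soft_material, gparams
    ):
        traj = simulate_growth(ref_mesh, soft_material, gparams, 0.75, 22, 20)
        v = traj.data["cavity_volume"].to_numpy()
        assert traj.direction == "reverse"
        assert v[-1] < v[0]

    def test_equal_ages_rejected(self, ref_mesh, soft_material, gparams):
        with pytest.raises(ValueError):
            simulate_growth(ref_mesh, soft_material, gparams, 0.75, 22, 22)


class TestNormativeTrajectory:
    def test_exponential_interpolation_hits_anchors(self):
        n = NormativeTrajectory()
        assert n.edv(22.0) == pytest.approx(1100.0)
        assert n.edv(40.0) == pytest.approx(8300.0)
        # log-linear midpoint
        assert n.edv(31.0) == pytest.approx(np.sqrt(1100.0 * 8300.0), rel=1e-12)

    def test_non_increasing_anchors_rejected(self):
        with pytest.raises(ValueError):
            NormativeTrajectory(anchors=((22.0, 1100.0), (40.0, 900.0)))

    def test_growth_params_validation(self):
        with pytest.raises(ValueError):
            GrowthParams(growth_dt=0.0)
        with pytest.raises(ValueError):
            GrowthParams(limit_min=1.2)
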