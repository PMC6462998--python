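"""Projection builders against the printed weight equations."""

import math

import numpy as np
import pytest

from dorsalflow.connectivity import (
    MstTemplateSpec,
    assign_focal_points,
    build_feedback_inhibition,
    build_lgn_v1,
    build_mst_lateral,
    build_mst_lip,
    build_mt_mst,
    build_v1_lateral,
    build_v1_mt,
    grid_coords,
    mst_template_weight,
    sample_map_at,
)
from dorsalflow.maps import GaborRF, OrientationMap, gabor, generate_map
from dorsalflow.retina import RGCParams, spatial_dog

GRID_POS = grid_coords(20)
INH_POS = grid_coords(10, spacing=2.0)


def const_map(theta: float, phase: float = 0.0, period: float = math.pi):
    shape = (20, 20)
    return OrientationMap(
        np.full(shape, theta % period),
        np.full(shape, phase % (2 * math.pi)),
        lambda_map=5.0,
        seed=0,
        period=period,
    )


@pytest.fixture(scope="module")
def v1_map():
    return generate_map((20, 20), 5.0, 40, seed=11, period=math.pi)


@pytest.fixture(scope="module")
def mt_map():
    return generate_map((20, 20), 5.0, 40, seed=21, period=2 * math.pi)


class TestLgnV1:
    def test_weights_follow_gabor_sign_mask(self, v1_map):
        on, off = build_lgn_v1(v1_map, GRID_POS, GRID_POS, gain=2.0, cutoff_frac=0.1)
        theta, phase = sample_map_at(v1_map, GRID_POS)
        j = 111
        rf = GaborRF((GRID_POS[j, 0], GRID_POS[j, 1]), theta[j], phase[j],
                     1.5, 0.75, 0.3)
        values = gabor(rf, GRID_POS[:, 0], GRID_POS[:, 1])
        cutoff = 0.1 * np.abs(values).max()
        on_pre = set(on.pre[on.post == j])
        assert on_pre == set(np.flatnonzero(values > cutoff))
        off_pre = set(off.pre[off.post == j])
        assert off_pre == set(np.flatnonzero(values < -cutoff))
        w = on.weight[on.post == j]
        np.testing.assert_allclose(np.sort(w), np.sort(2.0 * values[values > cutoff]))

    def test_default_weights_are_excitatory(self, v1_map):
        on, off = build_lgn_v1(v1_map, GRID_POS, GRID_POS)
        assert on.weight.min() >= 0.0 and off.weight.min() >= 0.0

    def test_maximal_cutoff_empties_the_projection(self, v1_map):
        on, off = build_lgn_v1(v1_map, GRID_POS, GRID_POS, cutoff_frac=1.0)
        assert on.n_synapses == 0 and off.n_synapses == 0

    def test_every_excitatory_cell_has_an_afferent(self, v1_map):
        on, off = build_lgn_v1(v1_map, GRID_POS, GRID_POS)
        targets = set(on.post) | set(off.post)
        assert targets == set(range(400))

    def test_push_pull_adds_anti_phase_inhibition(self, v1_map):
        on, _ = build_lgn_v1(v1_map, GRID_POS, GRID_POS, gain=1.0, pull_gain=0.5)
        assert on.weight.min() < 0.0 < on.weight.max()


class TestV1Lateral:
    def test_identical_rfs_get_maximal_excitation(self):
        from dorsalflow.maps import gabor_correlation

        omap = const_map(0.7, phase=1.0)
        sets = build_v1_lateral(omap, GRID_POS, INH_POS, g_exc=3.0)
        ee = sets[("V1e", "V1e")]
        # the strongest pair is a neighboring pair of identical RFs, whose
        # weight is g_exc times their (offset) Gabor correlation; which
        # neighbor offset wins depends on the carrier orientation
        a = GaborRF((0.0, 0.0), 0.7, 1.0, 1.0, 1.0, 0.3)
        best = max(
            gabor_correlation(a, GaborRF((dx, dy), 0.7, 1.0, 1.0, 1.0, 0.3))
            for dx, dy in ((1, 0), (0, 1), (1, 1), (1, -1))
        )
        assert ee.weight.max() == pytest.approx(3.0 * best, rel=0.1)
        assert np.all(ee.weight >= 0.0)

    def test_inhibition_follows_von_mises_phase_rule(self):
        # formula equality: w = -g * exp(kappa*(cos(dphase-pi)-1)) * gauss(d)
        omap = generate_map((20, 20), 5.0, 40, seed=2, period=math.pi)
        g_inh, kappa, sigma = 2.0, 2.0, 3.0
        sets = build_v1_lateral(omap, GRID_POS, INH_POS, g_inh=g_inh,
                                kappa_phase=kappa, sigma_inh=sigma)
        ie = sets[("V1i", "V1e")]
        assert ie.weight.max() <= 0.0
        _, phase_i = sample_map_at(omap, INH_POS)
        _, phase_e = sample_map_at(omap, GRID_POS)
        dphase = phase_i[ie.pre] - phase_e[ie.post]
        d2 = ((INH_POS[ie.pre] - GRID_POS[ie.post]) ** 2).sum(1)
        expected = -g_inh * np.exp(kappa * (np.cos(dphase - math.pi) - 1.0)) * np.exp(
            -d2 / (2 * sigma**2)
        )
        np.testing.assert_allclose(ie.weight, expected, atol=1e-12)
        # at matched distance, anti-phase pairs are inhibited hardest
        near = d2 < 0.6
        order = np.argsort(np.abs((dphase[near] + math.pi) % (2 * math.pi) - math.pi))
        w_near = -ie.weight[near]
        assert w_near[order[-1]] >= w_near[order[0]]

    def test_distant_orthogonal_pairs_prune_away(self):
        theta = np.zeros((20, 20))
        theta[:, 10:] = math.pi / 2
        omap = OrientationMap(theta, np.zeros((20, 20)), 5.0, 0, math.pi)
        sets = build_v1_lateral(omap, GRID_POS, INH_POS)
        ee = sets[("V1e", "V1e")]
        # a far-apart orthogonal pair: (0,0) grid corner vs (19,19)
        far = (ee.pre == 0) & (ee.post == 399)
        assert not far.any()

    def test_population_ratio_four_to_one(self, v1_map):
        sets = build_v1_lateral(v1_map, GRID_POS, INH_POS)
        assert len(GRID_POS) == 4 * len(INH_POS)
        assert set(sets) == {("V1e", "V1e"), ("V1e", "V1i"),
                             ("V1i", "V1e"), ("V1i", "V1i")}


class TestV1MT:
    def test_exhaustive_formula_equality(self, v1_map, mt_map):
        k_c, a_c, a_s, s_c, s_s = 2.0, 1.0, 0.5, 2.0, 6.0
        cs = build_v1_mt(v1_map, mt_map, GRID_POS, GRID_POS, k_c=k_c, a_c=a_c,
                         a_s=a_s, sigma_c=s_c, sigma_s=s_s, prune_frac=0.0)
        w = cs.to_dense(400, 400)
        theta_v1, _ = sample_map_at(v1_map, GRID_POS)
        theta_mt, _ = sample_map_at(mt_map, GRID_POS)
        dog = RGCParams(a_c=a_c, a_s=a_s, sigma_c=s_c, sigma_s=s_s)
        for i in range(0, 400, 7):  # post (MT)
            dx = GRID_POS[i, 0] - GRID_POS[:, 0]
            dy = GRID_POS[i, 1] - GRID_POS[:, 1]
            w_cs = spatial_dog(dog, dx, dy)
            ori_mt = (theta_mt[i] + math.pi / 2.0) % math.pi
            phi = np.abs(ori_mt - theta_v1 % math.pi)
            expected = np.where(phi <= math.pi / 2, k_c * w_cs * np.cos(phi), 0.0)
            np.testing.assert_allclose(w[i], expected, atol=1e-12)

    def test_orthogonal_beyond_gate_is_zero(self):
        # phi = 3*pi/4 for every pair -> all weights vanish
        v1 = const_map(0.0)
        mt = const_map(3 * math.pi / 4 + math.pi / 2, period=2 * math.pi)
        cs = build_v1_mt(v1, mt, GRID_POS, GRID_POS, k_c=1.0, prune_frac=0.0)
        assert cs.n_synapses == 0

    def test_cosine_ratio_at_pi_third(self):
        v1 = const_map(0.0)
        mt0 = const_map(math.pi / 2, period=2 * math.pi)  # phi = 0
        mt60 = const_map(math.pi / 3 + math.pi / 2, period=2 * math.pi)  # phi = pi/3
        w0 = build_v1_mt(v1, mt0, GRID_POS, GRID_POS, k_c=1.0,
                         prune_frac=0.0).to_dense(400, 400)
        w60 = build_v1_mt(v1, mt60, GRID_POS, GRID_POS, k_c=1.0,
                          prune_frac=0.0).to_dense(400, 400)
        nz = w0 != 0.0
        np.testing.assert_allclose(w60[nz] / w0[nz], 0.5, atol=1e-9)

    def test_nonpositive_amplification_rejected(self, v1_map, mt_map):
        with pytest.raises(ValueError):
            build_v1_mt(v1_map, mt_map, GRID_POS, GRID_POS, k_c=0.0)

    def test_motion_delays_graded_along_preference(self, v1_map, mt_map):
        cs = build_v1_mt(v1_map, mt_map, GRID_POS, GRID_POS, k_c=1.0,
                         motion_delay_v=20.0, motion_delay_base=100.0)
        assert cs.delay.min() >= 1.0 and cs.delay.max() <= 200.0
        theta_mt, _ = sample_map_at(mt_map, GRID_POS)
        # afferents ahead along the preferred direction arrive sooner
        j = cs.post[0]
        sel = cs.post == j
        d = np.array([math.cos(theta_mt[j]), math.sin(theta_mt[j])])
        s = (GRID_POS[cs.pre[sel]] - GRID_POS[j]) @ d
        expected = np.clip(100.0 - s / 20.0 * 1000.0, 1.0, 200.0)
        np.testing.assert_allclose(cs.delay[sel], expected)


class TestMstTemplates:
    spec = MstTemplateSpec("expansion", focal=(-7.0, 0.0))

    def test_orthogonal_direction_gated_out(self):
        # MT cell east of the focal point; outward direction is 0 rad
        w = mst_template_weight(self.spec, (0.0, 0.0), math.pi / 2, (0.0, 0.0))
        assert w == 0.0

    def test_focal_point_itself_is_degenerate(self):
        w = mst_template_weight(self.spec, (-7.0, 0.0), 0.0, (0.0, 0.0))
        assert w == 0.0

    def test_radial_falloff_ratio(self):
        # two eligible MT cells at different distances from the focal point
        w_near = mst_template_weight(self.spec, (-5.0, 0.0), 0.0, (-5.0, 0.0))
        w_far = mst_template_weight(self.spec, (-1.0, 0.0), 0.0, (-1.0, 0.0))
        ratio = w_far / w_near
        assert ratio == pytest.approx(
            math.exp(-self.spec.width * (6.0**2 - 2.0**2))
        )

    def test_contraction_gates_inward_motion(self):
        c = MstTemplateSpec("contraction", focal=(-7.0, 0.0))
        inward = mst_template_weight(c, (0.0, 0.0), math.pi, (0.0, 0.0))
        outward = mst_template_weight(c, (0.0, 0.0), 0.0, (0.0, 0.0))
        assert inward > 0.0 and outward == 0.0

    def test_mirror_symmetry_of_template(self):
        # reflecting focal point, MT position, MST position and direction
        # about the vertical axis leaves the weight unchanged
        rng = np.random.default_rng(5)
        for _ in range(50):
            fx = rng.choice([-7.0, 0.0, 7.0])
            mt = rng.uniform(-9, 9, 2)
            mst = rng.uniform(-9, 9, 2)
            d = rng.uniform(0, 2 * math.pi)
            w = mst_template_weight(
                MstTemplateSpec("expansion", focal=(fx, 0.0)), tuple(mt), d, tuple(mst)
            )
            w_ref = mst_template_weight(
                MstTemplateSpec("expansion", focal=(-fx, 0.0)),
                (-mt[0], mt[1]),
                (math.pi - d) % (2 * math.pi),
                (-mst[0], mst[1]),
            )
            assert w == pytest.approx(w_ref, abs=1e-12)

    def test_builder_matches_scalar_weight_function(self, mt_map):
        focal = assign_focal_points(GRID_POS)
        cs = build_mt_mst(mt_map, GRID_POS, GRID_POS, focal, "expansion", "MSTe",
                          gain=1.0)
        w = cs.to_dense(400, 400)
        theta, _ = sample_map_at(mt_map, GRID_POS)
        rng = np.random.default_rng(0)
        for i in rng.integers(0, 400, 40):  # MST cells
            spec = MstTemplateSpec("expansion", focal=(focal[i], 0.0))
            for j in rng.integers(0, 400, 20):  # MT cells
                expected = mst_template_weight(
                    spec, tuple(GRID_POS[j]), theta[j], tuple(GRID_POS[i])
                )
                assert w[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MstTemplateSpec("spiral")
        with pytest.raises(ValueError, match="meridian"):
            MstTemplateSpec("expansion", focal=(0.0, 1.0))


class TestMstLateral:
    focal_e = assign_focal_points(GRID_POS)
    focal_c = assign_focal_points(GRID_POS)

    def test_same_focal_excites_different_inhibits(self):
        sets = build_mst_lateral(GRID_POS, self.focal_e, self.focal_c,
                                 gain=1.0, sigma_ts=3.0)
        ee = sets[("MSTe", "MSTe")]
        same = self.focal_e[ee.pre] == self.focal_e[ee.post]
        assert np.all(ee.weight[same] > 0)
        assert np.all(ee.weight[~same] < 0)
        d2 = ((GRID_POS[ee.pre] - GRID_POS[ee.post]) ** 2).sum(1)
        expected = np.where(same, 1.0, -1.0) * np.exp(-d2 / (2 * 3.0**2))
        np.testing.assert_allclose(ee.weight, expected, atol=1e-12)

    def test_interlayer_all_inhibitory_with_focal_similarity(self):
        sets = build_mst_lateral(GRID_POS, self.focal_e, self.focal_c,
                                 gain=1.0, sigma_ts=3.0)
        ec = sets[("MSTe", "MSTc")]
        assert np.all(ec.weight <= 0.0)
        d2 = ((GRID_POS[ec.pre] - GRID_POS[ec.post]) ** 2).sum(1)
        df2 = (self.focal_e[ec.pre] - self.focal_c[ec.post]) ** 2
        expected = -np.exp(-d2 / 18.0) * np.exp(-df2 / 18.0)
        np.testing.assert_allclose(ec.weight, expected, atol=1e-12)

    def test_no_self_connections(self):
        sets = build_mst_lateral(GRID_POS, self.focal_e, self.focal_c)
        for key in (("MSTe", "MSTe"), ("MSTc", "MSTc")):
            cs = sets[key]
            assert not np.any(cs.pre == cs.post)


class TestMstLip:
    focal = assign_focal_points(GRID_POS)

    def test_sign_pattern(self):
        sets = build_mst_lip(self.focal, self.focal, g_exc=2.0, g_inh=0.5,
                             g_mutual=1.5)
        we = sets[("MSTe", "LIP")].to_dense(400, 2)
        left, center, right = self.focal == -7.0, self.focal == 0.0, self.focal == 7.0
        assert np.all(we[0, left] == 2.0) and np.all(we[1, left] == -0.5)
        assert np.all(we[1, right] == 2.0) and np.all(we[0, right] == -0.5)
        assert np.all(we[:, center] == -0.5)
        wc = sets[("MSTc", "LIP")].to_dense(400, 2)
        assert np.all(wc == -0.5)
        lip = sets[("LIP", "LIP")]
        assert set(zip(lip.pre, lip.post)) == {(0, 1), (1, 0)}
        assert np.all(lip.weight == -1.5)

    def test_left_right_afferents_are_mirror_images(self):
        sets = build_mst_lip(self.focal, self.focal)
        we = sets[("MSTe", "LIP")].to_dense(400, 2)
        # x-reflection of the 20x20 grid: column c -> 19 - c
        mirror = np.arange(400).reshape(20, 20)[:, ::-1].ravel()
        np.testing.assert_array_equal(we[0], we[1][mirror])


class TestFeedbackInhibition:
    def test_sign_pattern_and_alignment(self):
        sets = build_feedback_inhibition(GRID_POS, GRID_POS, g_v1_trn=2.0,
                                         g_v1_in=3.0, g_trn_lgn=1.5, g_in_lgn=0.5)
        assert np.all(sets[("V1e", "TRN_ON")].weight == 2.0)
        assert np.all(sets[("V1e", "IN_OFF")].weight == 3.0)
        assert np.all(sets[("TRN_ON", "LGN_ON")].weight == -1.5)
        assert np.all(sets[("IN_OFF", "LGN_OFF")].weight == -0.5)
        trn = sets[("TRN_ON", "LGN_ON")]
        np.testing.assert_array_equal(trn.pre, trn.post)  # retinotopic 1:1

    def test_zero_gain_empties_projection(self):
        sets = build_feedback_inhibition(GRID_POS, GRID_POS, g_trn_lgn=0.0)
        assert sets[("TRN_ON", "LGN_ON")].n_synapses == 0
        assert sets[("IN_ON", "LGN_ON")].n_synapses == 400
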