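import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seakit as sk
from seakit.scoring import (EULER_GAMMA, Z_TAYLOR_BRANCH, log10_p_value,
                            p_value, raw_score, z_score)

from conftest import brute_force_raw_score


def random_set(rng, n, n_bits=256, density=0.05):
    return [sk.Fingerprint(on_bits=frozenset(np.flatnonzero(rng.random(n_bits) < density)),
                           provider_id="p")
            for _ in range(n)]


class TestRawScore:
    def test_all_below_threshold_is_zero(self):
        a = [sk.Fingerprint(frozenset({1, 2}), "p")]
        b = [sk.Fingerprint(frozenset({2, 3}), "p")]  # TC = 1/3
        assert raw_score(a, b, ts=0.5) == 0.0

    def test_single_qualifying_pair(self):
        a = [sk.Fingerprint(frozenset({1, 2, 3, 4}), "p")]
        b = [sk.Fingerprint(frozenset({1, 2, 3, 4, 5}), "p")]  # TC = 0.8
        assert raw_score(a, b, ts=0.57) == pytest.approx(0.8)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            fa = random_set(rng, 20)
            fb = random_set(rng, 30)
            ts = float(rng.choice([0.0, 0.05, 0.1, 0.2]))
            assert raw_score(fa, fb, ts) == pytest.approx(
                brute_force_raw_score(fa, fb, ts), rel=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            raw_score([], [sk.Fingerprint(frozenset({1}), "p")], 0.0)


class TestZScore:
    def test_centered_and_scaled(self):
        mu, phi, eta = 0.001, 0.2, 0.8
        s = 50 * 60
        assert z_score(mu * s, 50, 60, mu, phi, eta) == pytest.approx(0.0)
        assert z_score(mu * s + phi * s ** eta, 50, 60, mu, phi, eta) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        # (40 - 0.001*10000) / (0.2 * 10000**0.8)
        z = z_score(40.0, 100, 100, mu=0.001, phi=0.2, eta=0.8)
        assert z == pytest.approx(30.0 / (0.2 * 10.0 ** 3.2), rel=1e-12)
        assert z == pytest.approx(0.09464, abs=5e-5)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            z_score(1.0, 10, 10, mu=0.1, phi=0.0, eta=0.5)


class TestPValue:
    def test_closed_form_at_zero(self):
        # 1 - exp(-e^{-gamma})
        expected = 1.0 - math.exp(-math.exp(-EULER_GAMMA))
        assert p_value(0.0) == pytest.approx(expected, rel=1e-12)
        assert p_value(0.0) == pytest.approx(0.4296, abs=5e-5)

    def test_limits(self):
        assert p_value(-50.0) == 1.0
        assert 0.0 <= p_value(600.0) < 1e-300

    def test_branch_continuity_at_switch(self):
        z = Z_TAYLOR_BRANCH
        x = -math.exp(-(z * math.pi / math.sqrt(6.0) + EULER_GAMMA))
        left = -math.expm1(x)
        right = -x - x * x / 2.0 - x ** 3 / 6.0
        assert abs(left - right) / left < 1e-6
        # and the implementation is continuous across the branch
        assert p_value(z) == pytest.approx(p_value(z + 1e-9), rel=1e-6)

    def test_strictly_decreasing(self):
        zs = np.linspace(-2.0, 60.0, 500)
        ps = [p_value(z) for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    @given(st.floats(min_value=-100.0, max_value=500.0))
    def test_always_a_probability(self, z):
        assert 0.0 <= p_value(z) <= 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            p_value(float("nan"))

    def test_log10_matches_direct_in_overlap(self):
        for z in (-1.0, 0.0, 5.0, 27.0, 28.5, 100.0):
            p = p_value(z)
            if p > 0:
                assert log10_p_value(z) == pytest.approx(math.log10(p), rel=1e-9)

    def test_log10_linear_tail_beyond_underflow(self):
        # where p underflows, log10 p keeps the Gumbel tail's linear slope in z
        slope = -math.pi / math.sqrt(6.0) / math.log(10.0)
        l1, l2 = log10_p_value(700.0), log10_p_value(800.0)
        assert (l2 - l1) / 100.0 == pytest.approx(slope, rel=1e-9)


class TestCompareSets:
    def test_self_comparison_highly_significant(self, planted_targets, planted_model):
        fps = planted_targets["T00"]
        score = sk.compare_sets(fps, fps, planted_model)
        assert score.p_value < 1e-10
        assert score.z_score > 10

    def test_symmetric_in_arguments(self, planted_targets, planted_model):
        a, b = planted_targets["T00"], planted_targets["T01"]
        s1 = sk.compare_sets(a, b, planted_model)
        s2 = sk.compare_sets(b, a, planted_model)
        assert (s1.raw_score, s1.z_score, s1.p_value) == (s2.raw_score, s2.z_score, s2.p_value)

    def test_null_comparisons_roughly_uniform_p(self, null_universe, null_model, null_tc):
        cfg = sk.BackgroundConfig(size_min=10, size_max=100, size_step=10,
                                  repetitions=45, seed=999,
                                  ts_grid=null_model._config().ts_grid)
        k = cfg.ts_grid.index(null_model.ts_)
        ps = []
        for smp in sk.generate_background_pairs(null_universe, cfg, tc_matrix=null_tc):
            z = z_score(smp.raw_scores[k], smp.n_a, smp.n_b,
                        null_model.mu_, null_model.phi_, null_model.eta_)
            ps.append(p_value(z))
        ps = np.asarray(ps)
        assert len(ps) >= 2000
        assert 0.03 <= (ps <= 0.05).mean() <= 0.07
        assert 0.35 <= (ps <= 0.5).mean() <= 0.65


class TestPredictTargets:
    def test_member_recovers_own_target_first(self, planted_universe, planted_targets,
                                              planted_model):
        member = planted_universe.family_members("T02")[0]
        fp = planted_universe.fingerprints[member]
        hits = sk.predict_targets(fp, planted_model, planted_targets, alpha=0.05)
        assert hits and hits[0][0] == "T02"

    def test_alpha_one_returns_everything(self, planted_universe, planted_targets,
                                          planted_model):
        fp = planted_universe.fingerprints[planted_universe.background_ids[0]]
        hits = sk.predict_targets(fp, planted_model, planted_targets, alpha=1.0)
        assert len(hits) == len(planted_targets)

    def test_threshold_nesting(self, planted_universe, planted_targets, planted_model):
        fp = planted_universe.fingerprints[planted_universe.family_members("T00")[3]]
        strict = {t for t, _ in sk.predict_targets(fp, planted_model, planted_targets, 0.01)}
        loose = {t for t, _ in sk.predict_targets(fp, planted_model, planted_targets, 0.05)}
        assert strict <= loose

    def test_empty_target_list_warns_and_returns_empty(self, planted_universe, planted_model):
        fp = planted_universe.fingerprints[planted_universe.background_ids[0]]
        assert sk.predict_targets(fp, planted_model, {}, alpha=0.05) == []

    def test_invalid_alpha_rejected(self, planted_universe, planted_targets, planted_model):
        fp = planted_universe.fingerprints[planted_universe.background_ids[0]]
        with pytest.raises(ValueError):
            sk.predict_targets(fp, planted_model, planted_targets, alpha=0.0)


class TestTargetNetwork:
    def test_zero_cutoff_empty(self, planted_targets, planted_model):
        assert sk.target_network(planted_targets, planted_model, 0.0) == []

    def test_duplicated_set_connected(self, planted_targets, planted_model):
        pair = {"A": planted_targets["T00"], "B": list(planted_targets["T00"])}
        edges = sk.target_network(pair, planted_model, 1e-10)
        assert [(e[0], e[1]) for e in edges] == [("A", "B")]

    def test_edge_count_monotone_in_cutoff(self, planted_targets, planted_model):
        counts = [len(sk.target_network(planted_targets, planted_model, p))
                  for p in (1e-12, 1e-4, 0.5, 1.0)]
        assert counts == sorted(counts)

    def test_deep_cutoff_uses_log_tail(self, planted_targets, planted_model):
        # self-similar duplicated sets reach the 1e-80 regime
        pair = {"A": planted_targets["T00"], "B": list(planted_targets["T00"])}
        edges = sk.target_network(pair, planted_model, 1e-80)
        assert len(edges) == 1
        assert edges[0][5] <= -80  # log10 p
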