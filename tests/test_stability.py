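import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import dietrrr as d


@pytest.fixture(scope="module")
def fitted_pair():
    cfg = d.default_config(seed=17, n_participants=300)
    i1, i2, r1, r2, truth = d.generate_cohort(cfg)
    m1 = d.fit_rrr(d.standardize(i1.foods, "wave1"), d.standardize(r1.values), 3)
    m2 = d.fit_rrr(d.standardize(i2.foods, "wave2"), d.standardize(r2.values), 3)
    return i1, i2, m1, m2


class TestConfirmatoryScore:
    def test_same_wave_confirmatory_equals_exploratory(self, fitted_pair):
        i1, _, m1, _ = fitted_pair
        conf = d.confirmatory_score(m1, i1)
        for f in m1.factor_names:
            r = np.corrcoef(conf.scores[f], m1.scores[f])[0, 1]
            assert abs(r - 1) < 1e-12

    def test_scores_are_zero_mean_unit_sd(self, fitted_pair):
        i1, i2, m1, _ = fitted_pair
        conf = d.confirmatory_score(m1, i2)
        np.testing.assert_allclose(conf.scores.mean(), 0, atol=1e-10)
        np.testing.assert_allclose(conf.scores.std(ddof=1), 1, atol=1e-10)

    def test_perfect_tracking_noise_free_gives_unit_correlation(self):
        cfg = d.default_config(seed=23, n_participants=300, tracking_rho=(1, 1, 1))
        cfg = replace(cfg, share_wave_noise=True)
        i1, i2, r1, r2, _ = d.generate_cohort(cfg)
        m1 = d.fit_rrr(d.standardize(i1.foods), d.standardize(r1.values), 1)
        conf = d.confirmatory_score(m1, i2)
        r = np.corrcoef(m1.scores["factor_1"], conf.scores["factor_1"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_missing_food_rejected(self, fitted_pair):
        i1, _, m1, _ = fitted_pair
        crippled = d.IntakeTable(
            foods=i1.foods.drop(columns=[m1.food_names[0]]), wave="w"
        )
        with pytest.raises(ValueError, match="lacks"):
            d.confirmatory_score(m1, crippled)

    def test_cross_wave_correlation_increases_with_tracking(self):
        means = []
        for rho in (0.2, 0.5, 0.8):
            rs = []
            for s in range(8):
                cfg = d.default_config(
                    seed=1000 + s, n_participants=300, tracking_rho=(rho, rho, rho)
                )
                i1, i2, r1, r2, _ = d.generate_cohort(cfg)
                m1 = d.fit_rrr(d.standardize(i1.foods), d.standardize(r1.values), 1)
                conf = d.confirmatory_score(m1, i2)
                rs.append(
                    abs(np.corrcoef(m1.scores["factor_1"], conf.scores["factor_1"])[0, 1])
                )
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]


class TestAlignSigns:
    def test_pure_reflection_flips_all(self, fitted_pair):
        _, _, m1, _ = fitted_pair
        negated = d.apply_signs(m1, -np.ones(m1.k))
        signs = d.align_signs(m1, negated)
        np.testing.assert_array_equal(signs, -np.ones(m1.k))
        realigned = d.apply_signs(negated, signs)
        pd.testing.assert_frame_equal(realigned.weights, m1.weights)

    def test_aligned_models_keep_identity(self, fitted_pair):
        _, _, m1, _ = fitted_pair
        np.testing.assert_array_equal(d.align_signs(m1, m1), np.ones(m1.k))

    def test_alignment_preserves_absolute_correlations(self, fitted_pair):
        _, _, m1, m2 = fitted_pair
        signs = d.align_signs(m1, m2)
        flipped = d.apply_signs(m2, signs)
        for f in m1.factor_names:
            r_before = np.corrcoef(m1.scores[f], m2.scores[f])[0, 1]
            r_after = np.corrcoef(m1.scores[f], flipped.scores[f])[0, 1]
            assert abs(r_before) == pytest.approx(abs(r_after), abs=1e-12)


class TestFisherCI:
    def test_null_symmetric_case(self):
        lo, hi = d.fisher_ci(0.0, 10003)
        assert lo == pytest.approx(-0.0196, abs=2e-4)
        assert hi == pytest.approx(0.0196, abs=2e-4)

    def test_closed_form_at_moderate_correlation(self):
        # tanh(atanh(0.47) +/- 1.96 / sqrt(464))
        lo, hi = d.fisher_ci(0.47, 467)
        assert lo == pytest.approx(0.3962, abs=5e-4)
        assert hi == pytest.approx(0.5379, abs=5e-4)

    def test_interval_contains_r(self):
        for r in (-0.9, -0.3, 0.0, 0.5, 0.95):
            lo, hi = d.fisher_ci(r, 50)
            assert lo < r < hi

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            d.fisher_ci(1.0, 100)
        with pytest.raises(ValueError):
            d.fisher_ci(0.5, 3)


class TestStabilityReport:
    @staticmethod
    def _report(seed=31, rho=(0.6, 0.5, 0.4), k=2):
        cfg = d.default_config(seed=seed, n_participants=300, tracking_rho=rho)
        i1, i2, r1, r2, _ = d.generate_cohort(cfg)
        m1 = d.fit_rrr(d.standardize(i1.foods, "w1"), d.standardize(r1.values), k)
        m2 = d.fit_rrr(d.standardize(i2.foods, "w2"), d.standardize(r2.values), k)
        c21 = d.confirmatory_score(m1, i2)
        c12 = d.confirmatory_score(m2, i1)
        return m1, m2, c21, c12, i1, i2

    def test_four_blocks_symmetry_and_cis(self):
        m1, m2, c21, c12, i1, i2 = self._report()
        rep = d.stability_report(m1, m2, c21, c12, i1, i2)
        cols = list(rep.correlations.columns)
        for block in ("expl_w1", "expl_w2", "conf_d2_l1", "conf_d1_l2"):
            assert sum(c.startswith(block) for c in cols) == m1.k
        np.testing.assert_allclose(np.diag(rep.correlations), 1.0, atol=1e-12)
        pd.testing.assert_frame_equal(rep.correlations, rep.correlations.T)
        mask = ~rep.ci_lower.isna()
        assert ((rep.ci_lower <= rep.correlations) | ~mask).all().all()
        assert ((rep.ci_upper >= rep.correlations) | ~mask).all().all()

    def test_same_wave_confirmatory_block_is_unit(self):
        m1, m2, c21, c12, i1, i2 = self._report()
        rep = d.stability_report(m1, m2, c21, c12, i1, i2)
        for f in m1.factor_names:
            assert rep.correlations.loc[
                f"conf_d2_l1:{f}", f"conf_d2_l1:{f}"
            ] == pytest.approx(1.0)

    def test_invariant_under_factor_sign_flips(self):
        m1, m2, c21, c12, i1, i2 = self._report()
        rep_a = d.stability_report(m1, m2, c21, c12, i1, i2)
        flip = np.array([-1.0, 1.0])
        m2f = d.apply_signs(m2, flip)
        c12f = d.confirmatory_score(m2f, i1)
        rep_b = d.stability_report(m1, m2f, c21, c12f, i1, i2)
        pd.testing.assert_frame_equal(
            rep_a.correlations, rep_b.correlations, atol=1e-10, rtol=0
        )

    def test_participant_mismatch_rejected(self):
        m1, m2, c21, c12, i1, i2 = self._report()
        broken = d.ConfirmatoryScore(
            scores=c21.scores.iloc[:-1], diet_wave="w2", loading_wave="w1",
            standardization="diet",
        )
        with pytest.raises(ValueError, match="participants"):
            d.stability_report(m1, m2, broken, c12, i1, i2)
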