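"""Hierarchical effects model: posterior machinery and recovery."""

import numpy as np
import pandas as pd
import pytest

from ppvkit.effects_model import (
    EffectsModelSpec,
    _build_design,
    _log_prob,
    _make_logp_grad,
    cv_contrast,
    fit_effects_model,
    validate_cohort,
)
from ppvkit.synthetic import CohortSimConfig, gen_cohort


@pytest.fixture(scope="module")
def cohort20():
    cohort, _, truth = gen_cohort(CohortSimConfig(n_patients=20, seed=11))
    return cohort, truth


@pytest.fixture(scope="module")
def posterior20(cohort20):
    cohort, _ = cohort20
    return fit_effects_model(cohort, iters=1200, chains=4, seed=3)


class TestValidation:
    def test_nonpositive_ppv_rejected(self, cohort20):
        cohort, _ = cohort20
        bad = cohort.copy()
        bad.loc[bad.index[0], "ppv_pct"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            validate_cohort(bad)

    def test_duplicate_rows_rejected(self, cohort20):
        cohort, _ = cohort20
        bad = pd.concat([cohort, cohort.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort(bad)

    def test_too_few_patients_rejected(self, cohort20):
        cohort, _ = cohort20
        small = cohort[cohort.patient_id.isin(cohort.patient_id.unique()[:3])]
        with pytest.raises(ValueError, match="5 patients"):
            fit_effects_model(small, iters=100, seed=0)


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self, cohort20):
        cohort, _ = cohort20
        spec = EffectsModelSpec()
        d = _build_design(cohort, spec)
        lg = _make_logp_grad(d, spec)
        rng = np.random.default_rng(0)
        th = rng.normal(0, 0.3, d.n_params)
        th[d.slices["a"]] += 2.0
        lp, grad = lg(th)
        for i in rng.choice(d.n_params, size=12, replace=False):
            e = np.zeros_like(th)
            e[i] = 1e-6
            num = (lg(th + e)[0] - lg(th - e)[0]) / 2e-6
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_single_and_vectorised_density_agree(self, cohort20):
        cohort, _ = cohort20
        spec = EffectsModelSpec()
        d = _build_design(cohort, spec)
        lg = _make_logp_grad(d, spec)
        rng = np.random.default_rng(1)
        ths = rng.normal(0, 0.2, (4, d.n_params))
        ths[:, d.slices["a"]] += 2.0
        vec = _log_prob(ths, d, spec)
        for k in range(4):
            assert lg(ths[k])[0] == pytest.approx(float(vec[k]), rel=1e-12)


class TestPosterior:
    def test_convergence_diagnostics(self, posterior20):
        assert posterior20.rhat_max < 1.05
        assert posterior20.ess_min > 50

    def test_relative_effects_recovered(self, posterior20, cohort20):
        _, truth = cohort20
        tab = posterior20.relative_effects_table()
        assert len(tab) == 12  # 2 methods x (3 vt + 3 rr) levels
        covered = 0
        for _, row in tab.iterrows():
            true_pct = 100 * truth[f"e_{row.dimension}"][row.method][row.level]
            assert row.lo_pct < row.median_pct < row.hi_pct
            # medians in the right neighbourhood even when an interval misses
            assert row.median_pct == pytest.approx(true_pct, abs=12)
            covered += int(row.lo_pct <= true_pct <= row.hi_pct)
        assert covered >= 10

    def test_reference_factor_is_unity(self, posterior20):
        draws = posterior20.relative_effect_draws("gam", "vt", 10.0)
        assert np.all(draws == 1.0)

    def test_correction_roundtrip_with_posterior_factors(self, posterior20):
        from ppvkit.filters import VentilatorSetting
        from ppvkit.ppv import correct_ppv

        eff = posterior20.relative_effects("gam")
        s = VentilatorSetting(vt=6, rr=24)
        corrected = correct_ppv(8.0, s, eff)
        assert corrected > 8.0  # low-V_T/high-RR PPV corrects upwards

    def test_cv_contrast_of_setting_with_itself_is_zero(self, posterior20):
        c = cv_contrast(posterior20, (6, 31, "classic"), (6, 31, "classic"))
        assert c["median"] == 0.0 and c["lo"] == 0.0 and c["hi"] == 0.0

    def test_classic_noisier_at_high_rr_detected(self, posterior20):
        # generator doubles the classic residual scale at RR = 31
        c = cv_contrast(posterior20, (6, 31, "classic"), (6, 31, "gam"))
        assert c["median"] > 0
        assert c["lo"] > 0  # interval excludes zero


class TestScaleInvariance:
    def test_rescaling_ppv_moves_only_intercepts(self, cohort20):
        cohort, _ = cohort20
        sub = cohort[cohort.patient_id.isin(cohort.patient_id.unique()[:12])]
        a = fit_effects_model(sub, iters=900, chains=3, seed=5)
        scaled = sub.copy()
        scaled["ppv_pct"] = scaled["ppv_pct"] * 3.0
        b = fit_effects_model(scaled, iters=900, chains=3, seed=5)
        ta, tb = a.relative_effects_table(), b.relative_effects_table()
        assert np.allclose(ta.median_pct, tb.median_pct, atol=2.0)
        da = np.median(a.draws["a"], axis=0)
        db = np.median(b.draws["a"], axis=0)
        assert np.allclose(db - da, np.log(3.0), atol=0.1)

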