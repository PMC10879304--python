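"""Classic max/min-pair PPV: formula, pairing, aliasing behaviour."""

import numpy as np
import pytest

from ppvkit.filters import VentilatorSetting
from ppvkit.ppv import correct_ppv, correct_ppv_pragmatic, ppv_classic, ppv_pair, RelativeEffects
from ppvkit.synthetic import BeatSimConfig, window_from_config
from tests.conftest import make_window


class TestPPVPair:
    @pytest.mark.parametrize(
        "pmax,pmin,expected", [(60, 40, 40.0), (50, 50, 0.0), (55, 45, 20.0)]
    )
    def test_normalized_difference_formula(self, pmax, pmin, expected):
        assert ppv_pair(pmax, pmin) == pytest.approx(expected)

    def test_nonpositive_minimum_rejected(self):
        with pytest.raises(ValueError):
            ppv_pair(50, 0)

    def test_inverted_pair_rejected(self):
        with pytest.raises(ValueError):
            ppv_pair(40, 60)


def percycle_oracle(t, pp, t_resp, n_pairs=3):
    """Brute force: split into whole respiratory cycles, PPV per cycle from
    that cycle's sampled max/min, mean of the last n_pairs complete cycles."""
    n_cyc = int((t[-1] - t[0]) // t_resp)
    vals = []
    for k in range(n_cyc):
        m = (t >= t[0] + k * t_resp) & (t < t[0] + (k + 1) * t_resp)
        if m.sum() >= 2:
            vals.append(ppv_pair(pp[m].max(), pp[m].min()))
    return float(np.mean(vals[-n_pairs:]))


class TestPPVClassic:
    def test_matches_per_cycle_oracle_on_regular_sine(self):
        # beats at 1 Hz, pp = 50 + 5 sin(2 pi t / 6): RR = 10, HR/RR = 6
        t = np.arange(0.0, 30.0)
        pp = 50 + 5 * np.sin(2 * np.pi * t / 6)
        w = make_window(t, pp, rr=10, duration=30.0)
        est = ppv_classic(w)
        oracle = percycle_oracle(t, pp, 6.0)
        assert est.available
        assert est.ppv == pytest.approx(oracle, abs=0.3)
        # true modulation is 20%; discrete sampling can only underestimate
        assert 15.0 < est.ppv <= 20.0

    def test_constant_pp_gives_zero(self):
        t = np.arange(0.0, 30.0)
        w = make_window(t, np.full(30, 50.0), rr=10, duration=30.0)
        est = ppv_classic(w)
        assert est.available and est.ppv == pytest.approx(0.0, abs=1e-12)

    def test_one_beat_per_cycle_aliases_to_zero(self):
        # HR = RR with phase-locked beats: every sampled PP is identical,
        # so the classic method reads ~0 despite a 15% true modulation
        w, truth = window_from_config(
            BeatSimConfig(hr=20, rr=20, ppv_true=15, phase_lock=0.2, duration_s=90)
        )
        est = ppv_classic(w)
        assert est.available
        assert est.ppv == pytest.approx(0.0, abs=1e-9)

    def test_too_few_pairs_flagged_unavailable_not_zero(self):
        t = np.arange(0.0, 8.0)
        pp = 50 + 5 * np.sin(2 * np.pi * t / 6)
        w = make_window(t, pp, rr=10, duration=8.0)
        est = ppv_classic(w)
        assert not est.available
        assert np.isnan(est.ppv)
        assert "pairs" in est.reason

    def test_invalid_window_unavailable(self):
        t = np.arange(0.0, 30.0)
        w = make_window(t, np.full(30, 50.0), rr=10, duration=30.0)
        w.valid = False
        assert not ppv_classic(w).available

    def test_pp_scale_invariance(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.uniform(0.7, 0.9, 40))
        pp = 50 + 6 * np.sin(2 * np.pi * t / 5) + rng.normal(0, 0.5, 40)
        w1 = make_window(t, pp, rr=12, duration=35.0)
        w2 = make_window(t, 3.0 * pp, rr=12, duration=35.0)
        assert ppv_classic(w1).ppv == pytest.approx(ppv_classic(w2).ppv, abs=1e-9)

    def test_hr_computed_from_included_beats(self):
        t = np.arange(0.0, 30.0)
        pp = 50 + 5 * np.sin(2 * np.pi * t / 6)
        w = make_window(t, pp, rr=10, duration=30.0)
        est = ppv_classic(w)
        assert est.hr == pytest.approx(60.0)
        assert est.hr_rr_ratio == pytest.approx(6.0)


class TestCorrections:
    def test_worked_example_low_vt_high_rr(self):
        # PPV 8% at V_T 6 ml/kg, RR 24/min with relative effects 0.64 and
        # 0.87 corrects to ~14% at the reference setting
        eff = RelativeEffects(vt={6: 0.64}, rr={24: 0.87})
        out = correct_ppv(8.0, VentilatorSetting(vt=6, rr=24), eff)
        assert out == pytest.approx(14.37, abs=0.01)
        assert round(out) == 14

    def test_reference_setting_is_identity(self):
        eff = RelativeEffects(vt={6: 0.64}, rr={24: 0.87})
        assert correct_ppv(9.5, VentilatorSetting(vt=10, rr=10), eff) == pytest.approx(9.5)

    def test_single_factor(self):
        eff = RelativeEffects(vt={8: 0.8}, rr={})
        assert correct_ppv(10.0, VentilatorSetting(vt=8, rr=10), eff) == pytest.approx(12.5)

    def test_missing_factor_raises(self):
        eff = RelativeEffects(vt={6: 0.64}, rr={})
        with pytest.raises(KeyError, match="rr=24"):
            correct_ppv(8.0, VentilatorSetting(vt=6, rr=24), eff)

    @pytest.mark.parametrize(
        "ppv,vt,expected", [(8, 6, 13.333), (12, 10, 12.0), (5, 4, 12.5)]
    )
    def test_pragmatic_proportional_correction(self, ppv, vt, expected):
        assert correct_ppv_pragmatic(ppv, vt) == pytest.approx(expected, abs=0.001)
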