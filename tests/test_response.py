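"""Fluid-challenge classification and DeLong ROC analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppvkit.response import delta_sv, roc_delong


class TestDeltaSV:
    def test_median_based_delta(self):
        pre = [57, 58, 58, 59, 60, 56]  # median 58
        post = [67, 68, 68, 69, 70, 66]  # median 68
        fc = delta_sv(pre, post)
        assert fc.sv_pre == 58 and fc.sv_post == 68
        assert fc.delta_sv == pytest.approx(100 * 10 / 58, abs=0.01)
        assert fc.responder

    def test_identical_phases_zero_delta(self):
        fc = delta_sv([70] * 6, [70] * 6)
        assert fc.delta_sv == 0.0 and not fc.responder

    def test_exactly_10pct_is_not_a_responder(self):
        fc = delta_sv([70] * 6, [77] * 6)
        assert fc.delta_sv == pytest.approx(10.0)
        assert not fc.responder

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            delta_sv([], [70] * 6)


def auc_bruteforce(scores, labels):
    """All positive-negative pairs; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def delong_var_bruteforce(scores, labels):
    """Structural components computed pair by pair."""
    pos = np.array([s for s, l in zip(scores, labels) if l], float)
    neg = np.array([s for s, l in zip(scores, labels) if not l], float)
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if len(pos) > 1:
        var += np.var(v10, ddof=1) / len(pos)
    if len(neg) > 1:
        var += np.var(v01, ddof=1) / len(neg)
    return var


class TestROCDeLong:
    def test_perfect_separation(self):
        r = roc_delong([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.threshold_opt == 10

    @pytest.mark.parametrize(
        "scores,labels,expected",
        [([1, 2, 3, 4], [0, 0, 1, 1], 1.0), ([1, 3, 2, 4], [0, 0, 1, 1], 0.75)],
    )
    def test_small_instances_match_pair_counting(self, scores, labels, expected):
        assert roc_delong(scores, labels).auc == pytest.approx(expected)

    def test_null_case_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(10, 3, 400)
        labels = rng.random(400) < 0.5
        r = roc_delong(scores, labels)
        assert r.auc == pytest.approx(0.5, abs=0.08)
        assert r.ci95[0] < 0.5 < r.ci95[1]

    def test_matches_bruteforce_on_random_instances_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            if labels.all() or not labels.any():
                continue
            # integer scores force ties
            scores = rng.integers(0, 8, n).astype(float)
            r = roc_delong(scores, labels)
            assert r.auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)
            assert r.auc_se**2 == pytest.approx(
                delong_var_bruteforce(scores, labels), abs=1e-12
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_leaves_auc_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.normal(8, 4, n)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            return
        a = roc_delong(scores, labels).auc
        b = roc_delong(np.exp(scores / 5.0), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_shrinks_with_sample_size(self):
        def width(n, seed):
            rng = np.random.default_rng(seed)
            pos = rng.normal(12, 3, n)
            neg = rng.normal(8, 3, n)
            r = roc_delong(
                np.r_[pos, neg], np.r_[np.ones(n, bool), np.zeros(n, bool)]
            )
            return r.ci95[1] - r.ci95[0]

        w_small = np.mean([width(25, s) for s in range(5)])
        w_big = np.mean([width(100, s) for s in range(5)])
        # ~1/sqrt(n): quadrupling n should halve the width
        assert w_big == pytest.approx(w_small / 2, rel=0.35)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roc_delong([1, 2, 3], [1, 1, 1])

    def test_ci_stays_in_unit_interval_near_one(self):
        r = roc_delong([1, 2, 3, 8, 9, 10, 11], [0, 0, 0, 1, 1, 1, 1])
        assert 0.0 <= r.ci95[0] <= r.auc <= r.ci95[1] <= 1.0
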