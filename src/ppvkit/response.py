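"""Fluid-challenge response and ROC analysis with DeLong intervals.

The stroke-volume response to a fluid bolus is
``ΔSV = 100·(SV_post − SV_pre)/SV_pre`` with SV_pre/SV_post the medians of
six stroke-volume samples over the two minutes before/after the challenge;
a patient is a *responder* when ΔSV exceeds 10% (strictly).

PPV's ability to discriminate responders is summarised by the area under
the ROC curve; its 95% confidence interval uses DeLong's structural-
components variance estimator, and the reported threshold maximizes
Youden's J (sensitivity + specificity − 1), with ties resolved toward the
lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["FluidChallenge", "ROCResult", "delta_sv", "roc_delong"]

RESPONDER_THRESHOLD = 10.0  #: percent ΔSV; strictly greater => responder


@dataclass(frozen=True)
class FluidChallenge:
    """One patient's stroke-volume response to a fluid bolus."""

    sv_pre_samples: tuple[float, ...]
    sv_post_samples: tuple[float, ...]
    sv_pre: float
    sv_post: float
    delta_sv: float  #: percent
    responder: bool


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    auc_se: float
    threshold_opt: float  #: PPV (%) maximizing Youden's J
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def delta_sv(pre, post) -> FluidChallenge:
    """Summarise a fluid challenge from pre/post SV sample lists (mL)."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("pre and post sample lists must be non-empty")
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("stroke volumes must be positive")
    sv_pre = float(np.median(pre))
    sv_post = float(np.median(post))
    d = 100.0 * (sv_post - sv_pre) / sv_pre
    return FluidChallenge(
        sv_pre_samples=tuple(pre),
        sv_post_samples=tuple(post),
        sv_pre=sv_pre,
        sv_post=sv_post,
        delta_sv=d,
        responder=d > RESPONDER_THRESHOLD,
    )


def _midrank_placements(scores_pos: np.ndarray, scores_neg: np.ndarray):
    """DeLong structural components via mid-ranks (ties count one half)."""
    m, n = scores_pos.size, scores_neg.size
    allv = np.concatenate([scores_pos, scores_neg])
    r_all = rankdata(allv)  # mid-ranks
    r_pos = rankdata(scores_pos)
    r_neg = rankdata(scores_neg)
    v10 = (r_all[:m] - r_pos) / n  # P(X > Y) + 0.5 P(X = Y), per positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # per negative
    return v10, v01


def roc_delong(scores, labels, ci_level: float = 0.95) -> ROCResult:
    """AUC with a DeLong confidence interval and the Youden threshold.

    ``scores`` are PPV values; ``labels`` truthy for fluid responders.
    The AUC equals the Mann–Whitney concordance probability (ties 1/2).
    When the normal-approximation interval leaves [0, 1] (AUC near the
    ends), it is recomputed on the logit scale.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("degenerate labels: both classes must be present")

    v10, v01 = _midrank_placements(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = auc - z * se, auc + z * se
    if (lo < 0.0 or hi > 1.0) and 0.0 < auc < 1.0 and se > 0:
        # delta method on the logit scale keeps the interval inside [0, 1]
        l_auc = np.log(auc / (1 - auc))
        l_se = se / (auc * (1 - auc))
        lo = 1.0 / (1.0 + np.exp(-(l_auc - z * l_se)))
        hi = 1.0 / (1.0 + np.exp(-(l_auc + z * l_se)))
    lo, hi = max(lo, 0.0), min(hi, 1.0)

    # Youden-optimal threshold over candidate cuts at observed scores
    cand = np.unique(scores)
    best = None
    for c in cand:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, thr, sens, spec = best
    return ROCResult(
        auc=auc,
        ci95=(float(lo), float(hi)),
        auc_se=se,
        threshold_opt=float(thr),
        sensitivity=sens,
        specificity=spec,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )
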