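"""Bland–Altman agreement between the GAM and classic PPV estimators.

Bias is ``mean(PPV_GAM − PPV_Classic)`` and the 95% limits of agreement
are ``bias ± 1.96·SD`` of the paired differences.  Confidence intervals
for bias and both limits come from a nonparametric case-resampling
bootstrap (percentile intervals, 4000 resamples by default, seeded).

Pairs can be stratified by the heart-rate/respiratory-rate ratio at 3.6
beats per breath — below this the classic estimator samples each
respiratory cycle too sparsely and is expected to read low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlandAltmanResult", "bland_altman", "stratify_by_hr_rr"]

HR_RR_CUT = 3.6


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float  #: mean(gam − classic), percentage points
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    stratum: str = ""


def _ba_point(d: np.ndarray) -> tuple[float, float, float, float]:
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def bland_altman(
    pairs,
    n_boot: int = 4000,
    seed: int | np.random.Generator = 0,
    stratum: str = "",
) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for (gam, classic) PPV pairs.

    ``pairs`` is a sequence of (gam, classic) values in percent; bootstrap
    CIs are percentile intervals over case resamples.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (gam, classic) pairs")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    d = arr[:, 0] - arr[:, 1]
    bias, sd, lo, hi = _ba_point(d)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boot = d[idx]
    b_bias = boot.mean(axis=1)
    b_sd = boot.std(axis=1, ddof=1)
    b_lo = b_bias - 1.96 * b_sd
    b_hi = b_bias + 1.96 * b_sd

    def pct(x):
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    return BlandAltmanResult(
        n=int(d.size),
        bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        ci_bias=pct(b_bias),
        ci_loa_low=pct(b_lo),
        ci_loa_high=pct(b_hi),
        stratum=stratum,
    )


def stratify_by_hr_rr(pairs, ratios, cut: float = HR_RR_CUT):
    """Split (gam, classic) pairs into HR/RR < cut and >= cut strata.

    Pairs where either estimate is missing (NaN) are dropped; the return
    is ``(low, high, n_dropped)`` with low/high as (n, 2) arrays.
    """
    arr = np.asarray(pairs, float)
    ratios = np.asarray(ratios, float)
    if arr.shape[0] != ratios.size:
        raise ValueError("pairs and ratios must align")
    ok = np.all(np.isfinite(arr), axis=1) & np.isfinite(ratios)
    n_dropped = int(np.sum(~ok))
    arr, ratios = arr[ok], ratios[ok]
    low = arr[ratios < cut]
    high = arr[ratios >= cut]
    return low, high, n_dropped
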