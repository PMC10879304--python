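"""PPV estimators: classic max/min pairing and GAM decomposition.

Pulse pressure variation quantifies the ventilator-induced oscillation of
arterial pulse pressure, as a percentage of mean PP.  Two estimators are
provided for a 30-s analysis window:

* :func:`ppv_classic` — the bedside-monitor convention: alternately locate
  a running PP maximum then minimum, each extremum within one respiratory
  cycle length of the previous one, compute per-pair PPV, and average the
  last three pairs.  With few beats per respiratory cycle (low HR/RR) the
  sampled extremes miss the true crest and trough, so this estimator
  underestimates.
* :func:`ppv_gam` — decompose the beat-wise PP series into a slow trend
  plus a zero-mean cyclic respiratory component via a penalized additive
  model; PPV is the cyclic component's peak-to-peak amplitude (read off a
  dense phase grid) divided by mean PP.  Pooling all beats across cycles
  makes this robust to sparse within-cycle sampling.

Also here: the ventilator-setting corrections that map a PPV observed at
one (V_T, RR) setting to the expected PPV at the reference setting
(V_T = 10 ml/kg, RR = 10/min), using multiplicative relative effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pgam import CyclicDecomposition, fit_cyclic_decomposition
from .filters import AnalysisWindow, VentilatorSetting

__all__ = [
    "PPVEstimate",
    "RelativeEffects",
    "ppv_pair",
    "ppv_classic",
    "ppv_gam",
    "correct_ppv",
    "correct_ppv_pragmatic",
    "estimates_to_frame",
]


@dataclass
class PPVEstimate:
    """A PPV value (%) with method tag and per-window diagnostics."""

    window_id: str
    method: str  #: 'classic' or 'gam'
    ppv: float  #: percent; nan when unavailable
    n_beats_used: int
    hr: float  #: beats/min from included beats
    hr_rr_ratio: float
    available: bool = True
    reason: str = ""
    pair_ppvs: list[float] = field(default_factory=list)  #: classic only
    decomposition: CyclicDecomposition | None = None  #: gam only

    @property
    def setting_label(self) -> str:
        return self.window_id


@dataclass(frozen=True)
class RelativeEffects:
    """Multiplicative ventilator-setting effects on PPV, relative to the
    reference setting V_T = 10 ml/kg, RR = 10/min (factor 1 by definition).

    ``vt[v]`` is the expected ratio PPV(V_T=v)/PPV(V_T=10) at fixed RR;
    ``rr[r]`` likewise for respiratory rate.
    """

    vt: dict[float, float]
    rr: dict[float, float]

    def factor(self, setting: VentilatorSetting) -> float:
        try:
            e_vt = 1.0 if setting.vt == 10 else self.vt[setting.vt]
        except KeyError:
            raise KeyError(f"no V_T effect available for vt={setting.vt:g}") from None
        try:
            e_rr = 1.0 if setting.rr == 10 else self.rr[setting.rr]
        except KeyError:
            raise KeyError(f"no RR effect available for rr={setting.rr:g}") from None
        return e_vt * e_rr


def ppv_pair(pp_max: float, pp_min: float) -> float:
    """PPV of one maximum–minimum pair:
    100·(PP_max − PP_min) / ((PP_max + PP_min)/2)."""
    if pp_min <= 0:
        raise ValueError("pp_min must be positive")
    if pp_max < pp_min:
        raise ValueError("pp_max must be >= pp_min")
    return 100.0 * (pp_max - pp_min) / ((pp_max + pp_min) / 2.0)


def _hr_of(t: np.ndarray) -> float:
    if t.size < 2 or t[-1] <= t[0]:
        return float("nan")
    return 60.0 * (t.size - 1) / (t[-1] - t[0])


def _alternating_extrema(t: np.ndarray, pp: np.ndarray, t_resp: float) -> list[int]:
    """Indices of alternating PP extrema.

    Each extremum is the best beat within one respiratory length *after*
    the previous committed extremum (so each maximum lies within one
    T_resp of the previous minimum and vice versa).  The chain starts with
    whichever extremum occurs first, decided by the first strict PP
    change; ties go to the earliest beat.
    """
    n = t.size
    if n < 2:
        return []
    # initial direction from the first strict PP change; flat series => max
    mode = "max"
    for j in range(1, n):
        if pp[j] != pp[0]:
            mode = "max" if pp[j] > pp[0] else "min"
            break
    extrema: list[int] = []
    start = 0
    t_prev = t[0]
    while start < n:
        if t_prev + t_resp > t[-1]:
            # search window truncated by the end of the data: the cycle is
            # incomplete, so this extremum can never be confirmed
            break
        stop = int(np.searchsorted(t, t_prev + t_resp, side="right"))
        if stop <= start:
            break
        seg = pp[start:stop]
        cand = start + int(np.argmax(seg) if mode == "max" else np.argmin(seg))
        extrema.append(cand)
        mode = "min" if mode == "max" else "max"
        t_prev = t[cand]
        start = cand + 1
    return extrema


def ppv_classic(w: AnalysisWindow) -> PPVEstimate:
    """Classic PPV: mean per-pair PPV of the last three max/min pairs.

    Pairs are non-overlapping and formed from the most recent committed
    extrema backwards, so the estimate reflects the end of the window.
    Fewer than three pairs leaves the estimate unavailable (not zero).
    """
    t_resp = w.setting.t_resp
    inc = w.beats.included
    t, pp = w.beats.t[inc], w.beats.pp[inc]
    hr = _hr_of(t)
    est = PPVEstimate(
        window_id=w.window_id,
        method="classic",
        ppv=float("nan"),
        n_beats_used=int(t.size),
        hr=hr,
        hr_rr_ratio=hr / w.setting.rr,
    )
    if not w.valid:
        est.available, est.reason = False, "window failed QC"
        return est
    extrema = _alternating_extrema(t, pp, t_resp)
    # pair consecutive extrema from the end backwards (non-overlapping)
    pair_ppvs = []
    for j in range(len(extrema) - 1, 0, -2):
        a, b = pp[extrema[j - 1]], pp[extrema[j]]
        pair_ppvs.append(ppv_pair(max(a, b), min(a, b)))
    pair_ppvs.reverse()  # chronological
    est.pair_ppvs = pair_ppvs
    if len(pair_ppvs) < 3:
        est.available, est.reason = False, f"only {len(pair_ppvs)} max/min pairs"
        return est
    est.ppv = float(np.mean(pair_ppvs[-3:]))
    return est


def ppv_gam(
    w: AnalysisWindow,
    k_cyc: int = 10,
    k_trend: int = 6,
    grid_points: int = 512,
) -> PPVEstimate:
    """GAM PPV: cyclic component's peak-to-peak amplitude over mean PP.

    Requires at least 10 included beats spanning at least three
    respiratory cycles.  Extrema of the cyclic component are taken on a
    dense phase grid, so they are never below the values at observed
    phases.
    """
    inc = w.beats.included
    t, pp = w.beats.t[inc], w.beats.pp[inc]
    hr = _hr_of(t)
    est = PPVEstimate(
        window_id=w.window_id,
        method="gam",
        ppv=float("nan"),
        n_beats_used=int(t.size),
        hr=hr,
        hr_rr_ratio=hr / w.setting.rr,
    )
    if not w.valid:
        est.available, est.reason = False, "window failed QC"
        return est
    if t.size < 10:
        est.available, est.reason = False, f"only {t.size} included beats"
        return est
    if (t[-1] - t[0]) < 3 * w.setting.t_resp:
        est.available, est.reason = False, "beats span fewer than 3 respiratory cycles"
        return est
    phase_ref = w.phase_ref if w.phase_ref is not None else w.t_start
    try:
        dec = fit_cyclic_decomposition(
            t,
            pp,
            t_resp=w.setting.t_resp,
            phase_ref=phase_ref,
            k_cyc=k_cyc,
            k_trend=k_trend,
            grid_points=grid_points,
        )
    except np.linalg.LinAlgError as e:
        est.available, est.reason = False, f"fit failed: {e}"
        return est
    est.decomposition = dec
    est.ppv = 100.0 * dec.peak_to_peak / dec.pp_mean
    return est


def correct_ppv(ppv: float, from_setting: VentilatorSetting, effects: RelativeEffects) -> float:
    """Map a PPV observed at ``from_setting`` to the reference setting
    (V_T = 10, RR = 10) by dividing out the multiplicative setting effects.

    E.g. PPV 8% observed at V_T = 6 (relative effect 0.64) and RR = 24
    (relative effect 0.87) corrects to 8/(0.64·0.87) ≈ 14%.
    """
    return ppv / effects.factor(from_setting)


def correct_ppv_pragmatic(ppv: float, vt: float) -> float:
    """Bedside approximation: treat PPV as directly proportional to V_T
    and ignore RR, i.e. PPV_ref = PPV · 10/V_T."""
    if vt <= 0:
        raise ValueError("vt must be positive")
    return ppv * 10.0 / vt


def estimates_to_frame(estimates: list[PPVEstimate]) -> pd.DataFrame:
    """Estimates table, one row per (window, method)."""
    return pd.DataFrame(
        {
            "window_id": [e.window_id for e in estimates],
            "method": [e.method for e in estimates],
            "ppv_pct": [e.ppv for e in estimates],
            "n_beats": [e.n_beats_used for e in estimates],
            "hr_per_min": [e.hr for e in estimates],
            "hr_rr_ratio": [e.hr_rr_ratio for e in estimates],
            "available": [int(e.available) for e in estimates],
        }
    )
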