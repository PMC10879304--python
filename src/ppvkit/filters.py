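"""Beat exclusion rules and 30-s analysis-window quality control.

Three rules clean a beat series before PPV estimation:

* **extrasystole** — a beat is ectopic if its inter-beat interval is less
  than 90% of the median of the (up to ten) preceding intervals; the beat
  after an ectopic is also excluded, because its PP is inflated by the
  prolonged filling time (post-extrasystolic potentiation);
* **outlier** — a beat whose PP deviates more than ±25% from the median PP
  of its ten nearest neighbour beats;
* **window QC** — a 30-s analysis window containing more than two
  extrasystoles is discarded entirely.

All comparisons are strict, exactly as worded above; boundary cases
(interval = 0.9·median, deviation = 25%, exactly two extrasystoles) are
*not* excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beats import BeatSeries

__all__ = [
    "VentilatorSetting",
    "AnalysisWindow",
    "flag_ectopics",
    "flag_outliers",
    "apply_beat_filters",
    "window_qc",
    "make_windows",
    "windows_to_frame",
]

#: minimum number of preceding intervals required before an ectopy call
MIN_HISTORY = 3


@dataclass(frozen=True)
class VentilatorSetting:
    """One ventilator configuration: tidal volume and respiratory rate.

    vt is in ml per kg predicted body weight, rr in breaths/min. The
    respiratory cycle length T_resp = 60/rr seconds.
    """

    vt: float
    rr: float

    def __post_init__(self) -> None:
        if not self.vt > 0:
            raise ValueError("vt must be positive")
        if not self.rr > 0:
            raise ValueError("rr must be positive")

    @property
    def t_resp(self) -> float:
        return 60.0 / self.rr

    def label(self) -> str:
        return f"vt{self.vt:g}_rr{self.rr:g}"


@dataclass
class AnalysisWindow:
    """A 30-s segment of a beat series tied to one ventilator setting."""

    window_id: str
    t_start: float
    t_end: float
    setting: VentilatorSetting
    beats: BeatSeries
    valid: bool = True
    n_extrasystoles: int = 0
    phase_ref: float | None = None  #: inspiration-onset time; window start if None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


def flag_ectopics(s: BeatSeries, max_history: int = 10) -> BeatSeries:
    """Flag premature (ectopic) beats and the beat following each.

    Beat *i* is ectopic iff ``t_i − t_{i−1} < 0.9 · median`` of the up-to-
    ``max_history`` preceding inter-beat intervals.  At the start of the
    series all available preceding intervals are used, and no call is made
    with fewer than three.  Flagging is invariant to rescaling time.
    """
    n = len(s)
    if n < 2:
        return replace(s)
    iv = np.diff(s.t)
    ectopic = np.zeros(n, dtype=bool)
    post = np.zeros(n, dtype=bool)
    for i in range(1, n):
        lo = max(0, i - 1 - max_history)
        hist = iv[lo : i - 1]
        if hist.size < MIN_HISTORY:
            continue
        if iv[i - 1] < 0.9 * np.median(hist):
            ectopic[i] = True
            if i + 1 < n:
                post[i + 1] = True
    return replace(s, ectopic=ectopic, post_ectopic=post & ~ectopic)


def flag_outliers(s: BeatSeries, n_neighbours: int = 10) -> BeatSeries:
    """Flag beats whose PP deviates more than ±25% from neighbours.

    The reference for beat *i* is the median PP of the ``n_neighbours``
    nearest *other* beats by index — 5 before / 5 after where possible,
    one-sided at the edges.  Invariant to rescaling PP.
    """
    n = len(s)
    if n < 2:
        return replace(s)
    half = n_neighbours // 2
    outlier = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        # shift the window at the edges to keep n_neighbours others
        if lo == 0:
            hi = min(n, n_neighbours + 1)
        elif hi == n:
            lo = max(0, n - n_neighbours - 1)
        idx = [j for j in range(lo, hi) if j != i]
        m = np.median(s.pp[idx])
        if abs(s.pp[i] - m) > 0.25 * m:
            outlier[i] = True
    return replace(s, outlier=outlier)


def apply_beat_filters(s: BeatSeries) -> BeatSeries:
    """Ectopy then outlier flagging on the continuous series."""
    return flag_outliers(flag_ectopics(s))


def window_qc(w: AnalysisWindow) -> AnalysisWindow:
    """Mark a window invalid if it contains more than two extrasystoles.

    Post-ectopic beats do not count toward the extrasystole tally.
    """
    n_es = int(np.sum(w.beats.ectopic))
    return replace(w, n_extrasystoles=n_es, valid=n_es <= 2)


def make_windows(
    s: BeatSeries,
    settings: list[VentilatorSetting],
    t_starts: list[float] | None = None,
    duration: float = 30.0,
    per_window_flags: bool = False,
) -> list[AnalysisWindow]:
    """Cut a flagged beat series into consecutive analysis windows.

    By default flags are computed once on the continuous series and
    inherited by each window (recordings are continuous, so a window's
    first beats have real predecessors).  ``per_window_flags`` recomputes
    them inside each window instead.
    """
    if t_starts is None:
        first = s.t[0] if len(s) else 0.0
        t_starts = [first + k * duration for k in range(len(settings))]
    if len(t_starts) != len(settings):
        raise ValueError("t_starts and settings must align")
    if not per_window_flags:
        s = apply_beat_filters(s)
    out = []
    for k, (t0, st) in enumerate(zip(t_starts, settings)):
        sub = s.slice_time(t0, t0 + duration)
        if per_window_flags:
            sub = apply_beat_filters(sub)
        w = AnalysisWindow(
            window_id=f"w{k:02d}_{st.label()}",
            t_start=t0,
            t_end=t0 + duration,
            setting=st,
            beats=sub,
        )
        out.append(window_qc(w))
    return out


def windows_to_frame(windows: list[AnalysisWindow]) -> pd.DataFrame:
    """Window manifest: one row per window."""
    return pd.DataFrame(
        {
            "window_id": [w.window_id for w in windows],
            "t_start_s": [w.t_start for w in windows],
            "vt_ml_per_kg": [w.setting.vt for w in windows],
            "rr_per_min": [w.setting.rr for w in windows],
            "valid": [int(w.valid) for w in windows],
            "n_extrasystoles": [w.n_extrasystoles for w in windows],
        }
    )
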