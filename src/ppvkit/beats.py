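"""Beat detection and beat-table I/O.

A *beat* is one cardiac cycle characterised by its diastolic onset time
(seconds) and its pulse pressure (PP = systolic − diastolic pressure, mmHg).
Beat series are the raw material of every PPV estimator in this package:
they can be detected from a uniformly sampled arterial pressure waveform
with :func:`detect_beats`, or ingested from a plain-CSV beat table with
:func:`read_beat_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Waveform",
    "BeatSeries",
    "detect_beats",
    "read_beat_table",
    "write_beat_table",
    "read_waveform",
]


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled arterial pressure signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    fs : float
        Sample rate, Hz.
    p : ndarray
        Pressure samples, mmHg.
    """

    t0: float
    fs: float
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if not self.fs > 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(p)):
            raise ValueError("waveform contains non-finite samples")
        if p.size < 2 * self.fs:
            raise ValueError("waveform shorter than 2 s")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.p.size) / self.fs

    @property
    def duration(self) -> float:
        return self.p.size / self.fs


@dataclass
class BeatSeries:
    """Ordered beats with per-beat exclusion flags.

    ``ectopic``, ``post_ectopic`` and ``outlier`` are independent flags; a
    beat carrying any of them is excluded, so ``included`` is derived and
    never stored.
    """

    t: np.ndarray
    pp: np.ndarray
    sbp: np.ndarray | None = None
    dbp: np.ndarray | None = None
    ectopic: np.ndarray = field(default=None)  # type: ignore[assignment]
    post_ectopic: np.ndarray = field(default=None)  # type: ignore[assignment]
    outlier: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pp = np.asarray(self.pp, dtype=float)
        if self.t.shape != self.pp.shape:
            raise ValueError("t and pp must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise ValueError(f"beat times not strictly increasing at row {bad}")
        if np.any(self.pp <= 0):
            bad = int(np.flatnonzero(self.pp <= 0)[0])
            raise ValueError(f"non-positive pulse pressure at row {bad}")
        for name in ("ectopic", "post_ectopic", "outlier"):
            v = getattr(self, name)
            if v is None:
                v = np.zeros(self.t.size, dtype=bool)
            setattr(self, name, np.asarray(v, dtype=bool))

    def __len__(self) -> int:
        return self.t.size

    @property
    def included(self) -> np.ndarray:
        return ~(self.ectopic | self.post_ectopic | self.outlier)

    def slice_time(self, t_start: float, t_end: float) -> "BeatSeries":
        """Beats with ``t_start <= t < t_end``, flags carried over."""
        m = (self.t >= t_start) & (self.t < t_end)
        return BeatSeries(
            t=self.t[m],
            pp=self.pp[m],
            sbp=None if self.sbp is None else self.sbp[m],
            dbp=None if self.dbp is None else self.dbp[m],
            ectopic=self.ectopic[m],
            post_ectopic=self.post_ectopic[m],
            outlier=self.outlier[m],
        )

    def to_frame(self, flags: bool = False) -> pd.DataFrame:
        d = {"time_s": self.t, "pp_mmhg": self.pp}
        if self.sbp is not None:
            d["sbp_mmhg"] = self.sbp
        if self.dbp is not None:
            d["dbp_mmhg"] = self.dbp
        if flags:
            d["ectopic"] = self.ectopic.astype(int)
            d["post_ectopic"] = self.post_ectopic.astype(int)
            d["outlier"] = self.outlier.astype(int)
            d["included"] = self.included.astype(int)
        return pd.DataFrame(d)


def detect_beats(w: Waveform, min_interval_s: float = 0.3) -> BeatSeries:
    """Segment an arterial waveform into beats.

    Systolic peaks are located with a refractory period of
    ``min_interval_s``; each beat's onset is the diastolic minimum in the
    interval preceding its systolic peak, and PP is the systolic maximum
    minus that minimum.  Detection is invariant to constant pressure
    offsets.  A flat (non-pulsatile) waveform yields an empty series.
    """
    if min_interval_s <= 0:
        raise ValueError("min_interval_s must be positive")
    p = w.p
    # prominence threshold: a beat must swing noticeably relative to the
    # signal's overall pulsatility; flat-lines therefore yield no peaks
    span = float(np.ptp(p))
    if span <= 0:
        warnings.warn("no beats found: waveform is flat", stacklevel=2)
        return BeatSeries(t=np.empty(0), pp=np.empty(0))
    distance = max(1, int(round(min_interval_s * w.fs)))
    peaks, _ = find_peaks(p, distance=distance, prominence=0.25 * span)
    if peaks.size == 0:
        warnings.warn("no beats found in waveform", stacklevel=2)
        return BeatSeries(t=np.empty(0), pp=np.empty(0))

    onsets = np.empty(peaks.size, dtype=int)
    prev = 0
    for k, pk in enumerate(peaks):
        seg = p[prev:pk]
        onsets[k] = prev + (int(np.argmin(seg)) if seg.size else 0)
        prev = pk
    pp = p[peaks] - p[onsets]
    good = pp > 0
    t = w.t0 + onsets[good] / w.fs
    return BeatSeries(
        t=t,
        pp=pp[good],
        sbp=p[peaks[good]].astype(float),
        dbp=p[onsets[good]].astype(float),
    )


def read_beat_table(path) -> BeatSeries:
    """Read a beat table CSV (``time_s,pp_mmhg[,sbp_mmhg,dbp_mmhg]``).

    Rejects non-monotone times and non-positive PP, naming the offending
    row (0-based, excluding the header).
    """
    df = pd.read_csv(path)
    required = {"time_s", "pp_mmhg"}
    if not required.issubset(df.columns):
        raise ValueError(f"beat table must have columns {sorted(required)}")
    return BeatSeries(
        t=df["time_s"].to_numpy(float),
        pp=df["pp_mmhg"].to_numpy(float),
        sbp=df["sbp_mmhg"].to_numpy(float) if "sbp_mmhg" in df else None,
        dbp=df["dbp_mmhg"].to_numpy(float) if "dbp_mmhg" in df else None,
        ectopic=df["ectopic"].to_numpy(bool) if "ectopic" in df else None,
        post_ectopic=df["post_ectopic"].to_numpy(bool) if "post_ectopic" in df else None,
        outlier=df["outlier"].to_numpy(bool) if "outlier" in df else None,
    )


def write_beat_table(series: BeatSeries, path, flags: bool = False) -> None:
    """Write a beat table CSV; round-trips through :func:`read_beat_table`."""
    series.to_frame(flags=flags).to_csv(path, index=False, float_format="%.9f")


def read_waveform(path) -> Waveform:
    """Read a waveform CSV (``time_s,pressure_mmhg``) with a uniform rate.

    The sample rate is inferred from the first two rows and uniformity is
    checked to 1e-6 s.
    """
    df = pd.read_csv(path)
    if not {"time_s", "pressure_mmhg"}.issubset(df.columns):
        raise ValueError("waveform CSV must have columns time_s,pressure_mmhg")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError("waveform must have at least two samples")
    dt = t[1] - t[0]
    if dt <= 0:
        raise ValueError("waveform times must be increasing")
    if np.max(np.abs(np.diff(t) - dt)) > 1e-6:
        raise ValueError("waveform sampling is not uniform (tolerance 1e-6 s)")
    return Waveform(t0=float(t[0]), fs=1.0 / dt, p=df["pressure_mmhg"].to_numpy(float))
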