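"""Ground-truth synthetic data at two levels.

* :func:`gen_beats` builds a beat-level PP series for one analysis window:
  beat times from a configurable heart rate (with optional timing jitter or
  an exact phase lock for aliasing experiments), PP as a slow trend plus a
  cyclic respiratory modulation of known peak-to-peak amplitude plus noise,
  and optional programmed extrasystoles.  The injected PPV is exact by
  construction: the modulation shape has peak-to-peak 2, scaled by
  ``pp_mean · ppv_true / 200``.

* :func:`gen_cohort` builds a multi-patient PPV table following the same
  generative structure as the hierarchical effects model: per-patient log
  intercepts, multiplicative V_T and RR effects per estimation method, and
  heavy-tailed (Student-t, ν = 4) residuals on the log scale with a
  per-setting scale.  It also emits stroke-volume sample series around a
  fluid challenge realizing a configured responder fraction.

The default cohort design is the study grid of ten ventilator settings:
all four tidal volumes (4, 6, 8, 10 ml/kg pbw) at RR = 10/min, and tidal
volumes 6 and 8 ml/kg at RR = 17, 24 and 31/min — higher V_T at high RR is
excluded by airway-pressure limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .beats import BeatSeries
from .filters import VentilatorSetting

__all__ = [
    "BeatSimConfig",
    "CohortSimConfig",
    "STUDY_GRID",
    "gen_beats",
    "gen_cohort",
]

#: the ten protocol ventilator settings (vt ml/kg pbw, rr /min)
STUDY_GRID: tuple[tuple[float, float], ...] = (
    (4, 10),
    (6, 10),
    (8, 10),
    (10, 10),
    (6, 17),
    (8, 17),
    (6, 24),
    (8, 24),
    (6, 31),
    (8, 31),
)


def _sine_shape(u: np.ndarray) -> np.ndarray:
    return np.sin(2 * np.pi * u)


def _skewed_shape(u: np.ndarray) -> np.ndarray:
    """Asymmetric modulation for an inspiration:expiration ratio of 1:2 —
    the rise is compressed into the first third of the cycle."""
    u = np.mod(u, 1.0)
    w = np.where(u < 1 / 3, 1.5 * u, 0.5 + 0.75 * (u - 1 / 3))
    return np.sin(2 * np.pi * w)


_SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sine": _sine_shape,
    "skewed": _skewed_shape,
}


@dataclass(frozen=True)
class BeatSimConfig:
    """Configuration for one synthetic beat-level window.

    ``ppv_true`` is the injected PPV in percent: the cyclic modulation has
    peak-to-peak amplitude ``pp_mean·ppv_true/100`` mmHg.  ``phase_lock``
    (a phase in [0, 1) cycles) disables jitter and anchors the first beat
    at that respiratory phase, for integer-HR/RR aliasing experiments.
    """

    duration_s: float = 30.0
    hr: float = 78.0
    hr_jitter_sd: float = 0.0  #: fraction of the inter-beat interval
    rr: float = 13.0
    ppv_true: float = 10.0
    pp_mean: float = 50.0
    trend: Sequence[float] = (0.0,)  #: polynomial coefficients, low order first
    noise_sd: float = 0.0
    ectopic_rate: float = 0.0  #: per minute
    ectopic_prematurity: float = 0.5  #: fraction of the normal interval, < 0.9
    modulation_shape: str = "sine"
    phase_lock: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hr, self.rr, self.pp_mean) <= 0 or self.duration_s <= 0:
            raise ValueError("rates, pp_mean and duration must be positive")
        if self.ppv_true < 0 or self.noise_sd < 0 or self.ectopic_rate < 0:
            raise ValueError("ppv_true, noise_sd and ectopic_rate must be >= 0")
        if not 0 < self.ectopic_prematurity < 0.9:
            raise ValueError("ectopic_prematurity must be in (0, 0.9)")
        if self.modulation_shape not in _SHAPES:
            raise ValueError(f"unknown modulation shape {self.modulation_shape!r}")


def gen_beats(cfg: BeatSimConfig, t_start: float = 0.0) -> tuple[BeatSeries, dict]:
    """Generate one window's beat series plus its ground-truth record.

    Returns ``(series, truth)`` where ``truth`` holds the injected PPV,
    the ectopic beat indices and the phase convention (phase zero at
    ``t_start``), so estimator output can be scored exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    ibi = 60.0 / cfg.hr
    t_resp = 60.0 / cfg.rr
    n = int(np.floor(cfg.duration_s / ibi)) + 1

    if cfg.phase_lock is not None:
        t = t_start + cfg.phase_lock * t_resp + ibi * np.arange(n)
    else:
        steps = ibi * (1.0 + cfg.hr_jitter_sd * rng.standard_normal(n))
        t = t_start + rng.uniform(0, ibi) + np.concatenate([[0.0], np.cumsum(steps[:-1])])
    t = t[t < t_start + cfg.duration_s]
    if t.size < 2:
        raise ValueError("configuration yields fewer than 2 beats")

    shape = _SHAPES[cfg.modulation_shape]
    amp = cfg.pp_mean * cfg.ppv_true / 200.0
    phase = (t - t_start) / t_resp
    trend = np.polynomial.polynomial.polyval(t - t_start, np.asarray(cfg.trend, float))
    pp = cfg.pp_mean + trend + amp * shape(phase) + cfg.noise_sd * rng.standard_normal(t.size)

    ect_idx: list[int] = []
    n_ect = rng.poisson(cfg.ectopic_rate * cfg.duration_s / 60.0)
    if n_ect > 0:
        # candidates leave history for the ectopy rule and never touch the
        # first beats, window edges or each other
        candidates = [i for i in range(12, t.size - 2)]
        rng.shuffle(candidates)
        for i in candidates:
            if len(ect_idx) == n_ect:
                break
            if all(abs(i - j) > 2 for j in ect_idx):
                ect_idx.append(i)
        ect_idx.sort()
        for i in ect_idx:
            # pull the beat early: new interval = prematurity * old interval
            t[i] = t[i - 1] + cfg.ectopic_prematurity * (t[i] - t[i - 1])
            pp[i] *= 0.6  # short filling time lowers stroke volume, hence PP

    pp = np.maximum(pp, 1e-3)
    truth = {
        "ppv_true": cfg.ppv_true,
        "pp_mean": cfg.pp_mean,
        "t_resp": t_resp,
        "phase_ref": t_start,
        "ectopic_indices": ect_idx,
        "hr": cfg.hr,
        "rr": cfg.rr,
    }
    return BeatSeries(t=t, pp=pp), truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for a multi-patient cohort PPV table.

    Truth defaults emulate the study's estimates: PPV is nearly
    proportional to V_T for both methods, while high RR attenuates the
    classic estimate far more than the GAM estimate (the sparse-sampling
    effect).  Residuals are Student-t with ν = 4 on the log scale, with a
    larger scale for the classic method at RR = 31/min.
    """

    n_patients: int = 50
    settings: tuple[tuple[float, float], ...] = STUDY_GRID
    ppv_ref_median: float = 10.0  #: median PPV (%) at V_T=10, RR=10
    tau: float = 0.4  #: between-patient sd of log intercepts
    e_vt: dict = field(
        default_factory=lambda: {
            "gam": {4: 0.49, 6: 0.64, 8: 0.81},
            "classic": {4: 0.49, 6: 0.64, 8: 0.81},
        }
    )
    e_rr: dict = field(
        default_factory=lambda: {
            "gam": {17: 0.95, 24: 0.87, 31: 0.81},
            "classic": {17: 0.93, 24: 0.80, 31: 0.56},
        }
    )
    sigma: dict | None = None  #: (vt, rr, method) -> log-scale residual scale
    sigma_default: float = 0.15
    t_dof: float = 4.0
    responder_fraction: float = 0.2
    responder_ppv_ratio: float = 1.8  #: intercept multiplier for responders
    drop_vt8_rr31_fraction: float = 0.0  #: patients missing the (8, 31) setting
    seed: int = 0

    def sigma_for(self, vt: float, rr: float, method: str) -> float:
        if self.sigma and (vt, rr, method) in self.sigma:
            return self.sigma[(vt, rr, method)]
        # classic is noisier at the highest RR (sparse-sampling effect)
        if method == "classic" and rr == 31:
            return 2.0 * self.sigma_default
        return self.sigma_default


def gen_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a cohort PPV table, SV fluid-challenge samples and truth.

    Returns ``(cohort, sv_samples, truth)``: ``cohort`` is long format
    (patient_id, vt_ml_per_kg, rr_per_min, method, ppv_pct), ``sv_samples``
    has six pre- and six post-challenge stroke-volume samples per patient,
    and ``truth`` retains every generative parameter.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    responder = rng.random(n) < cfg.responder_fraction
    log_ref = np.log(cfg.ppv_ref_median)
    u = cfg.tau * rng.standard_normal(n)
    u = u + np.where(responder, np.log(cfg.responder_ppv_ratio), 0.0)

    rows = []
    for p in range(n):
        settings = list(cfg.settings)
        if cfg.drop_vt8_rr31_fraction and rng.random() < cfg.drop_vt8_rr31_fraction:
            settings = [s for s in settings if s != (8, 31)]
        for vt, rr in settings:
            for method in ("gam", "classic"):
                e_v = 1.0 if vt == 10 else cfg.e_vt[method][vt]
                e_r = 1.0 if rr == 10 else cfg.e_rr[method][rr]
                sig = cfg.sigma_for(vt, rr, method)
                eta = log_ref + u[p] + np.log(e_v) + np.log(e_r)
                log_ppv = eta + sig * rng.standard_t(cfg.t_dof)
                rows.append((f"p{p:03d}", vt, rr, method, float(np.exp(log_ppv))))
    cohort = pd.DataFrame(
        rows, columns=["patient_id", "vt_ml_per_kg", "rr_per_min", "method", "ppv_pct"]
    )

    # fluid challenge: six SV samples per 2-min phase, sd 3 mL around means
    sv_rows = []
    delta_true = np.where(
        responder,
        rng.normal(17.0, 3.0, n),
        rng.normal(3.0, 3.0, n),
    )
    delta_true = np.maximum(delta_true, -20.0)
    sv_base = rng.normal(68.0, 12.0, n).clip(min=30.0)
    for p in range(n):
        post_mean = sv_base[p] * (1 + delta_true[p] / 100.0)
        for k in range(6):
            sv_rows.append((f"p{p:03d}", "pre", k, float(sv_base[p] + rng.normal(0, 3))))
        for k in range(6):
            sv_rows.append((f"p{p:03d}", "post", k, float(post_mean + rng.normal(0, 3))))
    sv_samples = pd.DataFrame(sv_rows, columns=["patient_id", "phase", "sample_idx", "sv_ml"])

    truth = {
        "ppv_ref_median": cfg.ppv_ref_median,
        "tau": cfg.tau,
        "e_vt": cfg.e_vt,
        "e_rr": cfg.e_rr,
        "t_dof": cfg.t_dof,
        "responder": responder.tolist(),
        "delta_sv_true": delta_true.tolist(),
        "patient_log_intercept": (log_ref + u).tolist(),
        "sigma": {
            f"{vt:g},{rr:g},{m}": cfg.sigma_for(vt, rr, m)
            for vt, rr in cfg.settings
            for m in ("gam", "classic")
        },
    }
    return cohort, sv_samples, truth


def window_from_config(cfg: BeatSimConfig, window_id: str = "w00", t_start: float = 0.0):
    """Convenience: generate beats, apply the exclusion filters and wrap
    them in a ready-to-estimate :class:`~ppvkit.filters.AnalysisWindow`."""
    from .filters import AnalysisWindow, apply_beat_filters, window_qc

    series, truth = gen_beats(cfg, t_start=t_start)
    series = apply_beat_filters(series)
    w = AnalysisWindow(
        window_id=window_id,
        t_start=t_start,
        t_end=t_start + cfg.duration_s,
        setting=VentilatorSetting(vt=8, rr=cfg.rr),
        beats=series,
        phase_ref=t_start,
    )
    return window_qc(w), truth
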