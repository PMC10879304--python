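"""Penalized-spline additive decomposition of a pulse-pressure series.

The model is

    pp(t) = beta0 + f_trend(t) + f_cyc(phi(t)) + eps,

with ``f_trend`` a cubic P-spline in time (slow non-respiratory drift of
PP, e.g. from volume shifts or vasomotor tone) and ``f_cyc`` a *cyclic*
cubic P-spline in respiratory phase ``phi(t) = (t − t_ref) mod T_resp``
(the ventilator-induced oscillation, forced to be periodic and zero-mean
over one respiratory cycle).  Both smooths carry second-order difference
penalties; the two smoothing parameters are chosen by generalized
cross-validation on a log-spaced grid.

The zero-mean constraint on ``f_cyc`` is imposed by centring its basis
columns over a dense uniform phase grid, which also keeps the cyclic
component identifiable against the intercept and trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["CyclicDecomposition", "fit_cyclic_decomposition"]

#: dense-grid resolution per respiratory period for peak-to-peak extraction
GRID_POINTS = 512


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, 3).toarray()


def _open_basis(x: np.ndarray, lo: float, hi: float, k: int) -> np.ndarray:
    """Clamped cubic B-spline basis with k coefficients on [lo, hi]."""
    if k < 4:
        raise ValueError("need at least 4 basis functions")
    inner = np.linspace(lo, hi, k - 2)
    knots = np.r_[[lo] * 3, inner, [hi] * 3]
    xc = np.clip(x, lo, hi)
    return _bspline_design(xc, knots)


def _cyclic_basis(phase: np.ndarray, period: float, k: int) -> np.ndarray:
    """Periodic cubic B-spline basis with k coefficients on [0, period)."""
    if k < 4:
        raise ValueError("need at least 4 cyclic basis functions")
    h = period / k
    knots = h * np.arange(-3, k + 4)
    B = _bspline_design(np.mod(phase, period), knots)  # n x (k+3)
    out = B[:, :k].copy()
    out[:, :3] += B[:, k:]  # wrap the trailing basis functions
    return out


def _diff2(k: int, cyclic: bool) -> np.ndarray:
    """Second-order difference penalty matrix D'D."""
    if cyclic:
        D = np.zeros((k, k))
        for i in range(k):
            D[i, i] = -2.0
            D[i, (i - 1) % k] = 1.0
            D[i, (i + 1) % k] = 1.0
    else:
        D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


@dataclass
class CyclicDecomposition:
    """Fitted trend + cyclic split of a beat-wise PP series."""

    phase_grid: np.ndarray  #: dense phase grid on [0, T_resp)
    f_cyc: np.ndarray  #: cyclic component on the grid, mmHg, zero mean
    trend_at_beats: np.ndarray  #: beta0 + f_trend evaluated at beat times
    cyc_at_beats: np.ndarray  #: f_cyc evaluated at observed beat phases
    residual_sd: float
    pp_mean: float  #: mean PP of the fitted beats, mmHg
    edf: float  #: effective degrees of freedom of the fit
    lambdas: tuple[float, float]  #: (trend, cyclic) smoothing parameters

    @property
    def peak_to_peak(self) -> float:
        return float(self.f_cyc.max() - self.f_cyc.min())


def fit_cyclic_decomposition(
    t: np.ndarray,
    pp: np.ndarray,
    t_resp: float,
    phase_ref: float = 0.0,
    k_cyc: int = 10,
    k_trend: int = 6,
    n_lambda: int = 7,
    grid_points: int = GRID_POINTS,
) -> CyclicDecomposition:
    """Fit the additive trend + cyclic model to one window's beats.

    Parameters use the known set respiratory rate (through ``t_resp``),
    not an estimate; ``phase_ref`` anchors phase zero (inspiration onset
    when available, otherwise the window start).
    """
    t = np.asarray(t, float)
    pp = np.asarray(pp, float)
    n = t.size
    if n < 5:
        raise ValueError("too few beats for decomposition")
    if t_resp <= 0:
        raise ValueError("t_resp must be positive")

    phase = np.mod(t - phase_ref, t_resp)
    grid = np.linspace(0.0, t_resp, grid_points, endpoint=False)

    C = _cyclic_basis(phase, t_resp, k_cyc)
    Cg = _cyclic_basis(grid, t_resp, k_cyc)
    gmean = Cg.mean(axis=0)
    C = C - gmean  # zero mean over one period
    Cg = Cg - gmean

    T = _open_basis(t, t[0], t[-1], k_trend)
    T = T - T.mean(axis=0)

    X = np.column_stack([np.ones(n), T, C])
    p = X.shape[1]
    S = np.zeros((p, p))
    St = _diff2(k_trend, cyclic=False)
    Sc = _diff2(k_cyc, cyclic=True)

    XtX = X.T @ X
    Xty = X.T @ pp
    lams = np.logspace(4, -4, n_lambda)  # descending: GCV ties favour smoothness
    best = None
    for lt in lams:
        for lc in lams:
            S[:, :] = 0.0
            S[1 : 1 + k_trend, 1 : 1 + k_trend] = lt * St
            S[1 + k_trend :, 1 + k_trend :] = lc * Sc
            A = XtX + S + 1e-9 * np.eye(p)
            try:
                beta = np.linalg.solve(A, Xty)
                edf = float(np.trace(np.linalg.solve(A, XtX)))
            except np.linalg.LinAlgError:
                continue
            resid = pp - X @ beta
            rss = float(resid @ resid)
            denom = max(n - edf, 1e-6)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0] - 1e-12:
                best = (gcv, beta, edf, rss, lt, lc)
    if best is None:
        raise np.linalg.LinAlgError("cyclic decomposition failed to fit")
    _, beta, edf, rss, lt, lc = best

    b_cyc = beta[1 + k_trend :]
    cyc_at_beats = C @ b_cyc
    trend_at_beats = beta[0] + T @ beta[1 : 1 + k_trend]
    return CyclicDecomposition(
        phase_grid=grid,
        f_cyc=Cg @ b_cyc,
        trend_at_beats=trend_at_beats,
        cyc_at_beats=cyc_at_beats,
        residual_sd=float(np.sqrt(rss / max(n - edf, 1.0))),
        pp_mean=float(pp.mean()),
        edf=edf,
        lambdas=(float(lt), float(lc)),
    )
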