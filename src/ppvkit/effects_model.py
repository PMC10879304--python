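"""Hierarchical Bayesian model of ventilator-setting effects on PPV.

The model describes repeated PPV measurements within patients across a
grid of ventilator settings, separately for the two estimation methods:

    log PPV_i ~ StudentT(nu = 4, eta_i, sigma_{s(i)})
    eta_i = a_{m(i)} + b_vt[m(i), vt(i)] + b_rr[m(i), rr(i)] + u_{p(i)}
    u_p ~ Normal(0, tau^2)

with a log link, so ``exp(b)`` are *multiplicative relative effects* on
PPV versus the reference setting (V_T = 10 ml/kg, RR = 10/min, factors 1
by definition).  The Student-t likelihood (four degrees of freedom, fixed)
makes the fit robust to outlying windows.  The residual scale sigma is
separate for every ventilator setting (and, by default, method), because
the estimators' precision varies with the setting — the classic method in
particular degrades at high RR.

Because the residual lives on the log scale, its scale is already a
*relative* dispersion: the coefficient of variation reported per setting
is ``sqrt(nu/(nu-2))·sigma_s`` (the SD of the t-distributed log residual),
expressed in percent of the expected PPV.

Priors are weakly informative and configurable: Normal(log 10, 1) for the
intercepts, Normal(0, 1) for the setting coefficients on the log scale,
half-Normal(0, 1) for tau and the sigmas.

Sampling uses Hamiltonian Monte Carlo with analytically derived
gradients, a diagonal mass matrix and dual-averaging step-size adaptation
(see :mod:`ppvkit._hmc`), with non-centred patient intercepts; convergence
is checked with split-R-hat and effective sample sizes (arviz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .ppv import RelativeEffects

__all__ = [
    "EffectsModelSpec",
    "EffectsPosterior",
    "validate_cohort",
    "fit_effects_model",
    "cv_contrast",
]

REF_VT = 10.0
REF_RR = 10.0


@dataclass(frozen=True)
class EffectsModelSpec:
    """Model structure and priors."""

    nu: float = 4.0  #: Student-t degrees of freedom (fixed, not estimated)
    sigma_per_method: bool = True  #: residual scale per (setting, method)
    prior_intercept_mean: float = float(np.log(10.0))
    prior_intercept_sd: float = 1.0
    prior_coef_sd: float = 1.0
    prior_tau_sd: float = 1.0
    prior_sigma_sd: float = 1.0


def validate_cohort(data: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format cohort table for the fit.

    Requires columns patient_id, vt_ml_per_kg, rr_per_min, method, ppv_pct;
    all PPV strictly positive (log link) and at most one row per
    (patient, setting, method).
    """
    req = ["patient_id", "vt_ml_per_kg", "rr_per_min", "method", "ppv_pct"]
    missing = [c for c in req if c not in data.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if (data["ppv_pct"] <= 0).any():
        raise ValueError("all ppv_pct must be positive (log link)")
    dup = data.duplicated(subset=["patient_id", "vt_ml_per_kg", "rr_per_min", "method"])
    if dup.any():
        raise ValueError(f"duplicate (patient, setting, method) rows: {int(dup.sum())}")
    return data


@dataclass
class _Design:
    """Index arrays mapping data rows onto the parameter vector."""

    methods: list
    vt_levels: list
    rr_levels: list
    patients: list
    settings: list  #: sigma strata labels (vt, rr[, method])
    n_params: int
    slices: dict
    col_a: np.ndarray
    col_vt: np.ndarray  #: -1 for reference rows
    col_rr: np.ndarray
    col_pat: np.ndarray
    col_sig: np.ndarray
    log_y: np.ndarray


def _build_design(data: pd.DataFrame, spec: EffectsModelSpec) -> _Design:
    methods = sorted(data["method"].unique())
    vt_levels = sorted(v for v in data["vt_ml_per_kg"].unique() if v != REF_VT)
    rr_levels = sorted(r for r in data["rr_per_min"].unique() if r != REF_RR)
    patients = sorted(data["patient_id"].unique())
    if spec.sigma_per_method:
        settings = sorted(
            set(zip(data["vt_ml_per_kg"], data["rr_per_min"], data["method"]))
        )
    else:
        settings = sorted(set(zip(data["vt_ml_per_kg"], data["rr_per_min"])))

    nm, nv, nr, np_, ns = (
        len(methods),
        len(vt_levels),
        len(rr_levels),
        len(patients),
        len(settings),
    )
    slices = {}
    off = 0
    for name, size in [
        ("a", nm),
        ("b_vt", nm * nv),
        ("b_rr", nm * nr),
        ("z", np_),
        ("log_tau", 1),
        ("log_sigma", ns),
    ]:
        slices[name] = slice(off, off + size)
        off += size

    m_idx = {m: i for i, m in enumerate(methods)}
    v_idx = {v: i for i, v in enumerate(vt_levels)}
    r_idx = {r: i for i, r in enumerate(rr_levels)}
    p_idx = {p: i for i, p in enumerate(patients)}
    s_idx = {s: i for i, s in enumerate(settings)}

    m = data["method"].map(m_idx).to_numpy()
    col_a = slices["a"].start + m
    vt = data["vt_ml_per_kg"].to_numpy()
    rr = data["rr_per_min"].to_numpy()
    col_vt = np.array(
        [
            -1 if v == REF_VT else slices["b_vt"].start + mi * nv + v_idx[v]
            for v, mi in zip(vt, m)
        ]
    )
    col_rr = np.array(
        [
            -1 if r == REF_RR else slices["b_rr"].start + mi * nr + r_idx[r]
            for r, mi in zip(rr, m)
        ]
    )
    col_pat = slices["z"].start + data["patient_id"].map(p_idx).to_numpy()
    if spec.sigma_per_method:
        keys = list(zip(vt, rr, data["method"]))
    else:
        keys = list(zip(vt, rr))
    col_sig = slices["log_sigma"].start + np.array([s_idx[k] for k in keys])

    return _Design(
        methods=methods,
        vt_levels=vt_levels,
        rr_levels=rr_levels,
        patients=patients,
        settings=settings,
        n_params=off,
        slices=slices,
        col_a=col_a,
        col_vt=col_vt,
        col_rr=col_rr,
        col_pat=col_pat,
        col_sig=col_sig,
        log_y=np.log(data["ppv_pct"].to_numpy(float)),
    )


def _log_prob(theta: np.ndarray, d: _Design, spec: EffectsModelSpec) -> np.ndarray:
    """Vectorised log posterior for a (walkers, n_params) matrix."""
    th = np.atleast_2d(theta)
    sl = d.slices
    a = th[:, d.col_a]
    bvt = np.where(d.col_vt >= 0, th[:, np.maximum(d.col_vt, 0)], 0.0)
    brr = np.where(d.col_rr >= 0, th[:, np.maximum(d.col_rr, 0)], 0.0)
    log_tau = th[:, sl["log_tau"]]
    tau = np.exp(log_tau)
    u = tau * th[:, d.col_pat]
    eta = a + bvt + brr + u
    log_sigma = th[:, d.col_sig]
    x = (d.log_y - eta) / np.exp(log_sigma)

    nu = spec.nu
    t_const = (
        gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi)
    )
    loglik = np.sum(
        t_const - 0.5 * (nu + 1) * np.log1p(x * x / nu) - log_sigma, axis=1
    )

    lp = np.zeros(th.shape[0])
    ia = th[:, sl["a"]]
    lp += np.sum(
        -0.5 * ((ia - spec.prior_intercept_mean) / spec.prior_intercept_sd) ** 2, axis=1
    )
    for name in ("b_vt", "b_rr"):
        b = th[:, sl[name]]
        lp += np.sum(-0.5 * (b / spec.prior_coef_sd) ** 2, axis=1)
    z = th[:, sl["z"]]
    lp += np.sum(-0.5 * z * z, axis=1)
    # half-Normal priors on tau and sigma, sampled on the log scale
    lp += np.sum(-0.5 * (tau / spec.prior_tau_sd) ** 2 + log_tau, axis=1)
    all_log_sig = th[:, sl["log_sigma"]]
    lp += np.sum(
        -0.5 * (np.exp(all_log_sig) / spec.prior_sigma_sd) ** 2 + all_log_sig, axis=1
    )
    return loglik + lp


def _make_logp_grad(d: _Design, spec: EffectsModelSpec):
    """Log posterior and analytic gradient for a single parameter vector."""
    sl = d.slices
    nu = spec.nu
    ndim = d.n_params
    t_const = gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi)
    vt_valid = d.col_vt >= 0
    rr_valid = d.col_rr >= 0
    col_vt = d.col_vt[vt_valid]
    col_rr = d.col_rr[rr_valid]
    z_sl, lt_sl, a_sl = sl["z"], sl["log_tau"], sl["a"]

    def logp_grad(theta: np.ndarray):
        grad = np.zeros(ndim)
        log_tau = theta[lt_sl.start]
        tau = np.exp(log_tau)
        z_row = theta[d.col_pat]
        eta = theta[d.col_a] + tau * z_row
        eta[vt_valid] += theta[col_vt]
        eta[rr_valid] += theta[col_rr]
        log_sig = theta[d.col_sig]
        sigma = np.exp(log_sig)
        r = (d.log_y - eta) / sigma
        r2 = r * r
        denom = nu + r2
        w = (nu + 1) * r / (denom * sigma)  # d loglik / d eta, per row

        logp = float(
            np.sum(t_const - 0.5 * (nu + 1) * np.log1p(r2 / nu) - log_sig)
        )
        grad += np.bincount(d.col_a, weights=w, minlength=ndim)
        grad += np.bincount(col_vt, weights=w[vt_valid], minlength=ndim)
        grad += np.bincount(col_rr, weights=w[rr_valid], minlength=ndim)
        gz = np.bincount(d.col_pat, weights=w, minlength=ndim)
        grad[z_sl] += tau * gz[z_sl]
        grad[lt_sl.start] += tau * float(np.sum(w * z_row))
        grad += np.bincount(
            d.col_sig, weights=(nu + 1) * r2 / denom - 1.0, minlength=ndim
        )

        # priors
        a = theta[a_sl]
        da = (a - spec.prior_intercept_mean) / spec.prior_intercept_sd**2
        logp += float(-0.5 * np.sum((a - spec.prior_intercept_mean) ** 2) / spec.prior_intercept_sd**2)
        grad[a_sl] -= da
        for name in ("b_vt", "b_rr"):
            b = theta[sl[name]]
            logp += float(-0.5 * np.sum(b * b) / spec.prior_coef_sd**2)
            grad[sl[name]] -= b / spec.prior_coef_sd**2
        z = theta[z_sl]
        logp += float(-0.5 * np.sum(z * z))
        grad[z_sl] -= z
        logp += float(-0.5 * (tau / spec.prior_tau_sd) ** 2 + log_tau)
        grad[lt_sl.start] += -((tau / spec.prior_tau_sd) ** 2) + 1.0
        ls_all = theta[sl["log_sigma"]]
        sig_all = np.exp(ls_all)
        logp += float(np.sum(-0.5 * (sig_all / spec.prior_sigma_sd) ** 2 + ls_all))
        grad[sl["log_sigma"]] += -((sig_all / spec.prior_sigma_sd) ** 2) + 1.0
        return logp, grad

    return logp_grad


@dataclass
class EffectsPosterior:
    """Posterior draws and summaries of the effects model."""

    draws: dict  #: name -> (n_draws,) or (n_draws, k) arrays
    methods: list
    vt_levels: list
    rr_levels: list
    patients: list
    settings: list
    spec: EffectsModelSpec
    rhat_max: float
    ess_min: float
    reliable: bool
    n_draws: int
    seed: int | None = None
    notes: str = ""

    def _coef_draws(self, method: str, dim: str, level: float) -> np.ndarray:
        levels = self.vt_levels if dim == "vt" else self.rr_levels
        name = "b_vt" if dim == "vt" else "b_rr"
        ref = REF_VT if dim == "vt" else REF_RR
        if level == ref:
            return np.zeros(self.n_draws)
        if level not in levels or method not in self.methods:
            raise KeyError(f"no {dim} effect for level {level:g}, method {method!r}")
        mi = self.methods.index(method)
        return self.draws[name][:, mi * len(levels) + levels.index(level)]

    def relative_effect_draws(self, method: str, dim: str, level: float) -> np.ndarray:
        """Posterior draws of the multiplicative effect (fraction of the
        reference-setting PPV)."""
        return np.exp(self._coef_draws(method, dim, level))

    def relative_effects_table(self) -> pd.DataFrame:
        """Median and 95% interval of every relative effect, in percent."""
        rows = []
        for m in self.methods:
            for dim, levels in (("vt", self.vt_levels), ("rr", self.rr_levels)):
                for lv in levels:
                    e = 100.0 * self.relative_effect_draws(m, dim, lv)
                    rows.append(
                        (
                            m,
                            dim,
                            lv,
                            float(np.median(e)),
                            float(np.percentile(e, 2.5)),
                            float(np.percentile(e, 97.5)),
                        )
                    )
        return pd.DataFrame(
            rows, columns=["method", "dimension", "level", "median_pct", "lo_pct", "hi_pct"]
        )

    def relative_effects(self, method: str) -> RelativeEffects:
        """Posterior-median multiplicative factors, for PPV correction."""
        vt = {
            lv: float(np.median(self.relative_effect_draws(method, "vt", lv)))
            for lv in self.vt_levels
        }
        rr = {
            lv: float(np.median(self.relative_effect_draws(method, "rr", lv)))
            for lv in self.rr_levels
        }
        return RelativeEffects(vt=vt, rr=rr)

    def _sigma_index(self, vt: float, rr: float, method: str | None) -> int:
        key = (vt, rr, method) if self.spec.sigma_per_method else (vt, rr)
        if key not in self.settings:
            raise KeyError(f"setting {key} not in model")
        return self.settings.index(key)

    def cv_draws(self, vt: float, rr: float, method: str | None = None) -> np.ndarray:
        """Coefficient-of-variation draws for one setting, in percent.

        With the log link the residual scale is already relative to the
        expected PPV; the CV is the SD of the t(nu) log residual:
        sqrt(nu/(nu-2))·sigma_s.
        """
        nu = self.spec.nu
        sigma = np.exp(self.draws["log_sigma"][:, self._sigma_index(vt, rr, method)])
        return 100.0 * np.sqrt(nu / (nu - 2.0)) * sigma

    def cv_table(self) -> pd.DataFrame:
        rows = []
        for key in self.settings:
            vt, rr = key[0], key[1]
            method = key[2] if self.spec.sigma_per_method else None
            cv = self.cv_draws(vt, rr, method)
            rows.append(
                (
                    vt,
                    rr,
                    method or "all",
                    float(np.median(cv)),
                    float(np.percentile(cv, 2.5)),
                    float(np.percentile(cv, 97.5)),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["vt_ml_per_kg", "rr_per_min", "method", "cv_median_pct", "cv_lo_pct", "cv_hi_pct"],
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            arr2 = arr if arr.ndim == 2 else arr[:, None]
            for j in range(arr2.shape[1]):
                col = arr2[:, j]
                rows.append(
                    (
                        f"{name}[{j}]",
                        float(np.median(col)),
                        float(np.percentile(col, 2.5)),
                        float(np.percentile(col, 97.5)),
                    )
                )
        return pd.DataFrame(rows, columns=["param", "median", "q2.5", "q97.5"])


def fit_effects_model(
    data: pd.DataFrame,
    spec: EffectsModelSpec | None = None,
    chains: int = 4,
    iters: int = 2000,
    seed: int = 0,
    require_convergence: bool = False,
) -> EffectsPosterior:
    """Sample the effects model posterior by Hamiltonian Monte Carlo.

    ``iters`` is the per-chain iteration count: the first half is warm-up
    (step-size and mass adaptation) and discarded.  A fit with split-R-hat
    >= 1.05 is flagged unreliable (and raises if ``require_convergence``).
    """
    from ._hmc import hmc_sample

    spec = spec or EffectsModelSpec()
    data = validate_cohort(data)
    if data["patient_id"].nunique() < 5:
        raise ValueError("need at least 5 patients")
    if data.groupby(["vt_ml_per_kg", "rr_per_min"]).ngroups < 2:
        raise ValueError("need at least 2 ventilator settings")

    d = _build_design(data, spec)
    ndim = d.n_params
    rng = np.random.default_rng(seed)
    logp_grad = _make_logp_grad(d, spec)

    # start chains scattered around the posterior mode: warm-up is then
    # spent adapting, not finding the typical set
    from scipy.optimize import minimize

    centre = np.zeros(ndim)
    centre[d.slices["a"]] = np.median(d.log_y)
    centre[d.slices["log_tau"]] = np.log(0.3)
    centre[d.slices["log_sigma"]] = np.log(0.2)
    opt = minimize(
        lambda th: tuple(-v for v in logp_grad(th)),
        centre,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    mode = opt.x if np.all(np.isfinite(opt.x)) else centre

    n_warm = iters // 2
    n_draw = iters - n_warm
    per_chain = []
    for _c in range(max(chains, 2)):
        x0 = mode + 0.1 * rng.standard_normal(ndim)
        ch_draws, _acc, _eps = hmc_sample(
            logp_grad, x0, n_warmup=n_warm, n_draws=n_draw, rng=rng
        )
        per_chain.append(ch_draws)
    chain = np.stack(per_chain)  # (chains, draws, ndim)
    rhat_max, ess_min = _diagnostics(chain)
    flat = chain.reshape(-1, ndim)

    draws = {
        name: np.squeeze(flat[:, sl]) if sl.stop - sl.start == 1 else flat[:, sl]
        for name, sl in d.slices.items()
    }
    draws["tau"] = np.exp(draws.pop("log_tau"))
    ls = draws.pop("log_sigma")
    draws["log_sigma"] = ls if ls.ndim == 2 else ls[:, None]

    reliable = rhat_max < 1.05
    if not reliable:
        msg = f"fit flagged unreliable: max R-hat {rhat_max:.3f} >= 1.05"
        if require_convergence:
            raise RuntimeError(msg)
        warnings.warn(msg, stacklevel=2)

    return EffectsPosterior(
        draws=draws,
        methods=d.methods,
        vt_levels=d.vt_levels,
        rr_levels=d.rr_levels,
        patients=d.patients,
        settings=d.settings,
        spec=spec,
        rhat_max=rhat_max,
        ess_min=ess_min,
        reliable=reliable,
        n_draws=flat.shape[0],
        seed=seed,
    )


def _diagnostics(chain: np.ndarray) -> tuple[float, float]:
    """Split-R-hat and bulk ESS over a (chains, draws, ndim) array."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.convert_to_dataset(chain))["x"].values
        ess = az.ess(az.convert_to_dataset(chain))["x"].values
    return float(np.nanmax(rhat)), float(np.nanmin(ess))


def cv_contrast(
    post: EffectsPosterior,
    setting_a: tuple,
    setting_b: tuple,
) -> dict:
    """Posterior difference of CVs between two (vt, rr, method) settings.

    Returns the median and 95% interval of ``CV(a) − CV(b)`` in
    percentage points, computed draw by draw.
    """
    cv_a = post.cv_draws(*setting_a)
    cv_b = post.cv_draws(*setting_b)
    diff = cv_a - cv_b
    return {
        "median": float(np.median(diff)),
        "lo": float(np.percentile(diff, 2.5)),
        "hi": float(np.percentile(diff, 97.5)),
    }
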