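"""Joint ML estimation of non-ignorable-dropout models.

Three models share the growth model (person + school random intercepts) as
their outcome part and differ in how the wave-2 response indicator is
modeled:

* Diggle-Kenward selection (DK): logit dropout probability depending on the
  past (wave-0) and current (wave-1) outcome, the latter unobserved for
  dropouts and integrated out.
* Wu-Carroll shared parameter (WC): probit dropout probability loading on
  the person random intercept u_i; outcome and dropout are linked through
  the shared latent effect.
* Little's two-class pattern mixture (PM): dropout pattern defines the
  class; class-specific fixed effects with (by default) equal variance
  components; time-dependent terms of the dropout class are not estimable
  without a restriction.

The joint likelihoods are assembled school block by school block.  The
school intercept is integrated by adaptive Gauss-Hermite quadrature centered
on its Gaussian-part posterior; person intercepts integrate analytically
wherever the selection factor allows (everywhere in WC, completers in DK)
and by nested adaptive quadrature otherwise.  No school effect enters any
selection equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm

from .data import ANALYSIS_TERMS, LongDataset, PersonView, person_view
from .gcm import (
    VC_NAMES,
    FitResult,
    GCMParams,
    VarianceComponents,
    _school_quadratics,
    fit_lmm,
)

_SQRT2 = np.sqrt(2.0)
_SQRTPI = np.sqrt(np.pi)


@dataclass
class JointFitResult:
    """Outcome-part estimates plus selection-equation estimates."""

    params: GCMParams
    vc: VarianceComponents
    selection: dict           # psi name -> estimate
    se: dict                  # all parameters
    ci95: dict
    loglik: float
    n_persons: int
    n_schools: int
    method: str
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    terms: tuple = ANALYSIS_TERMS

    def estimates(self) -> dict:
        out = dict(zip(self.terms, self.params.as_array()))
        out.update(zip(VC_NAMES, self.vc.as_array()))
        out.update(self.selection)
        return out

    def table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates().items():
            part = "selection" if name in self.selection else "outcome"
            s = self.se.get(name, np.nan)
            lo, hi = self.ci95.get(name, (np.nan, np.nan))
            rows.append((part, name, est, s, lo, hi))
        return pd.DataFrame(rows, columns=["part", "term", "estimate", "se", "ci_lo", "ci_hi"])


def _prepare(view: PersonView, selection_covariates):
    d = ~view.resp
    if not d.any():
        raise ValueError("selection parameters unidentified: data contain no dropout")
    if selection_covariates:
        missing = [c for c in selection_covariates if c not in view.covariates.columns]
        if missing:
            raise ValueError(f"selection covariates not in data: {missing}")
        Xs = view.covariates[list(selection_covariates)].to_numpy(float)
    else:
        Xs = np.empty((view.n_persons, 0))
    return d, Xs


def _gauss_part(view, gamma, su2, sv2, se2):
    """Per-school quadratic summaries of the Gaussian (outcome) part and the
    adaptive quadrature centering for the school intercept."""
    n = view.n_persons
    ones = np.ones(n)
    A, B, C, LN = _school_quadratics(
        view.y0,
        np.where(view.resp, view.y1, 0.0),
        view.X0 @ gamma,
        view.X1 @ gamma,
        view.resp,
        ones,
        ones,
        view.school,
        view.n_schools,
        (su2, sv2, se2),
    )
    var_post = sv2 / (1.0 + sv2 * A)
    v_hat = var_post * B
    sd_post = np.sqrt(np.maximum(var_post, 1e-300))
    return A, B, C, LN, v_hat, sd_post


def _log_gauss_at(A, B, C, LN, v):
    return LN - 0.5 * (A * v * v - 2.0 * B * v + C)


def _logphi_sigma(v, s2):
    return -0.5 * np.log(2.0 * np.pi * s2) - 0.5 * v * v / s2


def _aghq_loglik(log_fv, v_hat, sd_post, gh_t, gh_w):
    """Combine per-school node values log f(v_q) into log ∫ f(v) dv."""
    # log_fv: (S, Q) already includes prior phi(v; sv2) and all factors
    vals = log_fv + gh_t**2 + np.log(gh_w)
    m = vals.max(axis=1)
    return np.log(np.sum(np.exp(vals - m[:, None]), axis=1)) + m + np.log(_SQRT2 * sd_post)


# --------------------------------------------------------------------------
# Diggle-Kenward
# --------------------------------------------------------------------------

def _dk_loglik(theta, view, d, Xs, gh_v, gh_u, gh_y, disable_selection=False):
    p = 6
    gamma = theta[:p]
    su2, sv2, se2 = np.exp(2.0 * theta[p:p + 3])
    psi0, psi_y0, psi_y1 = theta[p + 3:p + 6]
    psi_x = theta[p + 6:]

    A, B, C, LN, v_hat, sd_post = _gauss_part(view, gamma, su2, sv2, se2)
    tq, wq = gh_v
    S, Q = v_hat.size, tq.size
    v_nodes = v_hat[:, None] + _SQRT2 * sd_post[:, None] * tq[None, :]  # (S, Q)

    log_fv = _logphi_sigma(v_nodes, sv2) + _log_gauss_at(
        A[:, None], B[:, None], C[:, None], LN[:, None], v_nodes
    )

    extra = 0.0
    if not disable_selection:
        # completers: observed (y0, y1) -> factor (1 - pi), independent of (u, v)
        comp = ~d
        lin_c = psi0 + psi_y0 * view.y0[comp] + psi_y1 * view.y1[comp]
        if psi_x.size:
            lin_c = lin_c + Xs[comp] @ psi_x
        extra = float(np.sum(-np.log1p(np.exp(lin_c))))  # log(1 - expit)

        if d.any():
            s00 = su2 + se2
            tau2 = su2 * se2 / s00
            tau = np.sqrt(tau2)
            m0d = view.X0[d] @ gamma
            m1d = view.X1[d] @ gamma
            y0d = view.y0[d]
            sch_d = view.school[d]
            lin_d0 = psi0 + psi_y0 * y0d
            if psi_x.size:
                lin_d0 = lin_d0 + Xs[d] @ psi_x
            tk, wk = gh_u
            tj, wj = gh_y
            wk_n = wk / _SQRTPI
            wj_n = wj / _SQRTPI
            # log P_d(v) on the quadrature grid, accumulated per school
            logP_sq = np.zeros((S, Q))
            eta_scale = su2 / s00
            for q in range(Q):
                vq = v_nodes[sch_d, q]                       # (D,)
                eta = eta_scale * (y0d - m0d - vq)           # posterior mean of u
                t_base = m1d + eta + vq                      # E[y1 | u=eta, v]
                # y1 nodes: t_base + sqrt2*tau*tk + sqrt2*se*tj
                y1n = (
                    t_base[:, None, None]
                    + _SQRT2 * tau * tk[None, :, None]
                    + _SQRT2 * np.sqrt(se2) * tj[None, None, :]
                )
                pi = special.expit(lin_d0[:, None, None] + psi_y1 * y1n)
                P = np.einsum("k,j,dkj->d", wk_n, wj_n, pi)
                np.add.at(logP_sq[:, q], sch_d, np.log(np.maximum(P, 1e-300)))
            log_fv = log_fv + logP_sq

    ll = _aghq_loglik(log_fv, v_hat, sd_post, tq, wq)
    return float(np.sum(ll)) + extra


# --------------------------------------------------------------------------
# Wu-Carroll
# --------------------------------------------------------------------------

def _wc_loglik(theta, view, d, Xs, gh_v, disable_selection=False):
    p = 6
    gamma = theta[:p]
    su2, sv2, se2 = np.exp(2.0 * theta[p:p + 3])
    psi0, lam = theta[p + 3:p + 5]
    psi_x = theta[p + 5:]

    A, B, C, LN, v_hat, sd_post = _gauss_part(view, gamma, su2, sv2, se2)
    tq, wq = gh_v
    v_nodes = v_hat[:, None] + _SQRT2 * sd_post[:, None] * tq[None, :]  # (S, Q)
    log_fv = _logphi_sigma(v_nodes, sv2) + _log_gauss_at(
        A[:, None], B[:, None], C[:, None], LN[:, None], v_nodes
    )

    if not disable_selection:
        s00 = su2 + se2
        # completers: u | (y0, y1, v) posterior
        tau2_c = 1.0 / (1.0 / su2 + 2.0 / se2)
        tau2_d = su2 * se2 / s00
        base = np.full(view.n_persons, psi0)
        if psi_x.size:
            base = base + Xs @ psi_x
        m0 = view.X0 @ gamma
        m1 = view.X1 @ gamma
        sel_sq = np.zeros_like(log_fv)
        comp = ~d
        if comp.any():
            r_sum = (view.y0[comp] - m0[comp])[:, None] + (
                np.where(view.resp, view.y1, 0.0)[comp] - m1[comp]
            )[:, None] - 2.0 * v_nodes[view.school[comp]]
            eta = tau2_c * r_sum / se2                      # (C, Q)
            a = base[comp][:, None] + lam * eta
            a = a / np.sqrt(1.0 + lam * lam * tau2_c)
            vals = norm.logcdf(-a)                          # log(1 - Phi(a))
            np.add.at(sel_sq, view.school[comp], vals)
        if d.any():
            eta = (su2 / s00) * (
                (view.y0[d] - m0[d])[:, None] - v_nodes[view.school[d]]
            )
            a = base[d][:, None] + lam * eta
            a = a / np.sqrt(1.0 + lam * lam * tau2_d)
            vals = norm.logcdf(a)                           # log Phi(a)
            np.add.at(sel_sq, view.school[d], vals)
        log_fv = log_fv + sel_sq

    ll = _aghq_loglik(log_fv, v_hat, sd_post, tq, wq)
    return float(np.sum(ll))


# --------------------------------------------------------------------------
# shared fitting driver
# --------------------------------------------------------------------------

def _fit_joint(
    nll_full,
    names,
    start,
    fix,
    method_label,
    view,
    quad_settings,
    compute_se=True,
    maxiter=500,
):
    names = list(names)
    fix = dict(fix or {})
    free_idx = [i for i, nm in enumerate(names) if nm not in fix]
    x_full0 = np.array(start, float)
    for nm, val in fix.items():
        if nm not in names:
            raise ValueError(f"cannot fix unknown parameter '{nm}'")
        x_full0[names.index(nm)] = val

    def embed(xfree):
        x = x_full0.copy()
        x[free_idx] = xfree
        return x

    def nll(xfree):
        try:
            val = nll_full(embed(xfree))
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            nll,
            x_full0[free_idx],
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )
    x_hat = embed(res.x)
    loglik = -float(res.fun)

    se = {nm: (0.0 if nm in fix else np.nan) for nm in names}
    if compute_se and free_idx:
        H = _hessian(nll, res.x)
        try:
            cov = np.linalg.inv(H)
            dg = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for pos, i in enumerate(free_idx):
                se[names[i]] = float(dg[pos])
        except np.linalg.LinAlgError:
            pass

    # map to reporting scale: variances exp(2x); delta method for their SEs
    est = dict(zip(names, x_hat))
    out_est, out_se = {}, {}
    for nm in names:
        if nm.startswith("log_sd_"):
            vc_name = {"log_sd_u": "sigma_u2", "log_sd_v": "sigma_v2", "log_sd_e": "sigma_e2"}[nm]
            var = float(np.exp(2.0 * est[nm]))
            out_est[vc_name] = var
            out_se[vc_name] = 2.0 * var * se[nm] if np.isfinite(se[nm]) else np.nan
        else:
            out_est[nm] = float(est[nm])
            out_se[nm] = se[nm]
    ci = {nm: (out_est[nm] - 1.96 * out_se[nm], out_est[nm] + 1.96 * out_se[nm])
          for nm in out_est if np.isfinite(out_se[nm])}

    gamma = np.array([out_est[t] for t in ANALYSIS_TERMS])
    vc = VarianceComponents(out_est["sigma_u2"], out_est["sigma_v2"], out_est["sigma_e2"])
    sel = {nm: out_est[nm] for nm in out_est
           if nm not in ANALYSIS_TERMS and nm not in VC_NAMES}
    return JointFitResult(
        params=GCMParams.from_array(gamma),
        vc=vc,
        selection=sel,
        se=out_se,
        ci95=ci,
        loglik=loglik,
        n_persons=view.n_persons,
        n_schools=view.n_schools,
        method=method_label,
        converged=bool(res.success),
        diagnostics={
            "n_iter": int(res.nit),
            "optimizer_message": str(res.message),
            "quadrature": quad_settings,
            "fixed": dict(fix),
        },
    )


def _hessian(f, x, h=1e-4):
    k = x.size
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


def _warm_start_outcome(view):
    base = fit_lmm(view, use_rows="observed_rows", method="fiml")
    logsd = 0.5 * np.log(np.maximum(base.vc.as_array(), 1e-8))
    return base, np.concatenate([base.params.as_array(), logsd])


def fit_diggle_kenward(
    data: LongDataset | PersonView,
    selection_covariates: list[str] | None = None,
    quad_nodes: int = 15,
    quad_nodes_y1: int = 21,
    fix: dict | None = None,
    compute_se: bool = True,
) -> JointFitResult:
    """Joint ML fit of the growth model with a logit dropout equation on the
    wave-0 (past) and wave-1 (current) outcome.

    The wave-1 outcome of dropouts is integrated over its conditional normal
    (Gauss-Hermite, centered at the conditional mean with sd sigma_e) nested
    inside adaptive quadrature over the person and school intercepts.
    """
    if quad_nodes < 3 or quad_nodes_y1 < 3:
        raise ValueError("quadrature needs at least 3 nodes")
    view = data if isinstance(data, PersonView) else person_view(data)
    d, Xs = _prepare(view, selection_covariates)
    sel_names = ["psi_intercept", "psi_y0", "psi_y1"] + [
        f"psi_{c}" for c in (selection_covariates or [])
    ]
    names = (
        list(ANALYSIS_TERMS)
        + ["log_sd_u", "log_sd_v", "log_sd_e"]
        + sel_names
    )
    base, x_out = _warm_start_outcome(view)
    # selection start: logit of dropout on the wave-0 outcome
    from .diagnostics import _logit_irls

    b0, _, _ = _logit_irls(d.astype(int), np.column_stack([np.ones(view.n_persons), view.y0]))
    start = np.concatenate([x_out, [b0[0], b0[1], 0.0], np.zeros(Xs.shape[1])])

    gh_v = np.polynomial.hermite.hermgauss(quad_nodes)
    gh_u = np.polynomial.hermite.hermgauss(quad_nodes)
    gh_y = np.polynomial.hermite.hermgauss(quad_nodes_y1)

    def nll_full(theta):
        return -_dk_loglik(theta, view, d, Xs, gh_v, gh_u, gh_y)

    return _fit_joint(
        nll_full, names, start, fix, "dk", view,
        {"v": quad_nodes, "u": quad_nodes, "y1": quad_nodes_y1},
        compute_se=compute_se,
    )


def fit_wu_carroll(
    data: LongDataset | PersonView,
    selection_covariates: list[str] | None = None,
    quad_nodes: int = 15,
    fix: dict | None = None,
    compute_se: bool = True,
) -> JointFitResult:
    """Joint ML fit of the growth model with a probit dropout equation
    loading on the shared person intercept u_i (coefficient ``lambda``)."""
    if quad_nodes < 3:
        raise ValueError("quadrature needs at least 3 nodes")
    view = data if isinstance(data, PersonView) else person_view(data)
    d, Xs = _prepare(view, selection_covariates)
    sel_names = ["psi_intercept", "lambda"] + [f"psi_{c}" for c in (selection_covariates or [])]
    names = list(ANALYSIS_TERMS) + ["log_sd_u", "log_sd_v", "log_sd_e"] + sel_names
    base, x_out = _warm_start_outcome(view)
    start = np.concatenate(
        [x_out, [norm.ppf(max(min(d.mean(), 1 - 1e-6), 1e-6)), 0.0], np.zeros(Xs.shape[1])]
    )
    gh_v = np.polynomial.hermite.hermgauss(quad_nodes)

    def nll_full(theta):
        return -_wc_loglik(theta, view, d, Xs, gh_v)

    return _fit_joint(
        nll_full, names, start, fix, "wc", view, {"v": quad_nodes},
        compute_se=compute_se,
    )


def joint_loglik_selection_disabled(
    method: str,
    params: GCMParams,
    vc: VarianceComponents,
    data: LongDataset | PersonView,
    quad_nodes: int = 15,
) -> float:
    """Joint log-likelihood with the selection part switched off; must equal
    the observed-data growth-model log-likelihood (shared-kernel check)."""
    view = data if isinstance(data, PersonView) else person_view(data)
    d = ~view.resp
    Xs = np.empty((view.n_persons, 0))
    theta = np.concatenate(
        [params.as_array(), 0.5 * np.log(np.maximum(vc.as_array(), 1e-300)), np.zeros(3)]
    )
    gh = np.polynomial.hermite.hermgauss(quad_nodes)
    if method == "dk":
        return _dk_loglik(theta, view, d, Xs, gh, gh, gh, disable_selection=True)
    if method == "wc":
        theta = theta[:-1]  # wc has 2 selection params
        return _wc_loglik(theta, view, d, Xs, gh, disable_selection=True)
    raise ValueError("method must be 'dk' or 'wc'")


# --------------------------------------------------------------------------
# pattern mixture
# --------------------------------------------------------------------------

@dataclass
class PatternMixtureResult:
    """Two-class pattern-mixture estimates (PM1 completers, PM0 dropouts)."""

    class_params: pd.DataFrame      # term x class table
    vc: VarianceComponents
    proportions: dict               # {"pm1": p1, "pm0": p0}
    mixture: pd.DataFrame           # mixture-averaged fixed effects
    restriction: str
    loglik: float
    converged: bool
    fit: FitResult
    diagnostics: dict = field(default_factory=dict)

    def estimates(self) -> dict:
        out = {}
        for _, r in self.class_params.iterrows():
            out[f"{r['term']}:{r['class']}"] = r["estimate"]
        out.update(zip(VC_NAMES, self.vc.as_array()))
        return out


_TIME_TERMS = ("time", "time:reas", "time:sc")
_BASE_TERMS = ("intercept", "reas", "sc")


def fit_pattern_mixture(
    data: LongDataset | PersonView,
    restriction: str = "none",
    equal_variances: bool = True,
) -> PatternMixtureResult:
    """Little's two-class pattern mixture for two-wave monotone dropout.

    With dropout dummies as the only membership covariates and two classes,
    membership is deterministic by response pattern.  Class-specific growth
    parameters are estimated with variance components constrained equal
    across classes (``equal_variances=True``, the identification used for
    reporting) or freed per class.  The dropout class provides no wave-1
    data, so its time-dependent terms are not estimable: ``restriction=
    'none'`` reports them as NA; ``'equal_growth'`` borrows them from the
    completer class, enabling a mixture-averaged time effect.
    """
    if restriction not in ("none", "equal_growth"):
        raise ValueError("restriction must be 'none' or 'equal_growth'")
    view = data if isinstance(data, PersonView) else person_view(data)
    comp = view.has_y1
    drop = ~comp
    n1, n0 = int(comp.sum()), int(drop.sum())
    if n0 == 0:
        fit = fit_lmm(view, use_rows="observed_rows", method="pm")
        cp = pd.DataFrame(
            {"class": "pm1", "term": list(ANALYSIS_TERMS),
             "estimate": fit.params.as_array(),
             "se": [fit.se[t] for t in ANALYSIS_TERMS]}
        )
        cp["ci_lo"] = cp["estimate"] - 1.96 * cp["se"]
        cp["ci_hi"] = cp["estimate"] + 1.96 * cp["se"]
        mix = cp.drop(columns="class")
        return PatternMixtureResult(
            class_params=cp, vc=fit.vc, proportions={"pm1": 1.0, "pm0": 0.0},
            mixture=mix, restriction=restriction, loglik=fit.loglik,
            converged=fit.converged, fit=fit,
            diagnostics={"note": "no dropout: single-class model"},
        )
    if n1 < 2 or n0 < 2:
        raise ValueError("each dropout class needs at least 2 persons")

    p1 = n1 / (n1 + n0)
    ind1 = comp.astype(float)[:, None]
    ind0 = drop.astype(float)[:, None]

    if not equal_variances:
        return _pm_separate(view, comp, drop, p1, restriction)

    cols0, cols1, terms = [], [], []
    base_idx = {t: i for i, t in enumerate(ANALYSIS_TERMS)}
    for t in _BASE_TERMS:
        j = base_idx[t]
        terms += [f"{t}:pm1", f"{t}:pm0"]
        cols0 += [view.X0[:, [j]] * ind1, view.X0[:, [j]] * ind0]
        cols1 += [view.X1[:, [j]] * ind1, view.X1[:, [j]] * ind0]
    for t in _TIME_TERMS:
        j = base_idx[t]
        if restriction == "none":
            terms += [f"{t}:pm1"]
            cols0 += [view.X0[:, [j]] * ind1]
            cols1 += [view.X1[:, [j]] * ind1]
        else:
            terms += [t]
            cols0 += [view.X0[:, [j]]]
            cols1 += [view.X1[:, [j]]]
    X0 = np.hstack(cols0)
    X1 = np.hstack(cols1)
    fit = fit_lmm(view, use_rows="observed_rows", design=(tuple(terms), X0, X1), method="pm")

    rows = []
    idx = {t: i for i, t in enumerate(terms)}
    for t in ANALYSIS_TERMS:
        for cls, present in (("pm1", True), ("pm0", t in _BASE_TERMS or restriction == "equal_growth")):
            if t in _TIME_TERMS and restriction == "equal_growth":
                key = t
            else:
                key = f"{t}:{cls}"
            if present and key in idx:
                est = fit.fixed_effects[key]
                s = fit.se[key]
                rows.append((cls, t, est, s, est - 1.96 * s, est + 1.96 * s))
            else:
                rows.append((cls, t, np.nan, np.nan, np.nan, np.nan))
    cp = pd.DataFrame(rows, columns=["class", "term", "estimate", "se", "ci_lo", "ci_hi"])

    mix_rows = []
    V = fit.vcov_fixed
    for t in ANALYSIS_TERMS:
        if t in _BASE_TERMS:
            i1, i0 = idx[f"{t}:pm1"], idx[f"{t}:pm0"]
            est = p1 * fit.fixed_effects[f"{t}:pm1"] + (1 - p1) * fit.fixed_effects[f"{t}:pm0"]
            var = (
                p1**2 * V[i1, i1] + (1 - p1) ** 2 * V[i0, i0] + 2 * p1 * (1 - p1) * V[i1, i0]
            )
            s = float(np.sqrt(var))
            mix_rows.append((t, est, s, est - 1.96 * s, est + 1.96 * s))
        elif restriction == "equal_growth":
            i = idx[t]
            est, s = fit.fixed_effects[t], fit.se[t]
            mix_rows.append((t, est, s, est - 1.96 * s, est + 1.96 * s))
        else:
            mix_rows.append((t, np.nan, np.nan, np.nan, np.nan))
    mix = pd.DataFrame(mix_rows, columns=["term", "estimate", "se", "ci_lo", "ci_hi"])

    return PatternMixtureResult(
        class_params=cp, vc=fit.vc, proportions={"pm1": p1, "pm0": 1 - p1},
        mixture=mix, restriction=restriction, loglik=fit.loglik,
        converged=fit.converged, fit=fit,
        diagnostics={"equal_variances": True},
    )


def _pm_separate(view, comp, drop, p1, restriction):
    """Variances freed per class: fit each pattern class on its own."""
    sub1 = _subset_view(view, comp)
    fit1 = fit_lmm(sub1, use_rows="complete_persons", method="pm1")
    sub0 = _subset_view(view, drop)
    # dropouts contribute a single row: time terms drop from the design and
    # the person effect folds into the residual (not separately identified)
    base_idx = [ANALYSIS_TERMS.index(t) for t in _BASE_TERMS]
    design0 = (
        tuple(_BASE_TERMS),
        sub0.X0[:, base_idx],
        sub0.X1[:, base_idx],
    )
    fit0 = fit_lmm(sub0, use_rows="observed_rows", person_effect=False,
                   design=design0, method="pm0")
    rows = []
    for t in ANALYSIS_TERMS:
        est, s = fit1.fixed_effects[t], fit1.se[t]
        rows.append(("pm1", t, est, s, est - 1.96 * s, est + 1.96 * s))
    for t in ANALYSIS_TERMS:
        if t in _BASE_TERMS:
            est, s = fit0.fixed_effects[t], fit0.se[t]
            rows.append(("pm0", t, est, s, est - 1.96 * s, est + 1.96 * s))
        else:
            rows.append(("pm0", t, np.nan, np.nan, np.nan, np.nan))
    cp = pd.DataFrame(rows, columns=["class", "term", "estimate", "se", "ci_lo", "ci_hi"])
    mix_rows = []
    for t in ANALYSIS_TERMS:
        if t in _BASE_TERMS:
            est = p1 * fit1.fixed_effects[t] + (1 - p1) * fit0.fixed_effects[t]
            s = float(np.sqrt(p1**2 * fit1.se[t] ** 2 + (1 - p1) ** 2 * fit0.se[t] ** 2))
            mix_rows.append((t, est, s, est - 1.96 * s, est + 1.96 * s))
        else:
            mix_rows.append((t, np.nan, np.nan, np.nan, np.nan))
    mix = pd.DataFrame(mix_rows, columns=["term", "estimate", "se", "ci_lo", "ci_hi"])
    return PatternMixtureResult(
        class_params=cp, vc=fit1.vc, proportions={"pm1": p1, "pm0": 1 - p1},
        mixture=mix, restriction=restriction,
        loglik=fit1.loglik + fit0.loglik, converged=fit1.converged and fit0.converged,
        fit=fit1, diagnostics={"equal_variances": False},
    )


def _subset_view(view: PersonView, mask: np.ndarray) -> PersonView:
    school_codes = view.school[mask]
    levels, inv = np.unique(school_codes, return_inverse=True)
    return PersonView(
        y0=view.y0[mask], y1=view.y1[mask], resp=view.resp[mask],
        school=inv, X0=view.X0[mask], X1=view.X1[mask], terms=view.terms,
        person_id=view.person_id[mask], school_levels=view.school_levels[levels],
        covariates=view.covariates.iloc[mask].reset_index(drop=True),
    )
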