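"""Linear growth model with nested person and school random intercepts.

The analysis model regresses the competence score on time (0/1), reasoning,
self-concept and the two time interactions, with independent zero-mean normal
random intercepts for persons (u) and schools (v) and a residual e:

    Y_tis = gamma0 + gamma1*TIME + gamma2*REAS + gamma3*SC
            + gamma4*TIME*REAS + gamma5*TIME*SC + u_i + v_s + e_tis

Estimation is maximum likelihood.  Because persons contribute at most two
waves and schools are independent, the marginal likelihood has a closed form
school block by school block: conditioning on v, persons are independent with
a 2x2 (or 1x1) covariance, and the scalar v integrates analytically.  The
same decomposition yields the row-weighted pseudo-log-likelihood used for
inverse-probability-weighted fits: each row's conditional Gaussian
contribution (wave-0 marginal, wave-1 conditional on wave 0) is raised to the
power of its weight; with unit weights this reproduces the exact likelihood.

Row selection implements the estimators compared in the sensitivity
analysis: ``complete_persons`` is listwise deletion, ``observed_rows`` is
observed-data ML ("FIML"), and ``complete_persons`` + weights is the
weighted (WE) fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import ANALYSIS_TERMS, LongDataset, PersonView, person_view

VC_NAMES = ("sigma_u2", "sigma_v2", "sigma_e2")
_LOG_SD_FLOOR = -8.0  # soft lower bound; hitting it flags a boundary estimate


@dataclass
class GCMParams:
    """Fixed effects of the growth model (gamma0..gamma5)."""

    gamma0: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    gamma3: float = 0.0
    gamma4: float = 0.0
    gamma5: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.gamma0, self.gamma1, self.gamma2, self.gamma3, self.gamma4, self.gamma5]
        )

    @classmethod
    def from_array(cls, a) -> "GCMParams":
        return cls(*[float(x) for x in np.asarray(a, float)])


@dataclass
class VarianceComponents:
    """Variances of the person effect u, school effect v and residual e."""

    sigma_u2: float
    sigma_v2: float
    sigma_e2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_u2, self.sigma_v2, self.sigma_e2])

    def validate(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("variance components must be finite and non-negative")

    @property
    def icc_person(self) -> float:
        """Share of total variance below the school level that repeats within
        person across waves (u+v over u+v+e)."""
        tot = self.sigma_u2 + self.sigma_v2 + self.sigma_e2
        return (self.sigma_u2 + self.sigma_v2) / tot

    @property
    def icc_school(self) -> float:
        tot = self.sigma_u2 + self.sigma_v2 + self.sigma_e2
        return self.sigma_v2 / tot


@dataclass
class FitResult:
    """Estimates, SEs, Wald 95% CIs and diagnostics of one model fit."""

    params: GCMParams
    vc: VarianceComponents
    se: dict
    ci95: dict
    loglik: float
    n_obs: int
    n_persons: int
    n_schools: int
    method: str
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    vcov_fixed: np.ndarray | None = None
    terms: tuple = ANALYSIS_TERMS
    fixed_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.fixed_effects:
            self.fixed_effects = dict(zip(self.terms, self.params.as_array()))

    def estimates(self) -> dict:
        out = dict(self.fixed_effects)
        out.update(zip(VC_NAMES, self.vc.as_array()))
        return out


# --------------------------------------------------------------------------
# likelihood kernel
# --------------------------------------------------------------------------

def _select_rows(view: PersonView, use_rows: str):
    """Return (mask_person, use_wave1) for the requested row policy.

    Selection keys on outcome presence, so completed (imputed) datasets are
    analyzed in full even though their response indicator still marks the
    originally missing cells.
    """
    if use_rows == "complete_persons":
        return view.has_y1.copy(), view.has_y1.copy()
    if use_rows == "observed_rows":
        keep = np.ones(view.n_persons, bool)
        return keep, view.has_y1.copy()
    raise ValueError("use_rows must be 'complete_persons' or 'observed_rows'")


def _row_weights(view: PersonView, weights) -> tuple[np.ndarray, np.ndarray]:
    """Per-person (w0, w1) row weights.  ``weights`` may be None, a scalar,
    a per-person array, or an (n, 2) array of per-row weights."""
    n = view.n_persons
    if weights is None:
        return np.ones(n), np.ones(n)
    w = np.asarray(weights, float)
    if w.ndim == 0:
        w = np.full(n, float(w))
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    if w.ndim == 1:
        if w.size != n:
            raise ValueError("per-person weights must have one entry per person")
        return w.copy(), w.copy()
    if w.shape != (n, 2):
        raise ValueError("row weights must be (n_persons, 2)")
    return w[:, 0].copy(), w[:, 1].copy()


def _school_quadratics(y0, y1, m0, m1, use1, w0, w1, school, n_schools, vc):
    """Per-person quadratic coefficients of the latent school intercept v.

    For each person the (possibly weighted) conditional log-density given v
    is -(a v^2 - 2 b v + c)/2 + lognorm, with the person effect u already
    integrated out.  Returns per-school sums A, B, C, LN.
    """
    su2, sv2, se2 = vc
    s00 = su2 + se2
    rho = su2 / s00
    s_c = (s00 - su2) * (s00 + su2) / s00  # s00 - su2^2/s00, stable form

    r0 = y0 - m0
    a = w0 / s00
    b = w0 * r0 / s00
    c = w0 * r0 * r0 / s00
    ln = -0.5 * w0 * np.log(2.0 * np.pi * s00)

    if np.any(use1):
        rc = np.where(use1, (y1 - m1) - rho * r0, 0.0)
        omr = 1.0 - rho
        w1u = np.where(use1, w1, 0.0)
        a = a + w1u * omr * omr / s_c
        b = b + w1u * omr * rc / s_c
        c = c + w1u * rc * rc / s_c
        ln = ln - 0.5 * w1u * np.log(2.0 * np.pi * s_c)

    A = np.bincount(school, a, minlength=n_schools)
    B = np.bincount(school, b, minlength=n_schools)
    C = np.bincount(school, c, minlength=n_schools)
    LN = np.bincount(school, ln, minlength=n_schools)
    return A, B, C, LN


def _loglik_from_quadratics(A, B, C, LN, sv2) -> float:
    # integral of exp(-(A v^2 - 2 B v)/2) against N(0, sv2)
    t = sv2 * A
    return float(np.sum(LN - 0.5 * C - 0.5 * np.log1p(t) + 0.5 * sv2 * B * B / (1.0 + t)))


def lmm_loglik(
    params: GCMParams,
    vc: VarianceComponents,
    data: LongDataset | PersonView,
    use_rows: str = "observed_rows",
    weights=None,
) -> float:
    """(Pseudo-)log-likelihood of the growth model on the selected rows.

    With ``weights`` given, each row's conditional contribution is scaled by
    its weight (weighted pseudo-log-likelihood); all weights equal to one
    reproduce the exact marginal Gaussian log-likelihood.
    """
    view = data if isinstance(data, PersonView) else person_view(data)
    vc.validate()
    gamma = params.as_array()
    if not np.all(np.isfinite(gamma)):
        raise ValueError("fixed effects must be finite")
    keep, use1 = _select_rows(view, use_rows)
    if not np.any(keep):
        raise ValueError("row selection is empty")
    w0, w1 = _row_weights(view, weights)
    sub = keep
    school_sub, levels = _recode(view.school[sub])
    A, B, C, LN = _school_quadratics(
        view.y0[sub],
        np.where(use1[sub], view.y1[sub], 0.0),
        view.X0[sub] @ gamma,
        view.X1[sub] @ gamma,
        use1[sub],
        w0[sub],
        w1[sub],
        school_sub,
        levels.size,
        vc.as_array(),
    )
    return _loglik_from_quadratics(A, B, C, LN, vc.sigma_v2)


def _recode(codes: np.ndarray):
    levels, inv = np.unique(codes, return_inverse=True)
    return inv, levels


# --------------------------------------------------------------------------
# profiled GLS for the fixed effects
# --------------------------------------------------------------------------

def _gls_gamma(view, keep, use1, w0, w1, vcarr, X0=None, X1=None):
    """Closed-form maximizer of the (pseudo-)log-likelihood over gamma for
    fixed variance components, plus the fixed-effect information matrix."""
    su2, sv2, se2 = vcarr
    s00 = su2 + se2
    rho = su2 / s00
    s_c = (s00 - su2) * (s00 + su2) / s00

    X0 = view.X0 if X0 is None else X0
    X1 = view.X1 if X1 is None else X1
    X0s, X1s = X0[keep], X1[keep]
    y0s = view.y0[keep]
    y1s = np.where(use1[keep], view.y1[keep], 0.0)
    u1 = use1[keep]
    w0s, w1s = w0[keep], np.where(u1, w1[keep], 0.0)
    school, levels = _recode(view.school[keep])
    ns = levels.size
    p = X0s.shape[1]

    omr = 1.0 - rho
    # per-person 2x2 precision blocks (wave-ordered conditional decomposition)
    q00 = w0s / s00 + w1s * rho * rho / s_c
    q01 = -w1s * rho / s_c
    q11 = w1s / s_c
    # coupling of the school intercept: b_i = k0*r0 + k1*r1
    k0 = w0s / s00 - w1s * rho * omr / s_c
    k1 = w1s * omr / s_c

    # M = sum_i Xi' Qi Xi  -  sum_s kappa_s g_s g_s'
    M = (
        np.einsum("ni,n,nj->ij", X0s, q00, X0s)
        + np.einsum("ni,n,nj->ij", X0s, q01, X1s)
        + np.einsum("ni,n,nj->ij", X1s, q01, X0s)
        + np.einsum("ni,n,nj->ij", X1s, q11, X1s)
    )
    h = X0s.T @ (q00 * y0s + q01 * y1s) + X1s.T @ (q01 * y0s + q11 * y1s)

    A = np.bincount(school, w0s / s00 + w1s * omr * omr / s_c, minlength=ns)
    kappa = sv2 / (1.0 + sv2 * A)
    kx = k0[:, None] * X0s + k1[:, None] * X1s
    g = np.zeros((ns, p))
    np.add.at(g, school, kx)
    d = np.bincount(school, k0 * y0s + k1 * y1s, minlength=ns)
    M = M - np.einsum("s,si,sj->ij", kappa, g, g)
    h = h - g.T @ (kappa * d)

    gamma = np.linalg.solve(M, h)
    return gamma, M


def fit_lmm(
    data: LongDataset | PersonView,
    use_rows: str = "observed_rows",
    weights=None,
    start: VarianceComponents | None = None,
    method: str | None = None,
    school_effect: bool = True,
    person_effect: bool = True,
    design: tuple | None = None,
    maxiter: int = 500,
) -> FitResult:
    """Maximum-(pseudo-)likelihood fit of the growth model.

    The fixed effects are profiled out in closed form; the variance
    components are optimized on the log-sd scale by quasi-Newton iteration.
    ``use_rows='complete_persons'`` is listwise deletion, ``'observed_rows'``
    is observed-data ML, and supplying ``weights`` gives the weighted
    pseudo-likelihood fit.  ``design`` may override the fixed-effect design
    as ``(terms, X0, X1)`` built on the same person order.
    """
    view = data if isinstance(data, PersonView) else person_view(data)
    keep, use1 = _select_rows(view, use_rows)
    if not np.any(keep):
        raise ValueError("row selection is empty")
    w0, w1 = _row_weights(view, weights)

    if design is not None:
        terms, X0, X1 = design
    else:
        terms, X0, X1 = view.terms, view.X0, view.X1
    _check_rank(X0, X1, keep, use1, terms)

    n_obs = int(keep.sum() + (use1 & keep).sum())
    schools_used = np.unique(view.school[keep])

    if start is None:
        start = _moment_start(view, keep, use1)
    free = [2]
    if person_effect:
        free.insert(0, 0)
    if school_effect:
        free.insert(-1, 1)
    free = sorted(free)
    x0 = np.log(np.sqrt(np.maximum(start.as_array()[free], 1e-4)))

    def unpack(x):
        v = np.zeros(3)
        v[free] = np.exp(2.0 * np.clip(x, _LOG_SD_FLOOR, 6.0))
        return v

    def nll(x):
        vcarr = unpack(x)
        gamma, _ = _gls_gamma(view, keep, use1, w0, w1, vcarr, X0, X1)
        school_sub, levels = _recode(view.school[keep])
        Aq, Bq, Cq, LNq = _school_quadratics(
            view.y0[keep],
            np.where(use1[keep], view.y1[keep], 0.0),
            X0[keep] @ gamma,
            X1[keep] @ gamma,
            use1[keep],
            w0[keep],
            w1[keep],
            school_sub,
            levels.size,
            vcarr,
        )
        return -_loglik_from_quadratics(Aq, Bq, Cq, LNq, vcarr[1])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(_LOG_SD_FLOOR, 6.0)] * len(free),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
        )
    vcarr = unpack(res.x)
    gamma, M = _gls_gamma(view, keep, use1, w0, w1, vcarr, X0, X1)
    loglik = -nll(res.x)

    cov_fixed = np.linalg.inv(M)
    se_fixed = np.sqrt(np.diag(cov_fixed))
    boundary = bool(np.any(res.x <= _LOG_SD_FLOOR + 1e-6))

    # variance-component SEs from the numerical Hessian on the log-sd scale
    se_vc = _vc_se(nll, res.x, unpack, free)

    fixed_effects = dict(zip(terms, gamma))
    params = GCMParams.from_array(
        [fixed_effects.get(t, np.nan) for t in ANALYSIS_TERMS]
    )
    vc = VarianceComponents(*vcarr)
    se = dict(zip(terms, se_fixed))
    se.update(zip(VC_NAMES, se_vc))
    ci95 = {t: (e - 1.96 * s, e + 1.96 * s) for t, e, s in zip(terms, gamma, se_fixed)}
    for name, e, s in zip(VC_NAMES, vcarr, se_vc):
        ci95[name] = (e - 1.96 * s, e + 1.96 * s)

    return FitResult(
        params=params,
        vc=vc,
        se=se,
        ci95=ci95,
        loglik=loglik,
        n_obs=n_obs,
        n_persons=int(keep.sum()),
        n_schools=int(schools_used.size),
        method=method or use_rows,
        converged=bool(res.success),
        diagnostics={
            "n_iter": int(res.nit),
            "optimizer_message": str(res.message),
            "boundary": boundary,
            "weighted": weights is not None,
        },
        vcov_fixed=cov_fixed,
        terms=tuple(terms),
        fixed_effects=fixed_effects,
    )


def _check_rank(X0, X1, keep, use1, terms):
    rows = [X0[keep]]
    if np.any(use1 & keep):
        rows.append(X1[use1 & keep])
    X = np.vstack(rows)
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name an offending column for the error message
        for j in range(X.shape[1]):
            others = np.delete(np.arange(X.shape[1]), j)
            if np.linalg.matrix_rank(X[:, others]) == r:
                raise ValueError(f"design matrix is rank deficient (column '{terms[j]}')")
        raise ValueError("design matrix is rank deficient")


def _moment_start(view, keep, use1) -> VarianceComponents:
    """Crude moment-based starting values for the variance components."""
    both = keep & use1
    y0 = view.y0[keep]
    tot = float(np.var(y0)) if y0.size > 1 else 1.0
    if np.any(both):
        d = view.y1[both] - view.y0[both]
        se2 = max(float(np.var(d)) / 2.0, 1e-3)
    else:
        se2 = tot / 3.0
    means = {}
    sch = view.school[keep]
    grand = y0.mean()
    df = np.bincount(sch)
    sm = np.bincount(sch, y0)
    with np.errstate(invalid="ignore"):
        smean = sm / np.maximum(df, 1)
    sv2 = max(float(np.var(smean[df > 0] - grand)) - se2 / max(df.mean(), 1.0), 1e-3)
    su2 = max(tot - sv2 - se2, 1e-3)
    return VarianceComponents(su2, sv2, se2)


def _vc_se(nll, xopt, unpack, free):
    """Delta-method SEs of the variance components from the numerical
    Hessian of the profile likelihood on the log-sd scale."""
    k = len(xopt)
    h = 1e-4
    H = np.zeros((k, k))
    f0 = nll(xopt)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            if i == j:
                H[i, i] = (nll(xopt + ei) - 2 * f0 + nll(xopt - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    nll(xopt + ei + ej)
                    - nll(xopt + ei - ej)
                    - nll(xopt - ei + ej)
                    + nll(xopt - ei - ej)
                ) / (4 * h**2)
    se_vc = np.full(3, np.nan)
    try:
        cov_x = np.linalg.inv(H)
        d = np.sqrt(np.maximum(np.diag(cov_x), 0.0))
        vcarr = unpack(xopt)
        for pos, idx in enumerate(free):
            # var = exp(2*x): d var/dx = 2 var
            se_vc[idx] = 2.0 * vcarr[idx] * d[pos]
    except np.linalg.LinAlgError:
        pass
    for i in range(3):
        if i not in free:
            se_vc[i] = 0.0
    return se_vc


def dense_gaussian_loglik(
    params: GCMParams, vc: VarianceComponents, data: LongDataset | PersonView,
    use_rows: str = "observed_rows",
) -> float:
    """Brute-force oracle: assemble the full dense covariance over all
    selected rows and evaluate the joint multivariate-normal density.
    Only sensible on tiny datasets; used to validate the block kernel."""
    from scipy.stats import multivariate_normal

    view = data if isinstance(data, PersonView) else person_view(data)
    keep, use1 = _select_rows(view, use_rows)
    gamma = params.as_array()
    ys, mus, pid, sid = [], [], [], []
    for i in range(view.n_persons):
        if not keep[i]:
            continue
        ys.append(view.y0[i])
        mus.append(view.X0[i] @ gamma)
        pid.append(i)
        sid.append(view.school[i])
        if use1[i]:
            ys.append(view.y1[i])
            mus.append(view.X1[i] @ gamma)
            pid.append(i)
            sid.append(view.school[i])
    y = np.array(ys)
    mu = np.array(mus)
    pid = np.array(pid)
    sid = np.array(sid)
    n = y.size
    cov = (
        vc.sigma_e2 * np.eye(n)
        + vc.sigma_u2 * (pid[:, None] == pid[None, :])
        + vc.sigma_v2 * (sid[:, None] == sid[None, :])
    )
    return float(multivariate_normal.logpdf(y, mean=mu, cov=cov))
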