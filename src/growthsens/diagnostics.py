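"""Pre-analysis selectivity machinery.

Little's MCAR test (EM-estimated mean/covariance, pattern-wise chi-square),
the mixed-effects dropout logit (school random intercept integrated by
adaptive Gauss-Hermite quadrature), and inverse probability weights derived
from a single-level response logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import chi2, norm

from .data import LongDataset


@dataclass
class McarTestResult:
    statistic: float
    df: int
    p_value: float
    n_patterns: int

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclass
class SelectivityResult:
    """Dropout-model estimates (dropout coded 1, logit link)."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    ci95: np.ndarray  # (k, 2)
    re_sd: float | None
    re_sd_ci95: tuple | None
    fitted_prob: pd.Series  # P(dropout) per person_id
    loglik: float
    converged: bool
    boundary: bool = False
    link: str = "logit"

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"term": self.names, "estimate": self.coef, "se": self.se,
             "ci_lo": self.ci95[:, 0], "ci_hi": self.ci95[:, 1]}
        )
        if self.re_sd is not None:
            out.loc[len(out)] = ["random_effect_sd", self.re_sd, np.nan,
                                 self.re_sd_ci95[0], self.re_sd_ci95[1]]
        return out


# --------------------------------------------------------------------------
# Little's MCAR test
# --------------------------------------------------------------------------

def _em_normal(Y: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """EM estimates (ML) of mean and covariance of a multivariate normal
    with values missing in arbitrary patterns."""
    n, p = Y.shape
    miss = np.isnan(Y)
    mu = np.nanmean(Y, axis=0)
    Yf = np.where(miss, mu, Y)
    Sigma = np.cov(Yf, rowvar=False, bias=True) + 1e-8 * np.eye(p)

    pat_ids, pat_inv = np.unique(miss, axis=0, return_inverse=True)
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for j, pat in enumerate(pat_ids):
            rows = Y[pat_inv == j]
            obs = ~pat
            m = pat
            nj = rows.shape[0]
            yo = rows[:, obs]
            if m.any():
                Soo = Sigma[np.ix_(obs, obs)]
                B = np.linalg.solve(Soo, Sigma[np.ix_(obs, m)]).T
                ym = mu[m] + (yo - mu[obs]) @ B.T
                Cm = Sigma[np.ix_(m, m)] - B @ Sigma[np.ix_(obs, m)]
                full = np.empty((nj, p))
                full[:, obs] = yo
                full[:, m] = ym
                T2m = full.T @ full
                T2m[np.ix_(m, m)] += nj * Cm
            else:
                full = yo
                T2m = np.zeros((p, p))
                T2m[np.ix_(obs, obs)] = yo.T @ yo
                fullp = np.empty((nj, p))
                fullp[:, obs] = yo
                full = fullp
            T1 += full.sum(axis=0)
            T2 += T2m
        mu_new = T1 / n
        Sigma_new = T2 / n - np.outer(mu_new, mu_new)
        delta = max(np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max())
        mu, Sigma = mu_new, Sigma_new
        if delta < tol:
            break
    return mu, Sigma


def little_mcar_test(wide_data: pd.DataFrame) -> McarTestResult:
    """Little's chi-square test of the MCAR hypothesis.

    ``wide_data``: one row per person, numeric columns with NaN for missing
    entries.  The statistic sums, over missingness patterns j,
    n_j (ybar_j - mu_obs,j)' Sigma_obs,j^-1 (ybar_j - mu_obs,j) with (mu,
    Sigma) the EM (ML) estimates; the reference is chi-square with
    sum_j k_j - k degrees of freedom.
    """
    Y = wide_data.to_numpy(float)
    Y = Y[~np.all(np.isnan(Y), axis=1)]
    n, p = Y.shape
    if p < 2:
        raise ValueError("Little's test needs at least 2 variables")
    miss = np.isnan(Y)
    pat_ids, pat_inv = np.unique(miss, axis=0, return_inverse=True)
    if pat_ids.shape[0] < 2:
        raise ValueError("test undefined: only a single missingness pattern present")
    mu, Sigma = _em_normal(Y)
    d2 = 0.0
    df = -p
    for j, pat in enumerate(pat_ids):
        rows = Y[pat_inv == j]
        obs = ~pat
        k = int(obs.sum())
        if k == 0:
            continue
        df += k
        ybar = rows[:, obs].mean(axis=0)
        diff = ybar - mu[obs]
        Soo = Sigma[np.ix_(obs, obs)]
        d2 += rows.shape[0] * float(diff @ np.linalg.solve(Soo, diff))
    return McarTestResult(
        statistic=float(d2), df=int(df), p_value=float(chi2.sf(d2, df)),
        n_patterns=int(pat_ids.shape[0]),
    )


# --------------------------------------------------------------------------
# dropout GLMM
# --------------------------------------------------------------------------

def build_selection_design(
    data: LongDataset, selection_covariates: list[str]
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    """Person-level dropout indicator and design for the selection model.

    Special covariate names ``outcome_w0`` and ``outcome_w0_sq`` map to the
    wave-0 outcome and its square; all other names are covariate columns.
    """
    person = data.person_table()
    d = 1 - person["responded"].to_numpy(int)  # 1 = dropout
    cols = [np.ones(len(person))]
    names = ["intercept"]
    for name in selection_covariates:
        if name == "outcome_w0":
            x = person["y0"].to_numpy(float)
        elif name == "outcome_w0_sq":
            x = person["y0"].to_numpy(float) ** 2
        elif name in person.columns:
            x = person[name].to_numpy(float)
        else:
            raise ValueError(f"selection covariate '{name}' not found in the data")
        cols.append(x)
        names.append(name)
    X = np.column_stack(cols)
    return person, d, X, names


def _check_separation(d: np.ndarray, X: np.ndarray, names: list[str]) -> None:
    if d.min() == d.max():
        raise ValueError("selection model undefined: dropout indicator is constant "
                         f"(all {'dropout' if d[0] else 'respondents'})")
    for j in range(1, X.shape[1]):
        x = X[:, j]
        vals = np.unique(x)
        if vals.size == 2:
            m1, m0 = d[x == vals[1]], d[x == vals[0]]
            if (m1.min() == m1.max()) and (m0.min() == m0.max()) and m1[0] != m0[0]:
                raise ValueError(f"complete separation: covariate '{names[j]}' perfectly predicts dropout")


def _logit_irls(d, X, max_iter=100, tol=1e-10):
    """Plain logistic ML by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        W = p * (1 - p)
        W = np.maximum(W, 1e-10)
        z = eta + (d - p) / W
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    p = special.expit(X @ beta)
    ll = float(np.sum(d * np.log(p) + (1 - d) * np.log1p(-p)))
    cov = np.linalg.inv((X.T * np.maximum(p * (1 - p), 1e-10)) @ X)
    return beta, cov, ll


def _glmm_school_loglik(d, X, school, n_schools, beta, log_sd, nodes, weights_gh):
    """Log-likelihood of the logit GLMM, school intercepts integrated by
    adaptive (mode/curvature-rescaled) Gauss-Hermite quadrature."""
    sd = np.exp(log_sd)
    eta0 = X @ beta
    # per-school Newton iterations for the integrand mode (vectorized)
    v = np.zeros(n_schools)
    for _ in range(50):
        p = special.expit(eta0 + v[school])
        g = np.bincount(school, d - p, minlength=n_schools) - v / sd**2
        h = -np.bincount(school, p * (1 - p), minlength=n_schools) - 1.0 / sd**2
        step = g / h
        v_new = v - step
        if np.max(np.abs(step)) < 1e-9:
            v = v_new
            break
        v = v_new
    tau = 1.0 / np.sqrt(-h)

    def h_fun(vv):
        eta = eta0 + vv[school]
        ll = d * eta - np.log1p(np.exp(eta))
        return (
            np.bincount(school, ll, minlength=n_schools)
            - 0.5 * vv**2 / sd**2
            - 0.5 * np.log(2 * np.pi * sd**2)
        )

    K = nodes.size
    vals = np.empty((n_schools, K))
    for k in range(K):
        vk = v + np.sqrt(2.0) * tau * nodes[k]
        vals[:, k] = h_fun(vk) + nodes[k] ** 2 + np.log(weights_gh[k])
    m = vals.max(axis=1)
    ls = m + np.log(np.sum(np.exp(vals - m[:, None]), axis=1))
    return float(np.sum(ls + np.log(np.sqrt(2.0) * tau))), v, tau


def fit_dropout_glmm(
    data: LongDataset,
    selection_covariates: list[str],
    school_random_intercept: bool = True,
    quad_nodes: int = 15,
) -> SelectivityResult:
    """Logit regression of dropout (1 = dropout) on the selection
    covariates, optionally with a school random intercept (adaptive
    Gauss-Hermite ML)."""
    person, d, X, names = build_selection_design(data, selection_covariates)
    _check_separation(d, X, names)

    if not school_random_intercept:
        beta, cov, ll = _logit_irls(d, X)
        if np.max(np.abs(beta)) > 30:
            j = int(np.argmax(np.abs(beta)))
            raise ValueError(f"complete separation suspected: covariate '{names[j]}' diverges")
        se = np.sqrt(np.diag(cov))
        ci = np.column_stack([beta - 1.96 * se, beta + 1.96 * se])
        fitted = pd.Series(special.expit(X @ beta), index=person["person_id"].to_numpy())
        return SelectivityResult(names, beta, se, ci, None, None, fitted, ll, True)

    schools, school = np.unique(person["school_id"].to_numpy(), return_inverse=True)
    ns = schools.size
    gh_nodes, gh_w = np.polynomial.hermite.hermgauss(quad_nodes)
    beta0, _, _ = _logit_irls(d, X)
    x0 = np.concatenate([beta0, [0.0]])  # log sd start at sd=1

    def nll(x):
        ll, _, _ = _glmm_school_loglik(d, X, school, ns, x[:-1], x[-1], gh_nodes, gh_w)
        return -ll

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(None, None)] * X.shape[1] + [(-6.0, 4.0)],
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6},
        )
    beta = res.x[:-1]
    log_sd = res.x[-1]
    if np.max(np.abs(beta)) > 30:
        j = int(np.argmax(np.abs(beta)))
        raise ValueError(f"complete separation suspected: covariate '{names[j]}' diverges")
    boundary = bool(log_sd <= -6.0 + 1e-6)

    H = _numerical_hessian(nll, res.x)
    k = X.shape[1]
    se = np.full(k, np.nan)
    sd_ci = (np.nan, np.nan)
    try:
        cov = np.linalg.inv(H)
        dg = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se = dg[:k]
        sd_hat = float(np.exp(log_sd))
        sd_ci = (sd_hat * np.exp(-1.96 * dg[k]), sd_hat * np.exp(1.96 * dg[k]))
    except np.linalg.LinAlgError:
        pass
    ci = np.column_stack([beta - 1.96 * se, beta + 1.96 * se])
    # fitted marginal dropout probabilities at the empirical Bayes school mode
    _, vhat, _ = _glmm_school_loglik(d, X, school, ns, beta, log_sd, gh_nodes, gh_w)
    fitted = pd.Series(
        special.expit(X @ beta + vhat[school]), index=person["person_id"].to_numpy()
    )
    return SelectivityResult(
        names, beta, se, ci, float(np.exp(log_sd)), sd_ci, fitted,
        -float(res.fun), bool(res.success), boundary,
    )


def _numerical_hessian(f, x, h=1e-4):
    k = x.size
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


# --------------------------------------------------------------------------
# inverse probability weights
# --------------------------------------------------------------------------

@dataclass
class WeightResult:
    person: pd.DataFrame  # person_id, p_respond, weight
    n_floored: int
    normalized: bool

    def row_weights(self, data: LongDataset) -> np.ndarray:
        """Per-row weights aligned to the long frame: a respondent's weight
        on both rows, 1 on nonrespondents' rows."""
        m = self.person.set_index("person_id")["weight"]
        w = data.frame["person_id"].map(m).to_numpy(float)
        return np.where(np.isnan(w), 1.0, w)

    def person_weights(self, person_ids: np.ndarray) -> np.ndarray:
        m = self.person.set_index("person_id")["weight"]
        w = pd.Series(person_ids).map(m).to_numpy(float)
        return np.where(np.isnan(w), 1.0, w)


def compute_ip_weights(
    data: LongDataset,
    selection_covariates: list[str],
    normalize: bool = True,
    truncate_quantile: float | None = None,
    prob_floor: float = 1e-3,
) -> WeightResult:
    """Inverse probability weights from a single-level response logit.

    The response model deliberately ignores the multilevel structure (plain
    logit of response = 1 - dropout).  Respondents receive 1/P(respond) on
    both of their rows; nonrespondents' rows keep weight 1.  Optionally the
    respondent weights are truncated at an upper quantile and normalized to
    mean 1.
    """
    person, d, X, names = build_selection_design(data, selection_covariates)
    if d.sum() == 0:  # full response: every weight is exactly 1
        out = pd.DataFrame(
            {"person_id": person["person_id"], "responded": 1,
             "p_respond": 1.0, "weight": 1.0}
        )
        return WeightResult(person=out, n_floored=0, normalized=normalize)
    _check_separation(d, X, names)
    r = 1 - d
    beta, _, _ = _logit_irls(r, X)
    p = special.expit(X @ beta)
    n_floored = int(np.sum(p[r == 1] < prob_floor))
    if n_floored:
        warnings.warn(
            f"{n_floored} fitted response probabilities below {prob_floor}; truncated",
            RuntimeWarning,
        )
    p = np.maximum(p, prob_floor)
    w = np.where(r == 1, 1.0 / p, 1.0)
    if truncate_quantile is not None:
        cap = np.quantile(w[r == 1], truncate_quantile)
        w = np.where(r == 1, np.minimum(w, cap), w)
    if normalize and np.any(r == 1):
        w = np.where(r == 1, w / np.mean(w[r == 1]), w)
    out = pd.DataFrame(
        {"person_id": person["person_id"], "responded": r, "p_respond": p, "weight": w}
    )
    return WeightResult(person=out, n_floored=n_floored, normalized=normalize)
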