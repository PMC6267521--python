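"""Two-level chained-equations multiple imputation and Rubin pooling.

The imputation model for the wave-2 outcome is a linear mixed model with a
person-level random intercept only — variation between schools is
deliberately ignored in the imputation step (the school level explains less
variance than the person level); the school effect is restored in the
analysis model fitted to each completed dataset.  Imputations are proper:
imputation-model parameters are drawn from their approximate posterior
before each predictive draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .data import LongDataset, person_view
from .gcm import FitResult, GCMParams, VarianceComponents, fit_lmm

#: auxiliary covariates used by default: the selectivity-analysis variables
DEFAULT_AUXILIARIES = (
    "sex", "migration", "age", "mode_home",
    "school_basic", "school_intermediate", "school_other",
)


@dataclass
class ImputationConfig:
    m: int = 20
    auxiliaries: tuple = DEFAULT_AUXILIARIES
    n_cycles: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("number of imputations m must be >= 2")


@dataclass
class PooledResult:
    """Rubin-combined estimates across imputations."""

    names: list
    qbar: np.ndarray
    wbar: np.ndarray   # within-imputation variance
    b: np.ndarray      # between-imputation variance
    t: np.ndarray      # total variance
    df: np.ndarray
    m: int
    method: str = "MI"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.t)

    def ci95(self) -> np.ndarray:
        q = t_dist.ppf(0.975, np.minimum(self.df, 1e12))
        return np.column_stack([self.qbar - q * self.se, self.qbar + q * self.se])

    def table(self) -> pd.DataFrame:
        ci = self.ci95()
        return pd.DataFrame(
            {"term": self.names, "estimate": self.qbar, "se": self.se,
             "ci_lo": ci[:, 0], "ci_hi": ci[:, 1], "df": self.df}
        )


def _imputation_design(view, aux_cols):
    """Analysis design plus auxiliary main effects (same row order)."""
    terms = list(view.terms) + list(aux_cols)
    A = view.covariates[list(aux_cols)].to_numpy(float) if aux_cols else np.empty((view.n_persons, 0))
    X0 = np.column_stack([view.X0, A])
    X1 = np.column_stack([view.X1, A])
    return tuple(terms), X0, X1


def impute_chained(data: LongDataset, config: ImputationConfig) -> list[LongDataset]:
    """Draw ``m`` completed datasets.

    Only the wave-1 outcome may be missing.  Each imputation draws the
    imputation-model parameters from their asymptotic posterior, then each
    nonrespondent's person intercept from its conditional posterior given the
    wave-0 outcome, then the missing outcome from the predictive normal.
    Chained iteration reduces to a single pass because exactly one variable
    is incomplete; the cycle loop is retained for generality but converges
    after the first pass.
    """
    config.validate()
    df = data.frame
    w0 = df[df["wave"] == 0]
    if w0["outcome"].isna().any():
        raise ValueError("impute_chained expects complete wave-0 outcomes")
    # analysis-model covariates already sit in the design; auxiliaries add to it
    aux = [c for c in config.auxiliaries if c in df.columns and c not in ("reas", "sc")]
    missing_aux = [c for c in aux if df[c].isna().any()]
    if missing_aux:
        raise ValueError(f"auxiliary covariates contain missing values: {missing_aux}")

    view = person_view(data)
    n_missing = int((~view.resp).sum())
    if n_missing == 0:
        return [data.copy() for _ in range(config.m)]

    design = _imputation_design(view, aux)
    # person-level model: school variance deliberately omitted
    base = fit_lmm(view, use_rows="observed_rows", school_effect=False,
                   design=design, method="imputation-model")
    beta_hat = _full_beta(base, design[0])
    Vbeta = base.vcov_fixed
    su2, se2 = base.vc.sigma_u2, base.vc.sigma_e2
    # posterior of the variance parameters on the log-sd scale
    sd_logsd = np.array([
        _safe_logsd_se(base.se["sigma_u2"], su2),
        _safe_logsd_se(base.se["sigma_e2"], se2),
    ])

    rng = np.random.default_rng(config.seed)
    mis = ~view.resp
    terms, X0, X1 = design
    chol = np.linalg.cholesky(0.5 * (Vbeta + Vbeta.T) + 1e-12 * np.eye(Vbeta.shape[0]))

    completed = []
    for _ in range(config.m):
        for _cycle in range(max(config.n_cycles, 1)):
            beta = beta_hat + chol @ rng.standard_normal(beta_hat.size)
            lsu = 0.5 * np.log(su2) + sd_logsd[0] * rng.standard_normal()
            lse = 0.5 * np.log(se2) + sd_logsd[1] * rng.standard_normal()
            su2_s, se2_s = np.exp(2 * lsu), np.exp(2 * lse)
            # nonrespondents: u | y0 ~ N(k*(y0 - x0'b), k*se2), k = su2/(su2+se2)
            r0 = view.y0[mis] - X0[mis] @ beta
            k = su2_s / (su2_s + se2_s)
            u = k * r0 + np.sqrt(k * se2_s) * rng.standard_normal(n_missing)
            y1 = X1[mis] @ beta + u + np.sqrt(se2_s) * rng.standard_normal(n_missing)
            # single incomplete variable: successive cycles are independent
            # redraws of the same predictive; keep the last
        comp = data.copy()
        cdf = comp.frame
        mmap = pd.Series(y1, index=view.person_id[mis])
        rows = (cdf["wave"] == 1) & cdf["person_id"].isin(set(view.person_id[mis]))
        cdf.loc[rows, "outcome"] = cdf.loc[rows, "person_id"].map(mmap).to_numpy()
        comp.meta["imputed"] = True
        completed.append(comp)
    return completed


def _full_beta(fit: FitResult, terms) -> np.ndarray:
    est = fit.estimates()
    return np.array([est[t] for t in terms])


def _safe_logsd_se(se_var, var):
    # se on log-sd scale from se on variance scale: d logsd = d var/(2 var)
    if not np.isfinite(se_var) or var <= 0:
        return 0.05
    return float(se_var / (2.0 * var))


def fit_mi(
    data: LongDataset,
    config: ImputationConfig,
    use_rows: str = "observed_rows",
) -> tuple[PooledResult, list[FitResult]]:
    """Impute, fit the full nested analysis model per completed dataset,
    and pool by Rubin's rules."""
    completed = impute_chained(data, config)
    fits = [fit_lmm(c, use_rows=use_rows, method="mi") for c in completed]
    return pool_rubin(fits), fits


def pool_rubin(fits: list[FitResult], m: int | None = None) -> PooledResult:
    """Rubin's combination rules over per-imputation fits.

    Qbar is the mean estimate, Wbar the mean squared SE, B the between
    variance, T = Wbar + (1 + 1/m) B; df by the standard small-sample
    formula (m-1)(1 + Wbar/((1+1/m)B))^2.
    """
    if m is None:
        m = len(fits)
    if m < 2 or len(fits) != m:
        raise ValueError("pooling requires m >= 2 fits")
    names = [n for n in fits[0].estimates() if n in fits[0].se]
    for f in fits[1:]:
        if [n for n in f.estimates() if n in f.se] != names:
            raise ValueError("mismatched parameter names across fits")
    est = np.array([[f.estimates()[t] for t in names] for f in fits])
    ses = np.array([[f.se[t] for t in names] for f in fits])
    qbar = est.mean(axis=0)
    wbar = np.mean(ses**2, axis=0)
    b = est.var(axis=0, ddof=1)
    t = wbar + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore"):
        df = (m - 1) * (1.0 + wbar / ((1.0 + 1.0 / m) * b)) ** 2
    df = np.where(b > 0, df, np.inf)
    return PooledResult(names=names, qbar=qbar, wbar=wbar, b=b, t=t, df=df, m=m)
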