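"""Orchestrate the sensitivity analysis across missing-data methods.

Runs the selectivity diagnostics (MCAR test, dropout model), derives
inverse-probability weights and auxiliary sets from the configured selection
variables, fits the growth model under each requested scheme (LWD, FIML, MI,
WE, DK, WC, PM), and collates one comparative coefficient table — the
tabular counterpart of a coefficient plot across methods — plus a
per-parameter robustness verdict.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ANALYSIS_TERMS, LongDataset, person_view
from .diagnostics import compute_ip_weights, fit_dropout_glmm, little_mcar_test
from .gcm import VC_NAMES, fit_lmm
from .imputation import DEFAULT_AUXILIARIES, ImputationConfig, fit_mi
from .mnar import fit_diggle_kenward, fit_pattern_mixture, fit_wu_carroll

ALL_METHODS = ("lwd", "fiml", "mi", "we", "dk", "wc", "pm")

DEFAULT_SELECTION_VARIABLES = (
    "reas", "sc", "sex", "migration", "age", "mode_home",
    "school_basic", "school_intermediate", "school_other",
    "outcome_w0", "outcome_w0_sq",
)


@dataclass
class SensitivityConfig:
    methods: tuple = ALL_METHODS
    selection_variables: tuple = DEFAULT_SELECTION_VARIABLES
    m_imputations: int = 20
    quad_nodes: int = 15
    pm_restriction: str = "none"
    #: covariates entering the DK/WC selection equations; None = all
    #: non-outcome selection variables
    mnar_selection_covariates: tuple | None = None
    normalize_weights: bool = True
    dropout_glmm_random_intercept: bool = True
    seed: int = 0

    def child_seed(self, label: str) -> int:
        h = int(hashlib.sha256(f"{self.seed}:{label}".encode()).hexdigest()[:8], 16)
        return h % (2**31 - 1)


@dataclass
class SensitivityReport:
    """Long method x parameter table plus diagnostics and metadata."""

    table: pd.DataFrame
    robustness: pd.DataFrame
    mcar_test: object
    selectivity: object
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, na_rep="NA")


def _rows_from_estimates(method, estimates, se, ci95, converged):
    rows = []
    for term in list(ANALYSIS_TERMS) + list(VC_NAMES):
        if term in estimates and np.isfinite(estimates[term]):
            s = se.get(term, np.nan)
            lo, hi = ci95.get(term, (np.nan, np.nan))
            rows.append((method, term, estimates[term], s, lo, hi, converged))
        else:
            rows.append((method, term, np.nan, np.nan, np.nan, np.nan, converged))
    return rows


def run_sensitivity(
    data: LongDataset,
    config: SensitivityConfig | None = None,
) -> SensitivityReport:
    """Fit every requested missing-data scheme on one dataset.

    A method that fails is recorded with ``converged=False`` and NA
    estimates instead of aborting the run.  For the pattern mixture the
    completer-class (pm1) and dropout-class (pm0) coefficient sets are
    reported as separate methods, mirroring the per-class panels of a
    coefficient plot; entries that the identification restriction leaves
    inestimable are explicit NAs.
    """
    config = config or SensitivityConfig()
    if not config.methods:
        raise ValueError("at least one method is required")
    data.validate()
    view = person_view(data)
    any_dropout = bool((~view.resp).any())

    # ---- diagnostics first
    person = data.person_table()
    mcar = None
    selectivity = None
    weights_res = None
    if any_dropout:
        wide = person[["y0", "y1"]].join(
            person[[c for c in ("reas", "sc") if c in person.columns]]
        )
        try:
            mcar = little_mcar_test(wide)
        except ValueError:
            mcar = None
        sel_vars = [
            v for v in config.selection_variables
            if v in person.columns or v in ("outcome_w0", "outcome_w0_sq")
        ]
        try:
            selectivity = fit_dropout_glmm(
                data, sel_vars,
                school_random_intercept=config.dropout_glmm_random_intercept,
                quad_nodes=config.quad_nodes,
            )
        except ValueError:
            selectivity = None
        weights_res = compute_ip_weights(
            data, sel_vars, normalize=config.normalize_weights
        )

    aux = tuple(
        v for v in config.selection_variables
        if v not in ("outcome_w0", "outcome_w0_sq", "reas", "sc") and v in person.columns
    )

    rows = []
    failures = {}

    def run(method, fn):
        try:
            fn()
        except Exception as exc:  # a failed method must not abort the report
            failures[method] = str(exc)
            rows.extend(_rows_from_estimates(method, {}, {}, {}, False))

    for method in config.methods:
        if method == "lwd":
            run("lwd", lambda: rows.extend(_fit_simple(view, "complete_persons", "lwd")))
        elif method == "fiml":
            run("fiml", lambda: rows.extend(_fit_simple(view, "observed_rows", "fiml")))
        elif method == "we":
            def _we():
                if weights_res is None:
                    rows.extend(_fit_simple(view, "complete_persons", "we"))
                    return
                w = weights_res.person_weights(view.person_id)
                fit = fit_lmm(view, use_rows="complete_persons", weights=w, method="we")
                rows.extend(_rows_from_estimates("we", fit.estimates(), fit.se, fit.ci95, fit.converged))
            run("we", _we)
        elif method == "mi":
            def _mi():
                icfg = ImputationConfig(
                    m=config.m_imputations,
                    auxiliaries=aux or DEFAULT_AUXILIARIES,
                    seed=config.child_seed("mi"),
                )
                pooled, _ = fit_mi(data, icfg)
                est = dict(zip(pooled.names, pooled.qbar))
                se = dict(zip(pooled.names, pooled.se))
                ci = pooled.ci95()
                ci95 = {n: (ci[i, 0], ci[i, 1]) for i, n in enumerate(pooled.names)}
                rows.extend(_rows_from_estimates("mi", est, se, ci95, True))
            run("mi", _mi)
        elif method == "dk":
            def _dk():
                # identified selection variables enter the dropout equation
                # alongside the past/current outcome
                sel = aux if config.mnar_selection_covariates is None else tuple(
                    config.mnar_selection_covariates
                )
                fit = fit_diggle_kenward(
                    view, selection_covariates=list(sel), quad_nodes=config.quad_nodes
                )
                rows.extend(_rows_from_estimates("dk", fit.estimates(), fit.se, fit.ci95, fit.converged))
            run("dk", _dk)
        elif method == "wc":
            def _wc():
                sel = aux if config.mnar_selection_covariates is None else tuple(
                    config.mnar_selection_covariates
                )
                fit = fit_wu_carroll(
                    view, selection_covariates=list(sel), quad_nodes=config.quad_nodes
                )
                rows.extend(_rows_from_estimates("wc", fit.estimates(), fit.se, fit.ci95, fit.converged))
            run("wc", _wc)
        elif method == "pm":
            def _pm():
                res = fit_pattern_mixture(view, restriction=config.pm_restriction)
                for cls in ("pm1", "pm0"):
                    sub = res.class_params[res.class_params["class"] == cls]
                    est = dict(zip(sub["term"], sub["estimate"]))
                    se = dict(zip(sub["term"], sub["se"]))
                    ci = {t: (lo, hi) for t, lo, hi in zip(sub["term"], sub["ci_lo"], sub["ci_hi"])}
                    est.update(zip(VC_NAMES, res.vc.as_array()))
                    rows.extend(_rows_from_estimates(cls, est, se, ci, res.converged))
            run("pm", _pm)
        else:
            raise ValueError(f"unknown method '{method}'")

    table = pd.DataFrame(
        rows, columns=["method", "parameter", "estimate", "se", "ci_lo", "ci_hi", "converged"]
    )
    robust_rows = []
    for t in ANALYSIS_TERMS:
        try:
            verdict = summarize_robustness_table(table, t)
        except ValueError:
            verdict = "not-assessable"
        robust_rows.append({"parameter": t, "verdict": verdict, **_robust_stats(table, t)})
    robustness = pd.DataFrame(robust_rows)
    meta = {
        "seed": config.seed,
        "methods": list(config.methods),
        "n_persons": int(view.n_persons),
        "n_schools": int(view.n_schools),
        "dropout_rate": data.dropout_rate(),
        "failures": failures,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: str(v) for k, v in vars(config).items()}, sort_keys=True
            ).encode()
        ).hexdigest()[:12],
    }
    return SensitivityReport(
        table=table, robustness=robustness, mcar_test=mcar,
        selectivity=selectivity, metadata=meta,
    )


def _fit_simple(view, use_rows, label):
    fit = fit_lmm(view, use_rows=use_rows, method=label)
    return _rows_from_estimates(label, fit.estimates(), fit.se, fit.ci95, fit.converged)


def _robust_stats(table, parameter):
    sub = table[(table["parameter"] == parameter) & table["estimate"].notna()]
    if sub.empty:
        return {"range": np.nan, "sign_agreement": np.nan, "ci_overlap": np.nan}
    est = sub["estimate"].to_numpy()
    lo, hi = sub["ci_lo"].to_numpy(), sub["ci_hi"].to_numpy()
    return {
        "range": float(est.max() - est.min()),
        "sign_agreement": bool(np.all(est > 0) or np.all(est < 0)),
        "ci_overlap": bool(np.nanmax(lo) <= np.nanmin(hi)),
    }


def summarize_robustness_table(table: pd.DataFrame, parameter: str) -> str:
    """Three-level robustness verdict for one parameter across methods.

    ``robust``: every method's 95% CI excludes zero with a common sign;
    ``sign-robust``: point estimates share a sign but at least one CI covers
    zero; ``non-robust`` otherwise.  (The paper argues comparatively and
    offers no quantitative criterion; this convention is the package's own.)
    """
    sub = table[(table["parameter"] == parameter) & table["estimate"].notna()]
    if sub.empty:
        raise ValueError(f"parameter '{parameter}' absent from the report")
    if len(sub) < 2:
        raise ValueError("robustness verdict needs at least 2 methods")
    est = sub["estimate"].to_numpy()
    lo = sub["ci_lo"].to_numpy()
    hi = sub["ci_hi"].to_numpy()
    same_sign = bool(np.all(est > 0) or np.all(est < 0))
    if not same_sign:
        return "non-robust"
    excl = np.where(est > 0, lo > 0, hi < 0)
    if np.all(np.nan_to_num(excl, nan=0.0)):
        return "robust"
    return "sign-robust"


def summarize_robustness(report: SensitivityReport, parameter: str) -> str:
    return summarize_robustness_table(report.table, parameter)


def plot_coefficients(report: SensitivityReport, path=None):
    """Plain coefficient plot (one panel per parameter, methods on the
    y-axis).  Convenience only; matplotlib imported lazily."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    terms = list(ANALYSIS_TERMS)
    fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharey=True)
    for ax, term in zip(axes.ravel(), terms):
        sub = report.table[report.table["parameter"] == term]
        y = np.arange(len(sub))
        ax.errorbar(
            sub["estimate"], y,
            xerr=np.vstack([sub["estimate"] - sub["ci_lo"], sub["ci_hi"] - sub["estimate"]]),
            fmt="o", capsize=3,
        )
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y, sub["method"])
        ax.set_title(term)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
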