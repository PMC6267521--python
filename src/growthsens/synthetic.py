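"""Synthetic clustered two-wave panels with configurable dropout mechanisms.

Emulates the structure of a large school-cohort competence panel: students
nested in schools, baseline covariates with realistic marginal moments and
correlations (Gaussian copula), outcomes from the linear growth model with
person/school random intercepts, and wave-2 dropout generated from MCAR,
covariate-driven (MAR) or outcome/latent-driven (MNAR) response models.

Also provides the incidental-selection demonstration (two uncorrelated
standard normals, selection on a latent propensity loading on both) together
with its closed-form truncated-normal oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import LongDataset, build_design
from .gcm import GCMParams, VarianceComponents

# ----------------------------------------------------------------- defaults
# Marginal moments of the baseline covariates (cohort descriptives):
# self-concept 2.522 (0.921), reasoning 8.654 (2.457), share of girls .497,
# migration background .256, age 14.92 (0.625), individually-tested-at-home
# share .313, school types basic .238 / intermediate .213 / other .200 with
# upper secondary as reference.
DEFAULT_COVARIATE_MEANS = {
    "sc_raw": 2.522,
    "reas_raw": 8.654,
    "sex": 0.497,
    "migration": 0.256,
    "age": 14.92,
    "mode_home": 0.313,
}
DEFAULT_COVARIATE_SDS = {"sc_raw": 0.921, "reas_raw": 2.457, "age": 0.625}
BINARY_COVARIATES = ("sex", "migration", "mode_home")
COPULA_ORDER = ("sc_raw", "reas_raw", "sex", "migration", "age", "mode_home")

# Latent-scale correlations (observed pairwise values of the cohort table;
# rows/cols in COPULA_ORDER, home-testing rows sign-flipped from the
# school-testing coding of the source table).
DEFAULT_COVARIATE_CORR = np.array(
    [
        [1.000, 0.222, -0.263, -0.037, -0.053, 0.087],
        [0.222, 1.000, -0.024, -0.144, -0.213, 0.328],
        [-0.263, -0.024, 1.000, 0.015, -0.094, 0.071],
        [-0.037, -0.144, 0.015, 1.000, 0.154, -0.097],
        [-0.053, -0.213, -0.094, 0.154, 1.000, -0.273],
        [0.087, 0.328, 0.071, -0.097, -0.273, 1.000],
    ]
)

SCHOOL_TYPE_PROBS = {"basic": 0.238, "intermediate": 0.213, "other": 0.200, "upper": 0.349}

# Default growth-model truth: intercept = cohort wave-0 mean; time effect in
# the middle of the plausible .53-.78 range; reasoning/self-concept main
# effects solved so that corr(REAS, Y0)=.494 and corr(SC, Y0)=.347 under the
# unit-total variance components below; small negative reasoning x time and
# near-zero self-concept x time moderation.
DEFAULT_GCM_PARAMS = GCMParams(0.037, 0.65, 0.525, 0.299, -0.10, 0.02)
# Person/school/residual variances reproducing the target intraclass
# correlations: within-person share (u+v) = .63, school share v = .31.
DEFAULT_VARIANCE_COMPONENTS = VarianceComponents(0.32, 0.31, 0.37)

# Dropout-logit coefficients of the selectivity analysis (dropout = 1);
# reasoning and self-concept enter z-standardized, competence is the wave-0
# outcome on its own scale.
TABLE3_DROPOUT_COEFFICIENTS = {
    "intercept": -1.941,
    "reas": -0.016,
    "sc": -0.079,
    "sex": -0.185,
    "migration": 0.039,
    "age": -0.159,
    "mode_home": 5.037,
    "school_basic": 0.750,
    "school_intermediate": 1.290,
    "school_other": 0.606,
    "outcome_w0": -0.137,
    "outcome_w0_sq": -0.002,
}
TABLE3_SCHOOL_RE_SD = 2.890


@dataclass
class GeneratorConfig:
    """Configuration of the clustered-panel generator."""

    n_schools: int = 538
    students_per_school: int | tuple[int, int] = 25
    covariate_means: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MEANS))
    covariate_sds: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SDS))
    covariate_corr: np.ndarray = field(default_factory=lambda: DEFAULT_COVARIATE_CORR.copy())
    school_type_probs: dict = field(default_factory=lambda: dict(SCHOOL_TYPE_PROBS))
    gcm_params: GCMParams = field(default_factory=lambda: replace(DEFAULT_GCM_PARAMS))
    variance_components: VarianceComponents = field(
        default_factory=lambda: replace(DEFAULT_VARIANCE_COMPONENTS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_schools < 1:
            raise ValueError("n_schools must be positive")
        sps = self.students_per_school
        if isinstance(sps, tuple):
            lo, hi = sps
            if lo < 1 or hi < lo:
                raise ValueError("students_per_school range must be 1 <= lo <= hi")
        elif sps < 1:
            raise ValueError("students_per_school must be positive")
        C = np.asarray(self.covariate_corr, float)
        if C.shape[0] != C.shape[1] or not np.allclose(C, C.T):
            raise ValueError("covariate_corr must be a symmetric square matrix")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("covariate_corr must have a unit diagonal")
        if np.linalg.eigvalsh(C).min() <= 1e-10:
            raise ValueError(
                "covariate_corr is not positive definite "
                f"(min eigenvalue {np.linalg.eigvalsh(C).min():.3e})"
            )
        self.variance_components.validate()
        if not np.isclose(sum(self.school_type_probs.values()), 1.0, atol=1e-6):
            raise ValueError("school_type_probs must sum to 1")


@dataclass
class DropoutSpec:
    """Wave-2 dropout mechanism.

    ``mechanism`` is one of MCAR, MAR_COVARIATE, DK_OUTCOME,
    WC_RANDOM_EFFECT, LATENT_CLASS.  ``coefficients`` are on the linear
    predictor scale of ``link``; special names ``outcome_w0``/``outcome_w1``/
    ``outcome_w0_sq`` refer to the outcomes and ``u`` to the realized person
    intercept.  If ``target_rate`` is given the intercept is shifted by
    bisection so the realized dropout fraction matches it.
    """

    mechanism: str = "MCAR"
    link: str = "logit"
    coefficients: dict = field(default_factory=dict)
    target_rate: float | None = None
    school_re_sd: float = 0.0
    seed: int = 0

    _ALLOWED = {
        "MCAR": {"intercept"},
        "MAR_COVARIATE": None,  # any covariate column + outcome_w0(_sq)
        "DK_OUTCOME": {"intercept", "outcome_w0", "outcome_w1"},
        "WC_RANDOM_EFFECT": {"intercept", "u"},
        "LATENT_CLASS": {"membership_intercept", "membership_u", "p_dropout_class0", "p_dropout_class1"},
    }

    def validate(self) -> None:
        if self.mechanism not in self._ALLOWED:
            raise ValueError(f"unknown dropout mechanism '{self.mechanism}'")
        if self.link not in ("logit", "probit"):
            raise ValueError("link must be 'logit' or 'probit'")
        allowed = self._ALLOWED[self.mechanism]
        if allowed is not None:
            bad = set(self.coefficients) - allowed
            if bad:
                raise ValueError(
                    f"coefficients {sorted(bad)} not defined for mechanism {self.mechanism}"
                )
        if self.target_rate is not None and not (0.0 <= self.target_rate < 1.0):
            raise ValueError("target_rate must lie in [0, 1)")


def mar_table3_spec(target_rate: float = 0.61, seed: int = 0) -> DropoutSpec:
    """The default covariate-driven (MAR) mechanism: selectivity-analysis
    coefficients with a school-level random intercept."""
    return DropoutSpec(
        mechanism="MAR_COVARIATE",
        link="logit",
        coefficients=dict(TABLE3_DROPOUT_COEFFICIENTS),
        target_rate=target_rate,
        school_re_sd=TABLE3_SCHOOL_RE_SD,
        seed=seed,
    )


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------

def generate_covariates(config: GeneratorConfig) -> LongDataset:
    """Clustered baseline covariates; outcomes left unset.

    Continuous covariates are Gaussian with the requested moments; binary
    ones threshold the same latent Gaussian copula at their marginal rates.
    School type is a school-constant four-level category drawn from a
    per-school latent normal.  ``reas``/``sc`` are the z-standardized scores
    used by the analysis model; the raw scales are kept alongside.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sps = config.students_per_school
    if isinstance(sps, tuple):
        sizes = rng.integers(sps[0], sps[1] + 1, size=config.n_schools)
    else:
        sizes = np.full(config.n_schools, int(sps))
    n = int(sizes.sum())
    school_of = np.repeat(np.arange(config.n_schools), sizes)

    L = np.linalg.cholesky(np.asarray(config.covariate_corr, float))
    Z = rng.standard_normal((n, len(COPULA_ORDER))) @ L.T

    cols = {}
    for j, name in enumerate(COPULA_ORDER):
        if name in BINARY_COVARIATES:
            p = config.covariate_means[name]
            cols[name] = (Z[:, j] > norm.ppf(1.0 - p)).astype(float)
        else:
            cols[name] = config.covariate_means[name] + config.covariate_sds[name] * Z[:, j]

    # school-constant type from a per-school latent normal
    names = list(config.school_type_probs)
    probs = np.array([config.school_type_probs[k] for k in names])
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    lat = rng.standard_normal(config.n_schools)
    type_idx = np.searchsorted(cuts, lat)
    stype = np.array(names, dtype=object)[type_idx][school_of]
    for t in ("basic", "intermediate", "other"):
        cols[f"school_{t}"] = (stype == t).astype(float)

    person = pd.DataFrame(cols)
    person["school_id"] = np.char.add("s", np.char.zfill((school_of + 1).astype(str), 4))
    person["person_id"] = np.char.add("p", np.char.zfill(np.arange(1, n + 1).astype(str), 6))
    # z-standardize the two growth predictors across all students
    for raw, z in (("reas_raw", "reas"), ("sc_raw", "sc")):
        x = person[raw]
        person[z] = (x - x.mean()) / x.std(ddof=0)

    long = pd.concat(
        [person.assign(wave=0), person.assign(wave=1)], ignore_index=True
    ).sort_values(["school_id", "person_id", "wave"], kind="mergesort", ignore_index=True)
    long["responded"] = 1
    long["outcome"] = np.nan
    cov_cols = [
        "reas", "sc", "sex", "migration", "age", "mode_home",
        "school_basic", "school_intermediate", "school_other", "reas_raw", "sc_raw",
    ]
    frame = long[["school_id", "person_id", "wave", "responded", "outcome", *cov_cols]]
    return LongDataset(frame=frame, meta={"generator_seed": config.seed})


def generate_outcomes(
    data: LongDataset,
    params: GCMParams | None = None,
    vc: VarianceComponents | None = None,
    seed: int = 0,
) -> LongDataset:
    """Fill both waves' outcomes from the growth model.

    The realized person effects u_i and school effects v_s (and later the
    masked wave-1 outcomes) are retained in the truth sidecar for oracle
    checks only.
    """
    params = params if params is not None else replace(DEFAULT_GCM_PARAMS)
    vc = vc if vc is not None else replace(DEFAULT_VARIANCE_COMPONENTS)
    vc.validate()
    rng = np.random.default_rng(seed)
    out = data.copy()
    df = out.frame
    for col in ("reas", "sc"):
        if col not in df.columns:
            raise ValueError(f"covariate column '{col}' required by the growth model is missing")

    person = df[df["wave"] == 0].reset_index(drop=True)
    n = len(person)
    schools, school_of = np.unique(person["school_id"].to_numpy(), return_inverse=True)
    u = np.sqrt(vc.sigma_u2) * rng.standard_normal(n)
    v = np.sqrt(vc.sigma_v2) * rng.standard_normal(schools.size)
    gamma = params.as_array()
    y = {}
    for w in (0, 1):
        X = build_design(person, w)
        e = np.sqrt(vc.sigma_e2) * rng.standard_normal(n)
        y[w] = X @ gamma + u + v[school_of] + e

    key = pd.MultiIndex.from_frame(df[["person_id", "wave"]])
    ymap = pd.Series(
        np.concatenate([y[0], y[1]]),
        index=pd.MultiIndex.from_arrays(
            [np.tile(person["person_id"], 2), np.repeat([0, 1], n)], names=["person_id", "wave"]
        ),
    )
    out.frame = df.assign(outcome=ymap.reindex(key).to_numpy())
    out.truth = pd.DataFrame(
        {
            "person_id": person["person_id"],
            "school_id": person["school_id"],
            "u": u,
            "v": v[school_of],
            "y0_true": y[0],
            "y1_true": y[1],
        }
    )
    return out


# --------------------------------------------------------------------------
# dropout
# --------------------------------------------------------------------------

def _linear_predictor(spec: DropoutSpec, person: pd.DataFrame, truth: pd.DataFrame | None, rng):
    """Linear predictor of the dropout probability, excluding the intercept."""
    n = len(person)
    lp = np.zeros(n)
    for name, coef in spec.coefficients.items():
        if name in ("intercept", "membership_intercept"):
            continue
        if name == "outcome_w0":
            x = person["y0"].to_numpy(float)
        elif name == "outcome_w0_sq":
            x = person["y0"].to_numpy(float) ** 2
        elif name == "outcome_w1":
            x = person["y1"].to_numpy(float)
        elif name == "u":
            if truth is None:
                raise ValueError("mechanism references the latent person effect but no truth is available")
            x = truth.set_index("person_id").loc[person["person_id"], "u"].to_numpy(float)
        elif name in person.columns:
            x = person[name].to_numpy(float)
        else:
            raise ValueError(f"dropout mechanism references absent covariate '{name}'")
        lp = lp + coef * x
    if spec.school_re_sd > 0:
        schools, school_of = np.unique(person["school_id"].to_numpy(), return_inverse=True)
        lp = lp + spec.school_re_sd * rng.standard_normal(schools.size)[school_of]
    return lp


def _link_prob(lp, link):
    return 1.0 / (1.0 + np.exp(-lp)) if link == "logit" else norm.cdf(lp)


def apply_dropout(data: LongDataset, spec: DropoutSpec) -> LongDataset:
    """Mask wave-1 outcomes according to the dropout mechanism.

    Wave-0 rows are never masked.  The intercept is shifted by bisection so
    the realized dropout fraction matches ``target_rate`` (bisection is run
    against the realized fraction under fixed uniform draws, so the match is
    within 1/n).  Masked true outcomes are kept in the truth sidecar.
    """
    spec.validate()
    out = data.copy()
    person = out.person_table()
    if person["y0"].isna().any() or person["y1"].isna().any():
        raise ValueError("apply_dropout requires complete outcomes for both waves")
    n = len(person)
    rng = np.random.default_rng(spec.seed)

    if spec.mechanism == "LATENT_CLASS":
        c = spec.coefficients
        if data.truth is None:
            raise ValueError("LATENT_CLASS mechanism requires the truth sidecar")
        u = data.truth.set_index("person_id").loc[person["person_id"], "u"].to_numpy(float)
        lp_mem = c.get("membership_intercept", 0.0) + c.get("membership_u", 0.0) * u
        cls = (rng.random(n) < _link_prob(lp_mem, spec.link)).astype(int)
        p0 = float(np.clip(c.get("p_dropout_class0", 0.2), 1e-9, 1 - 1e-9))
        p1 = float(np.clip(c.get("p_dropout_class1", 0.6), 1e-9, 1 - 1e-9))
        base = np.where(cls == 1, np.log(p1 / (1 - p1)), np.log(p0 / (1 - p0)))
        lp = base
        link = "logit"
        intercept0 = 0.0
    else:
        lp = _linear_predictor(spec, person, data.truth, rng)
        intercept0 = float(spec.coefficients.get("intercept", 0.0))
        link = spec.link

    uni = rng.random(n)

    def realized(delta):
        return float(np.mean(uni < _link_prob(lp + intercept0 + delta, link)))

    delta = 0.0
    if spec.target_rate is not None:
        if spec.target_rate <= 0.0:
            drop = np.zeros(n, bool)
        else:
            lo, hi = -40.0, 40.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if realized(mid) < spec.target_rate:
                    lo = mid
                else:
                    hi = mid
            delta = 0.5 * (lo + hi)
            drop = uni < _link_prob(lp + intercept0 + delta, link)
    else:
        drop = uni < _link_prob(lp + intercept0, link)

    dropped_ids = set(person.loc[drop, "person_id"])
    df = out.frame
    mask = (df["wave"] == 1) & df["person_id"].isin(dropped_ids)
    df.loc[mask, "responded"] = 0
    df.loc[mask, "outcome"] = np.nan
    out.meta["dropout"] = {
        "mechanism": spec.mechanism,
        "solved_intercept": intercept0 + delta,
        "realized_rate": float(np.mean(drop)),
    }
    if out.truth is None:
        out.truth = pd.DataFrame({"person_id": person["person_id"], "y1_true": person["y1"]})
    return out


# --------------------------------------------------------------------------
# incidental-selection demonstration and its oracle
# --------------------------------------------------------------------------

def selection_bias_demo(
    n: int,
    load_y: float,
    load_x: float,
    response_rate: float,
    seed: int = 0,
    selection: str = "threshold",
) -> float:
    """Observed corr(Y, X) among retained cases under incidental selection.

    Y and X are iid standard normal with true correlation 0; the response
    propensity is U = load_y*Y + load_x*X + noise with var(U) = 1.  Under
    ``threshold`` selection the top ``response_rate`` fraction by U is
    retained; ``bernoulli`` retains each case with probability
    logit^-1(a + 2U), a solved for the target rate (an attenuated variant).
    """
    if not (0.0 < response_rate <= 1.0):
        raise ValueError("response_rate must lie in (0, 1]")
    if abs(load_y) >= 1 or abs(load_x) >= 1 or load_y**2 + load_x**2 >= 1.0:
        raise ValueError("invalid propensity construction: load_y^2 + load_x^2 must be < 1")
    rng = np.random.default_rng(seed)
    yx = rng.standard_normal((n, 2))
    noise_sd = np.sqrt(1.0 - load_y**2 - load_x**2)
    u = load_y * yx[:, 0] + load_x * yx[:, 1] + noise_sd * rng.standard_normal(n)
    if selection == "threshold":
        k = int(round(response_rate * n))
        keep = np.argsort(u)[n - k:]
    elif selection == "bernoulli":
        uni = rng.random(n)
        lo, hi = -40.0, 40.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if np.mean(uni < 1.0 / (1.0 + np.exp(-(mid + 2.0 * u)))) < response_rate:
                lo = mid
            else:
                hi = mid
        keep = uni < 1.0 / (1.0 + np.exp(-(0.5 * (lo + hi) + 2.0 * u)))
    else:
        raise ValueError("selection must be 'threshold' or 'bernoulli'")
    sub = yx[keep]
    return float(np.corrcoef(sub[:, 0], sub[:, 1])[0, 1])


def truncation_oracle(load_y: float, load_x: float, response_rate: float) -> float:
    """Closed-form conditional correlation under single truncation.

    With c the (1-rate) standard-normal quantile, lambda = phi(c)/(1-Phi(c))
    and delta = lambda*(lambda-c), the correlation of Y and X given U > c is
    -load_y*load_x*delta / sqrt((1-load_y^2 delta)(1-load_x^2 delta)).
    """
    if response_rate <= 0.0 or response_rate > 1.0:
        raise ValueError("response_rate must lie in (0, 1]")
    if abs(load_y) >= 1 or abs(load_x) >= 1 or load_y**2 + load_x**2 >= 1.0:
        raise ValueError("invalid propensity construction: load_y^2 + load_x^2 must be < 1")
    if response_rate == 1.0 or load_y == 0.0 or load_x == 0.0:
        return 0.0
    c = norm.ppf(1.0 - response_rate)
    lam = norm.pdf(c) / response_rate
    delta = lam * (lam - c)
    num = -load_y * load_x * delta
    den = np.sqrt((1.0 - load_y**2 * delta) * (1.0 - load_x**2 * delta))
    return float(num / den)
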