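"""Linear mixed-effects models for torpor responses.

Three REML models mirror the analysis design: daily median active-phase
Ts (random intercept per individual), nightly minimum rest-phase Ts and
nightly torpor duration (random intercept plus a random treatment slope
per individual). Global fixed effects are the playback treatment, air
temperature on the response's averaging window, daily maximum wind speed,
body mass at capture, and sex; models are simplified by backward
elimination of the least-significant term at alpha = 0.05, with the
treatment term protected (it is the effect under test and is reported
whether or not significant).

Estimation uses statsmodels MixedLM. p-values use the residual-df t
approximation (df = n - k). Variance-partition (marginal/conditional) R^2
follows the standard mixed-model decomposition: fixed-effect variance
over total, and fixed plus random over total. Confidence intervals for
predicted condition means come from a parametric bootstrap (simulate from
the fitted model, refit, percentile interval).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "LmmFit",
    "fit_lmm",
    "simplify",
    "r2_mixed",
    "bootstrap_prediction_intervals",
    "NIGHT_MIN_SPEC",
    "DURATION_SPEC",
    "DAYTIME_SPEC",
]

log = logging.getLogger(__name__)

_TERM_COLUMNS = {
    "treatment": "treatment",
    "wind": "wind_daily_max",
    "mass": "body_mass_g",
    "sex": "sex_male",
}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed model."""

    response: str
    ta_column: str  # which averaging window feeds the Ta term
    fixed_terms: tuple[str, ...] = ("treatment", "ta", "wind", "mass", "sex")
    random_slope: bool = False  # random treatment slope per individual
    protected_terms: frozenset[str] = frozenset({"treatment"})
    alpha_drop: float = 0.05

    def column(self, term: str) -> str:
        return self.ta_column if term == "ta" else _TERM_COLUMNS[term]


DAYTIME_SPEC = ModelSpec("median_active_ts", "ta_active_mean", random_slope=False)
NIGHT_MIN_SPEC = ModelSpec("min_rest_ts", "ta_24h_mean", random_slope=True)
DURATION_SPEC = ModelSpec("torpor_duration_h", "ta_24h_mean", random_slope=True)


@dataclass
class LmmFit:
    """A fitted mixed model: coefficient table, variance components, R^2."""

    response: str
    coefficients: pd.DataFrame  # term, coef, se, df, t, p
    random_effect_sd: dict[str, float]
    residual_sd: float
    marginal_r2: float
    conditional_r2: float
    n_individuals: int
    n_observations: int
    converged: bool
    fallback_intercept_only: bool = False
    dropped_terms: list[tuple[str, float]] = field(default_factory=list)
    spec: ModelSpec | None = None
    _design: dict = field(default_factory=dict, repr=False)

    def coef(self, term: str) -> float:
        row = self.coefficients.set_index("term")
        return float(row.loc[term, "coef"])

    def pvalue(self, term: str) -> float:
        row = self.coefficients.set_index("term")
        return float(row.loc[term, "p"])

    @property
    def terms(self) -> list[str]:
        return [t for t in self.coefficients["term"] if t != "intercept"]

    def summary_text(self) -> str:
        lines = [
            f"response: {self.response} "
            f"(marginal R^2 = {self.marginal_r2:.3f}, "
            f"conditional R^2 = {self.conditional_r2:.3f}; "
            f"N = {self.n_individuals}, n = {self.n_observations})",
            f"{'fixed effects':<22}{'coeff.':>9}{'s.e.':>8}{'d.f.':>6}"
            f"{'t-stat.':>9}{'p-value':>9}",
        ]
        for r in self.coefficients.itertuples():
            p = "<0.001" if r.p < 0.001 else f"{r.p:.3f}"
            lines.append(f"{r.term:<22}{r.coef:>9.2f}{r.se:>8.2f}{r.df:>6.0f}"
                         f"{r.t:>9.1f}{p:>9}")
        lines.append(f"{'random effects':<22}{'s.d.':>9}")
        for k, v in self.random_effect_sd.items():
            lines.append(f"{'individual (' + k + ')':<22}{v:>9.2f}")
        lines.append(f"{'residual':<22}{self.residual_sd:>9.2f}")
        if self.fallback_intercept_only:
            lines.append("NOTE: random-slope fit did not converge; "
                         "intercept-only random structure was used")
        return "\n".join(lines)

    def coefficients_frame(self) -> pd.DataFrame:
        out = self.coefficients.copy()
        out.insert(0, "response", self.response)
        return out


def _prepare(table: pd.DataFrame, spec: ModelSpec, terms: tuple[str, ...]):
    cols = {t: spec.column(t) for t in terms}
    df = table.copy()
    if "sex" in terms:
        df["sex_male"] = (df["sex"] == "M").astype(float)
    if "included" in df.columns:
        df = df[df["included"]]
    need = [spec.response] + list(cols.values()) + ["bird_id"]
    df = df[need].dropna()
    kept = [t for t in terms if df[cols[t]].nunique() > 1]
    if dropped := set(terms) - set(kept):
        log.warning("constant column(s) dropped from design: %s", sorted(dropped))
    return df, cols, tuple(kept)


def fit_lmm(table: pd.DataFrame, spec: ModelSpec,
            terms: tuple[str, ...] | None = None) -> LmmFit:
    """REML fit of one model; never silently degrades the random structure.

    If the random-slope model fails to converge, it is refitted with a
    random intercept only, and the result carries a prominent
    ``fallback_intercept_only`` flag.
    """
    terms = tuple(terms if terms is not None else spec.fixed_terms)
    df, cols, terms = _prepare(table, spec, terms)
    if df["bird_id"].nunique() < 2:
        raise ValueError("need at least 2 individuals for a mixed model")
    if len(df) < 10:
        raise ValueError(f"only {len(df)} observations; need >= 10")

    endog = df[spec.response].to_numpy(float)
    X = pd.DataFrame({"intercept": np.ones(len(df))})
    for t in terms:
        X[t] = df[cols[t]].to_numpy(float)
    groups = df["bird_id"].to_numpy()

    def run(slope: bool):
        if slope and "treatment" not in terms:
            slope = False
        exog_re = (np.column_stack([np.ones(len(df)), df[cols["treatment"]]])
                   if slope else np.ones((len(df), 1)))
        model = sm.MixedLM(endog, X.to_numpy(), groups=groups, exog_re=exog_re)
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (None, "powell", "cg"):
                try:
                    res = (model.fit(reml=True) if method is None
                           else model.fit(reml=True, method=method))
                    break
                except np.linalg.LinAlgError:
                    continue
        if res is None:
            raise np.linalg.LinAlgError("mixed-model fit failed to start")
        return res, exog_re, slope

    res, exog_re, used_slope = run(spec.random_slope)
    fallback = False
    if spec.random_slope and not getattr(res, "converged", True):
        log.warning("%s: random-slope model did not converge; falling back "
                    "to random intercept (flagged)", spec.response)
        res, exog_re, used_slope = run(False)
        fallback = True

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fe = np.asarray(res.fe_params, float)
        se = np.asarray(res.bse_fe, float)
    dfres = len(df) - X.shape[1]
    tvals = fe / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dfres)
    coef_tbl = pd.DataFrame(
        {"term": X.columns, "coef": fe, "se": se, "df": dfres,
         "t": tvals, "p": pvals}
    )
    cov_re = np.atleast_2d(np.asarray(res.cov_re, float))
    re_sd = {"intercept": float(np.sqrt(max(cov_re[0, 0], 0.0)))}
    if used_slope:
        re_sd["treatment_slope"] = float(np.sqrt(max(cov_re[1, 1], 0.0)))
    scale = float(res.scale)

    fit = LmmFit(
        response=spec.response,
        coefficients=coef_tbl,
        random_effect_sd=re_sd,
        residual_sd=float(np.sqrt(scale)),
        marginal_r2=np.nan,
        conditional_r2=np.nan,
        n_individuals=int(df["bird_id"].nunique()),
        n_observations=int(len(df)),
        converged=bool(getattr(res, "converged", True)),
        fallback_intercept_only=fallback,
        spec=spec,
        _design={"X": X, "endog": endog, "groups": groups,
                 "exog_re": exog_re, "cov_re": cov_re, "scale": scale,
                 "cols": cols, "terms": terms, "df": df},
    )
    fit.marginal_r2, fit.conditional_r2 = r2_mixed(fit)
    return fit


def r2_mixed(fit: LmmFit) -> tuple[float, float]:
    """Variance-partition R^2 from the fitted components.

    marginal = var(fixed) / (var(fixed) + var(random) + var(residual));
    conditional adds the random-effect variance to the numerator. The
    fixed-effect variance is the sample variance of the linear predictor,
    and the random-effect variance averages z_i' Sigma z_i over rows.
    """
    d = fit._design
    X = d["X"].to_numpy(float)
    beta = fit.coefficients["coef"].to_numpy(float)
    var_f = float(np.var(X @ beta))
    z = np.asarray(d["exog_re"], float)
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", z, d["cov_re"], z)))
    var_e = d["scale"]
    total = var_f + var_r + var_e
    if total <= 0:
        return 0.0, 0.0
    return var_f / total, (var_f + var_r) / total


def simplify(table: pd.DataFrame, spec: ModelSpec) -> tuple[LmmFit, list]:
    """Backward elimination of least-significant non-protected terms.

    Refits after removing the non-protected term with the largest
    p >= alpha_drop; stops when every non-protected term is significant
    or only protected terms remain. The treatment term is never dropped.
    """
    terms = tuple(spec.fixed_terms)
    dropped: list[tuple[str, float]] = []
    while True:
        fit = fit_lmm(table, spec, terms)
        cand = [
            (t, fit.pvalue(t))
            for t in fit.terms
            if t not in spec.protected_terms
        ]
        cand = [(t, p) for t, p in cand if p >= spec.alpha_drop]
        if not cand:
            fit.dropped_terms = dropped
            return fit, dropped
        worst = max(cand, key=lambda tp: tp[1])
        dropped.append(worst)
        terms = tuple(t for t in fit.terms if t != worst[0])


def bootstrap_prediction_intervals(
    fit: LmmFit,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Parametric-bootstrap predicted condition means with percentile CIs.

    Responses are simulated from the fitted model (fixed effects, random
    effects drawn per individual from the estimated covariance, Gaussian
    residuals), the model refitted, and predictions collected at reference
    covariates (observed means of the retained continuous terms) for each
    condition. Deterministic given the seed. Refit failures are counted; a
    failure rate above 10% triggers a warning.
    """
    d = fit._design
    X = d["X"]
    beta = fit.coefficients["coef"].to_numpy(float)
    groups = d["groups"]
    uniq, inv = np.unique(groups, return_inverse=True)
    z = np.asarray(d["exog_re"], float)
    cov_re = d["cov_re"]
    sigma = np.sqrt(d["scale"])
    rng = np.random.default_rng(seed)
    has_treat = "treatment" in X.columns

    def ref_rows() -> pd.DataFrame:
        base = {c: [float(X[c].mean())] for c in X.columns}
        rows = []
        for cond in (0.0, 1.0) if has_treat else (None,):
            r = {k: v[0] for k, v in base.items()}
            if cond is not None:
                r["treatment"] = cond
            rows.append(r)
        return pd.DataFrame(rows)[X.columns]

    refs = ref_rows()
    point = refs.to_numpy(float) @ beta
    preds = []
    failures = 0
    mu = X.to_numpy(float) @ beta
    chol = np.linalg.cholesky(cov_re + 1e-12 * np.eye(cov_re.shape[0]))
    for _ in range(n_boot):
        b = rng.standard_normal((len(uniq), cov_re.shape[0])) @ chol.T
        y = mu + np.einsum("ij,ij->i", z, b[inv]) + rng.normal(0, sigma, len(mu))
        try:
            m = sm.MixedLM(y, X.to_numpy(), groups=groups, exog_re=z)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = m.fit(reml=True)
            preds.append(refs.to_numpy(float) @ np.asarray(r.fe_params, float))
        except Exception:  # refit failure on a resample
            failures += 1
    if n_boot and failures > 0.1 * n_boot:
        log.warning("bootstrap: %d/%d refits failed", failures, n_boot)
    arr = np.asarray(preds)
    labels = ["control", "treatment"] if has_treat else ["all"]
    if has_treat:  # paired treatment-minus-control contrast per resample
        arr = np.column_stack([arr, arr[:, 1] - arr[:, 0]])
        point = np.append(point, point[1] - point[0])
        labels = labels + ["difference"]
    a = (1 - level) / 2
    lo = np.percentile(arr, 100 * a, axis=0)
    hi = np.percentile(arr, 100 * (1 - a), axis=0)
    out = pd.DataFrame(
        {
            "condition": labels,
            "predicted": point,
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    out.attrs["n_failures"] = failures
    return out
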