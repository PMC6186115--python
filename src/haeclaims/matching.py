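"""Propensity-score matching and relative-risk estimation for CVAD exposure.

The exposure model is a multivariable logistic regression of CVAD use on
baseline covariates (age, region, payer, insurance type, pharmacy benefit,
initial treatment course, Charlson score); categorical levels carried by
fewer than five patients are collapsed to ``OTHER`` before fitting.  Exposed
patients are matched 1:1 to unexposed controls by greedy nearest neighbor
without replacement on the logit of the propensity score, with a caliper of
0.2 standard deviations of the logit (a common epidemiologic default) and a
seeded random processing order, so results are deterministic given the seed.

Relative risk comes from a log-link generalized linear model of the binary
outcome (any hospitalization and/or ED visit in the 12-month follow-up) on
exposure and optional covariates.  The Poisson family with a robust
(sandwich) variance is used rather than log-binomial: the point estimate is
the maximum-likelihood relative risk either way and the sandwich variance is
valid under mean-variance misspecification, while log-binomial fits
frequently fail to converge on small strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

MIN_LEVEL_SIZE = 5
CALIPER_SD = 0.2


class DegenerateExposureError(ValueError):
    """Both an exposed and an unexposed patient are required."""


@dataclass
class PropensityFit:
    scores: pd.Series          # per-patient P(exposure), open unit interval
    coefficients: pd.Series
    converged: bool
    separation: bool = False
    design_columns: list = field(default_factory=list)


@dataclass
class MatchedSet:
    pairs: list                # (exposed id, control id, |logit distance|)
    unmatched_exposed: list
    caliper: float

    @property
    def exposed_ids(self):
        return [p[0] for p in self.pairs]

    @property
    def control_ids(self):
        return [p[1] for p in self.pairs]


@dataclass
class RrEstimate:
    rr: float
    ci_low: float
    ci_high: float
    n_exposed: int
    n_control: int
    se_log_rr: float
    method: str
    unstable: bool = False

    def as_dict(self) -> dict:
        return {
            "rr": self.rr, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_exposed": self.n_exposed, "n_control": self.n_control,
            "se_log_rr": self.se_log_rr, "method": self.method,
            "unstable": self.unstable,
        }


def collapse_rare_levels(col: pd.Series, min_size: int = MIN_LEVEL_SIZE) -> pd.Series:
    """Replace categorical levels with < min_size patients by 'OTHER'."""
    counts = col.value_counts()
    rare = set(counts[counts < min_size].index)
    if rare:
        logger.info("collapsing %d rare level(s) of %s", len(rare), col.name)
    return col.where(~col.isin(rare), "OTHER")


def build_design(covariates: pd.DataFrame,
                 min_level_size: int = MIN_LEVEL_SIZE) -> pd.DataFrame:
    """Dummy-code categoricals (after rare-level collapsing), add intercept."""
    parts = [pd.Series(1.0, index=covariates.index, name="const")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            if s.nunique() > 1:
                parts.append(s.astype(float))
        else:
            s = collapse_rare_levels(s.astype(str), min_level_size)
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            # drop columns that became constant after collapsing
            parts.extend(dummies[c] for c in dummies.columns
                         if dummies[c].nunique() > 1)
    return pd.concat(parts, axis=1)


def fit_propensity(covariates: pd.DataFrame, exposure: pd.Series,
                   min_level_size: int = MIN_LEVEL_SIZE) -> PropensityFit:
    """Maximum-likelihood logistic model of exposure on baseline covariates."""
    exposure = exposure.astype(int)
    if exposure.nunique() < 2:
        raise DegenerateExposureError(
            "need at least one exposed and one unexposed patient")
    X = build_design(covariates, min_level_size)
    separation = False
    try:
        import warnings

        with warnings.catch_warnings():
            # near-separation fits warn; the converged/separation flags carry
            # that information to the caller instead
            warnings.simplefilter("ignore", RuntimeWarning)
            from statsmodels.tools.sm_exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(exposure.values, X.values).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params = pd.Series(res.params, index=X.columns)
        scores = pd.Series(res.predict(X.values), index=covariates.index)
    except Exception:  # PerfectSeparation or numerical failure
        separation, converged = True, False
        params = pd.Series(np.nan, index=X.columns)
        scores = pd.Series(exposure.mean(), index=covariates.index, dtype=float)
    eps = 1e-12
    scores = scores.clip(eps, 1 - eps)
    if converged and (scores.min() <= 0 or scores.max() >= 1):
        separation = True
    return PropensityFit(scores=scores, coefficients=params,
                         converged=converged, separation=separation,
                         design_columns=list(X.columns))


def match_pairs(fit: PropensityFit, exposure: pd.Series, seed: int,
                caliper_sd: float = CALIPER_SD,
                caliper: float | None = None) -> MatchedSet:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Matching is on logit(score); exposed patients are processed in an order
    randomized by ``seed``; each control is used at most once; candidate
    pairs farther apart than the caliper are rejected and the exposed
    patient reported unmatched.  Greedy (not optimal) matching is what is
    implemented and claimed.
    """
    exposure = exposure.astype(bool)
    logit = np.log(fit.scores / (1 - fit.scores))
    if caliper is None:
        sd = float(logit.std(ddof=1))
        caliper = caliper_sd * sd if sd > 0 else np.inf
    rng = np.random.default_rng(seed)
    # canonical order before shuffling: the pair set depends only on the
    # seed, never on the row order of the input
    exposed_ids = sorted(fit.scores.index[exposure], key=str)
    rng.shuffle(exposed_ids)
    controls = dict(logit[~exposure])  # id -> logit, stable insertion order
    pairs, unmatched = [], []
    for eid in exposed_ids:
        if not controls:
            unmatched.append(eid)
            continue
        target = logit[eid]
        best_id = min(controls, key=lambda c: (abs(controls[c] - target), str(c)))
        dist = abs(controls[best_id] - target)
        if dist <= caliper:
            pairs.append((eid, best_id, float(dist)))
            del controls[best_id]
        else:
            unmatched.append(eid)
    return MatchedSet(pairs=pairs, unmatched_exposed=unmatched,
                      caliper=float(caliper))


def estimate_rr(outcome: pd.Series, exposure: pd.Series,
                covariates: pd.DataFrame | None = None,
                alpha: float = 0.05) -> RrEstimate:
    """Relative risk of a binary outcome for exposed vs unexposed.

    Log-link Poisson GLM with HC0 sandwich variance; RR is the
    exponentiated exposure coefficient.  With zero events in either arm the
    MLE diverges, so the estimate falls back to the 2x2 table with a 0.5
    continuity correction in every cell (Katz log method) and is flagged
    unstable.
    """
    outcome = outcome.astype(int)
    exposure = exposure.astype(int)
    if outcome.sum() == 0:
        raise ValueError("no events in the data: relative risk undefined")
    n1, n0 = int(exposure.sum()), int((1 - exposure).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateExposureError("both arms must be non-empty")
    a = int(outcome[exposure == 1].sum())
    b = int(outcome[exposure == 0].sum())
    z = stats.norm.ppf(1 - alpha / 2)

    if a == 0 or b == 0:
        # continuity-corrected crude estimate; CI flagged unstable
        rr = ((a + 0.5) / (n1 + 0.5)) / ((b + 0.5) / (n0 + 0.5))
        se = np.sqrt(1 / (a + 0.5) - 1 / (n1 + 0.5) + 1 / (b + 0.5) - 1 / (n0 + 0.5))
        return RrEstimate(rr=float(rr),
                          ci_low=float(rr * np.exp(-z * se)),
                          ci_high=float(rr * np.exp(z * se)),
                          n_exposed=n1, n_control=n0, se_log_rr=float(se),
                          method="katz_continuity", unstable=True)

    parts = [pd.Series(1.0, index=outcome.index, name="const"),
             exposure.astype(float).rename("exposure")]
    if covariates is not None and len(covariates.columns):
        X_cov = build_design(covariates).drop(columns="const")
        parts.extend(X_cov[c] for c in X_cov.columns)
    X = pd.concat(parts, axis=1)
    model = sm.GLM(outcome.values, X.values, family=sm.families.Poisson())
    res = model.fit(cov_type="HC0")
    beta = res.params[1]
    se = res.bse[1]
    return RrEstimate(rr=float(np.exp(beta)),
                      ci_low=float(np.exp(beta - z * se)),
                      ci_high=float(np.exp(beta + z * se)),
                      n_exposed=n1, n_control=n0, se_log_rr=float(se),
                      method="poisson_robust", unstable=False)


def standardized_mean_difference(x1: pd.Series, x0: pd.Series) -> float:
    """(mean1 - mean0) / pooled SD; 0 when both groups are constant."""
    m1, m0 = float(np.mean(x1)), float(np.mean(x0))
    v1 = float(np.var(x1, ddof=1)) if len(x1) > 1 else 0.0
    v0 = float(np.var(x0, ddof=1)) if len(x0) > 1 else 0.0
    pooled = np.sqrt((v1 + v0) / 2)
    if pooled == 0:
        return 0.0
    return (m1 - m0) / pooled


def balance_diagnostics(covariates: pd.DataFrame, exposure: pd.Series,
                        matched: MatchedSet | None = None) -> pd.DataFrame:
    """SMD per covariate, pre-matching and (optionally) post-matching.

    Categorical covariates are expanded to level indicators, each with its
    own SMD row.
    """
    exposure = exposure.astype(bool)
    expanded = {}
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            expanded[col] = s.astype(float)
        else:
            for level, dummy in pd.get_dummies(s.astype(str), prefix=col,
                                               dtype=float).items():
                expanded[level] = dummy
    rows = []
    for name, series in expanded.items():
        pre = standardized_mean_difference(series[exposure], series[~exposure])
        row = {"covariate": name, "smd_pre": pre}
        if matched is not None:
            e = series.loc[matched.exposed_ids]
            c = series.loc[matched.control_ids]
            row["smd_post"] = standardized_mean_difference(e, c)
        rows.append(row)
    return pd.DataFrame(rows)
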