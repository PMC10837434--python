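"""EMA survey accounting and Poisson count models of TR-IM frequency.

The ecological-momentary-assessment schedule delivers five daily
surveys for fourteen days (70 total); the three mid-day surveys probe
trauma-related intrusive memories, for at most 42 TR-IM surveys.  A
subject's TR-IM frequency is the total count reported across their
completed TR-IM surveys; subjects completing fewer than 70% of all
surveys (49 of 70) are excluded.

TR-IM frequency is modeled with log-link Poisson regression: brain
measures (subregion volume or brain score) as predictor, age, sex and
number of completed TR-IM surveys as covariates, and log follow-up
duration as exposure offset.  Continuous predictors are standardized
(mean 0, SD 1) so exponentiated coefficients are incidence rate ratios
(IRR) per one SD; binary sex is centered but not scaled.  Model fit is
summarized by Nagelkerke's pseudo-R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .synthgen import N_DAYS, N_SLOTS_PER_DAY, TRIM_SLOTS

__all__ = [
    "PoissonFit",
    "PoissonCountModel",
    "compliance",
    "trim_frequency",
    "subject_summary",
    "fit_poisson",
    "nagelkerke",
    "pearson_r",
    "COMPLIANCE_MIN_SURVEYS",
    "MAX_TOTAL_SURVEYS",
    "MAX_TRIM_SURVEYS",
]

MAX_TOTAL_SURVEYS = N_DAYS * N_SLOTS_PER_DAY          # 70
MAX_TRIM_SURVEYS = N_DAYS * len(TRIM_SLOTS)           # 42
COMPLIANCE_FRACTION = 0.70
# 70% of 70 surveys
COMPLIANCE_MIN_SURVEYS = int(np.ceil(COMPLIANCE_FRACTION * MAX_TOTAL_SURVEYS))


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "day", "slot", "completed"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"EMA records missing columns: {sorted(missing)}")
    dup = records.duplicated(subset=["subject_id", "day", "slot"])
    if dup.any():
        raise ValueError("duplicate (subject, day, slot) EMA records")
    per_subject = records.groupby("subject_id").size()
    if (per_subject > MAX_TOTAL_SURVEYS).any():
        raise ValueError(f"a subject has more than {MAX_TOTAL_SURVEYS} records")
    return records


def compliance(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject survey counts and the 70%-compliance inclusion flag
    (included iff at least 49 of the 70 scheduled surveys completed)."""
    records = _validate_records(records)
    g = records.groupby("subject_id")["completed"].sum().astype(int)
    out = pd.DataFrame({
        "subject_id": g.index,
        "n_total_surveys": g.to_numpy(),
    })
    out["fraction"] = out["n_total_surveys"] / MAX_TOTAL_SURVEYS
    out["include_flag"] = out["n_total_surveys"] >= COMPLIANCE_MIN_SURVEYS
    return out.reset_index(drop=True)


def trim_frequency(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject TR-IM frequency, completed TR-IM survey count and
    follow-up duration.

    Frequency is the sum of counts over completed TR-IM slots;
    follow-up is the span in days from first to last completed survey,
    inclusive.  A subject with no completed surveys has no defined
    follow-up and is an error.
    """
    records = _validate_records(records)
    rows = []
    for sid, grp in records.groupby("subject_id"):
        done = grp[grp["completed"].astype(bool)]
        if done.empty:
            raise ValueError(f"subject {sid} has no completed surveys")
        trim = done[done["slot"].isin(TRIM_SLOTS)]
        freq = int(trim["trim_count"].fillna(0).sum())
        rows.append({
            "subject_id": sid,
            "trim_frequency": freq,
            "n_trim_surveys": int(len(trim)),
            "followup_days": float(done["day"].max() - done["day"].min() + 1),
        })
    return pd.DataFrame(rows)


def subject_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Compliance and TR-IM accounting merged into one table."""
    return compliance(records).merge(trim_frequency(records), on="subject_id")


# ---------------------------------------------------------------------------
# Poisson regression


@dataclass
class PoissonFit:
    """Results of an offset Poisson regression."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    irr: pd.Series
    irr_ci: pd.DataFrame  # columns: lower, upper
    loglik: float
    loglik_null: float
    nagelkerke_r2: float
    converged: bool
    n: int
    dispersion: float

    def summary_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "irr": self.irr.to_dict(),
            "irr_ci_lower": self.irr_ci["lower"].to_dict(),
            "irr_ci_upper": self.irr_ci["upper"].to_dict(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "nagelkerke_r2": self.nagelkerke_r2,
            "converged": self.converged,
            "n": self.n,
            "dispersion": self.dispersion,
        }


def nagelkerke(loglik: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's normalized likelihood-ratio pseudo-R².

    R²_CS = 1 - exp((2/n)(ll0 - ll)); R²_N = R²_CS / (1 - exp((2/n) ll0)).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik < loglik_null - 1e-8:
        raise ValueError(
            "model log-likelihood below null log-likelihood: the fit did "
            "not converge or the null model is not nested"
        )
    r2_cs = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik))
    r2_max = 1.0 - np.exp((2.0 / n) * loglik_null)
    if r2_max <= 0:
        return 0.0
    return float(max(r2_cs, 0.0) / r2_max)


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~np.isnan(x)])
    return len(vals) <= 2


def fit_poisson(
    data: pd.DataFrame,
    predictors: list[str],
    offset_field: str = "followup_days",
    outcome: str = "trim_frequency",
    standardize: bool = True,
) -> PoissonFit:
    """Offset Poisson regression of the count outcome.

    Continuous predictors are standardized to mean 0, SD 1 (sample SD)
    before fitting; binary predictors are centered only.  The offset is
    the log of ``offset_field`` (must be positive).  Fitting uses
    iteratively reweighted least squares (relative tolerance 1e-8, at
    most 100 iterations); non-convergence is flagged on the result, and
    a zero-variance predictor is an error.
    """
    cols = predictors + [offset_field, outcome]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = data[cols].dropna()
    n = len(df)
    if n < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} subjects, got {n}"
        )
    exposure = df[offset_field].to_numpy(dtype=float)
    if np.any(exposure <= 0):
        raise ValueError("offset values must be positive")

    X = pd.DataFrame(index=df.index)
    for p in predictors:
        x = df[p].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance predictor: {p}")
        if standardize and not _is_binary(x):
            X[p] = (x - x.mean()) / sd
        else:
            X[p] = x - x.mean()
    X = sm.add_constant(X, prepend=True)
    y = df[outcome].to_numpy(dtype=float)
    offset = np.log(exposure)

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=100, tol=1e-8)
    null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Poisson(),
                  offset=offset).fit(maxiter=100, tol=1e-8)

    z = stats.norm.ppf(0.975)
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    irr = np.exp(params)
    irr_ci = pd.DataFrame({
        "lower": np.exp(params - z * bse),
        "upper": np.exp(params + z * bse),
    }, index=X.columns)
    df_resid = max(n - X.shape[1], 1)
    return PoissonFit(
        params=params,
        bse=bse,
        pvalues=pd.Series(res.pvalues, index=X.columns),
        irr=irr,
        irr_ci=irr_ci,
        loglik=float(res.llf),
        loglik_null=float(null.llf),
        nagelkerke_r2=nagelkerke(float(res.llf), float(null.llf), n),
        converged=bool(res.converged),
        n=n,
        dispersion=float(res.pearson_chi2 / df_resid),
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-tailed t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


class PoissonCountModel(BaseEstimator):
    """Offset Poisson regression as a scikit-learn style estimator.

    ``fit(df)`` runs :func:`fit_poisson` on a subject table; fitted
    attributes mirror :class:`PoissonFit` fields with trailing
    underscores.  ``predict(df)`` returns expected counts on the
    training standardization (predictor scaling learned at fit time).
    """

    def __init__(
        self,
        predictors: tuple[str, ...] = ("brain_score", "age", "sex", "n_trim_surveys"),
        offset_field: str = "followup_days",
        outcome: str = "trim_frequency",
        standardize: bool = True,
    ) -> None:
        self.predictors = predictors
        self.offset_field = offset_field
        self.outcome = outcome
        self.standardize = standardize

    def fit(self, df: pd.DataFrame, y=None):
        fit = fit_poisson(
            df, list(self.predictors), offset_field=self.offset_field,
            outcome=self.outcome, standardize=self.standardize,
        )
        self.result_ = fit
        self.params_ = fit.params
        self.bse_ = fit.bse
        self.pvalues_ = fit.pvalues
        self.irr_ = fit.irr
        self.irr_ci_ = fit.irr_ci
        self.loglik_ = fit.loglik
        self.loglik_null_ = fit.loglik_null
        self.nagelkerke_r2_ = fit.nagelkerke_r2
        self.converged_ = fit.converged
        self.dispersion_ = fit.dispersion
        # remember training standardization for predict
        sub = df[list(self.predictors)].dropna()
        self.predictor_means_ = sub.mean()
        sds = sub.std(ddof=1)
        binary = {p: _is_binary(sub[p].to_numpy(dtype=float))
                  for p in self.predictors}
        self.predictor_scales_ = pd.Series(
            {p: (1.0 if (binary[p] or not self.standardize) else sds[p])
             for p in self.predictors}
        )
        return self

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise ValueError("model is not fitted")
        eta = np.full(len(df), self.params_["const"], dtype=float)
        for p in self.predictors:
            xp = (df[p].to_numpy(dtype=float) - self.predictor_means_[p])
            xp = xp / self.predictor_scales_[p]
            eta += self.params_[p] * xp
        eta += np.log(df[self.offset_field].to_numpy(dtype=float))
        return np.exp(eta)
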