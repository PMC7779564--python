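"""Cohort-level statistics: spatial variability, age and sex effects on CNR.

The cohort table has one row per subject with the contrast measures the
atlas pipeline produces: mean of per-slice peak CNRs and atlas-based mean
CNRs at the liberal (5%) and stringent (25%) probability thresholds, each
per hemisphere and collapsed (left/right mean). Age effects are ordinary
least squares regressions of a CNR measure on age; sex differences are
pooled-variance two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import ConfigurationError, DegenerateRegionError


@dataclass
class RegressionResult:
    """OLS summary in the shape the age analyses report."""

    predictor: str
    response: str
    n: int
    f_stat: float
    df: tuple[int, int]
    p_value: float
    r_squared: float
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "response": self.response,
            "n": self.n,
            "F": self.f_stat,
            "df": list(self.df),
            "p": self.p_value,
            "R2": self.r_squared,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
        }


def collapse_lr(left: float, right: float) -> float:
    """Collapse hemispheric values by their mean, ignoring a missing side."""
    vals = [v for v in (left, right) if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def spatial_sd_profile(peak_table: pd.DataFrame) -> pd.DataFrame:
    """Group SD (sample SD, mm) of peak x and y per slice and hemisphere.

    ``peak_table`` is the concatenated long-format slice-profile table across
    subjects. Slices with fewer than two non-missing peaks yield NaN
    (pairwise deletion; nothing is imputed).
    """

    def _sd(series: pd.Series) -> float:
        vals = series.dropna()
        return float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan")

    grouped = peak_table.groupby(["hemisphere", "slice"])
    out = grouped.agg(
        sd_x=("peak_x", _sd),
        sd_y=("peak_y", _sd),
        n_peaks=("peak_x", lambda s: int(s.notna().sum())),
    ).reset_index()
    return out.sort_values(["hemisphere", "slice"]).reset_index(drop=True)


def age_regression(
    table: pd.DataFrame,
    response: str,
    predictor: str = "age",
    min_age: float | None = None,
) -> RegressionResult:
    """OLS of a response column on age; optional older-subgroup filter.

    ``min_age`` keeps rows with age strictly greater than the cutoff
    (e.g. 60 for the older subgroup).
    """
    data = table[[predictor, response]].dropna()
    if min_age is not None:
        data = data[data[predictor] > min_age]
    if len(data) < 3:
        raise ConfigurationError(f"need >= 3 complete rows, got {len(data)}")
    y = data[response].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise DegenerateRegionError(f"response {response!r} is constant")
    X = sm.add_constant(data[predictor].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        predictor=predictor,
        response=response,
        n=len(data),
        f_stat=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
    )


def sex_difference(
    table: pd.DataFrame, response: str, sex_column: str = "sex"
) -> tuple[float, int, float]:
    """Two-sided pooled-variance t-test of a response between sexes.

    Returns (t, df, p) with df = n - 2.
    """
    data = table[[sex_column, response]].dropna()
    groups = [g[response].to_numpy(dtype=float) for _, g in data.groupby(sex_column)]
    if len(groups) != 2 or any(len(g) < 2 for g in groups):
        raise ConfigurationError("need two sex groups with >= 2 members each")
    t, p = sps.ttest_ind(groups[0], groups[1], equal_var=True)
    df = len(groups[0]) + len(groups[1]) - 2
    return float(t), int(df), float(p)


# ---------------------------------------------------------------------------
# Calibration / power helpers on cohort tables


def null_age_rejection_rate(
    responses: np.ndarray,
    age_range: tuple[int, int],
    n_subjects: int,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the age regression under the phantom null.

    Responses are resampled (with replacement) from an observed pool of
    pipeline CNR values and paired with freshly drawn ages, so response and
    age are independent by construction while the response distribution is
    the pipeline's own. Returns the fraction of ``n_reps`` cohorts whose age
    regression rejects at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    responses = np.asarray(responses, dtype=float)
    responses = responses[np.isfinite(responses)]
    if responses.size < 2:
        raise ConfigurationError("need a pool of >= 2 finite responses")
    hits = 0
    for _ in range(n_reps):
        ages = rng.integers(age_range[0], age_range[1] + 1, size=n_subjects)
        y = rng.choice(responses, size=n_subjects, replace=True)
        y = y + rng.normal(0.0, 1e-9, size=n_subjects)  # guard exact-tie degeneracy
        tab = pd.DataFrame({"age": ages, "cnr": y})
        if age_regression(tab, "cnr").p_value < alpha:
            hits += 1
    return hits / n_reps


def sex_shift_rejection_rate(
    responses: np.ndarray,
    n_subjects: int,
    shift_sd: float,
    female_fraction: float,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
) -> float:
    """Power of the sex t-test when one group is shifted by ``shift_sd`` SDs.

    Responses are resampled from the observed pipeline CNR pool; males get a
    mean shift of ``shift_sd`` times the pool SD.
    """
    rng = np.random.default_rng(seed)
    responses = np.asarray(responses, dtype=float)
    responses = responses[np.isfinite(responses)]
    sd = float(np.std(responses, ddof=1))
    hits = 0
    n_f = int(round(female_fraction * n_subjects))
    for _ in range(n_reps):
        y = rng.choice(responses, size=n_subjects, replace=True)
        sex = np.array(["F"] * n_f + ["M"] * (n_subjects - n_f))
        y = y + np.where(sex == "M", shift_sd * sd, 0.0)
        tab = pd.DataFrame({"sex": sex, "cnr": y})
        _, _, p = sex_difference(tab, "cnr")
        if p < alpha:
            hits += 1
    return hits / n_reps


__all__ = [
    "RegressionResult",
    "collapse_lr",
    "spatial_sd_profile",
    "age_regression",
    "sex_difference",
    "null_age_rejection_rate",
    "sex_shift_rejection_rate",
]
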