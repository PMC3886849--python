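"""Closed-form association statistics for the simulated cohort.

Group comparisons use one-way ANOVA (two groups: F equals the squared
pooled t).  Physiology-vs-injury associations are fit by ordinary least
squares with survival week as a fixed covariate — with a single measurement
per animal this is the identifiable reduction of a mixed-effects adjustment
for survival time.  The reported r^2 is the squared Pearson correlation
between the week-residualized predictor and outcome (a semi-partial
coefficient of determination); the cohort generator is calibrated under the
same definition, so recovery checks are self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
HI_PREDICTORS = ["BP", "CaO2", "glucose", "lactate"]
OUTCOMES = {"GFAP": "gfap_fraction", "Iba1": "iba1_fraction"}


@dataclass
class AssociationResult:
    predictor: str
    outcome: str
    slope: float
    se: float
    t: float
    p: float
    r2: float
    n: int
    adjusted_for: list[str] = field(default_factory=lambda: ["survival_week"])


def two_group_f_test(a, b) -> tuple[float, float, bool]:
    """One-way two-group ANOVA: (F, p, degenerate).

    Zero pooled variance with equal means gives (0, 1); zero variance with
    unequal means is flagged degenerate with p -> 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    pooled_var = (np.var(a, ddof=1) * (a.size - 1)
                  + np.var(b, ddof=1) * (b.size - 1)) / (a.size + b.size - 2)
    if pooled_var == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, False
        return np.inf, 0.0, True
    F, p = sps.f_oneway(a, b)
    return float(F), float(p), False


def epoch_vs_baseline(
    cohort_epochs: pd.DataFrame, variable: str, epoch: str,
    n_comparisons: int = 3,
) -> tuple[float, float]:
    """Paired epoch-vs-baseline comparison with Bonferroni correction.

    ``cohort_epochs`` is the long epoch table (one row per animal-epoch).
    Returns (mean difference, Bonferroni-adjusted paired-t p-value).
    """
    wide = cohort_epochs.pivot(index="animal_id", columns="epoch",
                               values=variable)
    if epoch not in wide.columns or "baseline" not in wide.columns:
        raise ValueError(f"epoch '{epoch}' or baseline missing from table")
    # animals without a row at the target epoch (controls) fall outside the
    # pairing; an existing row with a missing value (heart rate during the
    # occlusion) makes the comparison unusable
    at_epoch = cohort_epochs[cohort_epochs.epoch == epoch]
    if at_epoch[variable].isna().any():
        raise ValueError(
            f"'{variable}' is missing at epoch '{epoch}' for some animals")
    paired = wide.loc[wide.index.isin(at_epoch.animal_id),
                      ["baseline", epoch]].dropna()
    if len(paired) < 2:
        raise ValueError(f"no paired values for '{variable}' at '{epoch}'")
    diff = paired[epoch] - paired["baseline"]
    mean_diff = float(diff.mean())
    if np.allclose(diff, 0.0):
        return mean_diff, 1.0
    t, p = sps.ttest_rel(paired[epoch], paired["baseline"])
    return mean_diff, float(min(1.0, p * n_comparisons))


def adjusted_linear_assoc(x, y, week, predictor: str = "x",
                          outcome: str = "y") -> AssociationResult:
    """OLS fit of ``y ~ x + week`` with residualized r^2.

    The slope, SE, t and p come from the two-covariate least-squares fit;
    r^2 is the squared correlation between week-residualized x and y.  A
    constant covariate reduces exactly to simple linear regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    week = np.asarray(week, dtype=float)
    n = x.size
    if not (y.size == n and week.size == n):
        raise ValueError("x, y and week must be aligned")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if np.ptp(week) > 0:
        r_xw = np.corrcoef(x, week)[0, 1]
        if abs(r_xw) > 0.99:
            raise ValueError("predictor collinear with survival week")
    import statsmodels.api as sm

    X = np.column_stack([x, week]) if np.ptp(week) > 0 else x[:, None]
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    tval = float(fit.tvalues[1])
    pval = float(fit.pvalues[1])
    rx = _residualize(x, week)
    ry = _residualize(y, week)
    r2 = float(np.corrcoef(rx, ry)[0, 1] ** 2)
    return AssociationResult(predictor=predictor, outcome=outcome, slope=slope,
                             se=se, t=tval, p=pval, r2=r2, n=n)


def _residualize(v: np.ndarray, week: np.ndarray) -> np.ndarray:
    if np.ptp(week) == 0:
        return v - v.mean()
    W = np.column_stack([np.ones_like(week), week])
    beta, *_ = np.linalg.lstsq(W, v, rcond=None)
    return v - W @ beta


def multi_predictor_profile(
    summary: pd.DataFrame, epochs: pd.DataFrame,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Week-adjusted association of each H-I-epoch predictor with each marker.

    Returns one row per (predictor, outcome) with slope/t/p/r2 and the
    within-outcome rank by r^2 (1 = strongest predictor).
    """
    predictors = predictors or HI_PREDICTORS
    hi = summary[summary.group == "HI"]
    if len(hi) < 4:
        raise ValueError("insufficient H-I animals for association analysis")
    hi_epoch = epochs[epochs.epoch == "hypoxia_ischemia"].set_index("animal_id")
    hi_epoch = hi_epoch.loc[hi.animal_id]
    rows = []
    for outcome, col in OUTCOMES.items():
        for pred in predictors:
            res = adjusted_linear_assoc(
                hi_epoch[pred].to_numpy(), hi[col].to_numpy(),
                hi.survival_week.to_numpy(), predictor=pred, outcome=outcome)
            rows.append(vars(res) | {"adjusted_for": "survival_week"})
    df = pd.DataFrame(rows)
    df["rank"] = df.groupby("outcome")["r2"].rank(ascending=False).astype(int)
    return df
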