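"""Risk-factor association analysis: bivariate screening followed by
multivariable logistic regression of operative difficulty on the scored
risk factors.

The procedure mirrors the classic epidemiological two-stage analysis: every
candidate factor is first fit in a single-predictor logistic model, factors
with Wald p below the screening level (0.05 by default) enter a joint
maximum-likelihood logistic fit, and adjusted odds ratios with Wald 95%
confidence intervals are reported. Quasi-complete separation — common in
small surgical series where, e.g., every buried gallbladder converts to
open — is detected from exploding coefficients and flagged rather than
reported as a trustworthy estimate; an optional ridge-penalized refit
provides stabilized point estimates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import DEFAULT_THRESHOLDS, ScoreThresholds
from .scoring import score_sugrue
from .types import IntraopFindings, ValidationError

__all__ = [
    "ComputationError",
    "AssociationResult",
    "design_matrix",
    "outcome_vector",
    "screen_bivariate",
    "fit_multivariable",
    "associate",
]


class ComputationError(RuntimeError):
    """Raised when a model fit fails irrecoverably."""


# candidate risk factors, in the order the published table lists them;
# reference categories are the unexposed levels (age < cutoff, female, no
# history, BMI <= cutoff, no palpable GB, no scar, no stone, no adhesion,
# time <= cutoff, no spillage, no conversion, clip ligature)
def design_matrix(
    df: pd.DataFrame, thresholds: ScoreThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """0/1 indicator columns of the candidate risk factors of a cohort."""
    X = pd.DataFrame(index=df.index)
    X["age_over_cutoff"] = (
        df["age"] >= thresholds.age_cutoff
        if thresholds.age_inclusive
        else df["age"] > thresholds.age_cutoff
    ).astype(int)
    X["male"] = (df["sex"] == "male").astype(int)
    X["admission_history"] = df["admission_history_acute_cholecystitis"].astype(int)
    X["bmi_over_30"] = (df["bmi"] > thresholds.bmi_cutoff).astype(int)
    X["palpable_gb"] = df["palpable_gb"].astype(int)
    X["scar_infraumbilical"] = (df["abdominal_scar"] == "infraumbilical").astype(int)
    X["scar_supraumbilical"] = (df["abdominal_scar"] == "supraumbilical").astype(int)
    X["impacted_stone"] = df["impacted_stone_imaging"].astype(int)
    if "adhesion_grade" in df.columns:
        X["adhesion_lt50"] = (df["adhesion_grade"] == "less_than_50pct").astype(int)
        X["adhesion_burying"] = (df["adhesion_grade"] == "burying_gb").astype(int)
        X["time_over_cutoff"] = (
            df["time_to_identify_cystic_structures_min"] > thresholds.time_cutoff_min
        ).astype(int)
        X["bile_stone_spillage"] = df["bile_stone_spillage"].astype(int)
        X["conversion_to_open"] = df["conversion_to_open"].astype(int)
        X["ligature_stitch"] = (df["ligature"] == "stitch").astype(int)
    return X


def outcome_vector(
    df: pd.DataFrame, thresholds: ScoreThresholds = DEFAULT_THRESHOLDS
) -> pd.Series:
    """Operative difficulty (1 = difficult) under the default reference
    standard: standard intraoperative total at or above the mild/moderate
    boundary."""
    from .io import records_from_frame

    labels = [
        int(score_sugrue(intra, thresholds).total >= thresholds.standard_difficult_min)
        for _, intra in records_from_frame(df)
    ]
    return pd.Series(labels, index=df.index, name="difficult")


@dataclass
class AssociationResult:
    """Screening p-values and multivariable fit for each candidate factor.

    ``table`` has one row per candidate with columns: ``bivariate_p``,
    ``included``, ``coef``, ``aor``, ``ci_low``, ``ci_high``, ``p_value``,
    ``separation``. Factors excluded at screening carry NaN fit columns.
    """

    table: pd.DataFrame
    n_obs: int
    converged: bool
    penalized: bool = False


def _fit_logit(y: np.ndarray, X: pd.DataFrame, maxiter: int = 200):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings handled via coef bound
        return model.fit(disp=0, maxiter=maxiter)


def screen_bivariate(
    X: pd.DataFrame,
    y,
    alpha: float = 0.05,
    separation_bound: float = 15.0,
) -> pd.DataFrame:
    """Single-predictor logistic screen of every column of ``X``.

    Returns a frame with ``bivariate_p``, ``included`` (Wald p < alpha) and
    ``separation`` per candidate. A degenerate (constant) predictor is
    excluded with NaN p; a perfectly separating predictor is included with
    p reported as 0 and flagged.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class; screening is undefined")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    rows = []
    for name in X.columns:
        x = X[name]
        if x.nunique() < 2:
            rows.append((name, np.nan, False, False))
            continue
        try:
            res = _fit_logit(y, x.to_frame())
            coef = float(res.params.iloc[-1])
            p = float(res.pvalues.iloc[-1])
            separated = not np.isfinite(coef) or abs(coef) > separation_bound
        except Exception:
            separated, p = True, np.nan
        if separated:
            p = 0.0  # separation = overwhelming evidence, flagged for review
        rows.append((name, p, bool(p < alpha), separated))
    return pd.DataFrame(
        rows, columns=["variable", "bivariate_p", "included", "separation"]
    ).set_index("variable")


def _separation_suspects(X: pd.DataFrame, y: np.ndarray, bound: float) -> list[str]:
    """Name the columns whose single-predictor fit shows separation."""
    suspects = []
    for name in X.columns:
        try:
            res = _fit_logit(y, X[[name]], maxiter=50)
            coef = float(res.params.iloc[-1])
            if not np.isfinite(coef) or abs(coef) > bound:
                suspects.append(name)
        except Exception:
            suspects.append(name)
    return suspects


def fit_multivariable(
    X: pd.DataFrame,
    y,
    included: list[str] | None = None,
    ci_level: float = 0.95,
    separation_bound: float = 15.0,
    penalized: bool = False,
    screen: pd.DataFrame | None = None,
) -> AssociationResult:
    """Joint maximum-likelihood logistic fit of the included factors.

    Adjusted odds ratios are exponentiated coefficients with Wald
    ``ci_level`` intervals. Any coefficient beyond ``separation_bound`` in
    absolute value marks the factor as separated; with ``penalized=True`` a
    ridge (L2) refit replaces the point estimates (intervals are withheld
    for penalized estimates). A warning is issued when n is below ten
    observations per predictor.
    """
    y = np.asarray(y, dtype=float)
    if included is None:
        included = list(X.columns)
    if not included:
        raise ValidationError("no variables passed the screen; nothing to fit")
    missing = [v for v in included if v not in X.columns]
    if missing:
        raise ValidationError(f"included variables not in the design: {missing}")
    n = len(y)
    if n < 10 * len(included):
        warnings.warn(
            f"n={n} is below ten observations per predictor "
            f"({len(included)} predictors); estimates may be unstable",
            stacklevel=2,
        )
    Xi = X[included]
    try:
        res = _fit_logit(y, Xi)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception as exc:
        if not penalized:
            suspects = _separation_suspects(Xi, y, separation_bound)
            raise ComputationError(
                f"multivariable logistic fit failed: {exc} "
                f"(suspected separation in: {', '.join(suspects) or 'unknown'}); "
                "retry with penalized=True"
            ) from exc
        res, converged = None, False

    alpha_ci = 1.0 - ci_level
    table = pd.DataFrame(
        index=pd.Index(X.columns, name="variable"),
        columns=[
            "bivariate_p", "included", "coef", "aor",
            "ci_low", "ci_high", "p_value", "separation",
        ],
        dtype=object,
    )
    table["included"] = [c in included for c in X.columns]
    table["separation"] = False
    if screen is not None:
        table.loc[screen.index, "bivariate_p"] = screen["bivariate_p"]
        table.loc[screen.index, "separation"] = screen["separation"]

    if res is not None:
        conf = res.conf_int(alpha=alpha_ci)
        for name in included:
            coef = float(res.params[name])
            sep = not np.isfinite(coef) or abs(coef) > separation_bound
            table.loc[name, "coef"] = coef
            table.loc[name, "aor"] = float(np.exp(coef))
            table.loc[name, "ci_low"] = float(np.exp(conf.loc[name, 0]))
            table.loc[name, "ci_high"] = float(np.exp(conf.loc[name, 1]))
            table.loc[name, "p_value"] = float(res.pvalues[name])
            if sep:
                table.loc[name, "separation"] = True

    separated = [str(v) for v in table.index[table["separation"] & table["included"]]]
    if (not converged or separated) and not penalized:
        if not converged:
            worst = separated[0] if separated else "unknown"
            raise ComputationError(
                "multivariable logistic fit did not converge "
                f"(suspected separation in: {worst}); retry with penalized=True"
            )
    if penalized and (not converged or separated):
        if res is None:
            for name in _separation_suspects(Xi, y, separation_bound):
                table.loc[name, "separation"] = True
        # ridge refit: stable point estimates, no Wald intervals
        pen = sm.GLM(y, sm.add_constant(Xi, has_constant="add"),
                     family=sm.families.Binomial()).fit_regularized(
            alpha=1.0 / max(n, 1), L1_wt=0.0)
        for name in included:
            coef = float(pen.params[name])
            table.loc[name, "coef"] = coef
            table.loc[name, "aor"] = float(np.exp(coef))
            table.loc[name, ["ci_low", "ci_high", "p_value"]] = np.nan
        return AssociationResult(table=table, n_obs=n, converged=True, penalized=True)

    return AssociationResult(table=table, n_obs=n, converged=converged)


def associate(
    df: pd.DataFrame,
    outcome: pd.Series | None = None,
    alpha: float = 0.05,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    penalized: bool = False,
) -> AssociationResult:
    """Full two-stage analysis of a cohort frame: screen every candidate
    factor at ``alpha``, then fit the retained set jointly."""
    X = design_matrix(df, thresholds)
    y = outcome_vector(df, thresholds) if outcome is None else outcome
    screen = screen_bivariate(X, y, alpha=alpha)
    included = [str(v) for v in screen.index[screen["included"]]]
    if not included:
        table = screen.copy()
        for col in ("coef", "aor", "ci_low", "ci_high", "p_value"):
            table[col] = np.nan
        return AssociationResult(table=table, n_obs=len(y), converged=True)
    return fit_multivariable(
        X, y, included, penalized=penalized, screen=screen
    )
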