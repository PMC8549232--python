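"""Statistical layer: count validation, speed–accuracy control, mixed models.

The observation table holds one row per subject-leg (at most two rows per
subject).  Four analyses operate on it:

1. **Count validation** — a random-intercept mixed model of the examiner's
   manual count on the script count (perfect agreement predicts slope 1,
   intercept 0), the Nakagawa conditional pseudo-R² (variance explained by
   fixed plus random effects over the total), the median manual−script
   difference with empirical 2.5/97.5-percentile limits of agreement, and
   the slope of the difference on the manual count (does the examiner's
   error grow with the count?).
2. **Speed–accuracy residualisation** — error parameters grow with touch
   rate; a straight line of Ln(parameter) on the in-target count fitted on
   healthy controls predicts the speed-appropriate error, and the residual
   (observed − predicted) is the speed-controlled parameter for every row
   of both groups.
3. **Group × leg mixed models** — a full-factorial model of group
   (stroke/control) and leg (paretic+dominant vs non-paretic+non-dominant,
   the within-subject factor) with a random subject intercept.  With two
   legs per subject this is the classic split-plot design: the group effect
   is tested against the between-subject stratum and leg and group × leg
   against the within-subject stratum, which gives exact F tests under
   balance.  Post-hoc pairwise cell comparisons use sequential Bonferroni
   (Holm) adjustment.
4. **Spearman associations** with the conventional effect-size labels
   (|ρ| ≥ 0.10 small, ≥ 0.30 medium, ≥ 0.50 large).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("lemocot")

__all__ = [
    "ValidationResult",
    "ModelResult",
    "ResidualModel",
    "validate_observation_table",
    "validate_counts",
    "log_transform",
    "speed_accuracy_residuals",
    "fit_group_leg_model",
    "spearman_assoc",
    "holm_adjust",
    "LEG_PAIRING",
]

#: The within-subject factor pairs the first-tested legs across groups.
LEG_PAIRING = {
    "paretic": "leg_a", "dominant": "leg_a",
    "non-paretic": "leg_b", "non-dominant": "leg_b",
}

CLINICAL_COLUMNS = ("fugl_meyer", "tug_s", "walk_10m")


def validate_observation_table(df: pd.DataFrame, require_manual: bool = False) -> pd.DataFrame:
    """Check observation-table invariants; returns the (unmodified) table."""
    for col in ("subject", "group", "leg", "in_count"):
        if col not in df.columns:
            raise ValueError(f"observation table lacks required column {col!r}")
    per_subject = df.groupby("subject").size()
    if (per_subject > 2).any():
        bad = per_subject[per_subject > 2].index[0]
        raise ValueError(f"subject {bad!r} has more than two rows (legs)")
    unknown = set(df["leg"]) - set(LEG_PAIRING)
    if unknown:
        raise ValueError(f"unknown leg labels: {sorted(unknown)}")
    if require_manual and ("manual_count" not in df.columns or df["manual_count"].isna().any()):
        raise ValueError("manual_count must be present for every row")
    return df


def log_transform(values, name: str = "parameter") -> np.ndarray:
    """Natural log of strictly positive values; no silent offsets.

    A non-positive value is a data error and is reported by row rather than
    being shifted away.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(
            f"{name}: non-positive value {arr[bad[0]]!r} at row {int(bad[0])}; "
            "log transform requires positive values"
        )
    return np.log(arr)


# ---------------------------------------------------------------------------
# count validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    """Agreement between the examiner's count and the script count."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    conditional_pseudo_r2: float
    median_difference: float
    limits_of_agreement: tuple[float, float]
    difference_vs_count_slope: float
    difference_vs_count_p: float
    n_rows: int
    n_subjects: int
    model: str = "mixed"  # "mixed" | "ols_fallback"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _ols_line(y: np.ndarray, x: np.ndarray) -> tuple[float, float, tuple, tuple, float]:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    ci = np.nan_to_num(np.asarray(ci), nan=0.0)
    # zero-residual fits have zero-width intervals
    if not np.all(np.isfinite(ci)):
        ci = np.column_stack([fit.params, fit.params])
    return (float(fit.params[1]), float(fit.params[0]),
            (float(ci[1][0]), float(ci[1][1])), (float(ci[0][0]), float(ci[0][1])),
            float(fit.rsquared) if np.isfinite(fit.rsquared) else 1.0)


def validate_counts(table: pd.DataFrame, script_col: str = "in_count",
                    manual_col: str = "manual_count") -> ValidationResult:
    """Mixed-model agreement of manual vs script counts.

    Fits ``manual ~ script`` with a random subject intercept.  If the mixed
    fit is singular (e.g. one row per subject, or zero residual variance as
    in perfect agreement), it falls back to ordinary least squares with a
    logged warning; the conditional pseudo-R² then reduces to the OLS R².
    """
    df = validate_observation_table(table, require_manual=False).copy()
    if manual_col not in df.columns or df[manual_col].isna().any():
        raise ValueError(f"{manual_col} must be present for every row")
    if df["subject"].nunique() < 3:
        raise ValueError("count validation needs at least 3 subjects")
    y = df[manual_col].to_numpy(dtype=float)
    x = df[script_col].to_numpy(dtype=float)

    slope = intercept = None
    model_used = "mixed"
    pseudo_r2 = np.nan
    singular = df.groupby("subject").size().max() < 2
    if not singular:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(f"{manual_col} ~ {script_col}", df, groups=df["subject"])
                fit = md.fit(reml=True)
            var_u = float(np.asarray(fit.cov_re)[0, 0])
            var_e = float(fit.scale)
            fixed_pred = fit.predict(df)
            var_f = float(np.var(fixed_pred))
            denom = var_f + var_u + var_e
            pseudo_r2 = (var_f + var_u) / denom if denom > 0 else 1.0
            params = fit.params
            ci = fit.conf_int()
            slope = float(params[script_col])
            intercept = float(params["Intercept"])
            slope_ci = (float(ci.loc[script_col, 0]), float(ci.loc[script_col, 1]))
            intercept_ci = (float(ci.loc["Intercept", 0]), float(ci.loc["Intercept", 1]))
            if not (np.isfinite(slope) and np.isfinite(pseudo_r2)
                    and np.all(np.isfinite(slope_ci)) and np.all(np.isfinite(intercept_ci))):
                raise ValueError("non-finite mixed-model estimates")
        except Exception as exc:  # singular / non-convergent fit
            logger.warning("mixed count-validation fit failed (%s); "
                           "falling back to OLS", exc)
            slope = None
    if slope is None:
        model_used = "ols_fallback"
        if singular:
            logger.warning("one row per subject: count validation uses OLS")
        slope, intercept, slope_ci, intercept_ci, r2 = _ols_line(y, x)
        pseudo_r2 = r2

    diff = y - x
    median_diff = float(np.median(diff))
    loa = (float(np.percentile(diff, 2.5)), float(np.percentile(diff, 97.5)))
    if np.ptp(diff) == 0 or np.ptp(y) == 0:
        d_slope, d_p = 0.0, 1.0
    else:
        fit_d = sm.OLS(diff, sm.add_constant(y)).fit()
        d_slope, d_p = float(fit_d.params[1]), float(fit_d.pvalues[1])

    # widen degenerate zero-width intervals so they contain the estimate
    slope_ci = (min(slope_ci[0], slope), max(slope_ci[1], slope))
    intercept_ci = (min(intercept_ci[0], intercept), max(intercept_ci[1], intercept))
    return ValidationResult(
        slope=slope, slope_ci=slope_ci, intercept=intercept,
        intercept_ci=intercept_ci,
        conditional_pseudo_r2=float(min(max(pseudo_r2, 0.0), 1.0)),
        median_difference=median_diff, limits_of_agreement=loa,
        difference_vs_count_slope=d_slope, difference_vs_count_p=d_p,
        n_rows=len(df), n_subjects=int(df["subject"].nunique()),
        model=model_used,
    )


# ---------------------------------------------------------------------------
# speed–accuracy residual control
# ---------------------------------------------------------------------------

@dataclass
class ResidualModel:
    """Control-group prediction line and the residuals of all rows."""

    parameter: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    residuals: pd.Series = field(repr=False, default=None)
    n_controls: int = 0
    form: str = "ln_vs_count"


def speed_accuracy_residuals(
    table: pd.DataFrame,
    parameter: str,
    group_col: str = "group",
    control_label: str = "control",
    count_col: str = "in_count",
    form: str = "ln_vs_count",
) -> ResidualModel:
    """Residualise Ln(parameter) on the in-target count via the control fit.

    The prediction line is least squares on control rows only; residuals
    (observed − predicted Ln values) are returned for *every* row, so
    stroke rows are compared against the healthy speed–accuracy trade-off.
    ``form="ln_ln"`` regresses Ln(parameter) on Ln(count) instead.
    """
    df = table
    controls = df[df[group_col] == control_label]
    if len(controls) < 3:
        raise ValueError("need at least 3 control rows to fit the prediction model")
    ln_all = log_transform(df[parameter].to_numpy(), name=parameter)
    x_all = df[count_col].to_numpy(dtype=float)
    if form == "ln_ln":
        x_all = log_transform(x_all, name=count_col)
    elif form != "ln_vs_count":
        raise ValueError(f"unknown model form {form!r}")
    is_control = (df[group_col] == control_label).to_numpy()
    X_c = sm.add_constant(x_all[is_control])
    fit = sm.OLS(ln_all[is_control], X_c).fit()
    pred = fit.params[0] + fit.params[1] * x_all
    resid = ln_all - pred
    bse = np.nan_to_num(fit.bse, nan=0.0)
    return ResidualModel(
        parameter=parameter,
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        slope_se=float(bse[1]), intercept_se=float(bse[0]),
        residuals=pd.Series(resid, index=df.index, name=f"resid_ln_{parameter}"),
        n_controls=int(is_control.sum()), form=form,
    )


# ---------------------------------------------------------------------------
# group x leg mixed models
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """F tests, marginal means and Holm-adjusted post hocs for one outcome."""

    dv: str
    anova: pd.DataFrame  # effect, F, df1, df2, p
    emmeans: pd.DataFrame  # group, leg, mean, se, n
    posthoc: pd.DataFrame  # contrast, estimate, t, df, p_raw, p_holm
    n_subjects: int
    df_method: str = "split-plot error strata (between-/within-subject)"
    adjust_method: str = "holm (sequential Bonferroni)"

    def effect(self, name: str) -> pd.Series:
        return self.anova.set_index("effect").loc[name]


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Sequential-Bonferroni (Holm step-down) adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(np.mean(a) - np.mean(b)), float(res.statistic), float(res.df), float(res.pvalue)


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    res = sps.ttest_rel(a, b)
    return float(np.mean(a - b)), float(res.statistic), float(len(a) - 1), float(res.pvalue)


def fit_group_leg_model(table: pd.DataFrame, dv: str) -> ModelResult:
    """Group × leg split-plot mixed model with Holm post hocs.

    Legs are paired across groups into a two-level within-subject factor
    (paretic with dominant, non-paretic with non-dominant).  Subjects with
    a missing leg or a missing outcome are dropped with a logged warning
    (mirroring a participant whose variable error is undefined).  A
    constant outcome yields the degenerate all-zero F table rather than an
    error.
    """
    df = validate_observation_table(table).copy()
    if dv not in df.columns:
        raise ValueError(f"outcome column {dv!r} not in table")
    df = df[["subject", "group", "leg", dv]].dropna()
    df["leg2"] = df["leg"].map(LEG_PAIRING)
    complete = df.groupby("subject")["leg2"].nunique()
    keep = complete[complete == 2].index
    dropped = sorted(set(df["subject"]) - set(keep))
    if dropped:
        logger.warning("dropping %d subject(s) without both legs for dv=%s: %s",
                       len(dropped), dv, dropped)
    df = df[df["subject"].isin(keep)]
    for g in ("stroke", "control"):
        if df.loc[df["group"] == g, "subject"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 complete subjects")

    emm = (df.groupby(["group", "leg2"])[dv]
             .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
             .reset_index())

    effects = ["group", "leg2", "Interaction"]
    if np.ptp(df[dv].to_numpy(dtype=float)) == 0:
        anova = pd.DataFrame({
            "effect": ["group", "leg", "group:leg"],
            "F": [0.0, 0.0, 0.0], "df1": [1, 1, 1],
            "df2": [df["subject"].nunique() - 2] * 3, "p": [1.0, 1.0, 1.0],
        })
    else:
        import pingouin as pg

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(data=df, dv=dv, within="leg2", between="group",
                                 subject="subject")
        aov = aov.set_index("Source")
        p_col = "p-unc" if "p-unc" in aov.columns else "p_unc"
        anova = pd.DataFrame({
            "effect": ["group", "leg", "group:leg"],
            "F": [float(aov.loc[e, "F"]) for e in effects],
            "df1": [int(aov.loc[e, "DF1"]) for e in effects],
            "df2": [int(aov.loc[e, "DF2"]) for e in effects],
            "p": [float(aov.loc[e, p_col]) for e in effects],
        })

    # post hocs among the four cells
    wide = df.pivot_table(index=["subject", "group"], columns="leg2", values=dv).reset_index()
    sa = wide.loc[wide["group"] == "stroke", "leg_a"].to_numpy(dtype=float)
    sb = wide.loc[wide["group"] == "stroke", "leg_b"].to_numpy(dtype=float)
    ca = wide.loc[wide["group"] == "control", "leg_a"].to_numpy(dtype=float)
    cb = wide.loc[wide["group"] == "control", "leg_b"].to_numpy(dtype=float)
    contrasts = [
        ("stroke:leg_a - stroke:leg_b", _paired_t, (sa, sb)),
        ("control:leg_a - control:leg_b", _paired_t, (ca, cb)),
        ("stroke:leg_a - control:leg_a", _welch_t, (sa, ca)),
        ("stroke:leg_a - control:leg_b", _welch_t, (sa, cb)),
        ("stroke:leg_b - control:leg_a", _welch_t, (sb, ca)),
        ("stroke:leg_b - control:leg_b", _welch_t, (sb, cb)),
    ]
    rows = []
    for name, fn, (a, b) in contrasts:
        if np.ptp(np.concatenate([a, b])) == 0:
            est, t, dof, p = 0.0, 0.0, float(len(a) + len(b) - 2), 1.0
        else:
            est, t, dof, p = fn(a, b)
            if not np.isfinite(p):
                est, t, dof, p = est, 0.0, dof, 1.0
        rows.append({"contrast": name, "estimate": est, "t": t, "df": dof, "p_raw": p})
    posthoc = pd.DataFrame(rows)
    posthoc["p_holm"] = holm_adjust(posthoc["p_raw"].to_numpy())

    return ModelResult(
        dv=dv, anova=anova, emmeans=emm, posthoc=posthoc,
        n_subjects=int(df["subject"].nunique()),
    )


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------

_EFFECT_THRESHOLDS = ((0.50, "large"), (0.30, "medium"), (0.10, "small"))


def spearman_assoc(x, y) -> tuple[float, float, str]:
    """Spearman's ρ with p-value and the conventional effect-size label."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("spearman_assoc needs equal-length inputs with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), "undefined (constant input)"
    rho, p = sps.spearmanr(x, y)
    label = "negligible"
    for thr, lab in _EFFECT_THRESHOLDS:
        if abs(rho) >= thr:
            label = lab
            break
    return float(rho), float(p), label
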