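"""Cohort-level statistics: group comparisons and univariate regression.

The analysis layer mirrors a two-group observational study: per-subject
descriptor and regional-stasis records are collected in a cohort table
(a pandas DataFrame), group means are compared with two-sample t-tests
(pooled variance by default, Welch by flag), and the association between
residence time and each geometrical/functional parameter is assessed by
univariate ordinary least squares with R², a two-sided slope p-value and
a 95% confidence band for the mean prediction.  No multiple-testing
correction is applied — each univariate comparison is reported at the 5%
level on its own.  A leave-one-out leverage report flags associations
whose significance hinges on a single observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TTestResult",
    "RegressionResult",
    "two_sample_ttest",
    "univariate_regression",
    "group_summary",
    "shape_subgroup_analysis",
    "validate_cohort_table",
]

ALPHA = 0.05  # significance level

GROUP_LABELS = ("control", "af")


@dataclass
class TTestResult:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float
    variant: str
    significant: bool

    def __str__(self) -> str:
        star = " *" if self.significant else ""
        return (
            f"{self.mean_a:.3g} ± {self.sd_a:.3g} (n={self.n_a}) vs "
            f"{self.mean_b:.3g} ± {self.sd_b:.3g} (n={self.n_b}): "
            f"t={self.t:.3g}, p={self.p:.3g}{star}"
        )


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], variant: str = "pooled"
) -> TTestResult:
    """Two-sample t-test between independent samples.

    ``variant`` is ``"pooled"`` (equal-variance, the default) or
    ``"welch"``.  Identical samples give ``t = 0, p = 1``; samples with
    fewer than two values are an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2 for a t-test")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    t, p = float(t), float(p)
    if not np.isfinite(t):  # zero variance in both samples, equal means
        t, p = 0.0, 1.0
    return TTestResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        t=t,
        p=p,
        variant=variant,
        significant=bool(p < ALPHA),
    )


@dataclass
class RegressionResult:
    """Univariate OLS fit of y on x with inference on the slope."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    slope_se: float
    _model: object = field(repr=False, compare=False, default=None)

    def ci_band(self, x_eval: np.ndarray, alpha: float = ALPHA):
        """95% (by default) confidence band for the mean prediction,
        evaluable at any x.  Returns ``(fit, lower, upper)``."""
        x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
        X = sm.add_constant(x_eval, has_constant="add")
        pred = self._model.get_prediction(X)
        frame = pred.summary_frame(alpha=alpha)
        return (
            frame["mean"].to_numpy(),
            frame["mean_ci_lower"].to_numpy(),
            frame["mean_ci_upper"].to_numpy(),
        )

    def leave_one_out(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        """Refit without each observation in turn.

        Flags influential points: if the full fit is significant at 5%
        but removing one point is not (or vice versa), that point drives
        the conclusion.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rows = []
        for i in range(len(x)):
            keep = np.ones(len(x), bool)
            keep[i] = False
            sub = univariate_regression(x[keep], y[keep])
            rows.append(
                {
                    "excluded": i,
                    "slope": sub.slope,
                    "p_slope": sub.p_slope,
                    "significant": sub.p_slope < ALPHA,
                    "flips_significance": (sub.p_slope < ALPHA)
                    != (self.p_slope < ALPHA),
                }
            )
        return pd.DataFrame(rows)

    @property
    def significant(self) -> bool:
        return self.p_slope < ALPHA

    def summary(self) -> str:
        return (
            f"y = {self.slope:.4g} x + {self.intercept:.4g}  "
            f"(R² = {self.r_squared:.3f}, p = {self.p_slope:.3g}, n = {self.n})"
        )


def univariate_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of ``y`` on a single predictor ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_slope=float(model.pvalues[1]),
        n=len(x),
        slope_se=float(model.bse[1]),
        _model=model,
    )


def validate_cohort_table(
    table: pd.DataFrame, required: Optional[Sequence[str]] = None
) -> None:
    """Check cohort-table invariants: unique subject ids, known group
    labels, and (optionally) completeness of required fields, naming the
    offending subject and field."""
    if "subject_id" in table.columns:
        ids = table["subject_id"]
    else:
        ids = table.index.to_series()
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    if "group" not in table.columns:
        raise ValueError("cohort table needs a 'group' column")
    bad = set(table["group"].unique()) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    for col in required or []:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
        if table[col].isna().any():
            subj = ids[table[col].isna()].iloc[0]
            raise ValueError(f"subject {subj!r}: missing value for field {col!r}")


def group_summary(
    table: pd.DataFrame,
    fields: Optional[Sequence[str]] = None,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Mean ± SD per group with t-test p-values, one row per field.

    The returned frame has columns ``control``, ``af`` (formatted
    ``mean ± SD``), ``p_value`` and ``significant`` (the bold-at-5% flag
    of a printed table).
    """
    if fields is None:
        fields = [
            c
            for c in table.columns
            if c not in ("group", "subject_id", "sex", "laa_shape_label")
            and np.issubdtype(table[c].dtype, np.number)
        ]
    for g in GROUP_LABELS:
        if (table["group"] == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    validate_cohort_table(table, required=fields)
    rows = {}
    for fieldname in fields:
        a = table.loc[table["group"] == "control", fieldname].to_numpy(float)
        b = table.loc[table["group"] == "af", fieldname].to_numpy(float)
        res = two_sample_ttest(a, b, variant=variant)
        rows[fieldname] = {
            "control": f"{res.mean_a:.3g} ± {res.sd_a:.2g}",
            "af": f"{res.mean_b:.3g} ± {res.sd_b:.2g}",
            "p_value": res.p,
            "significant": res.significant,
        }
    return pd.DataFrame(rows).T


def shape_subgroup_analysis(
    table: pd.DataFrame,
    rt_fields: Sequence[str] = (
        "rt_la_with_laa",
        "rt_la_without_laa",
        "rt_laa",
    ),
) -> pd.DataFrame:
    """Residence time by appendage shape class within each group.

    Emits mean ± SD per (group, shape) subgroup and a t-test p-value
    only where both subgroups have n >= 2 — with a single subject in a
    subgroup only descriptive values are reported, never a p-value.
    """
    if "laa_shape_label" not in table.columns:
        raise ValueError("cohort table needs a 'laa_shape_label' column")
    rows = []
    for group in GROUP_LABELS:
        sub = table[table["group"] == group]
        if len(sub) == 0:
            continue
        cw = sub[sub["laa_shape_label"] == "chicken_wing"]
        ncw = sub[sub["laa_shape_label"] != "chicken_wing"]
        for fieldname in rt_fields:
            row = {"group": group, "field": fieldname,
                   "n_cw": len(cw), "n_non_cw": len(ncw)}
            for name, part in (("cw", cw), ("non_cw", ncw)):
                vals = part[fieldname].to_numpy(float) if len(part) else np.array([])
                row[f"mean_{name}"] = vals.mean() if len(vals) else np.nan
                row[f"sd_{name}"] = (
                    vals.std(ddof=1) if len(vals) >= 2 else np.nan
                )
            if len(cw) >= 2 and len(ncw) >= 2:
                res = two_sample_ttest(
                    cw[fieldname].to_numpy(float), ncw[fieldname].to_numpy(float)
                )
                row["p_value"] = res.p
            else:
                row["p_value"] = np.nan  # descriptive only
            rows.append(row)
    return pd.DataFrame(rows)
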