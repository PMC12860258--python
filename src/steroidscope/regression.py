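"""Sympercent regression of steroid excretion and cohort summary tables.

A *sympercent* is 100 x a difference in natural logs: regressing
``ln(steroid)`` on a binary contrast plus age, sex and BMI, the contrast
coefficient ``b`` scaled by 100 gives a percentage change that is
symmetric in direction (a +10 s% shift and a -10 s% shift multiply the
excretion by e^0.1 and e^-0.1 respectively).  One ordinary-least-squares
model per steroid; p-values are reported unadjusted across the 17 models.

The cohort summary reproduces a standard clinical "Table 1": per-group n,
% women, median (IQR) age and BMI, comorbidity prevalences, and trend
p-values (one-way ANOVA for numeric variables, chi-square for categorical).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import CohortTable, SteroidMatrix, ValidationError


def sympercent_regression(steroids: SteroidMatrix, cohort: CohortTable,
                          contrast: str | pd.Series,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-steroid OLS of ln(excretion) on [contrast, age, sex(F=1), BMI].

    ``contrast`` is either a boolean cohort column name or an aligned
    binary series.  Zero excretions are replaced by half the smallest
    positive value of that metabolite (logged via a warning).  Returns a
    table with the sympercent estimate ``s = 100 b``, its normal-theory
    95 % CI (in sympercents), the unadjusted p-value and n.
    """
    df = cohort.df
    mat = steroids.aligned_to(cohort).df
    if isinstance(contrast, str):
        cvec = df[contrast]
    else:
        cvec = pd.Series(np.asarray(contrast), index=df.index)
    cvec = cvec.astype(float)
    if cvec.nunique() < 2:
        raise ValidationError("contrast variable is constant")

    Xcov = pd.DataFrame({
        "contrast": cvec.to_numpy(),
        "age": df["age"].to_numpy(),
        "sex_F": (df["sex"] == "F").astype(float).to_numpy(),
        "bmi": df["bmi"].to_numpy(),
    }, index=df["patient_id"]).loc[mat.index]
    dropped = [c for c in Xcov.columns if c != "contrast" and Xcov[c].nunique() < 2]
    if dropped:
        warnings.warn(f"dropping zero-variance covariate(s): {dropped}", stacklevel=2)
        Xcov = Xcov.drop(columns=dropped)
    design = sm.add_constant(Xcov)

    rows = []
    for s in mat.columns:
        v = mat[s].to_numpy(float)
        if (v == 0).all():
            raise ValidationError(f"steroid {s} is all zero")
        if (v <= 0).any():
            repl = v[v > 0].min() / 2.0
            warnings.warn(f"{s}: {(v <= 0).sum()} zero value(s) replaced by {repl:g}",
                          stacklevel=2)
            v = np.where(v <= 0, repl, v)
        fit = sm.OLS(np.log(v), design).fit()
        b = fit.params["contrast"]
        lo, hi = fit.conf_int(alpha=alpha).loc["contrast"]
        rows.append(dict(steroid=s, sympercent=100.0 * b,
                         ci_low=100.0 * lo, ci_high=100.0 * hi,
                         p_value=fit.pvalues["contrast"], n=int(fit.nobs)))
    out = pd.DataFrame(rows).set_index("steroid")
    out.attrs["note"] = "p-values unadjusted; sex coded F=1/M=0"
    return out


def _pct(k: int, n: int) -> float:
    """Percentage at 1 decimal, round half to even."""
    return float(np.round(100.0 * k / n, 1))


def summarise_cohort(cohort: CohortTable) -> dict:
    """Group-wise clinical summary with ANOVA / chi-square trend p-values.

    Returns a dict with a per-group table (including a pooled MACS row =
    MACS1 + MACS2 and a Total row) and trend p-values computed across the
    four diagnostic groups.
    """
    df = cohort.df
    group_order = [g for g in ("NFAT", "MACS1", "MACS2", "CS")
                   if g in set(df["group"])]
    if not group_order:
        raise ValidationError("no recognised diagnostic groups")
    for g in group_order:
        if (df["group"] == g).sum() == 0:
            raise ValidationError(f"empty group {g}")

    flags = [c for c in ("hypertension", "t2d", "dyslipidaemia", "bilateral")
             if c in df.columns and df[c].notna().all()]

    def one(sub: pd.DataFrame) -> dict:
        rec = {"n": len(sub), "pct_women": _pct(int((sub["sex"] == "F").sum()), len(sub))}
        for col in ("age", "bmi"):
            q1, med, q3 = np.percentile(sub[col], [25, 50, 75])
            rec[f"{col}_median"] = float(med)
            rec[f"{col}_iqr"] = (float(q1), float(q3))
        for f in flags:
            rec[f"pct_{f}"] = _pct(int(sub[f].sum()), len(sub))
        return rec

    table = {g: one(df[df["group"] == g]) for g in group_order}
    macs = df[df["group"].isin(["MACS1", "MACS2"])]
    if len(macs):
        table["MACS"] = one(macs)
    table["Total"] = one(df)

    def _chi2(cont: np.ndarray) -> float:
        # a category entirely absent (e.g. a group that is 100% women)
        # leaves the test undefined
        if (cont.sum(axis=1) == 0).any():
            return float("nan")
        return float(stats.chi2_contingency(cont).pvalue)

    pvals: dict[str, float] = {}
    by_group = [df[df["group"] == g] for g in group_order]
    if len(group_order) > 1:
        for col in ("age", "bmi"):
            pvals[col] = float(stats.f_oneway(*[g[col] for g in by_group]).pvalue)
        cont = np.array([[(g["sex"] == "F").sum(), (g["sex"] == "M").sum()]
                         for g in by_group]).T
        pvals["sex"] = _chi2(cont)
        for f in flags:
            cont = np.array([[g[f].sum(), (~g[f].astype(bool)).sum()]
                             for g in by_group]).T
            pvals[f] = _chi2(cont)

    return {"groups": table, "p_values": pvals}
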