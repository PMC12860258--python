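"""Untargeted feature-table preprocessing.

Fixed order, enforced through the table's ``stage`` attribute:

1. :func:`qc_rsc_correct` — quality-control robust spline correction of
   injection-order intensity drift, fitted on pooled-QC samples only;
2. :func:`filter_features` — remove low-quality features (QC RSD > 30 % or
   detected in < 90 % of QC samples);
3. :func:`normalise_log` — natural log then per-feature z-score over study
   samples.

The drift model is a per-feature cubic smoothing spline of QC intensity
versus injection order, iteratively reweighted (Tukey bisquare) to
down-weight outlying QC injections; the smoothing parameter is chosen by
generalised cross-validation.  Every sample intensity is divided by the
spline value at its injection order and rescaled by the feature's median QC
intensity, so the QC median is invariant under correction.  With fewer than
4 QC injections the spline degenerates and linear interpolation is used.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .datamodel import FeatureTable

RSD_MAX = 30.0          # % — features above are removed
DETECTION_MIN = 0.90    # fraction of QC samples with a non-missing value


@dataclasses.dataclass
class DriftFit:
    """Per-feature drift model evaluated over the injection-order axis."""

    orders: np.ndarray                   # all injection orders (sorted)
    curves: pd.DataFrame                 # features x orders spline values
    reference: pd.Series                 # per-feature median QC intensity
    uncorrected: list[str]               # features left uncorrected (flat/invalid)


@dataclasses.dataclass
class FilterReport:
    """Per-feature QC quality metrics and keep/remove decision."""

    table: pd.DataFrame  # columns: rsd, detection, kept, reason

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def _robust_spline(x: np.ndarray, y: np.ndarray, eval_at: np.ndarray,
                   n_iter: int = 3) -> np.ndarray:
    """GCV smoothing spline with bisquare reweighting; linear if < 4 points."""
    if len(x) < 4:
        return np.interp(eval_at, x, y)
    w = np.ones_like(y)
    fit = None
    for _ in range(n_iter):
        try:
            spl = make_smoothing_spline(x, y, w=w)
        except Exception:
            return np.interp(eval_at, x, y)
        fit = spl(x)
        resid = y - fit
        s = np.median(np.abs(resid)) / 0.6745
        if s <= 1e-12 * max(1.0, np.median(np.abs(y))):
            break
        u = np.clip(resid / (4.685 * s), -1, 1)
        w = (1 - u ** 2) ** 2
        w = np.maximum(w, 1e-6)
    spl = make_smoothing_spline(x, y, w=w)
    return spl(np.clip(eval_at, x.min(), x.max()))


def qc_rsc_correct(table: FeatureTable) -> tuple[FeatureTable, DriftFit]:
    """QC-robust-spline correction of intensity drift, per feature.

    Missing cells stay missing; a feature whose spline evaluates <= 0 at any
    sample's injection order is flagged and left uncorrected (with a
    warning) rather than producing negative intensities.
    """
    table.require_stage("raw")
    qc_mask = table.is_qc.to_numpy()
    if qc_mask.sum() < 2:
        raise ValueError("QC-RSC requires at least 2 QC samples")

    orders = table.metadata["injection_order"].to_numpy()
    ab = table.abundances
    order_axis = np.sort(np.unique(orders))
    corrected = ab.copy()
    curves = {}
    uncorrected: list[str] = []
    reference = ab.loc[qc_mask].median()

    for feat in ab.columns:
        y_all = ab[feat].to_numpy()
        qc_obs = qc_mask & ~np.isnan(y_all)
        if qc_obs.sum() < 2:
            uncorrected.append(feat)
            curves[feat] = np.full_like(order_axis, np.nan, dtype=float)
            continue
        x = orders[qc_obs].astype(float)
        idx = np.argsort(x)
        x, yq = x[idx], y_all[qc_obs][idx]
        curve = _robust_spline(x, yq, order_axis.astype(float))
        curves[feat] = curve
        at_samples = curve[np.searchsorted(order_axis, orders)]
        if np.any(at_samples <= 0):
            uncorrected.append(feat)
            continue
        # reference level chosen so the QC median is exactly invariant
        ratio_qc = y_all[qc_obs] / at_samples[qc_obs]
        ref = reference[feat] / np.median(ratio_qc)
        corrected[feat] = y_all / at_samples * ref

    if uncorrected:
        warnings.warn(
            f"{len(uncorrected)} feature(s) left uncorrected "
            "(insufficient QCs or non-positive spline)", stacklevel=2)
    fit = DriftFit(order_axis, pd.DataFrame(curves, index=order_axis).T,
                   reference, uncorrected)
    return table.with_abundances(corrected, "corrected"), fit


def filter_features(table: FeatureTable) -> tuple[FeatureTable, FilterReport]:
    """Remove features with QC RSD > 30 % or QC detection < 90 %.

    RSD is 100*sd/mean over non-missing QC intensities (sample sd, n-1);
    detection is the fraction of QC samples with a non-missing value.
    Features with < 2 non-missing QC values cannot be assessed and are
    removed with reason ``detection``.
    """
    table.require_stage("corrected", "filtered")
    qc = table.qc
    if qc.empty:
        raise ValueError("feature filtering requires QC samples")
    n_qc = len(qc)
    rows = []
    for feat in table.abundances.columns:
        v = qc[feat].dropna().to_numpy()
        detection = len(v) / n_qc
        if len(v) < 2:
            rows.append((feat, np.nan, detection, False, "detection"))
            continue
        mean = v.mean()
        rsd = 100.0 * v.std(ddof=1) / mean if mean > 0 else np.inf
        if detection < DETECTION_MIN:
            rows.append((feat, rsd, detection, False, "detection"))
        elif rsd > RSD_MAX:
            rows.append((feat, rsd, detection, False, "rsd"))
        else:
            rows.append((feat, rsd, detection, True, "kept"))
    rep = pd.DataFrame(rows, columns=["feature", "rsd", "detection", "kept",
                                      "reason"]).set_index("feature")
    kept = list(rep.index[rep["kept"]])
    out = table.with_abundances(table.abundances[kept], "filtered")
    return out, FilterReport(rep)


def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature QC relative standard deviation (%)."""
    qc = table.qc
    mean = qc.mean()
    return 100.0 * qc.std(ddof=1) / mean


def normalise_log(table: FeatureTable) -> FeatureTable:
    """Natural log, then per-feature z-score over the study samples.

    Non-positive abundances are treated as missing (warned); zero-variance
    features are dropped (warned).  QC rows are transformed with the
    study-sample mean/sd so the output stays a rectangular table, but all
    downstream statistics use study rows only.
    """
    table.require_stage("filtered")
    ab = table.abundances.copy()
    nonpos = (ab <= 0).to_numpy(na_value=False)
    if nonpos.any():
        warnings.warn(f"{int(nonpos.sum())} non-positive abundance cell(s) "
                      "treated as missing", stacklevel=2)
        ab = ab.mask(ab <= 0)
    logged = np.log(ab)
    study = logged.loc[~table.is_qc]
    mu = study.mean()
    sd = study.std(ddof=1)
    degenerate = sd.index[(sd <= 0) | sd.isna()]
    if len(degenerate):
        warnings.warn(f"dropping {len(degenerate)} zero-variance feature(s)",
                      stacklevel=2)
        logged = logged.drop(columns=degenerate)
        mu, sd = mu.drop(degenerate), sd.drop(degenerate)
    z = (logged - mu) / sd
    return table.with_abundances(z, "normalised")
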