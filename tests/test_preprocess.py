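"""QC-RSC drift correction, quality filters, normalisation."""

import numpy as np
import pandas as pd
import pytest

from steroidscope.datamodel import FeatureTable, PipelineOrderError
from steroidscope.preprocess import (filter_features, normalise_log, qc_rsc_correct,
                                     qc_rsd)


def _table(ab_dict, qc_flags, orders):
    ids = [f"s{i}" for i in range(len(orders))]
    ab = pd.DataFrame(ab_dict, index=ids)
    meta = pd.DataFrame({"sample_id": ids,
                         "sample_type": ["QC" if q else "study" for q in qc_flags],
                         "injection_order": orders,
                         "assay": "lipidomics", "ion_mode": "pos"})
    return FeatureTable(ab, meta)


class TestDriftCorrection:
    def test_constant_qc_intensities_give_identity(self):
        t = _table({"f": [50.0, 50.0, 50.0, 50.0, 33.0]},
                   [1, 1, 1, 1, 0], [1, 5, 9, 13, 7])
        corrected, fit = qc_rsc_correct(t)
        np.testing.assert_allclose(corrected.abundances["f"], t.abundances["f"])
        assert not fit.uncorrected

    def test_linear_qc_trend_interpolates_exactly(self):
        """QCs 100/110/120/130 at orders 1/11/21/31; the spline interpolates
        the linear trend, so a sample at order 16 is rescaled by
        spline(16)=115 and the correction returns exactly the raw value."""
        t = _table({"f": [100.0, 110.0, 120.0, 130.0, 77.0]},
                   [1, 1, 1, 1, 0], [1, 11, 21, 31, 16])
        corrected, fit = qc_rsc_correct(t)
        assert corrected.abundances.loc["s4", "f"] == pytest.approx(77.0, abs=1e-9)

    def test_drift_removal_reduces_qc_rsd(self, preprocessed_drift):
        pre = qc_rsd(preprocessed_drift["raw"])
        post = qc_rsd(preprocessed_drift["corrected"])
        assert (post < pre).mean() >= 0.95

    def test_qc_median_invariant(self, preprocessed_drift):
        raw, corrected = preprocessed_drift["raw"], preprocessed_drift["corrected"]
        pd.testing.assert_series_equal(raw.qc.median(), corrected.qc.median())

    def test_missing_cells_stay_missing(self, small_sim):
        raw = small_sim["features"]
        corrected, _ = qc_rsc_correct(raw)
        assert raw.abundances.isna().equals(corrected.abundances.isna())

    def test_requires_two_qcs(self):
        t = _table({"f": [1.0, 2.0]}, [1, 0], [1, 2])
        with pytest.raises(ValueError, match="2 QC"):
            qc_rsc_correct(t)


class TestFilters:
    def _planted(self):
        rng = np.random.default_rng(7)
        n_qc, n_study = 12, 8
        cols = {}
        for j in range(30):
            cols[f"good{j}"] = np.r_[rng.normal(100, 2, n_qc),
                                     rng.normal(100, 30, n_study)]
        for j in range(10):  # high RSD in QCs
            cols[f"noisy{j}"] = np.r_[rng.normal(100, 60, n_qc).clip(1),
                                      rng.normal(100, 30, n_study)]
        for j in range(5):   # poor QC detection
            v = np.r_[rng.normal(100, 2, n_qc), rng.normal(100, 30, n_study)]
            v[:3] = np.nan
            cols[f"sparse{j}"] = v
        t = _table(cols, [1] * n_qc + [0] * n_study,
                   list(range(1, n_qc + n_study + 1)))
        t.stage = "corrected"
        return t

    def test_hand_arithmetic_rsd(self):
        t = _table({"a": [10.0, 10.0, 10.0, 5.0], "b": [10.0, 20.0, 30.0, 5.0]},
                   [1, 1, 1, 0], [1, 2, 3, 4])
        t.stage = "corrected"
        kept, rep = filter_features(t)
        assert rep.table.loc["a", "rsd"] == 0 and rep.table.loc["a", "kept"]
        assert rep.table.loc["b", "rsd"] == pytest.approx(50.0)
        assert rep.table.loc["b", "reason"] == "rsd"
        assert list(kept.abundances.columns) == ["a"]

    def test_exact_boundaries_are_kept(self):
        # RSD exactly 30% and detection exactly 90% survive (> and < rules)
        qc_vals = np.array([70.0, 100.0, 130.0])  # mean 100, sd 30 -> RSD 30
        t = _table({"edge": np.r_[qc_vals, [50.0]]}, [1, 1, 1, 0], [1, 2, 3, 4])
        t.stage = "corrected"
        _, rep = filter_features(t)
        assert rep.table.loc["edge", "rsd"] == pytest.approx(30.0)
        assert rep.table.loc["edge", "kept"]
        v = np.r_[np.full(9, 100.0), [np.nan], [50.0]]
        t = _table({"det90": v}, [1] * 10 + [0], list(range(1, 12)))
        t.stage = "corrected"
        _, rep = filter_features(t)
        assert rep.table.loc["det90", "detection"] == pytest.approx(0.9)
        assert rep.table.loc["det90", "kept"]

    def test_planted_failures_removed_exactly(self):
        t = self._planted()
        kept, rep = filter_features(t)
        removed = set(rep.table.index[~rep.table["kept"]])
        assert removed == {f"noisy{j}" for j in range(10)} | {
            f"sparse{j}" for j in range(5)}
        assert (rep.table.loc[[f"noisy{j}" for j in range(10)], "reason"]
                == "rsd").all()
        assert (rep.table.loc[[f"sparse{j}" for j in range(5)], "reason"]
                == "detection").all()

    def test_filters_idempotent(self, preprocessed_drift):
        filtered = preprocessed_drift["filtered"]
        again, rep = filter_features(filtered)
        pd.testing.assert_frame_equal(filtered.abundances, again.abundances)
        assert rep.table["kept"].all()


class TestNormalise:
    def test_two_point_zscore(self):
        t = _table({"f": [5.0, 5.0, 1.0, np.e ** 2]},
                   [1, 1, 0, 0], [1, 2, 3, 4])
        t.stage = "filtered"
        norm = normalise_log(t)
        study = norm.study["f"].to_numpy()
        np.testing.assert_allclose(study, [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_zero_variance_feature_dropped(self):
        t = _table({"flat": [np.e, np.e, np.e, np.e], "ok": [1.0, 2.0, 3.0, 4.0]},
                   [1, 1, 0, 0], [1, 2, 3, 4])
        t.stage = "filtered"
        with pytest.warns(UserWarning, match="zero-variance"):
            norm = normalise_log(t)
        assert list(norm.abundances.columns) == ["ok"]

    def test_study_mean_zero_sd_one(self, preprocessed_drift):
        study = preprocessed_drift["normalised"].study
        assert study.mean().abs().max() < 1e-10
        assert (study.std(ddof=1) - 1).abs().max() < 1e-10

    def test_pipeline_order_enforced(self, small_sim):
        raw = small_sim["features"]
        with pytest.raises(PipelineOrderError):
            filter_features(raw)
        with pytest.raises(PipelineOrderError):
            normalise_log(raw)
        corrected, _ = qc_rsc_correct(raw)
        with pytest.raises(PipelineOrderError):
            normalise_log(corrected)
        with pytest.raises(PipelineOrderError):
            qc_rsc_correct(corrected)
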