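"""Shared fixtures: small synthetic data sets reused across test modules.

Heavy fixtures are session-scoped so each is generated once per run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from steroidscope import preprocess
from steroidscope.simulate import (SimConfig, simulate_cohort,
                                   simulate_feature_table)


@pytest.fixture(scope="session")
def small_sim():
    """Small cohort + steroid matrix + feature table (fast, shared)."""
    cfg = SimConfig(n_per_group=(30, 20, 20, 15), n_features=60, seed=1)
    cohort, steroids, truth_c = simulate_cohort(cfg)
    features, truth_f = simulate_feature_table(cfg, cohort)
    return dict(cfg=cfg, cohort=cohort, steroids=steroids,
                features=features, truth_c=truth_c, truth_f=truth_f)


@pytest.fixture(scope="session")
def big_cohort():
    """n = 400 per group, for parameter-recovery checks."""
    cfg = SimConfig(n_per_group=(400, 400, 400, 400), seed=11)
    cohort, steroids, truth = simulate_cohort(cfg)
    return dict(cfg=cfg, cohort=cohort, steroids=steroids, truth=truth)


@pytest.fixture(scope="session")
def preprocessed_drift():
    """Feature table with strong drift, corrected + filtered + normalised."""
    cfg = SimConfig(n_per_group=(30, 20, 20, 15), n_features=300, seed=3,
                    drift_amplitude=0.5, missing_model=(-30.0, 1.0))
    cohort, _, _ = simulate_cohort(cfg)
    raw, truth = simulate_feature_table(cfg, cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected, fit = preprocess.qc_rsc_correct(raw)
        filtered, report = preprocess.filter_features(corrected)
        normalised = preprocess.normalise_log(filtered)
    return dict(cfg=cfg, cohort=cohort, raw=raw, corrected=corrected,
                filtered=filtered, normalised=normalised, fit=fit,
                report=report, truth=truth)


@pytest.fixture(scope="session")
def selection_state():
    """Full-width untargeted pipeline state for consensus selection.

    Study-condition sizes (104/70/70/47 samples, 2000 features, 50 planted
    informative features) with preprocessing, PPCA fit and M=3 imputations.
    """
    from steroidscope import ppca

    cfg = SimConfig(seed=5)
    cohort, _, _ = simulate_cohort(cfg)
    raw, truth = simulate_feature_table(cfg, cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected, _ = preprocess.qc_rsc_correct(raw)
        filtered, _ = preprocess.filter_features(corrected)
        normalised = preprocess.normalise_log(filtered)
    X = normalised.study.to_numpy()
    k = ppca.choose_k(X, k_max=10)
    model = ppca.fit_ppca(X, k=k, max_iter=100)
    imps = ppca.draw_imputations(model, X, M=3, seed=99)
    y = (cohort.df.set_index("patient_id")
         .loc[normalised.study.index, "group"].to_numpy())
    return dict(cfg=cfg, cohort=cohort, truth=truth, corrected=corrected,
                normalised=normalised, X=X, imps=imps, y=y,
                names=list(normalised.abundances.columns))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
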