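"""Consensus feature selection and fold-change summaries."""

import numpy as np
import pandas as pd
import pytest

from steroidscope.datamodel import AnnotationMap, FeatureTable
from steroidscope.lvq import LVQConfig
from steroidscope.ppca import ImputationSet, PPCAModel
from steroidscope.selection import consensus_select, fold_changes


def _imps(mats):
    model = PPCAModel(W=np.zeros((mats[0].shape[1], 1)),
                      mu=np.zeros(mats[0].shape[1]), sigma2=1.0, k=1,
                      loglik_trace=np.zeros(1), converged=True)
    return ImputationSet(matrices=[np.asarray(m, float) for m in mats],
                         model=model, seeds=list(range(len(mats))))


def _planted_matrix(rng, n=120, p=60, planted=(3, 7, 11), shift=2.5):
    X = rng.normal(0, 1, (n, p))
    y = np.repeat(["NFAT", "MACS1", "MACS2", "CS"], n // 4)
    grade = {"NFAT": 0.0, "MACS1": 1 / 3, "MACS2": 2 / 3, "CS": 1.0}
    for j in planted:
        X[:, j] += shift * np.array([grade[g] for g in y])
    return X, y


class TestConsensus:
    def test_identical_matrices_reduce_to_single_ranking(self, rng):
        X, y = _planted_matrix(rng)
        names = [f"f{j}" for j in range(X.shape[1])]
        sel = consensus_select(_imps([X, X]), y, names,
                               LVQConfig(epochs=60, omega_rank=3),
                               top_n=10, n_runs=3, seed=0)
        for clf in ("gmlvq", "ordinal"):
            r0, r1 = sel.rankings[clf]
            assert list(r0) == list(r1)
            assert sel.consensus[clf] == set(r0[:10])

    def test_planted_features_recovered_small_scale(self, rng):
        X, y = _planted_matrix(rng)
        X2 = X + rng.normal(0, 0.1, X.shape)   # mild imputation-like noise
        names = [f"f{j}" for j in range(X.shape[1])]
        sel = consensus_select(_imps([X, X2]), y, names, top_n=10,
                               n_runs=3, seed=1)
        assert {"f3", "f7", "f11"} <= sel.intersection

    def test_venn_inclusion_exclusion_exact(self, rng):
        X, y = _planted_matrix(rng)
        names = [f"f{j}" for j in range(X.shape[1])]
        sel = consensus_select(_imps([X, X]), y, names, top_n=15, n_runs=2, seed=2)
        v = sel.venn
        assert v["both"] == len(sel.intersection)
        assert v["gmlvq"] + v["ordinal"] - v["both"] == v["union"]
        assert v["gmlvq_only"] == v["gmlvq"] - v["both"]
        assert sel.intersection <= sel.consensus["gmlvq"]
        assert sel.intersection <= sel.consensus["ordinal"]

    def test_monotone_in_top_n(self, rng):
        X, y = _planted_matrix(rng)
        names = [f"f{j}" for j in range(X.shape[1])]
        small = consensus_select(_imps([X, X]), y, names, top_n=10, n_runs=2, seed=3)
        large = consensus_select(_imps([X, X]), y, names, top_n=25, n_runs=2, seed=3)
        for clf in ("gmlvq", "ordinal"):
            assert small.consensus[clf] <= large.consensus[clf]
        assert small.intersection <= large.intersection

    def test_permutation_invariant_to_column_order(self, rng):
        X, y = _planted_matrix(rng, p=30, planted=(2, 9))
        names = [f"f{j}" for j in range(X.shape[1])]
        perm = rng.permutation(X.shape[1])
        sel_a = consensus_select(_imps([X, X]), y, names, top_n=8, n_runs=2, seed=4)
        sel_b = consensus_select(_imps([X[:, perm], X[:, perm]]), y,
                                 [names[j] for j in perm], top_n=8, n_runs=2, seed=4)
        assert sel_a.intersection == sel_b.intersection

    def test_top_n_clamped_with_warning(self, rng):
        X, y = _planted_matrix(rng, p=20, planted=(1,))
        names = [f"f{j}" for j in range(X.shape[1])]
        with pytest.warns(UserWarning, match="clamping"):
            sel = consensus_select(_imps([X, X]), y, names, top_n=500,
                                   n_runs=2, seed=5)
        assert sel.top_n == 20


def _fc_table(values, y, stage="corrected"):
    n = len(values)
    ids = [f"s{i}" for i in range(n)]
    ab = pd.DataFrame(values, index=ids,
                      columns=[f"f{j}" for j in range(values.shape[1])])
    meta = pd.DataFrame({"sample_id": ids, "sample_type": "study",
                         "injection_order": range(1, n + 1),
                         "assay": "lipidomics", "ion_mode": "pos"})
    t = FeatureTable(ab, meta)
    t.stage = stage
    return t


class TestFoldChanges:
    def _ann(self, p, cls="glycerophospholipid"):
        feats = [f"f{j}" for j in range(p)]
        return AnnotationMap({f: frozenset([cls]) for f in feats},
                             frozenset(feats))

    def test_identical_groups_give_zero_fold_change(self, rng):
        vals = np.tile(rng.uniform(10, 100, 25), (40, 1))
        y = np.repeat(["NFAT", "MACS1"], 20)
        res = fold_changes(_fc_table(vals, y), y, self._ann(25),
                           {f"f{j}" for j in range(25)})
        np.testing.assert_allclose(res.per_feature["MACS1"], 0.0, atol=1e-12)

    def test_exact_doubling_gives_log2_fc_one(self, rng):
        base = rng.uniform(10, 100, 25)
        vals = np.vstack([np.tile(base, (20, 1)), np.tile(2 * base, (20, 1))])
        y = np.repeat(["NFAT", "CS"], 20)
        res = fold_changes(_fc_table(vals, y), y, self._ann(25),
                           {f"f{j}" for j in range(25)})
        np.testing.assert_allclose(res.per_feature["CS"], 1.0, atol=1e-12)

    def test_graded_shifts_give_increasing_class_medians(self, rng):
        base = rng.uniform(10, 100, 30)
        blocks = []
        for g, shift in (("NFAT", 1.0), ("MACS1", 2.0), ("MACS2", 4.0), ("CS", 8.0)):
            blocks.append(np.tile(base * shift, (15, 1))
                          * rng.uniform(0.95, 1.05, (15, 30)))
        y = np.repeat(["NFAT", "MACS1", "MACS2", "CS"], 15)
        res = fold_changes(_fc_table(np.vstack(blocks), y), y, self._ann(30),
                           {f"f{j}" for j in range(30)})
        med = (res.per_class.query("stratum == 'all'")
               .set_index("group")["median"])
        assert med["MACS1"] < med["MACS2"] < med["CS"]

    def test_small_classes_omitted(self, rng):
        vals = rng.uniform(10, 100, (20, 10))
        y = np.repeat(["NFAT", "CS"], 10)
        res = fold_changes(_fc_table(vals, y), y, self._ann(10, cls="ceramide"),
                           {f"f{j}" for j in range(10)})
        assert res.omitted_classes == ["ceramide"]
        assert res.per_class.empty

    def test_requires_baseline_group(self, rng):
        vals = rng.uniform(10, 100, (10, 5))
        y = np.repeat(["MACS1", "CS"], 5)
        with pytest.raises(ValueError, match="NFAT"):
            fold_changes(_fc_table(vals, y), y, self._ann(5), {"f0"})
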