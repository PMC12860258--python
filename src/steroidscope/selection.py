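"""Dual-classifier consensus feature selection and fold-change summaries.

GMLVQ and the ordinal variant are trained on every PPCA-imputed matrix;
features are ranked per matrix by mean relevance over repeated runs.  A
feature is *consistent* for a classifier when it sits in the top-``top_n``
list of every imputed matrix (strict reading; a relaxed quantile is
config-exposed), and the informative set is the intersection of the two
classifiers' consistent sets — agreement between methodologies standing in
for statistical significance on untargeted data.

Fold changes are mean log2 abundance differences of each diagnostic group
against NFAT, summarised per annotation class (median, IQR, 5th-95th
centile) over all selected features, the increased-only stratum, and the
decreased-only stratum.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .datamodel import AnnotationMap, FeatureTable
from .lvq import LVQConfig, repeated_runs
from .ppca import ImputationSet

#: a class needs at least this many selected features to be summarised
MIN_CLASS_FEATURES = 20


@dataclasses.dataclass
class ConsensusSelection:
    rankings: dict[str, list[pd.Index]]   # classifier -> per-imputation ranked ids
    consensus: dict[str, set[str]]        # classifier -> consistent set
    intersection: set[str]
    venn: dict[str, int]
    top_n: int


def _rank_features(X: np.ndarray, y: np.ndarray, names: list[str],
                   cfg: LVQConfig, n_runs: int, class_order, seed: int) -> pd.Index:
    profile, _ = repeated_runs(X, y, cfg, n_runs=n_runs, class_order=class_order,
                               seed=seed, feature_names=names)
    order = np.argsort(profile.mean)[::-1]
    return pd.Index([names[i] for i in order])


def consensus_select(imputations: ImputationSet, y: np.ndarray,
                     feature_names: list[str], cfg: LVQConfig | None = None,
                     top_n: int = 500, n_runs: int = 30,
                     class_order=("NFAT", "MACS1", "MACS2", "CS"),
                     consistency: float = 1.0, seed: int = 0) -> ConsensusSelection:
    """Top-``top_n`` consensus selection across imputations and classifiers.

    ``consistency`` is the fraction of imputed matrices in which a feature
    must reach the top list (1.0 = strict "in all", the default).  When no
    LVQ config is supplied, Omega is restricted to rank C-1 (the dimension
    of the class-mean subspace) — on feature tables far wider than the
    cohort a full-rank metric is neither identifiable nor affordable.
    """
    if cfg is None:
        cfg = LVQConfig(epochs=100, omega_rank=max(2, len(np.unique(y)) - 1))
    p = len(feature_names)
    if top_n > p:
        warnings.warn(f"top_n={top_n} > {p} features; clamping", stacklevel=2)
        top_n = p
    y = np.asarray(y)

    # training seeds are held fixed across imputed matrices so that ranking
    # differences between matrices reflect imputation variability alone
    rankings: dict[str, list[pd.Index]] = {"gmlvq": [], "ordinal": []}
    for X in imputations.matrices:
        for name, order in (("gmlvq", None), ("ordinal", class_order)):
            rankings[name].append(
                _rank_features(X, y, feature_names, cfg, n_runs, order,
                               seed=seed + (0 if name == "gmlvq" else 17)))

    consensus: dict[str, set[str]] = {}
    n_mat = len(imputations.matrices)
    need = int(np.ceil(consistency * n_mat))
    for name, ranked in rankings.items():
        counts: dict[str, int] = {}
        for r in ranked:
            for f in r[:top_n]:
                counts[f] = counts.get(f, 0) + 1
        consensus[name] = {f for f, c in counts.items() if c >= need}

    inter = consensus["gmlvq"] & consensus["ordinal"]
    venn = {
        "gmlvq": len(consensus["gmlvq"]),
        "ordinal": len(consensus["ordinal"]),
        "both": len(inter),
        "gmlvq_only": len(consensus["gmlvq"] - consensus["ordinal"]),
        "ordinal_only": len(consensus["ordinal"] - consensus["gmlvq"]),
        "union": len(consensus["gmlvq"] | consensus["ordinal"]),
    }
    return ConsensusSelection(rankings=rankings, consensus=consensus,
                              intersection=inter, venn=venn, top_n=top_n)


@dataclasses.dataclass
class FoldChangeSummary:
    per_feature: pd.DataFrame          # features x groups, log2 FC vs NFAT
    per_class: pd.DataFrame            # class/group/stratum boxplot stats
    omitted_classes: list[str]


def _box_stats(values: np.ndarray) -> dict[str, float]:
    q5, q25, q50, q75, q95 = np.percentile(values, [5, 25, 50, 75, 95])
    return dict(median=q50, q25=q25, q75=q75, p5=q5, p95=q95, n=len(values))


def fold_changes(table: FeatureTable, y: np.ndarray,
                 annotations: AnnotationMap, selection: set[str],
                 baseline: str = "NFAT") -> FoldChangeSummary:
    """Mean log2 fold-change of each group vs NFAT, summarised by class.

    Expects a drift-corrected (pre-normalisation) table so the values are
    genuine abundances; log2 is taken internally on positive cells.
    Classes with fewer than 20 selected features are omitted (noted), the
    display rule used for the class-level Venn/boxplot summaries.
    """
    table.require_stage("corrected", "filtered")
    y = np.asarray(y)
    study = table.study
    if len(study) != len(y):
        raise ValueError("labels must align with study samples")
    if baseline not in set(y):
        raise ValueError(f"baseline group {baseline!r} absent")
    feats = [f for f in selection if f in study.columns]
    log2ab = np.log2(study[feats].mask(study[feats] <= 0))
    groups = [g for g in pd.unique(y) if g != baseline]
    base_mean = log2ab[y == baseline].mean()
    fc = pd.DataFrame({g: log2ab[y == g].mean() - base_mean for g in groups})

    class_members = annotations.classes()
    rows = []
    omitted = []
    for cls, members in sorted(class_members.items()):
        sel = sorted(members & set(feats))
        if len(sel) < MIN_CLASS_FEATURES:
            omitted.append(cls)
            continue
        for g in groups:
            v = fc.loc[sel, g].dropna().to_numpy()
            for stratum, vv in (("all", v),
                                ("increased", v[v > 0]),
                                ("decreased", v[v < 0])):
                if len(vv) == 0:
                    continue
                rows.append(dict(lipid_class=cls, group=g, stratum=stratum,
                                 **_box_stats(vv)))
    per_class = pd.DataFrame(rows)
    return FoldChangeSummary(per_feature=fc, per_class=per_class,
                             omitted_classes=omitted)
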