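"""Steroid-feature Spearman correlation and pathway over-representation.

:func:`spearman_grid` correlates each (steroid, feature) pair by Spearman
rank correlation (midrank ties, t-approximation p-values) and controls the
false discovery rate by Benjamini-Hochberg across all computed pairs
jointly; :func:`ora` is the classical hypergeometric over-representation
test of annotation classes within a selected feature set, BH-adjusted
across pathways.  Steroid values are used raw — Spearman is invariant to
the monotone log transform used elsewhere.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnnotationMap


@dataclasses.dataclass
class CorrelationResult:
    table: pd.DataFrame          # steroid, feature, rho, p, q, significant
    n_significant: int
    n_significant_features: int
    skipped: list[tuple[str, str]]
    alpha: float


def spearman_grid(steroids: pd.DataFrame, features: pd.DataFrame,
                  alpha: float = 0.05, min_pairs: int = 10) -> CorrelationResult:
    """All-pairs Spearman correlation between two sample-aligned tables.

    Rows are matched on index (patients present in both); pairs with fewer
    than ``min_pairs`` complete observations are skipped with a note.
    Significance is BH q < ``alpha`` across every computed pair.
    """
    shared = steroids.index.intersection(features.index)
    S = steroids.loc[shared]
    F = features.loc[shared]
    rows, skipped = [], []
    for s in S.columns:
        sv = S[s].to_numpy(float)
        for f in F.columns:
            fv = F[f].to_numpy(float)
            ok = ~(np.isnan(sv) | np.isnan(fv))
            if ok.sum() < min_pairs:
                skipped.append((s, f))
                continue
            rho, p = stats.spearmanr(sv[ok], fv[ok])
            rows.append(dict(steroid=s, feature=f, rho=float(rho),
                             p=float(p), n=int(ok.sum())))
    table = pd.DataFrame(rows)
    if len(table):
        rej, q, _, _ = multipletests(table["p"], alpha=alpha, method="fdr_bh")
        table["q"] = q
        table["significant"] = rej
    else:
        table["q"] = []
        table["significant"] = []
    sig = table[table["significant"]] if len(table) else table
    return CorrelationResult(
        table=table,
        n_significant=int(len(sig)),
        n_significant_features=int(sig["feature"].nunique()) if len(sig) else 0,
        skipped=skipped, alpha=alpha)


@dataclasses.dataclass
class EnrichmentResult:
    table: pd.DataFrame          # pathway, overlap, sizes, p, q, significant
    alpha: float


def ora(selection: set[str], annotations: AnnotationMap,
        alpha: float = 0.05) -> EnrichmentResult:
    """Hypergeometric over-representation of each pathway in ``selection``.

    Upper-tail test: p = P(X >= overlap) for X ~ Hypergeom(background,
    pathway size, selection size); BH adjustment across pathways.
    """
    bg = annotations.background
    if not bg:
        raise ValueError("empty annotation background")
    stray = set(selection) - set(bg)
    if stray:
        raise ValueError(f"selection outside background: {sorted(stray)[:3]}")
    N = len(bg)
    n_sel = len(selection)
    rows = []
    for pathway, members in sorted(annotations.classes().items()):
        K = len(members)
        k = len(members & set(selection))
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sel))
        rows.append(dict(pathway=pathway, overlap=k, pathway_size=K,
                         selection_size=n_sel, background_size=N, p=p))
    table = pd.DataFrame(rows)
    rej, q, _, _ = multipletests(table["p"], alpha=alpha, method="fdr_bh")
    table["q"] = q
    table["significant"] = rej
    return EnrichmentResult(table=table, alpha=alpha)
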