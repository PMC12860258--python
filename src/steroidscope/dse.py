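"""Double-GMLVQ subspace learning (discriminative subspace emersion).

Two-stage procedure that asks which features discriminate a *secondary*
clinical label (hypertension, type-2 diabetes, bilateral tumours) beyond
the *primary* diagnostic-group structure:

1. train GMLVQ on the primary labels and eigendecompose its relevance
   matrix Lambda_1;
2. deflate the data by projecting onto the orthogonal complement of the
   top-r eigenvectors of Lambda_1 (r chosen as the smallest number of
   directions capturing >= 95 % of trace(Lambda_1));
3. train GMLVQ on the secondary label in that complement and map its
   relevances back to the original feature axes through the complement
   projector (diag of P Lambda_2 P, renormalised).

By construction the deflation removes whatever linear directions carried
the primary discrimination, so secondary relevance cannot simply re-read
the diagnostic-group signal.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .lvq import LVQConfig, LVQModel, RelevanceProfile, train_gmlvq


@dataclasses.dataclass
class DSEResult:
    primary_model: LVQModel
    secondary_models: list[LVQModel]
    projector: np.ndarray              # (d, d) complement projector P
    r: int                             # deflated directions
    secondary_relevances: RelevanceProfile
    secondary_accuracy: list[float]


def deflation_projector(lambda1: np.ndarray, trace_frac: float = 0.95
                        ) -> tuple[np.ndarray, int]:
    """Orthogonal-complement projector of the top-r eigenspace of Lambda_1.

    r is the smallest number of leading eigenvectors whose eigenvalues sum
    to >= ``trace_frac`` of the trace.  Raises when r would equal the full
    dimension (nothing left to train on).
    """
    evals, evecs = np.linalg.eigh(lambda1)
    idx = np.argsort(evals)[::-1]
    evals = np.clip(evals[idx], 0.0, None)
    evecs = evecs[:, idx]
    frac = np.cumsum(evals) / max(evals.sum(), 1e-300)
    r = int(np.searchsorted(frac, trace_frac) + 1)
    d = lambda1.shape[0]
    if r >= d:
        raise ValueError(f"deflation rank r={r} >= feature dimension {d}")
    V = evecs[:, :r]
    P = np.eye(d) - V @ V.T
    return P, r


def run_dse(X: np.ndarray, primary_y: np.ndarray, secondary_y: np.ndarray,
            cfg: LVQConfig | None = None, n_runs: int = 30,
            trace_frac: float = 0.95, seed: int = 0) -> DSEResult:
    """Two-stage double-GMLVQ analysis on an aligned (transformed) matrix.

    ``X`` rows, ``primary_y`` (diagnostic group) and ``secondary_y``
    (clinical flag) must be aligned; any subgroup selection (e.g. a
    specific diagnostic contrast) is applied by the caller beforehand.
    Stage 2 is repeated ``n_runs`` times with fresh seeds to give a
    relevance distribution per feature.
    """
    cfg = cfg or LVQConfig()
    X = np.asarray(X, float)
    primary_y = np.asarray(primary_y)
    secondary_y = np.asarray(secondary_y)
    if len(np.unique(secondary_y)) < 2:
        raise ValueError("secondary label is constant within the selected subgroup")

    primary = train_gmlvq(X, primary_y, dataclasses.replace(cfg, seed=seed))
    P, r = deflation_projector(primary.lambda_, trace_frac)
    Xd = X @ P

    models, rel_rows, accs = [], [], []
    for run in range(n_runs):
        run_cfg = dataclasses.replace(cfg, seed=seed + 104729 * (run + 1))
        model = train_gmlvq(Xd, secondary_y, run_cfg)
        models.append(model)
        lam_back = P @ model.lambda_ @ P
        rel = np.clip(np.diag(lam_back), 0.0, None)
        rel_rows.append(rel / max(rel.sum(), 1e-300))
        accs.append(float((model.predict(Xd) == secondary_y).mean()))

    return DSEResult(primary_model=primary, secondary_models=models,
                     projector=P, r=r,
                     secondary_relevances=RelevanceProfile(np.asarray(rel_rows)),
                     secondary_accuracy=accs)


def contrast_subset(groups: np.ndarray, flags: np.ndarray,
                    macs_labels: tuple = ("MACS1", "MACS2")) -> np.ndarray:
    """Row mask for the published contrast: {MACS or NFAT} with flag set.

    The returned mask selects flagged patients whose diagnostic group is
    NFAT or MACS; the primary label for stage 1 is then NFAT vs MACS within
    the mask.
    """
    groups = np.asarray(groups)
    flags = np.asarray(flags, bool)
    in_scope = np.isin(groups, ("NFAT",) + tuple(macs_labels))
    return in_scope & flags
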