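"""Generalised matrix LVQ (GMLVQ) and its ordinal variant.

Prototype-based classification with a learnt global quadratic metric

    d(x, w) = (x - w)^T  Lambda  (x - w),     Lambda = Omega^T Omega,

where ``Omega`` is trained jointly with the class prototypes and
``trace(Lambda)`` is renormalised to 1 after every update, so
``diag(Lambda)`` is a probability-like per-feature relevance profile.

Training minimises the GLVQ cost ``sum_i v_i * mu_i`` with
``mu = (d_J - d_K) / (d_J + d_K)``, ``d_J``/``d_K`` the distances to the
nearest same-class / different-class prototype.  In the ordinal variant the
classes carry a total order and each term is weighted by the absolute rank
distance ``v_i = |rank(class of K) - rank(y_i)|``, so confusing distant
classes costs more; with two classes every rank distance is 1 and the
ordinal variant is exactly GMLVQ.

Optimisation is full-batch gradient descent with exponential annealing and
(by default) step halving whenever the cost would increase, which makes the
recorded cost trace non-increasing.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit


@dataclasses.dataclass
class LVQConfig:
    protos_per_class: int = 1
    lr_w: float = 0.05
    lr_omega: float = 0.05
    epochs: int = 300
    seed: int = 0
    omega_rank: int | None = None   # None => square (full-rank) Omega
    anneal: float = 0.995           # per-epoch exponential decay of both rates
    monotone: bool = True           # halve step on cost increase
    jitter: float = 0.05            # prototype init jitter (x feature sd)


@dataclasses.dataclass
class LVQModel:
    prototypes: np.ndarray          # (P, d)
    proto_labels: np.ndarray        # (P,)
    omega: np.ndarray               # (m, d), trace(Omega^T Omega) = 1
    classes: np.ndarray             # ordered class labels
    class_order: dict | None        # label -> rank (ordinal mode only)
    cost_trace: np.ndarray

    @property
    def lambda_(self) -> np.ndarray:
        return self.omega.T @ self.omega

    @property
    def relevances(self) -> np.ndarray:
        """diag(Lambda): non-negative, sums to 1."""
        return np.einsum("ij,ij->j", self.omega, self.omega)

    def distances(self, X: np.ndarray) -> np.ndarray:
        """(n, P) matrix of learnt-metric squared distances to prototypes."""
        X = np.atleast_2d(np.asarray(X, float))
        Xp = X @ self.omega.T
        Wp = self.prototypes @ self.omega.T
        return ((Xp[:, None, :] - Wp[None, :, :]) ** 2).sum(-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.distances(X)
        return self.proto_labels[np.argmin(d, axis=1)]

    def score(self, X: np.ndarray, pos_label=None) -> np.ndarray:
        """Signed, normalised distance difference (d_neg - d_pos)/(sum).

        Positive values favour ``pos_label`` (default: last class).
        """
        if pos_label is None:
            pos_label = self.classes[-1]
        d = self.distances(X)
        pos = self.proto_labels == pos_label
        if not pos.any() or pos.all():
            raise ValueError("score requires prototypes on both sides of pos_label")
        d_pos = d[:, pos].min(1)
        d_neg = d[:, ~pos].min(1)
        return (d_neg - d_pos) / (d_neg + d_pos + 1e-300)


def lvq_distance(x: np.ndarray, w: np.ndarray, omega: np.ndarray) -> float:
    """Squared learnt-metric distance ``(x-w)^T Omega^T Omega (x-w)``."""
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    if x.shape != w.shape or omega.shape[1] != x.shape[0]:
        raise ValueError("dimension mismatch between x, w and Omega")
    z = omega @ (x - w)
    return float(z @ z)


def _normalise_omega(omega: np.ndarray) -> np.ndarray:
    return omega / np.sqrt((omega ** 2).sum())


def _cost_and_grads(X, y_idx, W, proto_idx, omega, v_weight):
    """GLVQ cost (mean over samples) and gradients w.r.t. W and Omega.

    ``v_weight(k_proto, i)`` returns the ordinal weight for sample i when
    its closest wrong prototype is ``k_proto``.
    """
    n = X.shape[0]
    Xp = X @ omega.T
    Wp = W @ omega.T
    d = ((Xp[:, None, :] - Wp[None, :, :]) ** 2).sum(-1)   # (n, P)
    same = proto_idx[None, :] == y_idx[:, None]
    d_same = np.where(same, d, np.inf)
    d_diff = np.where(~same, d, np.inf)
    J = np.argmin(d_same, axis=1)
    K = np.argmin(d_diff, axis=1)
    dJ = d[np.arange(n), J]
    dK = d[np.arange(n), K]
    denom = dJ + dK + 1e-300
    mu = (dJ - dK) / denom
    v = v_weight(K, np.arange(n))
    cost = float((v * mu).mean())
    gJ = v * 2.0 * dK / denom ** 2 / n
    gK = -v * 2.0 * dJ / denom ** 2 / n
    DJ = X - W[J]
    DK = X - W[K]
    # prototype gradient: sum_i g * (-2 Lambda delta)
    P = W.shape[0]
    grad_W = np.zeros_like(W)
    for p in range(P):
        mJ = J == p
        mK = K == p
        acc = np.zeros(X.shape[1])
        if mJ.any():
            acc += gJ[mJ] @ DJ[mJ]
        if mK.any():
            acc += gK[mK] @ DK[mK]
        grad_W[p] = -2.0 * (omega.T @ (omega @ acc))
    # Omega gradient: 2 Omega sum_i (gJ dJ dJ^T + gK dK dK^T)
    grad_O = 2.0 * (((omega @ DJ.T) * gJ) @ DJ + ((omega @ DK.T) * gK) @ DK)
    return cost, grad_W, grad_O


def _train(X: np.ndarray, y: np.ndarray, cfg: LVQConfig,
           class_order: Sequence | None) -> LVQModel:
    X = np.asarray(X, float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if class_order is not None:
        missing = set(np.unique(y)) - set(class_order)
        if missing:
            raise ValueError(f"class_order does not cover labels: {sorted(map(str, missing))}")
        classes = np.asarray([c for c in class_order if c in set(y)])
        order = {c: r for r, c in enumerate(classes)}
    else:
        classes = np.unique(y)
        order = None
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    for c, cnt in counts.items():
        if cnt < cfg.protos_per_class:
            raise ValueError(f"class {c!r} has {cnt} examples "
                             f"< protos_per_class={cfg.protos_per_class}")

    rng = np.random.default_rng(cfg.seed)
    d = X.shape[1]
    sd = X.std(0, ddof=0)
    sd[sd == 0] = 1.0
    protos, labels = [], []
    for c in classes:
        mean = X[y == c].mean(0)
        for _ in range(cfg.protos_per_class):
            protos.append(mean + cfg.jitter * sd * rng.standard_normal(d))
            labels.append(c)
    W = np.asarray(protos)
    proto_labels = np.asarray(labels)

    m = cfg.omega_rank or d
    if m > d:
        raise ValueError("omega_rank cannot exceed the feature dimension")
    if m == d:
        omega = np.eye(d)
    else:
        # low-rank mode: seed the transform with the between-class scatter
        # directions (a random projection of thousands of features carries
        # almost no class signal and the cost gradient cannot recover)
        means = np.asarray([X[y == c].mean(0) for c in classes])
        means = means - means.mean(0)
        _, _, Vt = np.linalg.svd(means, full_matrices=False)
        basis = Vt[:min(m, Vt.shape[0])]
        if basis.shape[0] < m:
            basis = np.vstack([basis,
                               rng.standard_normal((m - basis.shape[0], d))])
        omega = basis + 0.01 * rng.standard_normal((m, d))
    omega = _normalise_omega(omega)

    cls_idx = {c: i for i, c in enumerate(classes)}
    y_idx_cls = np.asarray([cls_idx[c] for c in y])
    proto_idx = np.asarray([cls_idx[c] for c in proto_labels])
    if order is None:
        def v_weight(K, rows):
            return np.ones(len(rows))
    else:
        rank_p = np.asarray([order[c] for c in proto_labels], float)
        rank_y = np.asarray([order[c] for c in y], float)

        def v_weight(K, rows):
            return np.abs(rank_p[K] - rank_y[rows])

    lr_w, lr_o = cfg.lr_w, cfg.lr_omega
    trace: list[float] = []
    saved = None
    for _ in range(cfg.epochs):
        cost, gW, gO = _cost_and_grads(X, y_idx_cls, W, proto_idx, omega, v_weight)
        if cfg.monotone and trace and cost > trace[-1] + 1e-12 and saved is not None:
            W, omega, cost, gW, gO = saved
            W, omega = W.copy(), omega.copy()
            lr_w *= 0.5
            lr_o *= 0.5
        trace.append(cost)
        saved = (W.copy(), omega.copy(), cost, gW, gO)
        W = W - lr_w * gW
        omega = _normalise_omega(omega - lr_o * gO)
        lr_w *= cfg.anneal
        lr_o *= cfg.anneal

    return LVQModel(prototypes=W, proto_labels=proto_labels, omega=omega,
                    classes=classes, class_order=order,
                    cost_trace=np.asarray(trace))


def train_gmlvq(X: np.ndarray, y: np.ndarray, cfg: LVQConfig | None = None) -> LVQModel:
    """Train GMLVQ (unordered classes)."""
    return _train(X, y, cfg or LVQConfig(), class_order=None)


def train_ordinal_lvq(X: np.ndarray, y: np.ndarray,
                      class_order: Sequence,
                      cfg: LVQConfig | None = None) -> LVQModel:
    """Train the ordinal (rank-weighted) variant; needs a total class order."""
    return _train(X, y, cfg or LVQConfig(), class_order=class_order)


def rank_distance(class_order: Sequence, a, b) -> int:
    """Absolute rank distance between two classes under a total order."""
    order = {c: r for r, c in enumerate(class_order)}
    return abs(order[a] - order[b])


# --------------------------------------------------------------------------
# embedding, evaluation, repeated runs
# --------------------------------------------------------------------------


def embed_2d(model: LVQModel, X: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Discriminative 2-D embedding: top-2 eigenvectors of Lambda x sqrt(eig).

    Returns (sample coordinates (n, 2), prototype coordinates (P, 2)).
    """
    lam = model.lambda_
    evals, evecs = np.linalg.eigh(lam)
    idx = np.argsort(evals)[::-1][:2]
    evals = np.clip(evals[idx], 0.0, None)
    if evals[0] <= 1e-12:
        raise ValueError("relevance matrix has rank 0; no embedding")
    axes = evecs[:, idx] * np.sqrt(evals)
    # deterministic sign: largest-magnitude loading positive
    for j in range(axes.shape[1]):
        i = np.argmax(np.abs(axes[:, j]))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    return np.asarray(X, float) @ axes, model.prototypes @ axes


_METRICS = ("ccr", "balanced", "auroc", "mean_rank_error")


def _metric_value(metric, y, pred, score, order):
    if metric == "ccr":
        return float((pred == y).mean())
    if metric == "balanced":
        return float(balanced_accuracy_score(y, pred))
    if metric == "auroc":
        return float(roc_auc_score(y, score))
    if metric == "mean_rank_error":
        ranks = {c: r for r, c in enumerate(order)}
        ry = np.asarray([ranks[c] for c in y], float)
        rp = np.asarray([ranks[c] for c in pred], float)
        return float(np.abs(ry - rp).mean())
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


def evaluate(model: LVQModel, X: np.ndarray, y: np.ndarray, metric: str = "ccr",
             ci: bool = False, n_boot: int = 2000, seed: int = 0):
    """Evaluate a trained model; optional stratified-bootstrap 95% CI."""
    y = np.asarray(y)
    pred = model.predict(X)
    score = None
    if metric == "auroc":
        if len(np.unique(y)) != 2:
            raise ValueError("AUROC requires binary labels")
        pos = model.classes[-1]
        score = model.score(X, pos_label=pos)
        y_bin = (y == pos).astype(int)
        value = _metric_value(metric, y_bin, None, score, None)
    else:
        order = (sorted(model.class_order, key=model.class_order.get)
                 if model.class_order else list(model.classes))
        value = _metric_value(metric, y, pred, None, order)
    if not ci:
        return value
    rng = np.random.default_rng(seed)
    idx_by_class = [np.where(y == c)[0] for c in np.unique(y)]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(ix, len(ix), replace=True)
                              for ix in idx_by_class])
        if metric == "auroc":
            boots[b] = _metric_value(metric, (y[idx] == model.classes[-1]).astype(int),
                                     None, score[idx], None)
        else:
            order = (sorted(model.class_order, key=model.class_order.get)
                     if model.class_order else list(model.classes))
            boots[b] = _metric_value(metric, y[idx], pred[idx], None, order)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return value, (float(lo), float(hi))


@dataclasses.dataclass
class RelevanceProfile:
    """Per-run feature relevances (runs x features); violin-plot data."""

    matrix: np.ndarray
    feature_names: list[str] | None = None

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(0)

    @property
    def sd(self) -> np.ndarray:
        return self.matrix.std(0, ddof=1) if len(self.matrix) > 1 else np.zeros(self.matrix.shape[1])


def repeated_runs(X: np.ndarray, y: np.ndarray, cfg: LVQConfig | None = None,
                  n_runs: int = 30, class_order: Sequence | None = None,
                  train_frac: float = 0.9, seed: int = 0,
                  feature_names: list[str] | None = None) -> tuple[RelevanceProfile, dict]:
    """Repeated stratified-holdout training protocol.

    Each run draws an independent stratified train/validation split and
    training seed, trains (ordinal when ``class_order`` is given), and
    collects per-run relevances diag(Lambda), validation CCR (plus AUROC
    for binary problems), and class prototypes.  The summary reports mean
    +/- SD prototype vectors per class and the relevance violin matrix.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    cfg = cfg or LVQConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    binary = len(np.unique(y)) == 2
    relev, ccrs, aucs = [], [], []
    protos: dict = {}
    for run in range(n_runs):
        run_seed = seed + 7919 * run
        sss = StratifiedShuffleSplit(n_splits=1, train_size=train_frac,
                                     random_state=run_seed % (2 ** 31))
        tr, va = next(sss.split(X, y))
        run_cfg = dataclasses.replace(cfg, seed=run_seed)
        if class_order is not None:
            model = train_ordinal_lvq(X[tr], y[tr], class_order, run_cfg)
        else:
            model = train_gmlvq(X[tr], y[tr], run_cfg)
        relev.append(model.relevances)
        ccrs.append(evaluate(model, X[va], y[va], "ccr"))
        if binary:
            aucs.append(evaluate(model, X[va], y[va], "auroc"))
        for c in model.classes:
            protos.setdefault(c, []).append(
                model.prototypes[model.proto_labels == c].mean(0))
    profile = RelevanceProfile(np.asarray(relev), feature_names)
    summary = {
        "ccr_mean": float(np.mean(ccrs)), "ccr_sd": float(np.std(ccrs, ddof=1)),
        "ccr_runs": ccrs,
        "prototype_mean": {c: np.mean(v, axis=0) for c, v in protos.items()},
        "prototype_sd": {c: np.std(v, axis=0, ddof=1) for c, v in protos.items()},
        "relevance_mean": profile.mean,
        "relevance_sd": profile.sd,
    }
    if binary:
        summary["auroc_mean"] = float(np.mean(aucs))
        summary["auroc_sd"] = float(np.std(aucs, ddof=1))
        summary["auroc_runs"] = aucs
    return profile, summary


def log_zscore(values: np.ndarray) -> np.ndarray:
    """log-transform then z-score columns (the steroid-matrix convention)."""
    v = np.asarray(values, float)
    if (v <= 0).any():
        positive_min = v[v > 0].min() if (v > 0).any() else 1.0
        v = np.where(v <= 0, positive_min / 2.0, v)
    lv = np.log(v)
    return (lv - lv.mean(0)) / lv.std(0, ddof=1)
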