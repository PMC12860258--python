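"""Prototype classification of the steroid metabolome.

Four-class ordinal LVQ across the NFAT -> MACS-1 -> MACS-2 -> CS spectrum
(repeated runs: relevance violins, 2-D embedding, CCR) and two-class GMLVQ
for NFAT vs pooled MACS (AUROC with bootstrap CI, prototype bars).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from steroidscope.datamodel import read_cohort, read_steroids
from steroidscope.lvq import (LVQConfig, embed_2d, evaluate, log_zscore,
                              repeated_runs, train_ordinal_lvq)

SEED = 7
ORDER = ("NFAT", "MACS1", "MACS2", "CS")
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "data" / "cohort.csv")
    steroids = read_steroids(ROOT / "data" / "steroids.csv").aligned_to(cohort)
    names = list(steroids.df.columns)
    X = log_zscore(steroids.values)
    y = cohort.df["group"].to_numpy()
    cfg = LVQConfig(epochs=150)

    profile, summary = repeated_runs(X, y, cfg, n_runs=30, class_order=ORDER,
                                     seed=SEED, feature_names=names)
    pd.DataFrame(profile.matrix, columns=names).to_csv(
        ROOT / "steroid_relevance_runs.csv", index=False)
    print(f"4-class ordinal CCR {summary['ccr_mean']:.3f} "
          f"+/- {summary['ccr_sd']:.3f} over 30 runs")
    top5 = [names[i] for i in np.argsort(profile.mean)[::-1][:5]]
    print("top-5 discriminatory steroids:", top5)
    (ROOT / "top5_steroids.json").write_text(json.dumps(top5))

    model = train_ordinal_lvq(X, y, ORDER, cfg)
    coords, protos = embed_2d(model, X)
    emb = pd.DataFrame(coords, columns=["dim1", "dim2"],
                       index=steroids.df.index)
    emb["group"] = y
    emb.to_csv(ROOT / "ordinal_embedding.csv")

    y2 = np.where(np.isin(y, ["MACS1", "MACS2"]), "MACS", y)
    mask = y2 != "CS"
    profile2, summary2 = repeated_runs(X[mask], y2[mask], cfg, n_runs=30,
                                       seed=SEED, feature_names=names)
    print(f"NFAT vs MACS AUROC {summary2['auroc_mean']:.3f} "
          f"+/- {summary2['auroc_sd']:.3f} over 30 runs")
    proto_bars = pd.DataFrame({
        f"{c}_{stat}": vec
        for c in summary2["prototype_mean"]
        for stat, vec in (("mean", summary2["prototype_mean"][c]),
                          ("sd", summary2["prototype_sd"][c]))
    }, index=names)
    proto_bars.to_csv(ROOT / "nfat_macs_prototypes.csv")
    metrics = {
        "ordinal_ccr_mean": summary["ccr_mean"], "ordinal_ccr_sd": summary["ccr_sd"],
        "nfat_macs_auroc_mean": summary2["auroc_mean"],
        "nfat_macs_auroc_sd": summary2["auroc_sd"],
        "top5_steroids": top5,
    }
    (ROOT / "classification_metrics.json").write_text(json.dumps(metrics, indent=2))


if __name__ == "__main__":
    main()
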