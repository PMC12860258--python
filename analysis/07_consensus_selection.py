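"""Dual-classifier top-500 consensus selection and lipid-class fold changes.

GMLVQ and ordinal LVQ rank every feature on each imputed matrix; features
in the top 500 of every matrix for both classifiers form the informative
set (Venn accounting mirrors the two-classifier agreement).  Fold changes
of the selected features vs NFAT are summarised per lipid class.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from steroidscope.datamodel import read_cohort, read_feature_table
from steroidscope.ppca import ImputationSet, PPCAModel
from steroidscope.preprocess import qc_rsc_correct
from steroidscope.selection import consensus_select, fold_changes
from steroidscope.simulate import annotations_from_truth

SEED = 7
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    cohort = read_cohort(data / "subcohort.csv")
    norm = read_feature_table(ROOT / "normalised.csv",
                              ROOT / "normalised_metadata.csv",
                              stage="normalised")
    names = list(norm.abundances.columns)
    mats = []
    for f in sorted((ROOT / "imputations").glob("imputed_*.csv")):
        mats.append(pd.read_csv(f, index_col=0).to_numpy())
    dummy = PPCAModel(W=np.zeros((len(names), 1)), mu=np.zeros(len(names)),
                      sigma2=1.0, k=1, loglik_trace=np.zeros(1), converged=True)
    imps = ImputationSet(matrices=mats, model=dummy,
                         seeds=list(range(len(mats))))
    study_ids = norm.abundances.index[norm.metadata["sample_type"] == "study"]
    y = cohort.df.set_index("patient_id").loc[study_ids, "group"].to_numpy()

    sel = consensus_select(imps, y, names, top_n=500, n_runs=30, seed=SEED)
    (ROOT / "venn.json").write_text(json.dumps(sel.venn, indent=2))
    pd.Series(sorted(sel.intersection), name="feature").to_csv(
        ROOT / "consensus_features.csv", index=False)
    truth = json.loads((data / "truth.json").read_text())
    planted = set(truth["informative"])
    print(f"consensus: {sel.venn['both']} features in both classifiers "
          f"(GMLVQ {sel.venn['gmlvq']}, ordinal {sel.venn['ordinal']}); "
          f"{len(planted & sel.intersection)}/{len(planted)} planted "
          "informative features recovered")

    raw = read_feature_table(data / "features.csv", data / "metadata.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected, _ = qc_rsc_correct(raw)
    ann = annotations_from_truth(truth)
    fcs = fold_changes(corrected, cohort.df["group"].to_numpy(), ann,
                       sel.intersection)
    fcs.per_class.to_csv(ROOT / "foldchange_by_class.csv", index=False)
    if len(fcs.per_class):
        for stratum in ("increased", "decreased"):
            med = (fcs.per_class.query("stratum == @stratum")
                   .groupby("group")["median"].median().round(3))
            print(f"median log2 FC vs NFAT ({stratum} features):", dict(med))


if __name__ == "__main__":
    main()
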