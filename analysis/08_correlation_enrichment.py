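"""Steroid-metabolome association and pathway over-representation.

Spearman correlations between the 5 most discriminatory steroids (from
03_steroid_classification.py) and the consensus serum features, with
BH-FDR control; hypergeometric over-representation of lipid classes in the
consensus set.
"""

import json
from pathlib import Path

import pandas as pd

from steroidscope.assoc import ora, spearman_grid
from steroidscope.datamodel import read_cohort, read_feature_table, read_steroids
from steroidscope.simulate import annotations_from_truth

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    top5 = json.loads((ROOT / "top5_steroids.json").read_text())
    cohort = read_cohort(data / "subcohort.csv")
    steroids = read_steroids(data / "substeroids.csv").aligned_to(cohort)
    norm = read_feature_table(ROOT / "normalised.csv",
                              ROOT / "normalised_metadata.csv",
                              stage="normalised")
    consensus = set(pd.read_csv(ROOT / "consensus_features.csv")["feature"])

    res = spearman_grid(steroids.df[top5], norm.study[sorted(consensus)])
    res.table.to_csv(ROOT / "correlations.csv", index=False)
    print(f"{res.n_significant} significant correlations "
          f"(BH q < {res.alpha}) over {len(res.table)} pairs, touching "
          f"{res.n_significant_features} distinct features")

    truth = json.loads((data / "truth.json").read_text())
    ann = annotations_from_truth(truth)
    enr = ora(consensus, ann)
    enr.table.to_csv(ROOT / "enrichment.csv", index=False)
    sig = enr.table[enr.table["significant"]]
    print("enriched classes:",
          ", ".join(f"{r.pathway} (q={r.q:.2g})" for r in sig.itertuples())
          or "none")


if __name__ == "__main__":
    main()
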