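"""Double-GMLVQ subspace analysis for clinical co-labels.

For each of hypertension, type-2 diabetes and bilateral tumours: learn the
NFAT-vs-MACS metric, deflate its dominant directions, and train a second
GMLVQ on the clinical flag in the complement.  The mean secondary
relevances name the steroids that discriminate the flag beyond the
diagnostic-group structure.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from steroidscope.datamodel import read_cohort, read_steroids
from steroidscope.dse import run_dse
from steroidscope.lvq import LVQConfig, log_zscore

SEED = 7
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "data" / "cohort.csv")
    steroids = read_steroids(ROOT / "data" / "steroids.csv").aligned_to(cohort)
    names = list(steroids.df.columns)
    X = log_zscore(steroids.values)
    groups = cohort.df["group"].to_numpy()
    primary = np.where(np.isin(groups, ["MACS1", "MACS2"]), "MACS", groups)
    mask = primary != "CS"

    for flag in ("hypertension", "t2d", "bilateral"):
        res = run_dse(X[mask], primary[mask],
                      cohort.df.loc[mask, flag].to_numpy(),
                      LVQConfig(epochs=150), n_runs=30, seed=SEED)
        rel = pd.DataFrame(res.secondary_relevances.matrix, columns=names)
        rel.to_csv(ROOT / f"dse_{flag}_relevance_runs.csv", index=False)
        top3 = rel.mean().sort_values(ascending=False).head(3)
        print(f"{flag}: deflated {res.r} direction(s); top secondary "
              "relevances: "
              + ", ".join(f"{s} ({v:.3f})" for s, v in top3.items()))


if __name__ == "__main__":
    main()
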