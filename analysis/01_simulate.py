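"""Generate the synthetic study data set.

Draws a full-size steroid-profiling cohort (649/451/140/65 patients across
NFAT, MACS-1, MACS-2 and CS) and, for the untargeted arm, a matched
sub-cohort (104/70/70/47) with a 2000-feature table carrying low-rank
structure, 50 planted informative lipid features, injection-order drift and
intensity-dependent missingness.  Writes everything under results/data/.
"""

import json
from pathlib import Path

from steroidscope.datamodel import write_cohort, write_feature_table, write_steroids
from steroidscope.simulate import SimConfig, simulate_cohort, simulate_feature_table

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    steroid_cfg = SimConfig(n_per_group=(649, 451, 140, 65), seed=SEED)
    cohort, steroids, _ = simulate_cohort(steroid_cfg)
    write_cohort(cohort, OUT / "cohort.csv")
    write_steroids(steroids, OUT / "steroids.csv")
    print(f"steroid cohort: {len(cohort)} patients, "
          f"{steroids.df.shape[1]} metabolites")

    untargeted_cfg = SimConfig(seed=SEED)   # 104/70/70/47, 2000 features
    sub_cohort, sub_steroids, _ = simulate_cohort(untargeted_cfg)
    features, truth = simulate_feature_table(untargeted_cfg, sub_cohort)
    write_cohort(sub_cohort, OUT / "subcohort.csv")
    write_steroids(sub_steroids, OUT / "substeroids.csv")
    write_feature_table(features, OUT / "features.csv", OUT / "metadata.csv")
    (OUT / "truth.json").write_text(json.dumps(
        {k: v for k, v in truth.items() if k != "drift_scale"},
        indent=2, default=str))
    print(f"untargeted sub-cohort: {len(sub_cohort)} patients, "
          f"{features.abundances.shape[1]} features, "
          f"{features.n_missing} missing cells "
          f"({features.n_missing / features.abundances.size:.1%})")


if __name__ == "__main__":
    main()
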