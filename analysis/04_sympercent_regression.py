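"""Sympercent regressions of steroid excretion on clinical contrasts.

One OLS model per steroid: ln(excretion) ~ contrast + age + sex + BMI,
for hypertension, type-2 diabetes and bilateral tumours; coefficients
reported as sympercents (100 x log-scale effect) with 95% CIs.
"""

from pathlib import Path

from steroidscope.datamodel import read_cohort, read_steroids
from steroidscope.regression import sympercent_regression

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "data" / "cohort.csv")
    steroids = read_steroids(ROOT / "data" / "steroids.csv")
    for contrast in ("hypertension", "t2d", "bilateral"):
        res = sympercent_regression(steroids, cohort, contrast)
        res.round(3).to_csv(ROOT / f"sympercent_{contrast}.csv")
        top = res.reindex(res["sympercent"].abs()
                          .sort_values(ascending=False).index).head(3)
        print(f"{contrast}: largest effects "
              + ", ".join(f"{s} {r.sympercent:+.1f} s% (p={r.p_value:.2g})"
                          for s, r in top.iterrows()))


if __name__ == "__main__":
    main()
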