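"""Published cohort summary counts and a synthetic cohort reconstruction.

The EURINE-ACT adrenal-tumour study reports per-group patient counts for its
multi-steroid-profiling cohort (n = 1305) and its untargeted serum
metabolome sub-cohort (n = 291).  Those printed counts are enough to
recompute every categorical summary statistic (percentages, chi-square
trends), so :func:`cohort_from_counts` expands them into a synthetic
patient-level :class:`~steroidscope.datamodel.CohortTable` whose categorical
margins match the publication exactly.  Numeric columns (age, BMI) are
filled with the printed group medians and carry no within-group variation —
the reconstruction supports categorical arithmetic, not numeric inference.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import CohortTable

#: Printed per-group counts for the full multi-steroid profiling cohort.
TABLE1_MAIN = {
    "NFAT": dict(n=649, women=416, hypertension=416, t2d=171, bilateral=107,
                 age_median=58, bmi_median=29.4),
    "MACS1": dict(n=451, women=303, hypertension=339, t2d=145, bilateral=136,
                  age_median=64, bmi_median=28.8),
    "MACS2": dict(n=140, women=103, hypertension=107, t2d=47, bilateral=42,
                  age_median=63, bmi_median=28.6),
    "CS": dict(n=65, women=56, hypertension=47, t2d=20, bilateral=13,
               age_median=48, bmi_median=28.7),
}

#: Printed per-group counts for the untargeted serum metabolome sub-cohort.
TABLE1_SUBCOHORT = {
    "NFAT": dict(n=104, women=83, hypertension=72, t2d=30, dyslipidaemia=30,
                 age_median=58, bmi_median=28.8),
    "MACS1": dict(n=70, women=70, hypertension=51, t2d=25, dyslipidaemia=26,
                  age_median=64, bmi_median=29.1),
    "MACS2": dict(n=70, women=70, hypertension=56, t2d=25, dyslipidaemia=29,
                  age_median=64, bmi_median=29.3),
    "CS": dict(n=47, women=42, hypertension=33, t2d=14, dyslipidaemia=10,
               age_median=48, bmi_median=28.9),
}


def cohort_from_counts(counts: dict | None = None, prefix: str = "P") -> CohortTable:
    """Expand per-group summary counts into a synthetic patient-level table.

    Flags are assigned to the first ``k`` patients of each group
    independently per flag; any statistic that depends only on per-group
    flag counts (prevalences, chi-square on the group x flag table) is then
    exact, while joint flag distributions are arbitrary.
    """
    counts = TABLE1_MAIN if counts is None else counts
    rows = []
    for group, c in counts.items():
        for i in range(c["n"]):
            rows.append({
                "patient_id": f"{prefix}-{group}-{i:04d}",
                "group": group,
                "sex": "F" if i < c["women"] else "M",
                "age": float(c["age_median"]),
                "bmi": float(c["bmi_median"]),
                "hypertension": i < c["hypertension"],
                "t2d": i < c["t2d"],
                "bilateral": i < c.get("bilateral", 0),
                **({"dyslipidaemia": i < c["dyslipidaemia"]}
                   if "dyslipidaemia" in c else {}),
            })
    return CohortTable(pd.DataFrame(rows))
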