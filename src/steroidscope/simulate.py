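"""Synthetic cohort, steroid-excretion and untargeted feature-table generator.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is exercisable without any patient data:

* group-graded log-normal steroid excretion — glucocorticoid metabolites and
  the precursor metabolite THS rise monotonically from NFAT over MACS-1 and
  MACS-2 to CS, classic androgen metabolites (androsterone,
  etiocholanolone, DHEA) fall, and the 11-oxygenated androgen metabolite
  11b-OHAn stays flat;
* sex/age/BMI covariate effects on the log scale;
* hypertension and type-2-diabetes labels drawn from a logistic model on
  named (z-scored, log) steroid excretions, so label-steroid coupling is
  recoverable by refitting;
* an untargeted feature table with low-rank latent structure, class-shifted
  "informative" lipid blocks graded across the diagnostic groups, smooth
  injection-order intensity drift, pooled-QC samples interleaved in the run,
  and intensity-dependent (missing-not-at-random) missingness.

Determinism contract: identical :class:`SimConfig` (including the seed)
gives bit-identical outputs.  Child seeds are derived from the master seed
by fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import AnnotationMap, CohortTable, FeatureTable, SteroidMatrix
from .panel import CLASSIC_ANDROGENS, GLUCOCORTICOIDS, STEROIDS

GROUPS = ("NFAT", "MACS1", "MACS2", "CS")

LIPID_CLASSES = (
    "glycerophospholipid", "lysoglycerophospholipid", "triacylglyceride",
    "ceramide", "sphingolipid", "acylcarnitine",
)

#: class shares of the informative block — skewed, as in real lipidome
#: perturbations where glycerophospholipids dominate the affected features
INFORMATIVE_CLASS_WEIGHTS = (0.50, 0.20, 0.12, 0.08, 0.06, 0.04)

#: typical 24-h urinary excretion baselines (ug/24 h)
BASELINES = {
    "F": 50.0, "E": 70.0, "THF": 1400.0, "5a-THF": 1100.0, "THE": 2400.0,
    "a-cortol": 300.0, "b-cortol": 350.0, "a-cortolone": 700.0,
    "b-cortolone": 450.0, "THS": 50.0, "PD": 900.0, "PT": 600.0,
    "5-PT": 250.0, "An": 1800.0, "Etio": 1500.0, "DHEA": 150.0,
    "11b-OHAn": 500.0,
}


def default_steroid_effects() -> dict[str, tuple[float, float, float, float]]:
    """Log-scale additive group gradients (NFAT, MACS1, MACS2, CS).

    Glucocorticoids and THS increase strictly, classic androgens decrease
    strictly, 11b-OHAn is exactly flat; remaining precursor metabolites
    carry a mild gradient.
    """
    eff: dict[str, tuple[float, float, float, float]] = {}
    for s in STEROIDS:
        if s in GLUCOCORTICOIDS:
            eff[s] = (0.0, 0.25, 0.5, 1.0)
        elif s == "THS":
            eff[s] = (0.0, 0.2, 0.4, 0.8)
        elif s in CLASSIC_ANDROGENS:
            eff[s] = (0.0, -0.2, -0.4, -0.8)
        elif s == "11b-OHAn":
            eff[s] = (0.0, 0.0, 0.0, 0.0)
        else:  # PD, PT, 5-PT
            eff[s] = (0.0, 0.05, 0.1, 0.2)
    return eff


def default_comorbidity_model() -> dict[str, dict[str, float]]:
    """Logistic coefficients (on z-scored log excretion) per clinical flag."""
    return {
        "hypertension": {"intercept": 0.55, "F": 0.5, "THF": 0.3, "11b-OHAn": 0.4},
        "t2d": {"intercept": -0.85, "E": 0.3, "11b-OHAn": 0.4},
    }


@dataclasses.dataclass
class SimConfig:
    """Generating parameters; defaults mirror the untargeted sub-cohort."""

    n_per_group: tuple[int, int, int, int] = (104, 70, 70, 47)
    n_features: int = 2000
    n_qc: int | None = None            # default: ~ every 10th injection
    seed: int = 0
    steroid_effects: dict[str, tuple] = dataclasses.field(
        default_factory=default_steroid_effects)
    covariate_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"sex_F": -0.3, "age": -0.005, "bmi": 0.01})
    comorbidity_model: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=default_comorbidity_model)
    bilateral_prob: tuple[float, ...] = (0.165, 0.30, 0.30, 0.20)
    women_frac: tuple[float, ...] = (0.64, 0.67, 0.74, 0.86)
    age_mean: tuple[float, ...] = (58.0, 64.0, 63.0, 48.0)
    noise_sd: float = 0.5              # steroid log-scale residual SD
    # untargeted table -----------------------------------------------------
    latent_rank: int = 5
    feature_noise_sd: float = 0.3      # study-sample residual SD (log)
    analytical_sd: float = 0.05        # QC analytical SD (log) => QC CV ~5%
    drift_amplitude: float = 0.1       # fractional intensity drift
    n_informative: int = 50
    informative_shift: float = 1.0     # log-scale class shift at CS
    missing_model: tuple[float, float] = (-2.2, 1.0)  # (intercept, slope)
    qc_missing: bool = False           # pooled QCs modelled as detected

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 4 or any(n < 2 for n in self.n_per_group):
            raise ValueError("n_per_group must be 4 integers, all >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.drift_amplitude <= 0.9:
            raise ValueError("drift_amplitude must be in [0, 0.9]")
        if self.latent_rank >= self.n_features:
            raise ValueError("latent_rank must be < n_features")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")


# fixed child-seed offsets per stage
_OFF_COHORT, _OFF_STEROID, _OFF_LABELS, _OFF_FEATURES = 11, 211, 307, 401


def _rng(cfg: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(int(cfg.seed) + offset)


def simulate_cohort(cfg: SimConfig,
                    covariates: bool = True,
                    ) -> tuple[CohortTable, SteroidMatrix, dict[str, Any]]:
    """Draw a cohort with group-graded log-normal steroid excretion.

    ``covariates=False`` switches off the sex/age/BMI terms (used by
    noise-free-limit checks).  Returns the cohort, the steroid matrix and a
    truth record holding every generating parameter.
    """
    rng_c = _rng(cfg, _OFF_COHORT)
    rng_s = _rng(cfg, _OFF_STEROID)
    rng_l = _rng(cfg, _OFF_LABELS)

    rows = []
    for g, grp in enumerate(GROUPS):
        for i in range(cfg.n_per_group[g]):
            sex = "F" if rng_c.random() < cfg.women_frac[g] else "M"
            age = float(np.clip(rng_c.normal(cfg.age_mean[g], 10.0), 18, 90))
            bmi = float(np.clip(rng_c.normal(29.0, 4.5), 17, 55))
            if grp == "NFAT":
                dst = rng_c.uniform(20, 50)
            elif grp == "MACS1":
                dst = rng_c.uniform(51, 138)
            elif grp == "MACS2":
                dst = rng_c.uniform(139, 600)
            else:
                dst = rng_c.uniform(150, 1200)
            rows.append(dict(patient_id=f"S{g}{i:04d}", group=grp, sex=sex,
                             age=round(age, 1), bmi=round(bmi, 1),
                             bilateral=bool(rng_c.random() < cfg.bilateral_prob[g]),
                             dyslipidaemia=bool(rng_c.random() < 0.3),
                             dst_cortisol=round(float(dst), 1)))
    df = pd.DataFrame(rows)

    cov = cfg.covariate_effects if covariates else {"sex_F": 0.0, "age": 0.0, "bmi": 0.0}
    gidx = df["group"].map({g: i for i, g in enumerate(GROUPS)}).to_numpy()
    cov_term = (cov["sex_F"] * (df["sex"] == "F").to_numpy(float)
                + cov["age"] * (df["age"].to_numpy() - 58.0)
                + cov["bmi"] * (df["bmi"].to_numpy() - 29.0))
    log_x = np.empty((len(df), len(STEROIDS)))
    for j, s in enumerate(STEROIDS):
        grad = np.asarray(cfg.steroid_effects[s])[gidx]
        log_x[:, j] = (np.log(BASELINES[s]) + grad + cov_term
                       + rng_s.normal(0.0, cfg.noise_sd, len(df)))
    steroids = pd.DataFrame(np.exp(log_x), index=df["patient_id"],
                            columns=list(STEROIDS))

    # comorbidity labels from the stated logistic model on z-scored logs
    z = (log_x - log_x.mean(0)) / log_x.std(0, ddof=0)
    zdf = pd.DataFrame(z, columns=list(STEROIDS))
    for flag, model in cfg.comorbidity_model.items():
        eta = np.full(len(df), model.get("intercept", 0.0))
        for name, coef in model.items():
            if name != "intercept":
                eta = eta + coef * zdf[name].to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        df[flag] = rng_l.random(len(df)) < p

    truth = dict(config=cfg, baselines=dict(BASELINES),
                 steroid_effects={k: tuple(v) for k, v in cfg.steroid_effects.items()},
                 covariate_effects=dict(cov),
                 comorbidity_model={k: dict(v) for k, v in cfg.comorbidity_model.items()},
                 noise_sd=cfg.noise_sd)
    return CohortTable(df), SteroidMatrix(steroids), truth


def _drift_curve(u: np.ndarray, scale: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth sinusoid-plus-linear multiplicative drift, shape (n, p)."""
    base = 0.6 * np.sin(2 * np.pi * 1.5 * u) + 0.4 * (2 * u - 1)
    return 1.0 + amplitude * np.outer(base, scale)


def simulate_feature_table(cfg: SimConfig, cohort: CohortTable,
                           ) -> tuple[FeatureTable, dict[str, Any]]:
    """Draw an untargeted feature table for an existing cohort.

    Log-abundance = feature baseline + low-rank latent term + graded class
    shift on the informative block + residual noise; intensities are then
    multiplied by a smooth injection-order drift, pooled-QC rows (study
    means plus analytical noise) are interleaved, and cells are deleted by a
    logistic-in-log-intensity model (lower intensity => more missing).
    """
    rng = _rng(cfg, _OFF_FEATURES)
    n = len(cohort)
    p = cfg.n_features
    n_qc = cfg.n_qc if cfg.n_qc is not None else max(2, round(n / 9))
    if n_qc < 2:
        raise ValueError("n_qc must be >= 2 (drift correction is undefined otherwise)")

    feat_ids = [f"feat{j:04d}" for j in range(p)]
    gidx = cohort.df["group"].map({g: i for i, g in enumerate(GROUPS)}).to_numpy()

    base = rng.uniform(4.0, 10.0, p)                     # ln-intensity baselines
    load = rng.normal(0.0, 0.5, (cfg.latent_rank, p))    # latent loadings
    scores = rng.normal(0.0, 1.0, (n, cfg.latent_rank))
    informative = rng.choice(p, size=cfg.n_informative, replace=False)
    informative.sort()
    signs = np.where(np.arange(cfg.n_informative) % 2 == 0, 1.0, -1.0)
    grade = np.array([0.0, 1 / 3, 2 / 3, 1.0])

    log_ab = base + scores @ load + rng.normal(0.0, cfg.feature_noise_sd, (n, p))
    shift = np.zeros((n, p))
    shift[:, informative] = np.outer(grade[gidx], signs * cfg.informative_shift)
    log_ab += shift

    # pooled-QC rows: per-feature study mean on the log scale + analytical noise
    qc_log = np.tile(log_ab.mean(0), (n_qc, 1)) + rng.normal(
        0.0, cfg.analytical_sd, (n_qc, p))

    # run order: QC positions evenly spaced over the whole injection sequence
    total = n + n_qc
    qc_pos = np.unique(np.linspace(1, total, n_qc).round().astype(int))
    while len(qc_pos) < n_qc:   # guard against rounding collisions
        cand = np.setdiff1d(np.arange(1, total + 1), qc_pos)
        qc_pos = np.sort(np.append(qc_pos, cand[0]))
    study_pos = np.setdiff1d(np.arange(1, total + 1), qc_pos)
    rng.shuffle(study_pos)      # randomised acquisition order for study rows

    all_log = np.vstack([log_ab, qc_log])
    all_pos = np.concatenate([study_pos, qc_pos])
    u = (all_pos - 1) / max(total - 1, 1)
    drift_scale = rng.uniform(0.5, 1.0, p)
    drift = _drift_curve(u, drift_scale, cfg.drift_amplitude)
    intensity = np.exp(all_log) * drift

    # MNAR deletion: p(missing) = sigmoid(a - b * centred log intensity).
    # Pooled QCs sit at the feature's typical concentration and are modelled
    # as detected unless qc_missing is set; low-quality features for filter
    # tests are planted explicitly rather than arising by default.
    a0, b = cfg.missing_model
    logi = np.log(intensity)
    centred = logi - logi.mean()
    p_miss = 1.0 / (1.0 + np.exp(-(a0 - b * centred)))
    if not cfg.qc_missing:
        p_miss[n:, :] = 0.0
    miss = rng.random(intensity.shape) < p_miss
    intensity = np.where(miss, np.nan, intensity)

    sample_ids = list(cohort.patient_ids) + [f"QC{k:03d}" for k in range(n_qc)]
    ab = pd.DataFrame(intensity, index=sample_ids, columns=feat_ids)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "sample_type": ["study"] * n + ["QC"] * n_qc,
        "injection_order": all_pos,
        "assay": "lipidomics",
        "ion_mode": "pos",
    })

    # background features spread evenly over classes; informative features
    # concentrate in the leading classes per INFORMATIVE_CLASS_WEIGHTS
    lipid_class = [LIPID_CLASSES[j % len(LIPID_CLASSES)] for j in range(p)]
    counts = np.floor(np.asarray(INFORMATIVE_CLASS_WEIGHTS)
                      * cfg.n_informative).astype(int)
    counts[0] += cfg.n_informative - counts.sum()
    informative_classes = np.repeat(LIPID_CLASSES, counts)
    for f, c in zip(informative, informative_classes):
        lipid_class[int(f)] = c

    truth = dict(
        feature_ids=feat_ids,
        informative=[feat_ids[j] for j in informative],
        informative_signs={feat_ids[j]: float(s)
                           for j, s in zip(informative, signs)},
        lipid_class=dict(zip(feat_ids, lipid_class)),
        group_grade=dict(zip(GROUPS, grade.tolist())),
        informative_shift=cfg.informative_shift,
        drift_scale=drift_scale.tolist(),
        drift_amplitude=cfg.drift_amplitude,
        latent_rank=cfg.latent_rank,
        missing_model=tuple(cfg.missing_model),
        expected_missing_fraction=float(p_miss.mean()),
        analytical_sd=cfg.analytical_sd,
        n_qc=n_qc,
    )
    return FeatureTable(ab, meta), truth


def annotations_from_truth(truth: dict[str, Any]) -> AnnotationMap:
    """Lipid-class annotation map over the full simulated feature space."""
    mapping = {f: frozenset([c]) for f, c in truth["lipid_class"].items()}
    return AnnotationMap(mapping, frozenset(truth["feature_ids"]))
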