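"""Synthetic sepsis-like cohort generator.

Generates tabular intensive-care cohorts with a fixed prevalence (default
216 septic of 640 patients), 24 numeric input features, class-conditional
distribution shifts, sporadic missing values and heterogeneous scales, so
the full training pipeline can be exercised offline.  The feature roster
follows the variables of a typical ICU sepsis table: respiratory rate,
lymphocytes (absolute and percent), white cells, neutrophils, platelets,
CRP, procalcitonin, heart rate, SpO2, temperature, systolic/diastolic/mean
blood pressure, APACHE II and SOFA severity scores, APACHE II predicted
mortality, gender and height, padded to 24 inputs with age and four
auxiliary labs (lactate, creatinine, bilirubin, INR).

Every class-conditional distribution is SYNTHETIC: families, locations and
physiologic plausibility ranges are chosen for clinical realism (septic
patients trend tachycardic, hypotensive, with raised inflammatory markers
and severity scores), not estimated from any hospital data.  Distributions
are declared once in :data:`DEFAULT_FEATURES` (versioned via
:data:`SPEC_VERSION`) and every continuous feature is modelled as a
two-component normal mixture on an identity or log scale, which also
covers the bimodal septic temperature (hypo/hyperthermia).

An effect-size dial interpolates the septic-class parameters between the
non-septic values (multiplier 0: features carry no label signal) and
beyond the defaults (large multipliers: nearly separable classes), which is
how downstream discrimination is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SPEC_VERSION",
    "FeatureSpec",
    "CohortSpec",
    "CohortDataset",
    "generate_cohort",
    "cohort_summary",
    "effect_size_dial",
    "DEFAULT_FEATURES",
]

SPEC_VERSION = "1.0"


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's class-conditional generator.

    Continuous features are two-component normal mixtures on ``scale``
    ("identity" or "log"): params = (weight1, mean1, sd1, mean2, sd2);
    a plain normal sets both components equal.  Binary features hold a
    Bernoulli probability per class.  ``lo``/``hi`` are physiologic
    plausibility clip bounds (identity scale).
    """

    name: str
    kind: str                      # "continuous" | "binary"
    scale: str = "identity"        # "identity" | "log"
    neg: tuple = ()                # non-septic params
    pos: tuple = ()                # septic params
    lo: float = -np.inf
    hi: float = np.inf


def _norm(name, neg_mu, neg_sd, pos_mu, pos_sd, lo, hi, scale="identity"):
    return FeatureSpec(name, "continuous", scale,
                       (1.0, neg_mu, neg_sd, neg_mu, neg_sd),
                       (1.0, pos_mu, pos_sd, pos_mu, pos_sd), lo, hi)


def _lognorm(name, neg_median, neg_sd, pos_median, pos_sd, lo, hi):
    return _norm(name, np.log(neg_median), neg_sd, np.log(pos_median), pos_sd,
                 lo, hi, scale="log")


#: the 24-feature roster with synthetic class-conditional distributions
DEFAULT_FEATURES: tuple = (
    _norm("RR", 16.0, 2.5, 24.0, 5.0, 6.0, 60.0),
    _lognorm("LYM", 1.9, 0.35, 0.9, 0.5, 0.1, 10.0),
    _norm("LYM100", 28.0, 7.0, 12.0, 6.0, 0.5, 60.0),
    _lognorm("WBC", 7.5, 0.30, 14.0, 0.5, 0.5, 80.0),
    _lognorm("neu", 4.5, 0.35, 11.0, 0.5, 0.2, 60.0),
    _norm("plt", 250.0, 60.0, 160.0, 80.0, 5.0, 1000.0),
    _lognorm("CRP", 6.0, 0.8, 120.0, 0.7, 0.1, 500.0),
    _lognorm("Procalcitonin", 0.08, 0.8, 4.0, 1.2, 0.01, 100.0),
    _norm("HR", 78.0, 10.0, 112.0, 15.0, 30.0, 220.0),
    _norm("spo2", 97.0, 1.5, 92.0, 4.0, 50.0, 100.0),
    # septic temperature is bimodal: hypothermic and febrile responses
    FeatureSpec("Temp", "continuous", "identity",
                (0.35, 36.8, 0.4, 36.8, 0.4),
                (0.35, 35.5, 0.6, 38.5, 0.7), 30.0, 43.0),
    _norm("BPSYS", 125.0, 12.0, 95.0, 15.0, 40.0, 250.0),
    _norm("bpDias", 75.0, 9.0, 55.0, 10.0, 20.0, 150.0),
    _norm("bpMean", 92.0, 9.0, 68.0, 11.0, 30.0, 180.0),
    _norm("Apache2_first", 8.0, 3.0, 22.0, 6.0, 0.0, 71.0),
    _norm("Sofa_first", 2.0, 1.5, 9.0, 3.5, 0.0, 24.0),
    _lognorm("Apache2_Mort", 8.0, 0.6, 40.0, 0.5, 0.5, 100.0),
    FeatureSpec("gender", "binary", neg=(0.55,), pos=(0.55,)),
    _norm("height", 168.0, 9.0, 168.0, 9.0, 140.0, 210.0),
    _norm("age", 41.0, 11.0, 46.0, 10.0, 18.0, 60.0),
    _lognorm("lactate", 1.1, 0.35, 3.2, 0.6, 0.2, 25.0),
    _lognorm("creatinine", 0.9, 0.25, 1.8, 0.6, 0.2, 20.0),
    _lognorm("bilirubin", 0.7, 0.4, 1.6, 0.8, 0.1, 40.0),
    _lognorm("inr", 1.05, 0.10, 1.5, 0.35, 0.5, 12.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort recipe: size, prevalence, feature roster, missingness, seed.

    ``effect_multiplier`` scales every septic-class parameter shift away
    from the non-septic parameters: 0 removes all label signal, 1 keeps the
    declared defaults, larger values approach separable classes.
    """

    n_patients: int = 640
    n_positive: int = 216
    features: tuple = DEFAULT_FEATURES
    missingness_rate: float = 0.05
    effect_multiplier: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.n_positive < self.n_patients):
            raise ValueError("need 0 < n_positive < n_patients")
        if len(self.features) != 24:
            raise ValueError("cohort roster must have exactly 24 features")
        if not (0.0 <= self.missingness_rate <= 0.2):
            raise ValueError("missingness_rate must lie in [0, 0.2]")
        if self.effect_multiplier < 0:
            raise ValueError("effect multiplier must be >= 0")

    def to_yaml(self, path=None) -> str:
        doc = {
            "spec_version": SPEC_VERSION,
            "n_patients": self.n_patients,
            "n_positive": self.n_positive,
            "missingness_rate": self.missingness_rate,
            "effect_multiplier": self.effect_multiplier,
            "seed": self.seed,
            "features": [
                {"name": f.name, "kind": f.kind, "scale": f.scale,
                 "neg": [float(v) for v in f.neg],
                 "pos": [float(v) for v in f.pos],
                 "lo": None if np.isinf(f.lo) else float(f.lo),
                 "hi": None if np.isinf(f.hi) else float(f.hi)}
                for f in self.features
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class CohortDataset:
    features: pd.DataFrame        # n_patients x 24
    labels: np.ndarray            # 0/1
    missing_mask: np.ndarray      # True where a value was removed
    spec: CohortSpec
    seed: Optional[int]

    def to_csv(self, path, spec_path=None) -> None:
        """Write the preprocessing CSV dialect (empty cells = missing) and,
        optionally, the generating spec as YAML beside it."""
        from .preprocessing import save_dataset_csv
        save_dataset_csv(path, self.features, self.labels)
        if spec_path is not None:
            self.spec.to_yaml(spec_path)


def _effective_pos(f: FeatureSpec, m: float) -> tuple:
    """Interpolate septic params toward (m=0) / beyond (m>1) the non-septic
    ones, componentwise."""
    return tuple(n + m * (p - n) for n, p in zip(f.neg, f.pos))


def _draw_continuous(f: FeatureSpec, params: tuple, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    w1, m1, s1, m2, s2 = params
    pick = rng.uniform(size=size) < w1
    vals = np.where(pick,
                    rng.normal(m1, abs(s1), size=size),
                    rng.normal(m2, abs(s2), size=size))
    if f.scale == "log":
        vals = np.exp(vals)
    return np.clip(vals, f.lo, f.hi)


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Draw a cohort: labels are assigned first (exact counts by
    construction), features class-conditionally, then missing entries are
    placed uniformly at random over continuous features only."""
    rng = np.random.default_rng(spec.seed)
    n, npos = spec.n_patients, spec.n_positive
    labels = np.zeros(n, dtype=int)
    labels[:npos] = 1
    labels = rng.permutation(labels)
    pos_rows = labels == 1

    cols = {}
    for f in spec.features:
        pos_params = _effective_pos(f, spec.effect_multiplier)
        if f.kind == "binary":
            p = np.where(pos_rows, pos_params[0], f.neg[0])
            cols[f.name] = (rng.uniform(size=n) < p).astype(float)
        else:
            vals = np.empty(n)
            vals[~pos_rows] = _draw_continuous(f, f.neg, int((~pos_rows).sum()), rng)
            vals[pos_rows] = _draw_continuous(f, pos_params, int(pos_rows.sum()), rng)
            cols[f.name] = vals
    X = pd.DataFrame(cols)

    mask = np.zeros((n, len(spec.features)), dtype=bool)
    if spec.missingness_rate > 0:
        continuous = np.array([f.kind == "continuous" for f in spec.features])
        hit = rng.uniform(size=mask.shape) < spec.missingness_rate
        mask = hit & continuous[None, :]
        Xv = X.to_numpy()
        Xv[mask] = np.nan
        X = pd.DataFrame(Xv, columns=X.columns)
    return CohortDataset(features=X, labels=labels, missing_mask=mask,
                         spec=spec, seed=spec.seed)


def cohort_summary(dataset: CohortDataset) -> pd.DataFrame:
    """Class-conditional mean/SD per feature (observed values only), with
    the cohort prevalence attached as ``df.attrs['prevalence']``."""
    X = dataset.features
    if len(X) == 0:
        raise ValueError("empty cohort")
    y = dataset.labels
    rows = []
    for name in X.columns:
        col = X[name]
        rows.append({
            "feature": name,
            "mean_nonseptic": col[y == 0].mean(),
            "sd_nonseptic": col[y == 0].std(ddof=0),
            "mean_septic": col[y == 1].mean(),
            "sd_septic": col[y == 1].std(ddof=0),
            "missing_frac": col.isna().mean(),
        })
    out = pd.DataFrame(rows)
    out.attrs["prevalence"] = float(np.mean(y))
    return out


def effect_size_dial(spec: CohortSpec, multiplier: float) -> CohortSpec:
    """Scale every class-conditional shift by ``multiplier`` (relative to
    the spec's current dial setting being 1x its declared shifts)."""
    if multiplier < 0:
        raise ValueError("effect multiplier must be >= 0")
    return replace(spec, effect_multiplier=spec.effect_multiplier * multiplier)
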