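"""Simulation of diabetes-anchored longitudinal cohorts with known ground truth.

The simulator stands in for an access-restricted population health extract: it
draws, per patient, a sex, an age at diabetes diagnosis (truncated normal,
mean 60.56, SD 13.83, floor 18 years), a set of comorbidities from a catalog
spanning a wide prevalence spectrum (down to below 0.001) with sex- and
age-dependent diagnosis rates, temporally ordered onset ages, and a
chronic-kidney-disease endpoint whose log-odds depend on the age at diabetes
diagnosis and on the pre-diabetes comorbidity history.  Every distributional
choice is recorded in the config, so audits can be validated by parameter
recovery rather than by eyeballing realism.

``inject_bias`` deliberately corrupts a cohort with known-magnitude failure
modes of sequence generators (female over-representation, rare-code dropout /
mode collapse, destroyed pairwise correlation, sex-specific trajectory delay,
missing sex or anchor) so that each audit can be tested against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .records import FEMALE, MALE, Cohort, CohortError, PatientRecord, Visit

__all__ = [
    "DiseaseSpec",
    "SimConfig",
    "BiasInjectionConfig",
    "GroundTruth",
    "default_disease_catalog",
    "simulate_cohort",
    "inject_bias",
    "ground_truth",
]

AGE_BANDS = ("young", "mid", "old")  # <45, 45-65, >65


def _band_of(age: np.ndarray) -> np.ndarray:
    """0=young(<45), 1=mid(45-65), 2=old(>65)."""
    return np.digitize(age, [45.0, 65.0])


@dataclass(frozen=True)
class DiseaseSpec:
    code: str
    base_prevalence: float
    female_multiplier: float = 1.0  # odds multiplier for women
    onset_age_mean: float = 55.0
    onset_age_sd: float = 12.0
    risk_weight: float = 0.0  # endpoint log-odds contribution if pre-diabetes
    # per-band odds multipliers: {"young": x, "mid": y, "old": z}; values may be
    # a single float or a {"female": f, "male": m} pair.
    age_profile: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.base_prevalence < 1.0:
            raise CohortError(f"{self.code}: base_prevalence must be in (0,1)")
        if self.onset_age_sd <= 0:
            raise CohortError(f"{self.code}: onset_age_sd must be positive")
        if self.female_multiplier <= 0:
            raise CohortError(f"{self.code}: female_multiplier must be positive")

    def band_multiplier(self, band: np.ndarray, female: np.ndarray) -> np.ndarray:
        out = np.ones(len(band))
        for i, name in enumerate(AGE_BANDS):
            spec = self.age_profile.get(name)
            if spec is None:
                continue
            if isinstance(spec, dict):
                fmult, mmult = float(spec["female"]), float(spec["male"])
            else:
                fmult = mmult = float(spec)
            sel = band == i
            out[sel & female] = fmult
            out[sel & ~female] = mmult
        return out


# Sex- and age-dependence used by the default catalog: women are diagnosed at a
# higher rate in early adulthood and late life, men during middle age.
_DEFAULT_AGE_PROFILE = {
    "young": {"female": 1.30, "male": 0.85},
    "mid": {"female": 0.85, "male": 1.30},
    "old": {"female": 1.25, "male": 0.90},
}


def default_disease_catalog(n_diseases: int = 80) -> tuple:
    """A deterministic catalog emulating ~80 comorbidities.

    Prevalences are log-spaced from 0.35 down to 5e-4; female odds multipliers
    cycle through mild imbalances plus two strongly sex-specific analogs; the
    eight most prevalent diseases carry endpoint risk weight.
    """
    prevalences = np.geomspace(0.35, 5e-4, n_diseases)
    fmults = [1.0, 1.25, 0.80, 1.10, 0.90, 1.40, 0.70, 1.05]
    out = []
    for i in range(n_diseases):
        fm = fmults[i % len(fmults)]
        if i == 10:  # cervical-cancer analog
            fm = 25.0
        elif i == 11:  # prostate-cancer analog
            fm = 0.04
        out.append(
            DiseaseSpec(
                code=f"C{i:02d}",
                base_prevalence=float(prevalences[i]),
                female_multiplier=fm,
                onset_age_mean=float(35.0 + (i * 7) % 41),  # 35..75
                onset_age_sd=float(8.0 + (i % 4) * 2.0),
                risk_weight=(0.9 - 0.1 * i) if i < 8 else 0.0,
                age_profile=dict(_DEFAULT_AGE_PROFILE),
            )
        )
    return tuple(out)


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 2000
    female_fraction: float = 0.5
    dm_age_mean: float = 60.56
    dm_age_sd: float = 13.83
    dm_age_floor: float = 18.0
    diseases: tuple = field(default_factory=default_disease_catalog)
    endpoint_intercept: float = -2.6
    endpoint_age_coef: float = 0.015
    year_range: tuple = (2003, 2022)
    # optional (start_rate, end_rate): endpoint label flipped with a probability
    # interpolated linearly across year_range (data-quality-over-time analog)
    label_noise_by_year: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise CohortError("n_patients must be >= 1")
        if not 0.0 < self.female_fraction < 1.0:
            raise CohortError("female_fraction must be in (0,1)")

    def vocabulary(self, anchor: str = "DM", endpoint: str = "CKD") -> tuple:
        return (anchor, endpoint) + tuple(d.code for d in self.diseases)


@dataclass(frozen=True)
class BiasInjectionConfig:
    female_shift_pp: float = 0.0
    rare_dropout: float = 0.0
    rare_threshold: float = 0.0
    corr_flip_pairs: tuple = ()
    trajectory_delay_years: float = 0.0
    delayed_sex: str = FEMALE
    sex_missing_rate: float = 0.0
    anchor_missing_rate: float = 0.0

    def __post_init__(self):
        for name in ("rare_dropout", "rare_threshold", "sex_missing_rate", "anchor_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortError(f"{name} must be in [0,1]")


# ---------------------------------------------------------------------------
# Vectorized generative core (shared by simulate_cohort and ground_truth)
# ---------------------------------------------------------------------------

def _draw_arrays(config: SimConfig, n: int, rng: np.random.Generator) -> dict:
    female = rng.random(n) < config.female_fraction
    a = (config.dm_age_floor - config.dm_age_mean) / config.dm_age_sd
    dm_age = truncnorm.rvs(
        a, np.inf, loc=config.dm_age_mean, scale=config.dm_age_sd,
        size=n, random_state=rng,
    )
    dm_age = np.round(dm_age, 1)

    D = len(config.diseases)
    onset = np.empty((n, D))
    flag = np.zeros((n, D), dtype=bool)
    for j, spec in enumerate(config.diseases):
        ons = np.clip(rng.normal(spec.onset_age_mean, spec.onset_age_sd, n), 0.0, 100.0)
        ons = np.round(ons, 1)
        band = _band_of(ons)
        mult = spec.band_multiplier(band, female)
        eta = logit(spec.base_prevalence) + np.where(female, np.log(spec.female_multiplier), 0.0)
        p = expit(eta + np.log(mult))
        flag[:, j] = rng.random(n) < p
        onset[:, j] = ons

    pre_flag = flag & (onset <= dm_age[:, None])
    weights = np.array([d.risk_weight for d in config.diseases])
    eta_end = config.endpoint_intercept + config.endpoint_age_coef * dm_age + pre_flag @ weights
    p_end = expit(eta_end)
    end_label = rng.random(n) < p_end
    end_age = np.round(dm_age + rng.uniform(0.5, 15.0, n), 1)

    y0, y1 = config.year_range
    year = rng.integers(y0, y1 + 1, n)
    if config.label_noise_by_year is not None:
        r0, r1 = config.label_noise_by_year
        frac = (year - y0) / max(y1 - y0, 1)
        p_flip = r0 + (r1 - r0) * frac
        flip = rng.random(n) < p_flip
        end_label = np.where(flip, ~end_label, end_label)
    return {
        "female": female, "dm_age": dm_age, "onset": onset, "flag": flag,
        "pre_flag": pre_flag, "p_end": p_end, "end_label": end_label,
        "end_age": end_age, "year": year,
    }


def simulate_cohort(config: SimConfig, anchor: str = "DM", endpoint: str = "CKD") -> Cohort:
    """Draw a cohort from the generative model.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    arr = _draw_arrays(config, config.n_patients, rng)
    codes = [d.code for d in config.diseases]
    records = []
    for i in range(config.n_patients):
        events = [(float(arr["dm_age"][i]), anchor)]
        for j in np.flatnonzero(arr["flag"][i]):
            events.append((float(arr["onset"][i, j]), codes[j]))
        if arr["end_label"][i]:
            events.append((float(arr["end_age"][i]), endpoint))
        by_age: dict = {}
        for age, code in events:
            by_age.setdefault(round(age, 1), set()).add(code)
        visits = tuple(Visit.make(age, by_age[age]) for age in sorted(by_age))
        records.append(
            PatientRecord(
                id=f"p{i:06d}",
                sex=FEMALE if arr["female"][i] else MALE,
                visits=visits,
                diagnosis_year=int(arr["year"][i]),
            )
        )
    return Cohort(
        records=tuple(records),
        vocabulary=config.vocabulary(anchor, endpoint),
        anchor_code=anchor,
        endpoint_code=endpoint,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Monte-Carlo summary of the generative model implied by a SimConfig."""

    prevalence: dict  # code -> overall prevalence
    prevalence_female: dict
    prevalence_male: dict
    sex_gap_pp: dict  # code -> 100*(female - male)
    female_fraction: float
    endpoint_rate: float
    bayes_auroc: float  # AUROC of the true endpoint probability
    n_draws: int


def ground_truth(config: SimConfig, n_draws: int = 200_000) -> GroundTruth:
    """Pure function of the config (internal RNG derived from config.seed)."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng((config.seed + 777_001) % (2**31))
    arr = _draw_arrays(config, n_draws, rng)
    female = arr["female"]
    codes = [d.code for d in config.diseases]
    prev = {c: float(arr["flag"][:, j].mean()) for j, c in enumerate(codes)}
    prev_f = {c: float(arr["flag"][female, j].mean()) for j, c in enumerate(codes)}
    prev_m = {c: float(arr["flag"][~female, j].mean()) for j, c in enumerate(codes)}
    gap = {c: 100.0 * (prev_f[c] - prev_m[c]) for c in codes}
    labels = arr["end_label"]
    if labels.all() or not labels.any():
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(labels, arr["p_end"]))
    return GroundTruth(
        prevalence=prev,
        prevalence_female=prev_f,
        prevalence_male=prev_m,
        sex_gap_pp=gap,
        female_fraction=config.female_fraction,
        endpoint_rate=float(labels.mean()),
        bayes_auroc=auroc,
        n_draws=n_draws,
    )


# ---------------------------------------------------------------------------
# Bias injector
# ---------------------------------------------------------------------------

def _rebuild(record: PatientRecord, events) -> PatientRecord:
    """Re-group (age, code) events into visits by rounded age."""
    by_age: dict = {}
    for age, code in events:
        by_age.setdefault(round(age, 1), set()).add(code)
    visits = tuple(Visit.make(age, by_age[age]) for age in sorted(by_age))
    return replace(record, visits=visits)


def _events_of(record: PatientRecord):
    out = []
    for v in record.visits:
        age = v.effective_age
        for c in v.codes:
            out.append((age, c))
    return out


def inject_bias(cohort: Cohort, bias: BiasInjectionConfig, seed: int = 0) -> Cohort:
    """Apply known-magnitude generator pathologies to a cohort copy."""
    rng = np.random.default_rng(seed)
    records = list(cohort.records)
    n = len(records)

    if bias.female_shift_pp:
        share = sum(r.sex == FEMALE for r in records) / n
        target = share + bias.female_shift_pp / 100.0
        if not 0.0 < target < 1.0:
            raise CohortError("female_shift_pp pushes the female share out of (0,1)")
        n_flip = int(round(bias.female_shift_pp / 100.0 * n))
        males = [i for i, r in enumerate(records) if r.sex == MALE]
        if n_flip > len(males):
            raise CohortError("not enough male records to realize female_shift_pp")
        for i in rng.choice(males, size=n_flip, replace=False):
            records[i] = replace(records[i], sex=FEMALE)

    if bias.rare_dropout > 0.0:
        counts: dict = {}
        for r in records:
            for c in r.codes():
                counts[c] = counts.get(c, 0) + 1
        rare = {
            c for c, k in counts.items()
            if c != cohort.anchor_code and k / n < bias.rare_threshold
        }
        if rare:
            for i, r in enumerate(records):
                hit = rare & r.codes()
                if not hit:
                    continue
                dropped = {c for c in hit if rng.random() < bias.rare_dropout}
                if dropped:
                    events = [(a, c) for a, c in _events_of(r) if c not in dropped]
                    records[i] = _rebuild(r, events)

    for pair in bias.corr_flip_pairs:
        a, b = pair
        carriers = [i for i, r in enumerate(records) if r.has_code(b)]
        ages = [records[i].first_age_of(b) for i in carriers]
        ages = [x for x in ages if x is not None] or [50.0]
        for i in carriers:  # strip b everywhere
            events = [(ag, c) for ag, c in _events_of(records[i]) if c != b]
            records[i] = _rebuild(records[i], events)
        targets = rng.choice(n, size=len(carriers), replace=False)
        for i in targets:  # re-assign independently of a
            age = float(rng.choice(ages))
            records[i] = _rebuild(records[i], _events_of(records[i]) + [(age, b)])

    if bias.trajectory_delay_years:
        d = bias.trajectory_delay_years
        for i, r in enumerate(records):
            if r.sex != bias.delayed_sex:
                continue
            events = [
                (ag if c == cohort.anchor_code else ag + d, c)
                for ag, c in _events_of(r)
            ]
            records[i] = _rebuild(r, events)

    if bias.sex_missing_rate > 0.0:
        for i, r in enumerate(records):
            if rng.random() < bias.sex_missing_rate:
                records[i] = replace(records[i], sex=None)

    if bias.anchor_missing_rate > 0.0:
        for i, r in enumerate(records):
            if r.has_code(cohort.anchor_code) and rng.random() < bias.anchor_missing_rate:
                events = [(a, c) for a, c in _events_of(r) if c != cohort.anchor_code]
                records[i] = _rebuild(r, events)

    return cohort.with_records(records)


# ---------------------------------------------------------------------------
# YAML round-trip for configs
# ---------------------------------------------------------------------------

def sim_config_to_yaml(config: SimConfig, path) -> None:
    d = {
        "n_patients": config.n_patients,
        "female_fraction": config.female_fraction,
        "dm_age_mean": config.dm_age_mean,
        "dm_age_sd": config.dm_age_sd,
        "dm_age_floor": config.dm_age_floor,
        "endpoint_intercept": config.endpoint_intercept,
        "endpoint_age_coef": config.endpoint_age_coef,
        "year_range": list(config.year_range),
        "label_noise_by_year": list(config.label_noise_by_year) if config.label_noise_by_year else None,
        "seed": config.seed,
        "diseases": [
            {
                "code": s.code,
                "base_prevalence": s.base_prevalence,
                "female_multiplier": s.female_multiplier,
                "onset_age_mean": s.onset_age_mean,
                "onset_age_sd": s.onset_age_sd,
                "risk_weight": s.risk_weight,
                "age_profile": s.age_profile,
            }
            for s in config.diseases
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def sim_config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    diseases = tuple(DiseaseSpec(**spec) for spec in d.pop("diseases"))
    d["year_range"] = tuple(d["year_range"])
    if d.get("label_noise_by_year"):
        d["label_noise_by_year"] = tuple(d["label_noise_by_year"])
    return SimConfig(diseases=diseases, **d)
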