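"""Algorithmic sex-bias forensics for synthetic cohorts.

Measures: the cohort-level Sex Bias Delta (percentage-point difference in
female representation, synthetic minus real); per-disease sex-stratified
prevalence and age-distribution fidelity; feature amplification (the
across-run correlation between a disease's sex-specific prevalence shift and
the run's Sex Bias Delta); sex-signal portability (logistic-regression sex
prediction transferred between real and synthetic cohorts); the prevalence /
relative-error curve used to locate the prevalence tier below which the
generator degrades; and standardized effect sizes (Cohen's d for continuous
features, Cohen's h for proportions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .fidelity import _ks_statistic
from .records import BOOLEAN, CONTINUOUS, FEMALE, MALE, Cohort, PatientFeatureTable, flatten

__all__ = [
    "sex_bias_delta",
    "per_feature_sex_stats",
    "feature_amplification",
    "sex_transfer_auroc",
    "prevalence_error_curve",
    "effect_sizes",
    "PrevalenceErrorCurve",
]


def _female_share(cohort: Cohort) -> float:
    sexed = [r for r in cohort.records if r.sex in (FEMALE, MALE)]
    if not sexed:
        raise ValueError("cohort has no sexed records")
    return sum(r.sex == FEMALE for r in sexed) / len(sexed)


def sex_bias_delta(real: Cohort, synth: Cohort) -> float:
    """100 * (female share in synthetic - female share in real), in pp."""
    return 100.0 * (_female_share(synth) - _female_share(real))


def _prevalence_by_sex(cohort: Cohort) -> pd.DataFrame:
    codes = cohort.comorbidity_codes
    rows = {}
    for sex in (FEMALE, MALE):
        recs = [r for r in cohort.records if r.sex == sex]
        n = len(recs)
        rows[sex] = {
            c: (sum(r.has_code(c) for r in recs) / n if n else float("nan"))
            for c in codes
        }
    return pd.DataFrame(rows)


def per_feature_sex_stats(real: Cohort, synth: Cohort) -> pd.DataFrame:
    """Per disease: prevalence by sex in both cohorts, female-male difference
    (pp), per-sex KS on age at first diagnosis among the diagnosed, and the
    sex-specific prevalence shift (synth-real in women) - (synth-real in men).
    """
    pr = _prevalence_by_sex(real)
    ps = _prevalence_by_sex(synth)
    rows = []
    for code in real.comorbidity_codes:
        row = {
            "code": code,
            "prevalence_female_real": pr.loc[code, FEMALE],
            "prevalence_male_real": pr.loc[code, MALE],
            "prevalence_female_synth": ps.loc[code, FEMALE],
            "prevalence_male_synth": ps.loc[code, MALE],
        }
        row["female_male_diff_real_pp"] = 100.0 * (
            row["prevalence_female_real"] - row["prevalence_male_real"]
        )
        row["female_male_diff_synth_pp"] = 100.0 * (
            row["prevalence_female_synth"] - row["prevalence_male_synth"]
        )
        row["sexspec_shift_pp"] = 100.0 * (
            (row["prevalence_female_synth"] - row["prevalence_female_real"])
            - (row["prevalence_male_synth"] - row["prevalence_male_real"])
        )
        for sex in (FEMALE, MALE):
            ar = [
                r.first_age_of(code)
                for r in real.records
                if r.sex == sex and r.has_code(code)
            ]
            asyn = [
                r.first_age_of(code)
                for r in synth.records
                if r.sex == sex and r.has_code(code)
            ]
            ar = [a for a in ar if a is not None]
            asyn = [a for a in asyn if a is not None]
            key = f"ks_{'female' if sex == FEMALE else 'male'}"
            if ar and asyn:
                row[key] = _ks_statistic(np.array(ar), np.array(asyn))
            else:
                row[key] = float("nan")  # disease absent in one cohort for this sex
        rows.append(row)
    return pd.DataFrame(rows).set_index("code")


def feature_amplification(runs: Sequence[tuple]) -> pd.Series:
    """Across-run correlation of per-disease sex-specific shift vs the run's
    Sex Bias Delta.  ``runs`` is a sequence of (shift_by_code: dict, delta).
    NaN where either series has zero variance."""
    if len(runs) < 3:
        raise ValueError("feature amplification needs at least 3 runs")
    deltas = np.array([d for _, d in runs], dtype=float)
    codes = list(runs[0][0])
    out = {}
    for code in codes:
        shifts = np.array([shift[code] for shift, _ in runs], dtype=float)
        if np.std(shifts) == 0 or np.std(deltas) == 0:
            out[code] = float("nan")
        else:
            out[code] = float(pearsonr(shifts, deltas)[0])
    return pd.Series(out, name="amplification_r")


def _sex_design(table: PatientFeatureTable, stats: Optional[dict] = None):
    """Feature matrix (all columns except sex) + labels; continuous columns
    median-imputed and standardized by the provided (or own) statistics."""
    frame = table.frame
    y = (frame["sex"] == FEMALE).to_numpy()
    known = frame["sex"].isin([FEMALE, MALE]).to_numpy()
    cols = [c for c in frame.columns if c != "sex"]
    blocks = []
    fitted = {} if stats is None else stats
    for c in cols:
        v = frame[c].astype(float).to_numpy()
        if table.schema[c] == CONTINUOUS:
            if stats is None:
                obs = v[~np.isnan(v)]
                med = float(np.median(obs)) if obs.size else 0.0
                mu = float(obs.mean()) if obs.size else 0.0
                sd = float(obs.std()) if obs.size else 0.0
                fitted[c] = (med, mu, sd if sd > 0 else 1.0)
            med, mu, sd = fitted[c]
            v = np.where(np.isnan(v), med, v)
            v = (v - mu) / sd
        blocks.append(v[:, None])
    return np.hstack(blocks)[known], y[known], fitted


def sex_transfer_auroc(
    source: PatientFeatureTable,
    target: PatientFeatureTable,
    seed: int = 0,
) -> float:
    """Fit L2 logistic regression predicting sex on the source table, report
    AUROC on the target table (features standardized by source statistics)."""
    xs, ys, stats = _sex_design(source)
    if len(np.unique(ys)) < 2:
        raise ValueError("source cohort has a single sex")
    xt, yt, _ = _sex_design(target, stats)
    if len(np.unique(yt)) < 2:
        raise ValueError("target cohort has a single sex")
    model = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)  # L2 default
    model.fit(xs, ys)
    return float(roc_auc_score(yt, model.predict_proba(xt)[:, 1]))


@dataclass
class PrevalenceErrorCurve:
    per_disease: pd.DataFrame  # real/synth prevalence + relative error
    summaries: dict = field(default_factory=dict)  # threshold -> {correlation, rmse, n}

    def rmse_at(self, t: float) -> float:
        return self.summaries[t]["relative_error_rmse"]

    def correlation_at(self, t: float) -> float:
        return self.summaries[t]["prevalence_correlation"]


def prevalence_error_curve(
    real: Cohort,
    synth: Cohort,
    thresholds: Sequence[float] = (0.0, 0.013, 0.05),
) -> PrevalenceErrorCurve:
    """Relative prevalence error per disease, with correlation and
    relative-error RMSE summaries over diseases at/above each threshold."""
    codes = real.comorbidity_codes
    nr, ns = len(real.records), len(synth.records)
    rows = []
    for c in codes:
        p_r = sum(r.has_code(c) for r in real.records) / nr
        p_s = sum(r.has_code(c) for r in synth.records) / ns
        rel = abs(p_s - p_r) / p_r if p_r > 0 else float("nan")
        rows.append({"code": c, "real": p_r, "synth": p_s, "relative_error": rel})
    df = pd.DataFrame(rows).set_index("code")
    summaries = {}
    for t in thresholds:
        sel = df[(df["real"] >= t) & df["relative_error"].notna()]
        if len(sel) >= 2 and sel["real"].std() > 0 and sel["synth"].std() > 0:
            corr = float(pearsonr(sel["real"], sel["synth"])[0])
        else:
            corr = float("nan")
        rmse = float(np.sqrt(np.mean(sel["relative_error"] ** 2))) if len(sel) else float("nan")
        summaries[t] = {
            "prevalence_correlation": corr,
            "relative_error_rmse": rmse,
            "n_diseases": int(len(sel)),
        }
    return PrevalenceErrorCurve(per_disease=df, summaries=summaries)


def effect_sizes(real: PatientFeatureTable, synth: PatientFeatureTable) -> pd.Series:
    """Standardized real-vs-synthetic differences per feature: Cohen's d
    (pooled SD) for continuous columns, Cohen's h (arcsine difference of
    proportions) for boolean columns.  NaN where the pooled SD is zero."""
    out = {}
    for col in real.frame.columns:
        kind = real.schema[col]
        if kind == CONTINUOUS:
            a = real.frame[col].dropna().to_numpy(dtype=float)
            b = synth.frame[col].dropna().to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                out[col] = float("nan")
                continue
            sp = np.sqrt(
                ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                / (len(a) + len(b) - 2)
            )
            out[col] = float((a.mean() - b.mean()) / sp) if sp > 0 else float("nan")
        elif kind == BOOLEAN:
            p1 = float(real.frame[col].astype(float).mean())
            p2 = float(synth.frame[col].astype(float).mean())
            out[col] = float(
                2.0 * (np.arcsin(np.sqrt(p1)) - np.arcsin(np.sqrt(p2)))
            )
    return pd.Series(out, name="effect_size")
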