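"""Privacy and novelty audits for synthetic patient tables.

Three attack families:

- *New row synthesis* (NRS): fraction of synthetic rows that match some real
  row (identical categoricals, continuous values within a tolerance relative
  to the real column range, identical missing positions); the score is the
  complement of that fraction.
- *Attribute disclosure* (DPS / DPeS): a correct-attribution attack — the
  adversary knows the key columns (default sex and age at diabetes), finds
  synthetic rows agreeing on them, and predicts the sensitive attribute by
  majority vote.  The score compares the attack accuracy against a baseline
  (modal-category guess for the full attack, uniform random guess for the
  subsampled estimate) and is clamped to [0, 1].
- *Membership inference* (MIA): a zero-knowledge distance-to-closest-record
  attacker; scores are the negative nearest-synthetic-row mixed-type distance;
  reported as AUROC plus the orientation-invariant AUROC* = max(a, 1-a) and
  the absolute advantage over random, delta = |a - 0.5|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .records import BOOLEAN, CATEGORICAL, CONTINUOUS, PatientFeatureTable

__all__ = [
    "PrivacyReport",
    "new_row_synthesis",
    "disclosure_protection",
    "membership_inference",
    "auroc_star",
    "auroc_delta",
    "privacy_report",
]


def auroc_star(auroc: float) -> float:
    """Orientation-invariant attack score max(a, 1-a)."""
    return max(auroc, 1.0 - auroc)


def auroc_delta(auroc: float) -> float:
    """Absolute advantage over random guessing |a - 0.5|."""
    return abs(auroc - 0.5)


# ---------------------------------------------------------------------------
# New row synthesis
# ---------------------------------------------------------------------------

def _encode_for_matching(real: PatientFeatureTable, synth: PatientFeatureTable):
    """Return (real, synth) numeric arrays + per-column kinds and tolerances.

    Categorical/boolean columns are integer-coded over the union of levels;
    continuous tolerances are relative to the real column range.
    """
    cols = list(real.frame.columns)
    r_parts, s_parts, tols = [], [], []
    for col in cols:
        kind = real.schema[col]
        r = real.frame[col]
        s = synth.frame[col]
        if kind == CONTINUOUS:
            rv = r.to_numpy(dtype=float)
            sv = s.to_numpy(dtype=float)
            obs = rv[~np.isnan(rv)]
            rng = float(obs.max() - obs.min()) if obs.size else 0.0
            tols.append(rng)
            r_parts.append(rv)
            s_parts.append(sv)
        else:
            levels = sorted(
                set(r.dropna().unique()) | set(s.dropna().unique()), key=str
            )
            lut = {lev: i for i, lev in enumerate(levels)}
            r_parts.append(r.map(lut).to_numpy(dtype=float))
            s_parts.append(s.map(lut).to_numpy(dtype=float))
            tols.append(-1.0)  # categorical marker: exact match required
    return np.column_stack(r_parts), np.column_stack(s_parts), np.array(tols)


def _match_matrix(
    r: np.ndarray, s: np.ndarray, tols: np.ndarray, tol: float, chunk: int = 256
) -> np.ndarray:
    """Boolean vector: for each synthetic row, does any real row match."""
    out = np.zeros(len(s), dtype=bool)
    r_nan = np.isnan(r)
    for start in range(0, len(s), chunk):
        sb = s[start : start + chunk]
        sb_nan = np.isnan(sb)
        ok = np.ones((len(sb), len(r)), dtype=bool)
        for j in range(r.shape[1]):
            rj = r[:, j][None, :]
            sj = sb[:, j][:, None]
            both_nan = sb_nan[:, j][:, None] & r_nan[:, j][None, :]
            any_nan = sb_nan[:, j][:, None] | r_nan[:, j][None, :]
            if tols[j] < 0:  # categorical: exact
                col_ok = (sj == rj) | both_nan
            else:
                col_ok = (np.abs(sj - rj) <= tol * tols[j]) | both_nan
            col_ok &= ~(any_nan & ~both_nan)
            ok &= col_ok
            if not ok.any():
                break
        out[start : start + chunk] = ok.any(axis=1)
    return out


def new_row_synthesis(
    real: PatientFeatureTable,
    synth: PatientFeatureTable,
    tol: float = 0.01,
    diagnosis_count_columns: Optional[Sequence[str]] = None,
):
    """NRS = 1 - fraction of synthetic rows matching some real row.

    Also reports the mean diagnosis count (number of true flags over the given
    boolean columns, default all boolean columns) among the matched rows.
    """
    if real.schema != synth.schema:
        raise ValueError("real and synthetic tables must share one schema")
    if len(real) == 0:
        raise ValueError("real table is empty")
    r, s, tols = _encode_for_matching(real, synth)
    matched = _match_matrix(r, s, tols, tol)
    match_fraction = float(matched.mean()) if len(s) else 0.0
    flag_cols = (
        list(diagnosis_count_columns)
        if diagnosis_count_columns is not None
        else [c for c in synth.frame.columns if synth.schema[c] == BOOLEAN]
    )
    if matched.any() and flag_cols:
        mean_dx = float(
            synth.frame.loc[matched, flag_cols].astype(float).sum(axis=1).mean()
        )
    else:
        mean_dx = float("nan")
    return 1.0 - match_fraction, {
        "match_fraction": match_fraction,
        "n_matches": int(matched.sum()),
        "mean_diagnosis_count_of_matches": mean_dx,
    }


# ---------------------------------------------------------------------------
# Attribute disclosure
# ---------------------------------------------------------------------------

def _attack_accuracy(
    real: pd.DataFrame,
    synth: pd.DataFrame,
    key_cols: Sequence[str],
    key_kinds: dict,
    key_ranges: dict,
    sensitive_col: str,
    tol: float,
    baseline_guess,
) -> float:
    """Correct-attribution attack: key-match synthetic rows, majority vote."""
    hits = 0
    synth_keys = {c: synth[c].to_numpy() for c in key_cols}
    synth_sens = synth[sensitive_col].to_numpy()
    for _, row in real.iterrows():
        mask = np.ones(len(synth), dtype=bool)
        for c in key_cols:
            v = row[c]
            sv = synth_keys[c]
            if key_kinds[c] == CONTINUOUS:
                if pd.isna(v):
                    mask &= pd.isna(sv.astype(float))
                else:
                    mask &= np.abs(sv.astype(float) - float(v)) <= tol * key_ranges[c]
            else:
                mask &= (sv == v) if not pd.isna(v) else pd.isna(sv)
            if not mask.any():
                break
        if mask.any():
            vals, counts = np.unique(synth_sens[mask].astype(str), return_counts=True)
            guess = vals[np.argmax(counts)]
        else:
            guess = baseline_guess
        if str(row[sensitive_col]) == str(guess):
            hits += 1
    return hits / len(real) if len(real) else 0.0


def disclosure_protection(
    real: PatientFeatureTable,
    synth: PatientFeatureTable,
    key_cols: Sequence[str] = ("sex", "age_at_diabetes"),
    sensitive_col: str = "CKD",
    mode: str = "full",
    n_subsamples: int = 10,
    subsample_size: int = 500,
    tol: float = 0.01,
    seed: int = 0,
) -> float:
    """Disclosure protection score in [0, 1]; 1 = attack no better than baseline.

    ``mode='full'`` attacks every real row with a modal-category baseline;
    ``mode='estimate'`` averages the attack over random real subsamples against
    a uniform-random-guess baseline.
    """
    if real.schema != synth.schema:
        raise ValueError("real and synthetic tables must share one schema")
    if real.schema.get(sensitive_col) == CONTINUOUS:
        raise ValueError("sensitive column must be discrete")
    key_kinds = {c: real.schema[c] for c in key_cols}
    key_ranges = {}
    for c in key_cols:
        if key_kinds[c] == CONTINUOUS:
            obs = real.frame[c].dropna()
            key_ranges[c] = float(obs.max() - obs.min()) if len(obs) else 1.0
    sens_real = real.frame[sensitive_col].astype(str)
    counts = sens_real.value_counts()
    if len(counts) < 2:
        return 1.0  # degenerate baseline: nothing to disclose
    rng = np.random.default_rng(seed)
    if mode == "full":
        acc_base = float(counts.iloc[0] / counts.sum())  # modal-category guess
        baseline_guess = counts.index[0]
        acc_attack = _attack_accuracy(
            real.frame, synth.frame, key_cols, key_kinds, key_ranges,
            sensitive_col, tol, baseline_guess,
        )
    elif mode == "estimate":
        acc_base = 1.0 / len(counts)  # uniform random guess over observed categories
        accs = []
        for _ in range(n_subsamples):
            size = min(subsample_size, len(real))
            idx = rng.choice(len(real), size=size, replace=False)
            sub = real.frame.iloc[idx]
            guess = str(rng.choice(counts.index.to_numpy()))
            accs.append(
                _attack_accuracy(
                    sub, synth.frame, key_cols, key_kinds, key_ranges,
                    sensitive_col, tol, guess,
                )
            )
        acc_attack = float(np.mean(accs))
    else:
        raise ValueError("mode must be 'full' or 'estimate'")
    if acc_base >= 1.0:
        return 1.0
    score = 1.0 - max(0.0, acc_attack - acc_base) / (1.0 - acc_base)
    return float(min(1.0, max(0.0, score)))


# ---------------------------------------------------------------------------
# Membership inference
# ---------------------------------------------------------------------------

def _mixed_distance_to_nearest(
    queries: PatientFeatureTable, synth: PatientFeatureTable, chunk: int = 512
) -> np.ndarray:
    """Per query row, the smallest mixed-type distance to any synthetic row:
    range-normalized absolute difference for continuous columns (ranges from
    the synthetic table), 0/1 mismatch for discrete, averaged over columns.
    Missing-vs-missing counts 0; missing-vs-present counts 1.
    """
    cols = list(synth.frame.columns)
    q_parts, s_parts, kinds, ranges = [], [], [], []
    for col in cols:
        kind = synth.schema[col]
        kinds.append(kind)
        if kind == CONTINUOUS:
            sv = synth.frame[col].to_numpy(dtype=float)
            qv = queries.frame[col].to_numpy(dtype=float)
            obs = sv[~np.isnan(sv)]
            ranges.append(float(obs.max() - obs.min()) if obs.size and obs.max() > obs.min() else 1.0)
            s_parts.append(sv)
            q_parts.append(qv)
        else:
            levels = sorted(
                set(synth.frame[col].dropna().unique())
                | set(queries.frame[col].dropna().unique()),
                key=str,
            )
            lut = {lev: i for i, lev in enumerate(levels)}
            s_parts.append(synth.frame[col].map(lut).to_numpy(dtype=float))
            q_parts.append(queries.frame[col].map(lut).to_numpy(dtype=float))
            ranges.append(1.0)
    from scipy.spatial.distance import cdist

    s = np.column_stack(s_parts)
    q = np.column_stack(q_parts)
    ranges = np.array(ranges)
    is_cont = np.array([k == CONTINUOUS for k in kinds])
    # fast path: complete columns where mismatch equals the scaled L1 gap
    # (continuous, or discrete with at most two levels coded 0/1)
    complete = ~(np.isnan(s).any(axis=0) | np.isnan(q).any(axis=0))
    two_level = np.array(
        [
            is_cont[j]
            or max(np.nanmax(s[:, j], initial=0), np.nanmax(q[:, j], initial=0)) <= 1
            for j in range(s.shape[1])
        ]
    )
    fast = complete & two_level
    slow = np.flatnonzero(~fast)
    s_fast = s[:, fast] / ranges[fast]
    q_fast = q[:, fast] / ranges[fast]
    out = np.empty(len(q))
    for start in range(0, len(q), chunk):
        qb = q[start : start + chunk]
        d = cdist(q_fast[start : start + chunk], s_fast, "cityblock")
        for j in slow:
            sj = s[:, j][None, :]
            qj = qb[:, j][:, None]
            s_nan = np.isnan(sj)
            q_nan = np.isnan(qj)
            both = q_nan & s_nan
            either = q_nan | s_nan
            if is_cont[j]:
                col_d = np.abs(qj - sj) / ranges[j]
            else:
                col_d = (qj != sj).astype(float)
            col_d = np.where(both, 0.0, np.where(either, 1.0, col_d))
            d += col_d
        d /= s.shape[1]
        out[start : start + chunk] = d.min(axis=1)
    return out


def membership_inference(
    members: PatientFeatureTable,
    nonmembers: PatientFeatureTable,
    synth: PatientFeatureTable,
    seed: int = 0,
):
    """Zero-knowledge distance-to-closest-record attack; returns
    (auroc, auroc_star, delta).  Member/non-member groups are downsampled to
    equal size with the given seed."""
    if len(synth) == 0:
        raise ValueError("synthetic table is empty")
    rng = np.random.default_rng(seed)
    n = min(len(members), len(nonmembers))
    if n == 0:
        raise ValueError("member and non-member tables must be non-empty")

    def _sample(t: PatientFeatureTable) -> PatientFeatureTable:
        if len(t) == n:
            return t
        idx = rng.choice(len(t), size=n, replace=False)
        return PatientFeatureTable(t.frame.iloc[idx].reset_index(drop=True), t.schema)

    mem = _sample(members)
    non = _sample(nonmembers)
    scores_m = -_mixed_distance_to_nearest(mem, synth)
    scores_n = -_mixed_distance_to_nearest(non, synth)
    y = np.concatenate([np.ones(n), np.zeros(n)])
    s = np.concatenate([scores_m, scores_n])
    a = float(roc_auc_score(y, s))
    return a, auroc_star(a), auroc_delta(a)


@dataclass
class PrivacyReport:
    nrs: float
    match_fraction: float
    mean_diagnosis_count_of_matches: float
    dps: float
    dpes: float
    mia_auroc: float
    mia_auroc_star: float
    mia_delta: float

    def scores(self) -> dict:
        return {
            "NRS": self.nrs,
            "DPS": self.dps,
            "DPeS": self.dpes,
            "MIA_auroc": self.mia_auroc,
            "MIA_auroc_star": self.mia_auroc_star,
            "MIA_delta": self.mia_delta,
            "match_fraction": self.match_fraction,
            "mean_diagnosis_count_of_matches": self.mean_diagnosis_count_of_matches,
        }


def privacy_report(
    members: PatientFeatureTable,
    nonmembers: PatientFeatureTable,
    synth: PatientFeatureTable,
    sensitive_col: str = "CKD",
    seed: int = 0,
    dps_subsample: int = 300,
) -> PrivacyReport:
    nrs, stats = new_row_synthesis(members, synth)
    dps = disclosure_protection(members, synth, sensitive_col=sensitive_col, mode="full")
    dpes = disclosure_protection(
        members, synth, sensitive_col=sensitive_col, mode="estimate",
        subsample_size=dps_subsample, seed=seed,
    )
    a, a_star, delta = membership_inference(members, nonmembers, synth, seed=seed)
    return PrivacyReport(
        nrs=nrs,
        match_fraction=stats["match_fraction"],
        mean_diagnosis_count_of_matches=stats["mean_diagnosis_count_of_matches"],
        dps=dps,
        dpes=dpes,
        mia_auroc=a,
        mia_auroc_star=a_star,
        mia_delta=delta,
    )
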