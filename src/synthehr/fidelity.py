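"""Distribution-and-structure fidelity metrics for synthetic cohorts.

All column-wise metrics operate on a pair of :class:`PatientFeatureTable`
objects sharing one schema; the co-occurrence correlation operates on the
cohorts themselves because it needs visit order.  Scores in [0, 1] read
"1 = perfect fidelity"; the sliced Wasserstein distance reads "0 = perfect".

Metrics
-------
- boundary adherence (BAS): synthetic continuous values inside the real range;
- category adherence (CAS): synthetic discrete values drawn from real categories;
- Kolmogorov–Smirnov complement (KSS): mean of 1 - D over continuous columns;
- total-variation complement (TVS): mean of 1 - TVD over discrete columns;
- correlation similarity (CrSS): 1 - |r_real - r_synth| / 2 averaged over
  continuous column pairs;
- contingency similarity (CtSS): 1 - |V_real - V_synth| (Cramér's V) averaged
  over column pairs, continuous members discretized into equal-width bins;
- sliced Wasserstein distance (SWD): mean 1D Wasserstein-1 distance of
  min-max-normalized features projected onto random unit directions;
- co-occurrence correlation (CoC): Pearson correlation of the real and
  synthetic ordered-pair precedence frequencies across patient trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, wasserstein_distance

from .records import BOOLEAN, CATEGORICAL, Cohort, PatientFeatureTable

__all__ = [
    "FidelityReport",
    "boundary_adherence",
    "category_adherence",
    "ks_complement",
    "tv_complement",
    "correlation_similarity",
    "contingency_similarity",
    "sliced_wasserstein",
    "cooccurrence_correlation",
    "cramers_v",
    "fidelity_report",
]


@dataclass
class MetricResult:
    score: float  # nan when undefined
    per_item: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return not np.isnan(self.score)


def _check_schema(real: PatientFeatureTable, synth: PatientFeatureTable) -> None:
    if real.schema != synth.schema:
        raise ValueError("real and synthetic tables must share one schema")


# ---------------------------------------------------------------------------
# Adherence
# ---------------------------------------------------------------------------

def boundary_adherence(real: PatientFeatureTable, synth: PatientFeatureTable) -> MetricResult:
    _check_schema(real, synth)
    per: dict = {}
    notes: list = []
    for col in real.continuous_columns:
        r = real.frame[col].to_numpy(dtype=float)
        s = synth.frame[col].to_numpy(dtype=float)
        r_obs = r[~np.isnan(r)]
        if len(s) == 0:
            continue
        if r_obs.size == 0:
            # real column entirely missing: only missing synthetic values valid
            valid = np.isnan(s)
        else:
            lo, hi = r_obs.min(), r_obs.max()
            inside = (s >= lo) & (s <= hi)
            missing_ok = np.isnan(s) & bool(np.isnan(r).any())
            valid = inside | missing_ok
        per[col] = float(valid.mean())
    if not per:
        notes.append("no continuous columns: boundary adherence undefined")
        return MetricResult(float("nan"), per, notes)
    return MetricResult(float(np.mean(list(per.values()))), per, notes)


def category_adherence(real: PatientFeatureTable, synth: PatientFeatureTable) -> MetricResult:
    _check_schema(real, synth)
    per: dict = {}
    notes: list = []
    for col in real.discrete_columns:
        r = real.frame[col]
        s = synth.frame[col]
        cats = set(r.dropna().unique())
        valid = s.isin(cats) | (s.isna() & bool(r.isna().any()))
        per[col] = float(valid.mean()) if len(s) else float("nan")
    if not per:
        notes.append("no discrete columns: category adherence undefined")
        return MetricResult(float("nan"), per, notes)
    return MetricResult(float(np.mean(list(per.values()))), per, notes)


# ---------------------------------------------------------------------------
# Univariate distribution similarity
# ---------------------------------------------------------------------------

def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic (max ECDF gap)."""
    allv = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), allv, side="right") / len(x)
    cdf_y = np.searchsorted(np.sort(y), allv, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_complement(real: PatientFeatureTable, synth: PatientFeatureTable) -> MetricResult:
    _check_schema(real, synth)
    per: dict = {}
    notes: list = []
    for col in real.continuous_columns:
        r = real.frame[col].dropna().to_numpy(dtype=float)
        s = synth.frame[col].dropna().to_numpy(dtype=float)
        if r.size == 0 or s.size == 0:
            notes.append(f"{col}: empty after missing removal, skipped")
            continue
        per[col] = 1.0 - _ks_statistic(r, s)
    if not per:
        notes.append("no scorable continuous columns")
        return MetricResult(float("nan"), per, notes)
    return MetricResult(float(np.mean(list(per.values()))), per, notes)


def tv_complement(real: PatientFeatureTable, synth: PatientFeatureTable) -> MetricResult:
    _check_schema(real, synth)
    per: dict = {}
    for col in real.discrete_columns:
        r = real.frame[col]
        s = synth.frame[col]
        cats = sorted(set(r.dropna().unique()) | set(s.dropna().unique()), key=str)
        fr = r.value_counts(normalize=True)
        fs = s.value_counts(normalize=True)
        tvd = 0.5 * sum(abs(fr.get(c, 0.0) - fs.get(c, 0.0)) for c in cats)
        per[col] = 1.0 - float(tvd)
    if not per:
        return MetricResult(float("nan"), per, ["no discrete columns"])
    return MetricResult(float(np.mean(list(per.values()))), per, [])


# ---------------------------------------------------------------------------
# Pairwise structure
# ---------------------------------------------------------------------------

def correlation_similarity(real: PatientFeatureTable, synth: PatientFeatureTable) -> MetricResult:
    """Pairwise Pearson-correlation similarity over continuous columns.

    Pair score 1 - |r_real - r_synth| / 2; the division by 2 bounds the score
    in [0, 1] (a maximal sign flip, +1 vs -1, scores 0).  Pairwise-complete
    observations; zero-variance pairs are skipped and noted.
    """
    _check_schema(real, synth)
    cols = real.continuous_columns
    per: dict = {}
    notes: list = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            rs = []
            for table in (real, synth):
                sub = table.frame[[a, b]].dropna()
                x = sub[a].to_numpy(dtype=float)
                y = sub[b].to_numpy(dtype=float)
                if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
                    rs.append(None)
                else:
                    rs.append(float(pearsonr(x, y)[0]))
            if None in rs:
                notes.append(f"({a},{b}): zero variance or too few observations, skipped")
                continue
            per[(a, b)] = 1.0 - abs(rs[0] - rs[1]) / 2.0
    if not per:
        return MetricResult(float("nan"), per, notes or ["<2 scorable continuous columns"])
    return MetricResult(float(np.mean(list(per.values()))), per, notes)


def cramers_v(x: pd.Series, y: pd.Series, levels_x=None, levels_y=None) -> float:
    """Cramér's V over the given (or observed) level sets; 0 for degenerate tables."""
    tab = pd.crosstab(x, y)
    if levels_x is not None:
        tab = tab.reindex(index=levels_x, fill_value=0)
    if levels_y is not None:
        tab = tab.reindex(columns=levels_y, fill_value=0)
    obs = tab.to_numpy(dtype=float)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0] if obs.size else obs
    n = obs.sum()
    if n == 0 or min(obs.shape) < 2:
        return 0.0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    k = min(obs.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def _discretized(table: PatientFeatureTable, col: str, edges: dict) -> pd.Series:
    if table.schema[col] in (CATEGORICAL, BOOLEAN):
        return table.frame[col].astype(object).where(table.frame[col].notna(), "<NA>")
    e = edges[col]
    binned = pd.cut(table.frame[col], bins=e, include_lowest=True)
    return binned.cat.add_categories("<NA>").fillna("<NA>").astype(object)


def contingency_similarity(
    real: PatientFeatureTable, synth: PatientFeatureTable, n_bins: int = 10
) -> MetricResult:
    """Cramér's-V similarity over all column pairs; continuous members are
    discretized into equal-width bins with edges taken from the real data."""
    _check_schema(real, synth)
    cols = list(real.frame.columns)
    edges: dict = {}
    for col in real.continuous_columns:
        r = real.frame[col].dropna().to_numpy(dtype=float)
        both = np.concatenate([r, synth.frame[col].dropna().to_numpy(dtype=float)])
        if both.size == 0:
            edges[col] = np.linspace(0, 1, n_bins + 1)
            continue
        lo = r.min() if r.size else both.min()
        hi = r.max() if r.size else both.max()
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        e = np.linspace(lo, hi, n_bins + 1)
        # widen so synthetic values outside the real range still land in a bin
        e[0] = min(e[0], both.min()) - 1e-9
        e[-1] = max(e[-1], both.max()) + 1e-9
        edges[col] = e
    per: dict = {}
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            xr, yr = _discretized(real, a, edges), _discretized(real, b, edges)
            xs, ys = _discretized(synth, a, edges), _discretized(synth, b, edges)
            lx = sorted(set(xr.unique()) | set(xs.unique()), key=str)
            ly = sorted(set(yr.unique()) | set(ys.unique()), key=str)
            vr = cramers_v(xr, yr, lx, ly)
            vs = cramers_v(xs, ys, lx, ly)
            per[(a, b)] = 1.0 - abs(vr - vs)
    if not per:
        return MetricResult(float("nan"), per, ["<2 columns"])
    return MetricResult(float(np.mean(list(per.values()))), per, [])


# ---------------------------------------------------------------------------
# Multivariate geometry
# ---------------------------------------------------------------------------

def _numeric_matrix(table: PatientFeatureTable, reference: PatientFeatureTable):
    """Encode a table numerically: flags 0/1, categories one-hot (levels from
    the reference), continuous columns median-imputed (reference median)."""
    blocks = []
    names = []
    for col in table.frame.columns:
        kind = table.schema[col]
        if kind == BOOLEAN:
            blocks.append(table.frame[col].astype(float).to_numpy()[:, None])
            names.append(col)
        elif kind == CATEGORICAL:
            levels = sorted(reference.frame[col].dropna().unique(), key=str)
            for lev in levels:
                blocks.append((table.frame[col] == lev).astype(float).to_numpy()[:, None])
                names.append(f"{col}={lev}")
        else:
            obs = reference.frame[col].dropna()
            med = float(obs.median()) if len(obs) else 0.0
            blocks.append(table.frame[col].fillna(med).to_numpy(dtype=float)[:, None])
            names.append(col)
    return np.hstack(blocks), names


def sliced_wasserstein(
    real: PatientFeatureTable,
    synth: PatientFeatureTable,
    n_directions: int = 1000,
    seed: int = 0,
) -> MetricResult:
    """Average 1D Wasserstein-1 distance along random unit directions, after
    min-max normalization of each feature to [0, 1] using real-data bounds."""
    _check_schema(real, synth)
    xr, _ = _numeric_matrix(real, real)
    xs, _ = _numeric_matrix(synth, real)
    lo = xr.min(axis=0)
    hi = xr.max(axis=0)
    keep = hi > lo  # zero-range features excluded from projection
    if not keep.any():
        return MetricResult(float("nan"), {}, ["all features have zero range"])
    xr = (xr[:, keep] - lo[keep]) / (hi[keep] - lo[keep])
    xs = (xs[:, keep] - lo[keep]) / (hi[keep] - lo[keep])
    rng = np.random.default_rng(seed)
    d = xr.shape[1]
    dirs = rng.normal(size=(n_directions, d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pr = xr @ dirs.T
    ps = xs @ dirs.T
    dists = [wasserstein_distance(pr[:, k], ps[:, k]) for k in range(n_directions)]
    return MetricResult(float(np.mean(dists)), {}, [])


# ---------------------------------------------------------------------------
# Temporal co-occurrence
# ---------------------------------------------------------------------------

def _precedence_frequencies(cohort: Cohort) -> np.ndarray:
    """f(a -> b): fraction of patients in whom a's first occurrence is at a
    strictly earlier visit index than b's, over all ordered non-anchor pairs."""
    codes = [c for c in cohort.vocabulary if c != cohort.anchor_code]
    idx = {c: k for k, c in enumerate(codes)}
    m = len(codes)
    counts = np.zeros((m, m))
    n = len(cohort.records)
    for r in cohort.records:
        first: dict = {}
        for vi, v in enumerate(r.visits):
            for c in v.codes:
                if c in idx and c not in first:
                    first[c] = vi
        present = list(first.items())
        for a, ia in present:
            for b, ib in present:
                if a != b and ia < ib:
                    counts[idx[a], idx[b]] += 1
    f = counts / n if n else counts
    mask = ~np.eye(m, dtype=bool)
    return f[mask]


def cooccurrence_correlation(real: Cohort, synth: Cohort) -> MetricResult:
    if set(real.vocabulary) != set(synth.vocabulary):
        raise ValueError("cohorts must share a vocabulary")
    fr = _precedence_frequencies(real)
    fs = _precedence_frequencies(synth)
    if len(np.unique(fr)) < 2 or len(np.unique(fs)) < 2:
        return MetricResult(float("nan"), {}, ["<2 distinct pair frequencies: undefined"])
    r = float(pearsonr(fr, fs)[0])
    return MetricResult(r, {}, [])


# ---------------------------------------------------------------------------
# Aggregated report
# ---------------------------------------------------------------------------

@dataclass
class FidelityReport:
    bas: MetricResult
    cas: MetricResult
    kss: MetricResult
    tvs: MetricResult
    crss: MetricResult
    ctss: MetricResult
    swd: MetricResult
    coc: MetricResult

    def scores(self) -> dict:
        return {
            "BAS": self.bas.score,
            "CAS": self.cas.score,
            "KSS": self.kss.score,
            "TVS": self.tvs.score,
            "CrSS": self.crss.score,
            "CtSS": self.ctss.score,
            "SWD": self.swd.score,
            "CoC": self.coc.score,
        }


def fidelity_report(
    real_cohort: Cohort,
    synth_cohort: Cohort,
    real_table: PatientFeatureTable = None,
    synth_table: PatientFeatureTable = None,
    n_directions: int = 1000,
    seed: int = 0,
    skip_pairwise: bool = False,
) -> FidelityReport:
    from .records import flatten

    rt = real_table if real_table is not None else flatten(real_cohort)
    st = synth_table if synth_table is not None else flatten(synth_cohort)
    empty = MetricResult(float("nan"), {}, ["skipped"])
    return FidelityReport(
        bas=boundary_adherence(rt, st),
        cas=category_adherence(rt, st),
        kss=ks_complement(rt, st),
        tvs=tv_complement(rt, st),
        crss=empty if skip_pairwise else correlation_similarity(rt, st),
        ctss=empty if skip_pairwise else contingency_similarity(rt, st),
        swd=sliced_wasserstein(rt, st, n_directions=n_directions, seed=seed),
        coc=cooccurrence_correlation(real_cohort, synth_cohort),
    )
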