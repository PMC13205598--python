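"""End-to-end experiment orchestration and median [min-max] aggregation.

Two robustness designs over the generate-refine-validate pipeline:

- SSMR (Single Split, Multiple Replica): one train/test split of the real
  cohort, several generator seeds — isolates generative stochasticity.
- MSSR (Multiple Split, Single Replica): several splits, one generator run
  each — isolates dependence on the particular training data.

Each run trains the generator on the real training split, samples a raw
synthetic cohort, refines it, scores fidelity and privacy on both raw and
refined cohorts against the training data, audits the sex-rate trajectory,
and runs the TSTR endpoint prediction against the real test split.  Metrics
aggregate to a median [min-max] summary table across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .daae import DAAEConfig, DAAEModel
from .fidelity import fidelity_report
from .privacy import privacy_report
from .records import Cohort, flatten
from .refine import refine_cohort, refine_for_prediction
from .simulate import SimConfig, simulate_cohort
from .trajectory import rate_difference_series, dtw_distance, _populated
from .tstr import build_task, run_tstr

__all__ = ["ExperimentPlan", "run_experiment", "summarize", "split_cohort"]

log = logging.getLogger("synthehr")


@dataclass(frozen=True)
class ExperimentPlan:
    design: str = "SSMR"
    n_runs: int = 3
    split_fraction: float = 0.8
    sim_config: SimConfig = field(default_factory=lambda: SimConfig(n_patients=2000))
    daae_config: DAAEConfig = field(default_factory=lambda: DAAEConfig(epochs=50))
    seeds: Optional[tuple] = None  # generator seeds, one per run
    split_seeds: Optional[tuple] = None
    cv: tuple = (2, 5)  # desk-scale CV for the TSTR stage
    swd_directions: int = 200
    skip_pairwise: bool = True  # pairwise metrics are O(p^2); opt in at scale

    def resolved_seeds(self):
        gen = self.seeds if self.seeds is not None else tuple(range(self.n_runs))
        if self.design == "SSMR":
            splits = (
                self.split_seeds
                if self.split_seeds is not None
                else (0,) * self.n_runs
            )
            if len(set(splits)) != 1:
                raise ValueError("SSMR requires a single shared split seed")
            if len(set(gen)) != len(gen):
                raise ValueError("SSMR requires distinct generator seeds")
        elif self.design == "MSSR":
            splits = (
                self.split_seeds
                if self.split_seeds is not None
                else tuple(range(self.n_runs))
            )
            if len(set(splits)) != len(splits):
                raise ValueError("MSSR requires distinct split seeds")
        else:
            raise ValueError("design must be 'SSMR' or 'MSSR'")
        if len(gen) != self.n_runs or len(splits) != self.n_runs:
            raise ValueError("need one generator seed and one split seed per run")
        return gen, splits


def split_cohort(cohort: Cohort, train_fraction: float, seed: int):
    """Patient-level split, stratified by endpoint status."""
    labels = [r.has_code(cohort.endpoint_code) for r in cohort.records]
    idx = np.arange(len(cohort.records))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=labels
    )
    recs = cohort.records
    return (
        cohort.with_records([recs[i] for i in sorted(train_idx)]),
        cohort.with_records([recs[i] for i in sorted(test_idx)]),
    )


def _run_once(real: Cohort, plan: ExperimentPlan, gen_seed: int, split_seed: int) -> dict:
    import dataclasses

    train, test = split_cohort(real, plan.split_fraction, split_seed)
    dcfg = dataclasses.replace(plan.daae_config, seed=gen_seed)
    results = DAAEModel(train, dcfg).fit()
    raw = results.sample(len(train.records), seed=gen_seed + 10_000)
    refined, discard = refine_cohort(raw)
    metrics: dict = {"discard_fraction": discard.fraction_total_discarded}

    train_table = flatten(train)
    test_table = flatten(test)
    for tag, cohort in (("raw", raw), ("refined", refined)):
        if not cohort.records:
            continue
        rep = fidelity_report(
            train, cohort, real_table=train_table,
            n_directions=plan.swd_directions, seed=gen_seed,
            skip_pairwise=plan.skip_pairwise,
        )
        for name, score in rep.scores().items():
            metrics[f"{name}_{tag}"] = score
        priv = privacy_report(
            train_table, test_table, flatten(cohort),
            sensitive_col=real.endpoint_code, seed=gen_seed,
        )
        metrics[f"NRS_{tag}"] = priv.nrs
        metrics[f"DPeS_{tag}"] = priv.dpes
        metrics[f"MIA_auroc_{tag}"] = priv.mia_auroc
        try:
            orig_series = rate_difference_series(train)
            rep_series = rate_difference_series(cohort)
            common = _populated(orig_series) & _populated(rep_series)
            if common.any():
                metrics[f"DTW_{tag}"] = dtw_distance(
                    orig_series.diff[common], rep_series.diff[common]
                )
        except ValueError:
            pass

    pred_refined, _ = refine_for_prediction(refined)
    pred_train, _ = refine_for_prediction(train)
    pred_test, _ = refine_for_prediction(test)
    try:
        real_task = build_task(pred_train)
        synth_task = build_task(pred_refined)
        test_task = build_task(pred_test)
        for scenario in ("real", "synthetic", "hybrid"):
            res = run_tstr(
                real_task, synth_task, test_task,
                scenario=scenario, cv=plan.cv, seed=gen_seed,
            )
            metrics[f"TSTR_auroc_{scenario}"] = res.mean_auroc
            metrics[f"TSTR_auroc_sd_{scenario}"] = res.sd_auroc
    except ValueError as exc:
        metrics["TSTR_error"] = str(exc)
    return metrics


def run_experiment(plan: ExperimentPlan):
    """Run every replica of the plan; failed runs are recorded and excluded
    from the summary.  Returns (summary table, per-run metric dicts)."""
    gen_seeds, split_seeds = plan.resolved_seeds()
    real = simulate_cohort(plan.sim_config)
    per_run = []
    for k, (gs, ss) in enumerate(zip(gen_seeds, split_seeds)):
        log.info("run %d/%d: generator seed %d, split seed %d", k + 1, plan.n_runs, gs, ss)
        try:
            metrics = _run_once(real, plan, gs, ss)
            metrics["run"] = k
            metrics["generator_seed"] = gs
            metrics["split_seed"] = ss
            metrics["failed"] = False
        except Exception as exc:  # noqa: BLE001 - runs must not kill the batch
            log.warning("run %d failed: %s", k, exc)
            metrics = {"run": k, "failed": True, "error": str(exc)}
        per_run.append(metrics)
    ok = [m for m in per_run if not m.get("failed")]
    if len(ok) < len(per_run):
        log.warning("%d of %d runs failed; summary excludes them", len(per_run) - len(ok), len(per_run))
    return summarize(ok), per_run


def summarize(per_run) -> pd.DataFrame:
    """Median [min-max] per metric across runs."""
    if not per_run:
        raise ValueError("summarize needs at least one successful run")
    skip = {"run", "generator_seed", "split_seed", "failed", "error"}
    names = [k for k in per_run[0] if k not in skip]
    rows = []
    for name in names:
        vals = np.array(
            [
                m[name]
                for m in per_run
                if isinstance(m.get(name), (int, float, np.floating))
                and np.isfinite(m[name])
            ]
        )
        if vals.size == 0:
            continue
        rows.append(
            {
                "metric": name,
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n_runs": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
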