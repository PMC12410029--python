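"""End-to-end policy benchmark on synthetic cohorts.

For each (scenario, policy, seed) cell: generate a pool, freeze a
subject-level test set, optionally run the audit, curate a training
cohort under a fixed budget, train a classifier, and evaluate the
fairness panel on the frozen test set. Policies:

- ``naive``                 — collect at the pool's empirical prevalence
- ``naive_calibrated``      — naive plus Platt-style score recalibration
                              (the calibration comparator; note AUROC is
                              invariant to monotone recalibration)
- ``balanced_erm``          — equal per-group counts at the budget
- ``aequity_guided``        — audit-diagnosed plan (balanced or
                              prioritised), training label unchanged
- ``aequity_guided_label``  — guided plan plus label selection: trains on
                              the audit's least-biased outcome

Evaluation always uses the cohort's true-need outcome when one exists, so
proxy-label policies are scored against what they should have predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .aeq_analysis import AEqConfig
from .classifiers import make_classifier
from .cohort import Cohort
from .curation import (
    CurationPlan,
    apply_plan,
    balanced_erm_baseline,
    freeze_test_set,
    plan_collection,
)
from .fairness import FairnessReport, evaluate
from .pipeline import audit_config, run_diagnosis
from .synthetic_data import ScenarioConfig, generate

__all__ = ["POLICIES", "BenchmarkConfig", "run_cell", "benchmark_suite"]

POLICIES = (
    "naive",
    "naive_calibrated",
    "balanced_erm",
    "aequity_guided",
    "aequity_guided_label",
)


@dataclass(frozen=True)
class BenchmarkConfig:
    budget: int | None = None  # default: half the post-freeze pool
    backend: str = "logistic"
    test_fraction: float = 0.2
    initial_fraction: float = 0.5  # balanced pilot sample, as a share of budget
    diag_n_boot: int = 20
    eval_n_boot: int = 50
    aeq: AEqConfig | None = None
    alpha: float = 0.05


def _prevalence_counts(pools: dict[str, int], budget: int) -> dict[str, int]:
    total = sum(pools.values())
    groups = sorted(pools)
    raw = {g: budget * pools[g] / total for g in groups}
    counts = {g: int(np.floor(raw[g])) for g in groups}
    for g in sorted(groups, key=lambda g: (-(raw[g] - np.floor(raw[g])), g)):
        if sum(counts.values()) >= budget:
            break
        counts[g] += 1
    return counts


def _train_outcome(cohort: Cohort, policy: str, diagnosis) -> str:
    names = cohort.outcome_names
    if policy == "aequity_guided_label" and diagnosis is not None:
        return diagnosis.selected_outcome or names[0]
    if "proxy" in names:  # status quo trains on the proxy label
        return "proxy"
    return names[0]


def _eval_outcome(cohort: Cohort) -> str:
    names = cohort.outcome_names
    return "need" if "need" in names else names[0]


def run_cell(
    scenario: str,
    policy: str,
    seed: int,
    config: BenchmarkConfig | None = None,
    scenario_config: ScenarioConfig | None = None,
) -> dict:
    """One benchmark cell; returns a flat record including the report."""
    config = config or BenchmarkConfig()
    if policy not in POLICIES:
        raise ValueError(f"unknown policy '{policy}' (have {POLICIES})")
    sc = scenario_config or ScenarioConfig(scenario=scenario, seed=seed)
    if sc.scenario != scenario or sc.seed != seed:
        sc = replace(sc, scenario=scenario, seed=seed)
    cohort, truth = generate(sc)
    pool, test, registry = freeze_test_set(cohort, config.test_fraction, seed)
    pools = pool.counts_by_group()
    budget = config.budget or sum(pools.values()) // 2

    diagnosis = None
    if policy.startswith("aequity"):
        aeq_cfg = config.aeq or audit_config(n_boot=config.diag_n_boot)
        diagnosis = run_diagnosis(pool, aeq_cfg, seed=seed, alpha=config.alpha)

    if policy in ("naive", "naive_calibrated"):
        plan = CurationPlan(
            mode="naive-prevalence",
            budget=budget,
            current_counts={g: 0 for g in pools},
            target_counts=_prevalence_counts(pools, budget),
        )
        curated = apply_plan(plan, pool, seed=seed, test_registry=registry)
    elif policy == "balanced_erm":
        curated = balanced_erm_baseline(pool, budget, seed=seed)
        plan = None
    else:
        n_init = int(config.initial_fraction * budget)
        current = {g: n_init // len(pools) for g in sorted(pools)}
        plan = plan_collection(diagnosis, budget, current, pools)
        curated = apply_plan(plan, pool, seed=seed, test_registry=registry)

    y_train = _train_outcome(curated, policy, diagnosis)
    y_eval = _eval_outcome(test)
    clf = make_classifier(config.backend, seed=seed)
    clf.fit(curated.features(), curated.outcome(y_train))
    scores = clf.predict_proba(test.features())

    if policy == "naive_calibrated":
        # Platt-style recalibration on a held-in slice of the curated data
        cal = LogisticRegression(max_iter=1000)
        cal_scores = clf.predict_proba(curated.features())[:, None]
        cal.fit(cal_scores, curated.outcome(y_train))
        scores = cal.predict_proba(scores[:, None])[:, 1]

    report = evaluate(
        scores,
        test.outcome(y_eval),
        test.group_labels(),
        threshold=0.5,
        n_boot=config.eval_n_boot,
        seed=seed,
        subject_ids=test.subject_ids(),
    )
    return {
        "scenario": scenario,
        "policy": policy,
        "seed": seed,
        "budget": budget,
        "train_outcome": y_train,
        "eval_outcome": y_eval,
        "diagnosis": None if diagnosis is None else diagnosis.dataset_bias.category,
        "prioritized_group": None if diagnosis is None else diagnosis.prioritized_group,
        "counts": curated.counts_by_group(),
        "report": report,
    }


def benchmark_suite(
    policies: list[str],
    scenarios: list[str],
    n_seeds: int = 20,
    config: BenchmarkConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Long-format results over (scenario, policy, seed) cells.

    A failing cell is recorded with its error and the suite continues.
    """
    rows = []
    for scenario in scenarios:
        for seed_offset in range(n_seeds):
            seed = base_seed + seed_offset
            for policy in policies:
                try:
                    cell = run_cell(scenario, policy, seed, config)
                    rep: FairnessReport = cell.pop("report")
                    row = dict(cell)
                    a, b = rep.group_pair
                    for metric in ("auroc", "tpr", "fnr", "ppv", "fdr"):
                        row[f"{metric}_{a}"] = rep.metrics[a][metric]
                        row[f"{metric}_{b}"] = rep.metrics[b][metric]
                        row[f"bias_{metric}"] = rep.bias[metric]
                    row["abs_bias_auroc"] = rep.abs_bias("auroc")
                    row["error"] = None
                except Exception as exc:  # cell isolation: log and continue
                    row = {
                        "scenario": scenario,
                        "policy": policy,
                        "seed": seed,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                rows.append(row)
    return pd.DataFrame(rows)
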