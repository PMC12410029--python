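"""Turning a diagnosis into a data-collection plan, and materialising it.

The guided rule set is the paper-style mapping: sampling bias -> balanced
collection; complexity bias -> prioritise the higher-AEq group; no bias ->
collect at the empirical prevalence. Plans respect a fixed total budget N
and per-group pool limits via a greedy waterfall (prioritised group first,
spill to balanced allocation when its pool is exhausted).

A test-set registry enforces the no-overlap contract: test subjects are
frozen before any curation and can never re-enter a curated cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bias_diagnosis import BiasDiagnosis
from .cohort import Cohort

__all__ = [
    "CurationPlan",
    "PlanError",
    "plan_collection",
    "apply_plan",
    "balanced_erm_baseline",
    "freeze_test_set",
]


class PlanError(ValueError):
    pass


@dataclass
class CurationPlan:
    mode: str  # "balanced" | "prioritize:<group>" | "naive-prevalence"
    budget: int
    current_counts: dict[str, int]
    target_counts: dict[str, int]
    selected_outcome: str | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.target_counts.values()):
            raise PlanError("target counts must be nonnegative")
        if sum(self.target_counts.values()) > self.budget:
            raise PlanError("target counts exceed the budget")

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "budget": self.budget,
                "current_counts": self.current_counts,
                "target_counts": self.target_counts,
                "selected_outcome": self.selected_outcome,
                "notes": self.notes,
            },
            **kw,
        )


def _balanced_targets(groups: list[str], budget: int, pools: Mapping[str, int]) -> tuple[dict, list]:
    """Equal split with lexicographic remainder, pool-capped with spill."""
    groups = sorted(groups)
    targets = {g: 0 for g in groups}
    notes: list[str] = []
    remaining = budget
    while remaining > 0:
        open_groups = [g for g in groups if targets[g] < pools[g]]
        if not open_groups:
            notes.append(f"all pools exhausted with {remaining} of the budget unspent")
            break
        share, extra = divmod(remaining, len(open_groups))
        progressed = False
        for i, g in enumerate(open_groups):
            add = min(share + (1 if i < extra else 0), pools[g] - targets[g])
            if add:
                targets[g] += add
                remaining -= add
                progressed = True
            if targets[g] == pools[g]:
                notes.append(f"pool exhausted for group {g} at {pools[g]}")
        if not progressed:
            break
    return targets, notes


def _prevalence_targets(budget: int, pools: Mapping[str, int]) -> tuple[dict, list]:
    """Largest-remainder proportional allocation, pool-capped."""
    groups = sorted(pools)
    total = sum(pools.values())
    if total == 0:
        raise PlanError("empty pool")
    raw = {g: budget * pools[g] / total for g in groups}
    targets = {g: min(int(np.floor(raw[g])), pools[g]) for g in groups}
    leftovers = sorted(groups, key=lambda g: (-(raw[g] - np.floor(raw[g])), g))
    i = 0
    notes: list[str] = []
    while sum(targets.values()) < min(budget, total) and i < 10 * len(groups):
        g = leftovers[i % len(groups)]
        if targets[g] < pools[g]:
            targets[g] += 1
        i += 1
    return targets, notes


def plan_collection(
    diagnosis: BiasDiagnosis,
    budget: int,
    current_counts: Mapping[str, int],
    pool_counts: Mapping[str, int],
) -> CurationPlan:
    """Map a diagnosis to target per-group counts under budget and pools.

    sampling -> balanced; complexity -> prioritise the diagnosed group
    (all incremental capacity until its pool is exhausted, then spill to
    balanced over the rest); none -> prevalence-proportional; mixed ->
    prioritise, with a warning note.
    """
    groups = sorted(pool_counts)
    current = {g: int(current_counts.get(g, 0)) for g in groups}
    pools = {g: int(pool_counts[g]) for g in groups}
    if budget < sum(current.values()):
        raise PlanError(
            f"budget {budget} below already-collected total {sum(current.values())}"
        )
    for g in groups:
        if current[g] > pools[g]:
            raise PlanError(f"current count for {g} exceeds its pool")

    category = diagnosis.dataset_bias.category
    notes: list[str] = []
    if category in ("sampling",):
        mode = "balanced"
        targets, notes = _balanced_targets(groups, budget, pools)
    elif category in ("complexity", "mixed"):
        pg = diagnosis.prioritized_group
        if pg is None or pg not in groups:
            raise PlanError(f"diagnosis prioritizes unknown group {pg!r}")
        mode = f"prioritize:{pg}"
        if category == "mixed":
            notes.append("mixed diagnosis: prioritisation chosen, interpret with care")
        targets = dict(current)
        increment = budget - sum(current.values())
        take = min(increment, pools[pg] - current[pg])
        targets[pg] += take
        increment -= take
        if increment > 0:
            notes.append(
                f"pool for prioritised group {pg} exhausted at {pools[pg]}; "
                f"spilling {increment} to balanced allocation"
            )
            others = [g for g in groups if g != pg]
            spill_pools = {g: pools[g] - targets[g] for g in others}
            spill, spill_notes = _balanced_targets(others, increment, spill_pools)
            for g in others:
                targets[g] += spill[g]
            notes += spill_notes
    else:  # none
        mode = "naive-prevalence"
        targets, notes = _prevalence_targets(budget, pools)

    return CurationPlan(
        mode=mode,
        budget=budget,
        current_counts=current,
        target_counts=targets,
        selected_outcome=diagnosis.selected_outcome,
        notes=notes,
    )


def freeze_test_set(
    pool: Cohort, test_fraction: float = 0.2, seed: int = 0
) -> tuple[Cohort, Cohort, frozenset[str]]:
    """Split off a held-out test set by *subject*, before any curation.

    Returns (train_pool, test_set, registry of frozen test subject_ids).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7E57)))
    subjects = np.unique(pool.subject_ids())
    n_test = int(round(test_fraction * subjects.size))
    test_subjects = frozenset(rng.choice(subjects, size=n_test, replace=False).tolist())
    mask = np.array([s in test_subjects for s in pool.subject_ids()])
    return pool.subset(~mask), pool.subset(mask), test_subjects


def apply_plan(
    plan: CurationPlan,
    pool: Cohort,
    seed: int = 0,
    test_registry: frozenset[str] | None = None,
) -> Cohort:
    """Materialise a plan: seeded sampling without replacement per group.

    Any overlap between the pool and registered test subjects is an error
    (the no-overlapping-patients contract).
    """
    if test_registry:
        overlap = set(pool.subject_ids()) & set(test_registry)
        if overlap:
            raise PlanError(
                f"pool contains {len(overlap)} registered test subjects "
                f"(e.g. {sorted(overlap)[:3]}); freeze the test set first"
            )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA7)))
    parts = []
    labels = pool.group_labels()
    for g in sorted(plan.target_counts):
        want = plan.target_counts[g]
        idx = np.flatnonzero(labels == g)
        if want > idx.size:
            raise PlanError(f"plan wants {want} from group {g}, pool has {idx.size}")
        take = rng.choice(idx, size=want, replace=False)
        parts.append(np.sort(take))
    sel = np.concatenate(parts) if parts else np.array([], dtype=int)
    mask = np.zeros(pool.n, dtype=bool)
    mask[sel] = True
    return pool.subset(mask)


def balanced_erm_baseline(pool: Cohort, budget: int, seed: int = 0) -> Cohort:
    """Balanced empirical risk minimisation: equal per-group counts at N.

    The paper-style comparator policy; identical machinery to a balanced
    plan (odd budgets break ties lexicographically by group name).
    """
    pools = pool.counts_by_group()
    targets, notes = _balanced_targets(sorted(pools), budget, pools)
    plan = CurationPlan(
        mode="balanced",
        budget=budget,
        current_counts={g: 0 for g in pools},
        target_counts=targets,
        notes=notes,
    )
    return apply_plan(plan, pool, seed=seed)
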