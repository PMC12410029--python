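import numpy as np
import pytest

from aequity.bias_diagnosis import BiasDiagnosis, DatasetBias
from aequity.curation import (
    PlanError,
    apply_plan,
    balanced_erm_baseline,
    freeze_test_set,
    plan_collection,
)
from tests.conftest import make_cohort


def diagnosis(category, prioritized=None, selected="outcome") -> BiasDiagnosis:
    return BiasDiagnosis(
        outcome="outcome",
        label_bias={"selected_outcome": selected},
        dataset_bias=DatasetBias(category, prioritized),
        evidence={},
    )


class TestPlanCollection:
    def test_prioritize_with_pool_cap_spills_to_balanced(self):
        """Complexity at N=1000 from (250,250), pool (A:2000, B:400):
        B fills to its pool of 400, the remaining 200 spill to A -> 600."""
        plan = plan_collection(
            diagnosis("complexity", "B"), 1000, {"A": 250, "B": 250}, {"A": 2000, "B": 400}
        )
        assert plan.target_counts == {"A": 600, "B": 400}
        assert any("spill" in note for note in plan.notes)

    def test_prioritize_without_cap(self):
        plan = plan_collection(
            diagnosis("complexity", "B"), 1000, {"A": 300, "B": 300}, {"A": 5000, "B": 5000}
        )
        assert plan.target_counts == {"A": 300, "B": 700}

    def test_no_bias_prevalence_proportional(self):
        plan = plan_collection(diagnosis("none"), 100, {"A": 0, "B": 0}, {"A": 700, "B": 300})
        assert plan.target_counts == {"A": 70, "B": 30}

    def test_sampling_balanced_split(self):
        plan = plan_collection(diagnosis("sampling"), 100, {"A": 0, "B": 0}, {"A": 500, "B": 500})
        assert plan.target_counts == {"A": 50, "B": 50}

    def test_odd_budget_tie_break_lexicographic(self):
        plan = plan_collection(diagnosis("sampling"), 201, {"A": 0, "B": 0}, {"A": 500, "B": 500})
        assert plan.target_counts == {"A": 101, "B": 100}

    def test_infeasible_budget_rejected(self):
        with pytest.raises(PlanError, match="budget"):
            plan_collection(diagnosis("sampling"), 100, {"A": 80, "B": 80}, {"A": 500, "B": 500})

    def test_plan_never_exceeds_budget_or_pools(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            pools = {g: int(rng.integers(10, 400)) for g in "AB"}
            budget = int(rng.integers(20, 600))
            cat = rng.choice(["sampling", "complexity", "none", "mixed"])
            pri = "B" if cat in ("complexity", "mixed") else None
            try:
                plan = plan_collection(diagnosis(cat, pri), budget, {"A": 0, "B": 0}, pools)
            except PlanError:
                continue
            assert sum(plan.target_counts.values()) <= budget
            assert all(plan.target_counts[g] <= pools[g] for g in pools)


class TestApplyPlan:
    def test_exact_counts_and_determinism(self):
        pool = make_cohort(n=400, seed=2)
        plan = plan_collection(diagnosis("sampling"), 100, {"A": 0, "B": 0}, pool.counts_by_group())
        c1 = apply_plan(plan, pool, seed=7)
        c2 = apply_plan(plan, pool, seed=7)
        assert c1.counts_by_group() == {"A": 50, "B": 50}
        assert sorted(c1.subject_ids()) == sorted(c2.subject_ids())

    def test_registered_test_subjects_block_overlapping_pool(self):
        cohort = make_cohort(n=400, seed=3)
        train_pool, test, registry = freeze_test_set(cohort, 0.2, seed=0)
        assert not set(train_pool.subject_ids()) & set(test.subject_ids())
        plan = plan_collection(
            diagnosis("sampling"), 100, {"A": 0, "B": 0}, cohort.counts_by_group()
        )
        with pytest.raises(PlanError, match="test subjects"):
            apply_plan(plan, cohort, seed=0, test_registry=registry)  # un-split pool overlaps

    def test_plan_exceeding_pool_rejected(self):
        pool = make_cohort(n=60, seed=4)  # only 30 per group actually available
        plan = plan_collection(diagnosis("sampling"), 100, {"A": 0, "B": 0},
                               {"A": 500, "B": 500})
        with pytest.raises(PlanError):
            apply_plan(plan, pool, seed=0)


class TestBalancedErm:
    def test_equal_counts(self):
        pool = make_cohort(n=600, seed=5)
        curated = balanced_erm_baseline(pool, 200, seed=1)
        assert curated.counts_by_group() == {"A": 100, "B": 100}

    def test_odd_budget_deterministic_tie_break(self):
        pool = make_cohort(n=600, seed=5)
        curated = balanced_erm_baseline(pool, 201, seed=1)
        assert curated.counts_by_group() == {"A": 101, "B": 100}

    def test_sampling_diagnosis_plan_equals_balanced_erm(self):
        """When the diagnosis is sampling bias, the guided plan and the
        balanced-ERM comparator allocate identical target counts."""
        pool = make_cohort(n=600, seed=6)
        pools = pool.counts_by_group()
        plan = plan_collection(diagnosis("sampling"), 240, {"A": 0, "B": 0}, pools)
        erm = balanced_erm_baseline(pool, 240, seed=2)
        assert plan.target_counts == erm.counts_by_group()
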