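
import numpy as np
import pytest

from aequity.aeq_analysis import (
    AEqConfig,
    AEqResult,
    compare_aeq,
    compare_aeq_family,
    compute_aeq,
)
from aequity.learning_curve import ScopeSizeError
from tests.conftest import make_cohort

FAST = AEqConfig(grid=(16, 32, 64, 128), n_boot=6)


def fake_result(values, outcome="o", group="g", fp=("fp",)) -> AEqResult:
    values = np.asarray(values, dtype=float)
    return AEqResult(
        outcome=outcome,
        group=group,
        aeq=float(values.mean()),
        boot_values=values,
        ci95=(float(values.min()), float(values.max())),
        n_boot=len(values),
        n_scope=100,
        flags=[],
        config_fingerprint=fp,
    )


class TestComputeAeq:
    def test_identical_groups_same_seed_identical_aeq(self):
        """Two groups that are byte-identical copies of the same examples
        must receive exactly the same AEq under the same seed."""
        base = make_cohort(n=600, groups=("A",), seed=5)
        dfB = base.data.copy()
        dfB["group"] = "B"
        dfB["subject_id"] = "b" + dfB["subject_id"]
        both = base.data.merge(dfB, how="outer")
        from aequity.cohort import Cohort

        cohort = Cohort(both, base.feature_cols)
        rA = compute_aeq(cohort, "outcome", "A", config=FAST, seed=11)
        rB = compute_aeq(cohort, "outcome", "B", config=FAST, seed=11)
        assert rA.aeq == rB.aeq
        np.testing.assert_array_equal(rA.boot_values, rB.boot_values)

    def test_deterministic_json(self, small_cohort):
        r1 = compute_aeq(small_cohort, "outcome", "A", config=FAST, seed=3)
        r2 = compute_aeq(small_cohort, "outcome", "A", config=FAST, seed=3)
        assert r1.to_json(sort_keys=True) == r2.to_json(sort_keys=True)

    def test_scope_too_small_names_deficit(self):
        tiny = make_cohort(n=60, seed=1)
        with pytest.raises(ScopeSizeError, match="deficit"):
            compute_aeq(tiny, "outcome", "A", config=FAST, seed=0)

    def test_joint_scope_runs_group_balanced(self, small_cohort):
        r = compute_aeq(small_cohort, "outcome", "joint", config=FAST, seed=0)
        assert r.group == "joint"
        assert len(r.boot_values) == FAST.n_boot


class TestCompareAeq:
    def test_self_comparison_is_null(self):
        r = fake_result([5.0, 5.1, 4.9, 5.05])
        cmp_ = compare_aeq(r, r)
        assert cmp_.delta == 0.0
        assert cmp_.p_adjusted == 1.0

    def test_delta_sign_and_symmetry(self):
        a = fake_result([6.0, 6.1, 5.9], group="a")
        b = fake_result([5.0, 5.1, 4.9], group="b")
        ab, ba = compare_aeq(a, b), compare_aeq(b, a)
        assert ab.delta == pytest.approx(-ba.delta)
        assert ab.p_raw == pytest.approx(ba.p_raw)

    def test_needs_two_boot_values(self):
        with pytest.raises(ValueError):
            compare_aeq(fake_result([5.0]), fake_result([5.0, 5.1]))

    def test_unpaired_fallback_when_sizes_differ(self):
        a = fake_result([6.0, 6.1, 5.9, 6.05], group="a")
        b = fake_result([5.0, 5.1, 4.9], group="b")
        cmp_ = compare_aeq(a, b)
        assert "unpaired" in cmp_.test
        assert cmp_.ci95[0] <= cmp_.delta <= cmp_.ci95[1]


class TestCompareFamily:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        a = fake_result(rng.normal(5, 0.1, 20), group="a")
        b = fake_result(rng.normal(5.05, 0.1, 20), group="b")
        raw = compare_aeq(a, b, family_size=1).p_raw
        adj3 = compare_aeq(a, b, family_size=3).p_adjusted
        assert adj3 == pytest.approx(min(1.0, raw * 3))

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(1)
        a = fake_result(rng.normal(5, 0.2, 10), group="a")
        b = fake_result(rng.normal(5, 0.2, 10), group="b")
        assert compare_aeq(a, b, family_size=50).p_adjusted == 1.0

    def test_anova_and_pairwise(self):
        rng = np.random.default_rng(2)
        results = [fake_result(rng.normal(5, 0.1, 15), group=g) for g in "abc"]
        comparisons, anova = compare_aeq_family(results)
        assert len(comparisons) == 3
        assert anova["F"] is not None and 0 <= anova["p_raw"] <= 1

    def test_family_smaller_than_pairs_rejected(self):
        rng = np.random.default_rng(3)
        results = [fake_result(rng.normal(5, 0.1, 10), group=g) for g in "abc"]
        with pytest.raises(ValueError):
            compare_aeq_family(results, family_size=2)

    def test_null_anova_type_one_error_controlled(self):
        """Three identical-distribution scopes: the rejection rate at
        alpha=0.05 stays at or below 0.10 over 100 simulated repetitions."""
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(100):
            results = [fake_result(rng.normal(5, 0.3, 12), group=g) for g in "abc"]
            _, anova = compare_aeq_family(results)
            rejections += anova["p_raw"] < 0.05
        assert rejections / 100 <= 0.10


class TestGroupRelabeling:
    def test_group_names_permute_without_changing_values(self, small_cohort):
        """Swapping group names permutes results but not AEq values."""
        swapped = small_cohort.data.copy()
        swapped["group"] = swapped["group"].map({"A": "B", "B": "A"})
        from aequity.cohort import Cohort

        sw = Cohort(swapped, small_cohort.feature_cols)
        orig_A = compute_aeq(small_cohort, "outcome", "A", config=FAST, seed=2)
        new_B = compute_aeq(sw, "outcome", "B", config=FAST, seed=2)
        assert orig_A.aeq == new_B.aeq
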