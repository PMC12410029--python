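import numpy as np
import pytest

from aequity.aeq_analysis import AEqComparison, AEqResult
from aequity.bias_diagnosis import (
    DiagnosisError,
    detect_residual_unfairness,
    diagnose_dataset_bias,
    diagnose_label_bias,
)


def comparison(delta, ci, p_adj, a=("o", "g1"), b=("o", "g2")) -> AEqComparison:
    return AEqComparison(
        scope_a=a, scope_b=b, delta=delta, ci95=ci, p_raw=p_adj, p_adjusted=p_adj,
        test="welch-t",
    )


def result(mean, sd, n, group, outcome="o", fp=("cfg",), seed=0) -> AEqResult:
    vals = np.random.default_rng(seed).normal(mean, sd, n)
    se = vals.std(ddof=1) / np.sqrt(n)
    return AEqResult(
        outcome=outcome, group=group, aeq=float(vals.mean()), boot_values=vals,
        ci95=(float(vals.mean() - 1.96 * se), float(vals.mean() + 1.96 * se)),
        n_boot=n, n_scope=1000, flags=[], config_fingerprint=fp, seed=seed,
    )


class TestLabelBias:
    def test_cost_style_deltas_flag_and_selection(self):
        """A cost-like outcome with delta 0.47 (CI 0.36-0.52) is flagged;
        a chronic-conditions-like outcome with delta 0.06 (CI -0.04 to
        0.16) is not, and is selected as least biased."""
        deltas = {
            "cost": comparison(0.47, (0.36, 0.52), 0.001),
            "chronic": comparison(0.06, (-0.04, 0.16), 0.4),
        }
        block = diagnose_label_bias(deltas)
        assert block["flagged"] == {"cost": True, "chronic": False}
        assert block["selected_outcome"] == "chronic"

    def test_single_null_outcome(self):
        block = diagnose_label_bias({"only": comparison(0.0, (-0.1, 0.1), 1.0)})
        assert block["flagged"] == {"only": False}
        assert block["selected_outcome"] == "only"

    def test_tie_broken_by_wider_ci_overlap_with_zero(self):
        deltas = {
            "narrow": comparison(0.10, (0.05, 0.15), 0.5),
            "wide": comparison(0.10, (-0.20, 0.40), 0.5),
        }
        assert diagnose_label_bias(deltas)["selected_outcome"] == "wide"

    def test_multi_stratum_evidence_summed(self):
        deltas = {
            "proxy": [comparison(0.4, (0.3, 0.5), 0.01), comparison(-0.3, (-0.5, -0.1), 0.01)],
            "need": [comparison(0.05, (-0.1, 0.2), 0.9), comparison(-0.02, (-0.2, 0.1), 0.9)],
        }
        block = diagnose_label_bias(deltas)
        assert block["selected_outcome"] == "need"
        assert block["flagged"]["proxy"] and not block["flagged"]["need"]

    def test_empty_rejected(self):
        with pytest.raises(DiagnosisError):
            diagnose_label_bias({})


class TestDatasetBias:
    def test_joint_pulled_to_higher_group_is_complexity(self):
        """Joint at the higher group's value and significantly above the
        lower one, groups differing: the complexity signature."""
        by_group = {"W": result(7.00, 0.18, 50, "W", seed=1),
                    "B": result(6.60, 0.18, 50, "B", seed=2)}
        joint = result(7.00, 0.18, 50, "joint", seed=3)
        bias, evidence, trace = diagnose_dataset_bias(by_group, joint)
        assert bias.category == "complexity"
        assert bias.prioritized_group == "W"  # the higher-AEq group
        assert any(s["step"] == "rule-fired" for s in trace)

    def test_identical_groups_is_sampling(self):
        by_group = {"A": result(6.0, 0.2, 40, "A", seed=4),
                    "B": result(6.0, 0.2, 40, "B", seed=5)}
        joint = result(5.95, 0.2, 40, "joint", seed=6)
        bias, _, _ = diagnose_dataset_bias(by_group, joint)
        assert bias.category == "sampling"
        assert bias.prioritized_group is None

    def test_joint_above_every_group_is_complexity(self):
        by_group = {"A": result(5.5, 0.15, 50, "A", seed=7),
                    "B": result(5.6, 0.15, 50, "B", seed=8)}
        joint = result(6.4, 0.15, 50, "joint", seed=9)
        bias, _, _ = diagnose_dataset_bias(by_group, joint)
        assert bias.category == "complexity"
        assert bias.prioritized_group == "B"

    def test_groups_differ_joint_at_lower_value_sampling_with_warning(self):
        by_group = {"A": result(5.2, 0.15, 50, "A", seed=10),
                    "B": result(6.2, 0.15, 50, "B", seed=11)}
        joint = result(5.15, 0.15, 50, "joint", seed=12)
        bias, _, _ = diagnose_dataset_bias(by_group, joint)
        assert bias.category == "sampling"
        assert bias.warnings  # residual-heterogeneity warning emitted

    def test_exactly_one_category(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            by_group = {g: result(rng.uniform(5, 7), 0.2, 30, g, seed=100 + trial * 3 + i)
                        for i, g in enumerate("AB")}
            joint = result(rng.uniform(5, 7), 0.2, 30, "joint", seed=200 + trial)
            bias, _, _ = diagnose_dataset_bias(by_group, joint)
            assert bias.category in ("sampling", "complexity", "mixed", "none")

    def test_group_relabeling_preserves_category(self):
        kw = dict(sd=0.18, n=50)
        b1, _, _ = diagnose_dataset_bias(
            {"X": result(7.0, 0.18, 50, "X", seed=1), "Y": result(6.6, 0.18, 50, "Y", seed=2)},
            result(7.0, 0.18, 50, "joint", seed=3),
        )
        b2, _, _ = diagnose_dataset_bias(
            {"Y": result(7.0, 0.18, 50, "Y", seed=1), "X": result(6.6, 0.18, 50, "X", seed=2)},
            result(7.0, 0.18, 50, "joint", seed=3),
        )
        assert b1.category == b2.category
        assert b1.prioritized_group == "X" and b2.prioritized_group == "Y"

    def test_config_mismatch_rejected(self):
        by_group = {"A": result(6.0, 0.2, 30, "A", fp=("g1",)),
                    "B": result(6.0, 0.2, 30, "B", fp=("g2",))}
        with pytest.raises(DiagnosisError, match="config"):
            diagnose_dataset_bias(by_group, result(6.0, 0.2, 30, "joint", fp=("g1",)))


class TestResidualUnfairness:
    def test_identical_groups_not_flagged(self):
        post = {"A": result(6.0, 0.2, 40, "A", seed=21),
                "B": result(6.0, 0.2, 40, "B", seed=22)}
        assert detect_residual_unfairness(post)["residual_unfairness"] is False

    def test_separated_groups_flagged(self):
        post = {"A": result(5.5, 0.1, 40, "A", seed=23),
                "B": result(6.5, 0.1, 40, "B", seed=24)}
        assert detect_residual_unfairness(post)["residual_unfairness"] is True

    def test_single_group_rejected(self):
        with pytest.raises(DiagnosisError):
            detect_residual_unfairness({"A": result(6.0, 0.2, 40, "A")})
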