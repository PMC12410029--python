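"""Classifying dataset bias from AEq relations.

Three mechanisms are distinguished:

- **label bias** (performance-invariant): for some candidate outcome the
  two groups' AEq values differ significantly — the label does not mean
  the same thing for both groups. Mitigation: pick the outcome with the
  smallest between-group AEq difference.
- **sampling bias**: groups share a distribution but one is
  under-represented; the joint AEq sits at or below the over-represented
  group's value and the group AEqs agree. Mitigation: balanced collection.
- **complexity bias**: one group is intrinsically more heterogeneous; the
  joint AEq exceeds every group's value, or is pulled toward the higher
  group's value while the groups differ. Mitigation: prioritise
  collection from the higher-AEq group.

All rules are gated on significance (Bonferroni-adjusted t tests on
bootstrap AEq replicates plus percentile CIs), and every comparison the
decision consulted is recorded in an ordered ``decision_trace``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .aeq_analysis import AEqComparison, AEqResult, compare_aeq

__all__ = [
    "BiasDiagnosis",
    "DatasetBias",
    "diagnose_label_bias",
    "diagnose_dataset_bias",
    "detect_residual_unfairness",
]


class DiagnosisError(ValueError):
    pass


@dataclass
class DatasetBias:
    category: str  # sampling | complexity | mixed | none
    prioritized_group: str | None
    warnings: list[str] = field(default_factory=list)


@dataclass
class BiasDiagnosis:
    """Full diagnosis for one outcome (plus label evidence across outcomes)."""

    outcome: str
    label_bias: dict
    dataset_bias: DatasetBias
    evidence: dict
    decision_trace: list[dict] = field(default_factory=list)

    @property
    def prioritized_group(self) -> str | None:
        return self.dataset_bias.prioritized_group

    @property
    def selected_outcome(self) -> str | None:
        return self.label_bias.get("selected_outcome")

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "label_bias": self.label_bias,
            "dataset_bias": {
                "category": self.dataset_bias.category,
                "prioritized_group": self.dataset_bias.prioritized_group,
                "warnings": self.dataset_bias.warnings,
            },
            "evidence": self.evidence,
            "decision_trace": self.decision_trace,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_markdown(self) -> str:
        db = self.dataset_bias
        lines = [
            f"# Bias diagnosis — outcome `{self.outcome}`",
            "",
            f"- dataset bias: **{db.category}**",
            f"- prioritized group: **{db.prioritized_group or 'none (balanced collection)'}**",
            f"- selected outcome (label-bias rule): **{self.selected_outcome}**",
        ]
        if db.warnings:
            lines += [""] + [f"> warning: {w}" for w in db.warnings]
        lines += ["", "## Decision trace", ""]
        for step in self.decision_trace:
            lines.append(f"- {step['step']}: {step.get('detail', '')}")
        return "\n".join(lines)


def _ci_zero_margin(ci: tuple[float, float]) -> float:
    """How comfortably a CI covers zero (negative if it excludes zero)."""
    lo, hi = ci
    return min(hi, -lo)


def diagnose_label_bias(
    deltas: Mapping[str, "AEqComparison | list[AEqComparison]"], alpha: float = 0.05
) -> dict:
    """Flag label-biased outcomes and select the least-biased one.

    Each outcome maps to one between-group comparison or to several (one
    per label stratum, mirroring per-risk-category audits); an outcome's
    distributional difference is the sum of \\|delta\\| over its strata.
    An outcome is flagged when any of its comparisons is significant
    (adjusted p < alpha and CI excluding 0). The selected outcome
    minimises the summed \\|delta\\|; ties break toward the wider CI
    overlap with 0, then lexicographic outcome name.
    """
    if not deltas:
        raise DiagnosisError("diagnose_label_bias needs at least one outcome comparison")
    flagged = {}
    rows = []
    detail = {}
    for name in sorted(deltas):
        cmps = deltas[name]
        if isinstance(cmps, AEqComparison):
            cmps = [cmps]
        if not cmps:
            raise DiagnosisError(f"outcome '{name}' has no comparisons")
        flagged[name] = bool(any(c.significant(alpha) for c in cmps))
        score = sum(abs(c.delta) for c in cmps)
        margin = min(_ci_zero_margin(c.ci95) for c in cmps)
        rows.append((score, -margin, name))
        detail[name] = {
            "abs_delta_sum": score,
            "comparisons": [c.to_dict() for c in cmps],
            # backwards-friendly single-comparison view
            "delta": cmps[0].delta if len(cmps) == 1 else score,
            "ci95": list(cmps[0].ci95) if len(cmps) == 1 else None,
        }
    rows.sort()
    selected = rows[0][2]
    return {
        "flagged": {k: v for k, v in flagged.items()},
        "any_flagged": any(flagged.values()),
        "delta_by_outcome": detail,
        "selected_outcome": selected,
        "alpha": alpha,
    }


def _closer_to_high(
    joint: AEqResult, hi: AEqResult, lo: AEqResult, alpha: float, family: int
) -> tuple[bool, dict]:
    """Is the joint AEq significantly closer to the higher group's value?

    Statistic: T = |AEq_joint - AEq_hi| - |AEq_joint - AEq_lo| on the
    bootstrap means, with a percentile CI from paired resampling of the
    replicate triples (joint_i, hi_i, lo_i). Closer-to-high requires the
    whole CI below zero.
    """
    m = min(len(joint.boot_values), len(hi.boot_values), len(lo.boot_values))
    vj = np.asarray(joint.boot_values[:m])
    vh = np.asarray(hi.boot_values[:m])
    vl = np.asarray(lo.boot_values[:m])
    T = abs(vj.mean() - vh.mean()) - abs(vj.mean() - vl.mean())
    rng = np.random.default_rng(0x5EED)
    idx = rng.integers(0, m, size=(1000, m))
    Tb = np.abs(vj[idx].mean(1) - vh[idx].mean(1)) - np.abs(vj[idx].mean(1) - vl[idx].mean(1))
    ci = (float(np.percentile(Tb, 2.5)), float(np.percentile(Tb, 97.5)))
    p = float(2 * min(np.mean(Tb >= 0), np.mean(Tb <= 0)))  # two-sided percentile p
    p_adj = min(1.0, p * family)
    closer = T < 0 and p_adj < alpha and ci[1] < 0
    detail = {"T": float(T), "ci95": list(ci), "p_adjusted": p_adj}
    return closer, detail


def diagnose_dataset_bias(
    aeq_by_group: Mapping[str, AEqResult],
    aeq_joint: AEqResult,
    alpha: float = 0.05,
    outcome: str | None = None,
) -> tuple[DatasetBias, dict, list[dict]]:
    """Decide sampling vs complexity (vs mixed) from joint/group AEq relations.

    Returns (DatasetBias, evidence, decision_trace). The Bonferroni family
    is the full set of tests this call performs.
    """
    if len(aeq_by_group) < 2:
        raise DiagnosisError("dataset-bias diagnosis needs >= 2 groups")
    fps = {r.config_fingerprint for r in aeq_by_group.values()} | {aeq_joint.config_fingerprint}
    if len(fps) > 1:
        raise DiagnosisError("scopes were computed under different configs (grid/epsilon/stratum)")

    groups = sorted(aeq_by_group)
    by_aeq = sorted(groups, key=lambda g: (aeq_by_group[g].aeq, g))
    lo_g, hi_g = by_aeq[0], by_aeq[-1]
    lo_r, hi_r = aeq_by_group[lo_g], aeq_by_group[hi_g]

    n_pairs = len(groups) * (len(groups) - 1) // 2
    family = n_pairs + len(groups) + 1  # pairs + joint-vs-each + closeness test

    trace: list[dict] = []
    comparisons: dict[str, dict] = {}

    cmp_hi_lo = compare_aeq(hi_r, lo_r, family_size=family)
    comparisons[f"{hi_g}-vs-{lo_g}"] = cmp_hi_lo.to_dict()
    groups_differ = cmp_hi_lo.significant(alpha)
    trace.append(
        {
            "step": "groups-differ",
            "detail": f"AEq({hi_g})-AEq({lo_g}) = {cmp_hi_lo.delta:.3f}, "
            f"p_adj={cmp_hi_lo.p_adjusted:.3g} -> {groups_differ}",
        }
    )

    joint_vs = {}
    for g in groups:
        c = compare_aeq(aeq_joint, aeq_by_group[g], family_size=family)
        comparisons[f"joint-vs-{g}"] = c.to_dict()
        joint_vs[g] = c
    joint_exceeds_all = all(c.delta > 0 and c.significant(alpha) for c in joint_vs.values())
    trace.append(
        {
            "step": "joint-exceeds-every-group",
            "detail": f"{joint_exceeds_all} "
            + ", ".join(f"{g}: {joint_vs[g].delta:+.3f}" for g in groups),
        }
    )
    joint_sig_above_min = joint_vs[lo_g].delta > 0 and joint_vs[lo_g].significant(alpha)

    closer, closer_detail = _closer_to_high(aeq_joint, hi_r, lo_r, alpha, family)
    comparisons["joint-closer-to-high"] = closer_detail
    trace.append({"step": "joint-closer-to-high-group", "detail": f"{closer} {closer_detail}"})

    warnings: list[str] = []
    if joint_exceeds_all or (groups_differ and closer):
        category, prioritized = "complexity", hi_g
        rule = "complexity: joint AEq above every group, or pulled to the higher group"
    elif not groups_differ and not joint_sig_above_min:
        category, prioritized = "sampling", None
        rule = "sampling: group AEqs agree and joint is at/below the minimum group"
    elif groups_differ and not joint_sig_above_min:
        category, prioritized = "sampling", None
        rule = "sampling with residual heterogeneity: joint at/below the lower group"
        warnings.append(
            "group AEqs differ but the joint sits at the lower (oversampled-like) "
            "value; balanced collection chosen, residual heterogeneity possible"
        )
    else:
        category, prioritized = "mixed", hi_g
        rule = "mixed: no single mechanism's signature; prioritising the higher-AEq group"
        warnings.append("dataset-bias signature ambiguous (mixed); interpret with care")
    trace.append({"step": "rule-fired", "detail": rule})

    evidence = {
        "aeq_by_group": {g: aeq_by_group[g].to_dict() for g in groups},
        "aeq_joint": aeq_joint.to_dict(),
        "comparisons": comparisons,
        "alpha": alpha,
        "bonferroni_family": family,
    }
    return DatasetBias(category, prioritized, warnings), evidence, trace


def detect_residual_unfairness(
    post_aeq_by_group: Mapping[str, AEqResult], alpha: float = 0.05
) -> dict:
    """Post-intervention check: do group AEqs still differ for one outcome?"""
    if len(post_aeq_by_group) < 2:
        raise DiagnosisError("residual-unfairness check needs >= 2 groups")
    groups = sorted(post_aeq_by_group)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    flag = False
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            c = compare_aeq(post_aeq_by_group[a], post_aeq_by_group[b], family_size=n_pairs)
            pairwise[f"{a}-vs-{b}"] = c.to_dict()
            flag = flag or c.significant(alpha)
    return {"residual_unfairness": bool(flag), "pairwise": pairwise, "alpha": alpha}
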