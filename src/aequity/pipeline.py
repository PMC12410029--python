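"""High-level audit pipeline: cohort in, BiasDiagnosis out.

Mirrors the guided-collection workflow: (1) compute AEq per (group,
outcome) within each label stratum and pick the least-biased outcome
(label-bias scan); (2) on the working outcome, compute per-group and
group-balanced joint AEq and classify the dataset bias mechanism.
"""

from __future__ import annotations

from dataclasses import replace


from .aeq_analysis import (
    JOINT,
    AEqConfig,
    AEqResult,
    compare_aeq,
    compute_aeq,
)
from .bias_diagnosis import (
    BiasDiagnosis,
    diagnose_dataset_bias,
    diagnose_label_bias,
)
from .cohort import Cohort
from .encoders import Encoder

__all__ = ["AUDIT_GRID", "AUDIT_LADDER", "ladder_grid", "audit_config", "run_label_bias_scan", "run_diagnosis"]

# Small-sample audit grid: AEq is designed to work on a few percent of the
# data, and modest scopes (strata of ~500 examples) must still fit. The
# half-octave (factor sqrt-2) spacing stabilises the decay-curve fit, and
# the low start keeps the convergence point off the grid floor.
AUDIT_GRID: tuple[int, ...] = (16, 23, 32, 45, 64, 91, 128, 181, 256, 362, 512)

# full half-octave ladder; scans pick the longest prefix their scope allows
AUDIT_LADDER: tuple[int, ...] = AUDIT_GRID + (724, 1024)


def ladder_grid(scope_size: int, ladder: tuple[int, ...] = AUDIT_LADDER) -> tuple[int, ...]:
    """Longest ladder prefix whose largest size fits the 60% training split."""
    limit = int(0.6 * scope_size)
    grid = tuple(g for g in ladder if g <= limit)
    if len(grid) < 4:
        raise ValueError(f"scope of {scope_size} examples is too small for a learning curve")
    return grid


def audit_config(
    n_boot: int = 50,
    grid: tuple[int, ...] = AUDIT_GRID,
    stratum: int | None = None,
    **kw,
) -> AEqConfig:
    return AEqConfig(grid=grid, n_boot=n_boot, stratum=stratum, **kw)


def _audit_scope_size(cohort: Cohort, outcome: str, config: AEqConfig) -> int:
    """Equalised per-scope audit-subset size: the smallest group scope.

    Comparing scopes of unequal size confounds AEq with pool size (a
    smaller pool converges later), so the audit draws the same number of
    examples from every scope — the balanced-subset protocol.
    """
    sub = cohort
    if config.stratum is not None:
        sub = sub.restrict_stratum(outcome, config.stratum)
    counts = sub.counts_by_group()
    return min(counts.values())


def run_label_bias_scan(
    cohort: Cohort,
    config: AEqConfig | None = None,
    encoder: Encoder | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    strata: tuple[int, ...] | None = (1, 0),
) -> dict:
    """Between-group AEq difference per candidate outcome.

    Audited per label stratum (both the positive and the negative
    assignment by default — the per-risk-category protocol: "the patients
    assigned this label" and "the patients not assigned it" are each a
    population whose group composition the label should not distort).
    ``strata=None`` audits each outcome's full scope once instead.
    Two-group cohorts only; the Bonferroni family is the number of
    (outcome, stratum) comparisons.
    """
    config = config or audit_config()
    groups = cohort.groups
    if len(groups) != 2:
        raise ValueError("label-bias scan is defined for exactly 2 groups")
    g1, g2 = groups
    strata_list: list[int | None] = list(strata) if strata is not None else [None]
    deltas: dict[str, list] = {}
    results: dict[tuple[str, str, int | None], AEqResult] = {}
    family = len(cohort.outcome_names) * len(strata_list)
    # one equalised scope size for the whole scan: comparisons across
    # outcomes then share their subsample structure and scope-size effects
    # cancel instead of masquerading as label differences
    scan_size = min(
        _audit_scope_size(cohort, outcome, replace(config, stratum=stratum))
        for outcome in cohort.outcome_names
        for stratum in strata_list
    )
    scan_grid = ladder_grid(scan_size, AUDIT_LADDER[: len(AUDIT_GRID) + 1])
    for outcome in cohort.outcome_names:
        per_outcome = []
        for stratum in strata_list:
            cfg = replace(config, stratum=stratum, scope_size=scan_size, grid=scan_grid)
            r1 = compute_aeq(cohort, outcome, g1, encoder, cfg, seed)
            r2 = compute_aeq(cohort, outcome, g2, encoder, cfg, seed)
            results[(outcome, g1, stratum)] = r1
            results[(outcome, g2, stratum)] = r2
            per_outcome.append(compare_aeq(r1, r2, family_size=family))
        deltas[outcome] = per_outcome
    block = diagnose_label_bias(deltas, alpha)
    block["group_order"] = [g1, g2]
    block["strata"] = [s if s is not None else "all" for s in strata_list]
    return {"label_bias": block, "aeq_results": results, "deltas": deltas}


def run_diagnosis(
    cohort: Cohort,
    config: AEqConfig | None = None,
    encoder: Encoder | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    outcome: str | None = None,
) -> BiasDiagnosis:
    """Full diagnosis: label-bias scan (when several outcomes exist), then
    sampling/complexity classification on the working outcome."""
    config = config or audit_config()
    if outcome is None and len(cohort.outcome_names) > 1:
        scan = run_label_bias_scan(cohort, config, encoder, seed, alpha)
        label_block = scan["label_bias"]
        outcome = label_block["selected_outcome"]
    else:
        outcome = outcome or cohort.outcome_names[0]
        if len(cohort.outcome_names) > 1:
            scan = run_label_bias_scan(cohort, config, encoder, seed, alpha)
            label_block = scan["label_bias"]
        else:
            label_block = {
                "flagged": {outcome: False},
                "any_flagged": False,
                "delta_by_outcome": {},
                "selected_outcome": outcome,
                "alpha": alpha,
                "note": "single outcome; label-bias scan not applicable",
            }

    ds_config = replace(config, stratum=None)
    ds_size = _audit_scope_size(cohort, outcome, ds_config)
    ds_grid = tuple(g for g in ds_config.grid if g <= 0.6 * ds_size)
    if len(ds_grid) < 4:
        raise ValueError(
            f"smallest group scope ({ds_size} examples) leaves fewer than 4 "
            "grid sizes; provide a smaller grid or more data"
        )
    ds_config = replace(ds_config, scope_size=ds_size, grid=ds_grid)
    by_group = {
        g: compute_aeq(cohort, outcome, g, encoder, ds_config, seed) for g in cohort.groups
    }
    joint = compute_aeq(cohort, outcome, JOINT, encoder, ds_config, seed)
    dataset_bias, evidence, trace = diagnose_dataset_bias(by_group, joint, alpha, outcome)
    return BiasDiagnosis(
        outcome=outcome,
        label_bias=label_block,
        dataset_bias=dataset_bias,
        evidence=evidence,
        decision_trace=trace,
    )
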