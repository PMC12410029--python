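"""Canned validation experiments on the synthetic study conditions.

Each function runs one self-contained experiment — generate cohorts under
the canonical scenario settings, run the audit or the curation benchmark,
and measure a rate or an error — and returns plain numbers. They back
both the validation test suite and the reproduction script, so the
numbers those report are always recomputed from scratch.

Problem sizes (replicate counts, grids) are the package's standard
desk-scale settings: large enough for the rates to be stable, small
enough to run on a single CPU in minutes.
"""

from __future__ import annotations

import numpy as np

from .aeq_analysis import compare_aeq, compute_aeq
from .benchmark import BenchmarkConfig, run_cell
from .fairness import FairnessReport, bias_reduction
from .learning_curve import LearningCurve, convergence_size, fit_decay_curve
from .pipeline import audit_config, run_diagnosis, run_label_bias_scan
from .synthetic_data import ScenarioConfig, generate

__all__ = [
    "worked_example_reductions",
    "curve_fit_battery",
    "null_coverage",
    "mechanism_recovery",
    "label_selection_rate",
    "guided_collection_benchmark",
]

LN2 = float(np.log(2.0))


def _report_with_bias(value: float) -> FairnessReport:
    return FairnessReport(
        groups=["A", "B"], group_pair=("A", "B"), threshold=0.5,
        n_per_group={}, metrics={}, ci95={}, bias={"auroc": value},
    )


def worked_example_reductions() -> dict[str, float]:
    """Bias-reduction percentages for two published AUROC-gap pairs.

    Inputs are pre/post between-group AUROC gaps (in percentage points)
    reported for two chest-radiograph findings; the reductions are
    computed by the package's own formula.
    """
    edema = bias_reduction(_report_with_bias(5.0), _report_with_bias(2.0))
    atelectasis = bias_reduction(_report_with_bias(6.4), _report_with_bias(0.6))
    return {
        "edema_pct": float(edema["percent"]),
        "atelectasis_pct": float(round(atelectasis["percent"], 1)),
    }


def curve_fit_battery(seed: int = 0, n_cases: int = 20) -> dict[str, float]:
    """Noiseless decay-curve recovery against the closed form.

    Returns the worst relative parameter error and the worst deviation of
    the located convergence point from the analytic solution
    u* = log2(b c^2 (ln 2)^2 / eps) / c.
    """
    rng = np.random.default_rng(seed)
    grid = (16, 32, 64, 128, 256, 512)
    worst_param = 0.0
    worst_ustar = 0.0
    for _ in range(n_cases):
        a = float(rng.uniform(0.0, 0.3))
        b = float(rng.uniform(0.5, 5.0))
        c = float(rng.uniform(0.3, 2.0))
        eps = float(rng.uniform(1e-4, 1e-2))
        losses = a + b * np.asarray(grid, float) ** (-c)
        curve = LearningCurve(grid=grid, losses=losses[None, :])
        fit_decay_curve(curve)
        fa, fb, fc = curve.fit_params
        worst_param = max(
            worst_param,
            abs(fa - a) / max(a, 1e-3),
            abs(fb - b) / b,
            abs(fc - c) / c,
        )
        convergence_size(curve, epsilon=eps)
        analytic = max(np.log2(b * (c * LN2) ** 2 / eps) / c, np.log2(grid[0]))
        worst_ustar = max(worst_ustar, abs(curve.aeq - analytic))
    return {"max_rel_param_error": worst_param, "max_ustar_deviation": worst_ustar}


def null_coverage(
    n_reps: int = 40, base_seed: int = 0, n_per_group: int = 4000, n_boot: int = 20
) -> float:
    """Fraction of null repetitions whose AEq-difference CI covers zero.

    Two groups drawn i.i.d. from one distribution; the audit compares
    their AEq values and the CI of the difference should cover 0.
    """
    covered = 0
    for i in range(n_reps):
        seed = base_seed * 1000 + i
        cohort, _ = generate(
            ScenarioConfig(scenario="none", n_per_group=n_per_group, seed=seed)
        )
        cfg = audit_config(n_boot=n_boot)
        rA = compute_aeq(cohort, "outcome", "A", config=cfg, seed=seed)
        rB = compute_aeq(cohort, "outcome", "B", config=cfg, seed=seed)
        lo, hi = compare_aeq(rA, rB).ci95
        covered += lo <= 0.0 <= hi
    return covered / n_reps


def mechanism_recovery(
    scenario: str, n_seeds: int = 20, base_seed: int = 0, n_boot: int = 40
) -> float:
    """Fraction of seeded cohorts whose dataset-bias mechanism is
    classified correctly (sampling or complexity, at default effect
    sizes)."""
    want = {"sampling": "sampling", "complexity": "complexity"}[scenario]
    hits = 0
    for i in range(n_seeds):
        seed = base_seed * 1000 + i
        cohort, _ = generate(ScenarioConfig(scenario=scenario, seed=seed))
        diag = run_diagnosis(cohort, audit_config(n_boot=n_boot), seed=seed)
        hits += diag.dataset_bias.category == want
    return hits / n_seeds


def label_selection_rate(n_seeds: int = 20, base_seed: int = 0, n_boot: int = 20) -> float:
    """Fraction of label-scenario cohorts for which the audit selects the
    undistorted (true-need) outcome."""
    hits = 0
    for i in range(n_seeds):
        seed = base_seed * 1000 + i
        cohort, truth = generate(ScenarioConfig(scenario="label", seed=seed))
        scan = run_label_bias_scan(cohort, audit_config(n_boot=n_boot), seed=seed)
        hits += scan["label_bias"]["selected_outcome"] == truth.clean_outcome
    return hits / n_seeds


def guided_collection_benchmark(
    n_seeds: int = 20, base_seed: int = 0, backend: str = "logistic"
) -> dict[str, float]:
    """Guided vs naive vs balanced-ERM curation on the complexity scenario.

    Returns the fraction of seeds where guided curation yields a smaller
    absolute AUROC gap than naive collection, plus the mean |gap| under
    each policy and the mean bias reduction (%) of guided vs naive.
    """
    cfg = BenchmarkConfig(backend=backend, diag_n_boot=20, eval_n_boot=5)
    wins = 0
    gaps = {"naive": [], "balanced_erm": [], "aequity_guided": []}
    for i in range(n_seeds):
        seed = base_seed * 1000 + i
        for policy in gaps:
            cell = run_cell("complexity", policy, seed, cfg)
            gaps[policy].append(abs(cell["report"].bias["auroc"]))
        wins += gaps["aequity_guided"][-1] < gaps["naive"][-1]
    means = {k: float(np.mean(v)) for k, v in gaps.items()}
    reduction = 100.0 * (means["naive"] - means["aequity_guided"]) / means["naive"]
    return {
        "guided_beats_naive_frac": wins / n_seeds,
        "mean_abs_bias_naive": means["naive"],
        "mean_abs_bias_balanced_erm": means["balanced_erm"],
        "mean_abs_bias_guided": means["aequity_guided"],
        "bias_reduction_pct": float(reduction),
    }
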