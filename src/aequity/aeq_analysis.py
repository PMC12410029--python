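"""AEq per (group, outcome) scope, with bootstrap CIs and significance tests.

AEq is the log2 of the sample size at which the reconstruction-loss
learning curve converges for a scope. A scope is either one group's
examples for one outcome, or the group-balanced joint pool ("joint").
Higher AEq means the scope is harder to learn: more samples are needed
before the compressive head generalises.

Statistical protocol: each scope is bootstrapped (default 50 replicates);
the per-replicate learning curves yield a distribution of AEq values whose
mean and standard error give the reported value and its 95% CI
(mean +/- 1.96 SE across bootstraps). Between-scope differences are tested
with two-sample t tests (two scopes) or one-way ANOVA (several scopes),
Bonferroni-adjusted over the family of comparisons. The replicate values
are resamples of one subsample rather than independent draws, so these
tests are anticonservative; every report carries that caveat flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .autoencoder import AutoencoderConfig
from .cohort import Cohort, CohortError
from .encoders import Encoder, identity_encoder
from .learning_curve import (
    DEFAULT_GRID,
    LearningCurve,
    ScopeSizeError,
    convergence_size,
    fit_decay_curve,
    fit_power_law,
    loss_at_sizes,
    marginal_floor,
)

__all__ = [
    "AEqConfig",
    "AEqResult",
    "AEqComparison",
    "compute_aeq",
    "compare_aeq",
    "compare_aeq_family",
]

JOINT = "joint"

BOOTSTRAP_CAVEAT = "t-test-on-bootstrap-replicates-anticonservative"


@dataclass(frozen=True)
class AEqConfig:
    """Configuration shared by every scope in one analysis.

    Scopes compared against each other must be computed under the same
    config; the diagnosis layer enforces this via :meth:`fingerprint`.
    """

    grid: tuple[int, ...] = DEFAULT_GRID
    n_boot: int = 50
    epsilon: float | None = None  # None -> relative default 0.01 * fitted b
    stratum: int | None = None  # restrict scope to outcome == stratum
    scope_size: int | None = None  # equalised audit-subset size per scope
    ae: AutoencoderConfig = field(default_factory=AutoencoderConfig)

    def fingerprint(self) -> tuple:
        return (
            tuple(self.grid), self.n_boot, self.epsilon,
            self.stratum, self.scope_size, self.ae,
        )


@dataclass
class AEqResult:
    """AEq for one (outcome, group-or-joint) scope."""

    outcome: str
    group: str  # group name or "joint"
    aeq: float
    boot_values: np.ndarray
    ci95: tuple[float, float]
    n_boot: int
    n_scope: int
    flags: list[str]
    config_fingerprint: tuple
    curve: LearningCurve | None = None
    seed: int | None = None

    @property
    def scope(self) -> tuple[str, str]:
        return (self.outcome, self.group)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "group": self.group,
            "aeq": float(self.aeq),
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            "boot_values": [float(v) for v in self.boot_values],
            "n_boot": int(self.n_boot),
            "n_scope": int(self.n_scope),
            "flags": list(self.flags),
            "seed": self.seed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass
class AEqComparison:
    """Difference in AEq between two scopes."""

    scope_a: tuple[str, str]
    scope_b: tuple[str, str]
    delta: float
    ci95: tuple[float, float]
    p_raw: float
    p_adjusted: float
    test: str
    flags: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> bool:
        """Adjusted p below alpha *and* the delta CI excludes zero."""
        lo, hi = self.ci95
        return self.p_adjusted < alpha and (lo > 0 or hi < 0)

    def to_dict(self) -> dict:
        return {
            "scope_a": list(self.scope_a),
            "scope_b": list(self.scope_b),
            "delta": float(self.delta),
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            "p_raw": float(self.p_raw),
            "p_adjusted": float(self.p_adjusted),
            "test": self.test,
            "flags": list(self.flags),
        }


def _scope_features(
    cohort: Cohort, outcome: str, group: str, config: AEqConfig
) -> tuple[np.ndarray, list[tuple[int, int]] | None]:
    """Materialise the example matrix for a scope.

    Returns the scope's full feature matrix plus, for the joint scope,
    per-group row blocks so the bootstrap can draw group-balanced
    resamples (joint-vs-group comparisons then reflect structure rather
    than prevalence). ``config.scope_size`` is enforced downstream as a
    per-replicate resample cap, which equalises the effective audit size
    across scopes without conditioning on one fixed subsample.
    """
    sub = cohort
    if config.stratum is not None:
        sub = sub.restrict_stratum(outcome, config.stratum)
    else:
        sub.outcome(outcome)  # validates the outcome exists
    if group == JOINT:
        blocks: list[tuple[int, int]] = []
        parts = []
        start = 0
        for g in sub.groups:
            feats = sub.restrict_group(g).features()
            if feats.shape[0] == 0:
                raise ScopeSizeError(f"joint scope for '{outcome}': group {g} is empty")
            parts.append(feats)
            blocks.append((start, start + feats.shape[0]))
            start += feats.shape[0]
        return np.concatenate(parts, axis=0), blocks
    if group not in sub.groups:
        raise CohortError(f"group '{group}' not present in scope for outcome '{outcome}'")
    feats = sub.restrict_group(group).features()
    if config.scope_size is not None and feats.shape[0] < config.scope_size:
        raise ScopeSizeError(
            f"scope ({outcome}, {group}): {feats.shape[0]} examples, "
            f"audit subset needs {config.scope_size}"
        )
    return feats, None


def compute_aeq(
    cohort: Cohort,
    outcome: str,
    group: str = JOINT,
    encoder: Encoder | None = None,
    config: AEqConfig | None = None,
    seed: int = 0,
) -> AEqResult:
    """Compute AEq for one scope with a bootstrap distribution.

    The loss matrix is populated once (``n_boot`` bootstrap replicates per
    grid size); each replicate's loss row is then fitted and converged
    independently to give a per-replicate AEq value. The reported AEq is
    the mean of replicate values; the 95% CI is mean +/- 1.96 standard
    errors of that mean. The mean-loss curve is also fitted and kept for
    inspection.
    """
    config = config or AEqConfig()
    feats, blocks = _scope_features(cohort, outcome, group, config)
    if encoder is None:
        encoder = identity_encoder(feats.shape[1])

    need = int(np.ceil(max(config.grid) / 0.6))
    n_eff = min(feats.shape[0], config.scope_size or feats.shape[0])
    if n_eff < need:
        raise ScopeSizeError(
            f"scope ({outcome}, {group}): {n_eff} examples available, "
            f"but grid size {max(config.grid)} needs >= {need} "
            f"(deficit {need - n_eff})"
        )

    scope_name = f"{outcome}/{group}"
    curve = loss_at_sizes(
        feats,
        encoder,
        grid=config.grid,
        n_boot=config.n_boot,
        seed=seed,
        ae_config=config.ae,
        scope=scope_name,
        sample_cap=config.scope_size,
        balance_blocks=blocks,
    )

    fit_decay_curve(curve)
    convergence_size(curve, config.epsilon)

    # Per-replicate AEq: refit each bootstrap loss row with the floor `a`
    # anchored, leaving amplitude and decay rate free. A free floor lets 3
    # parameters chase a handful of noisy points and swamps the
    # decay-rate signal; but each replicate carries its own bootstrapped
    # validation set, so its asymptote sits at an offset from the pooled
    # one. The anchor is therefore the pooled floor shifted by the
    # replicate's tail offset — a low-noise estimate of the replicate's
    # own asymptote that stays out of the least-squares problem.
    grid_arr = np.asarray(curve.grid, dtype=np.float64)
    pooled_a = marginal_floor(grid_arr, curve.mean_losses, curve.size_weights())
    pooled_tail = float(np.nanmean(curve.mean_losses[-3:]))
    size_w = curve.size_weights()
    boot_vals: list[float] = []
    flags: set[str] = set(curve.flags)
    for row in curve.losses:
        if np.isfinite(row).sum() < 4:
            continue
        rep_a = max(0.0, pooled_a + float(np.nanmean(row[-3:])) - pooled_tail)
        rep = LearningCurve(grid=curve.grid, losses=row[None, :], scope=scope_name)
        try:
            rep.fit_params, rep.curve_rmse = fit_power_law(
                grid_arr, row, fixed_a=rep_a, weights=size_w
            )
        except Exception:
            continue
        convergence_size(rep, config.epsilon)
        boot_vals.append(float(rep.aeq))
        flags.update(f for f in rep.flags if f in ("extrapolated", "degenerate-flat"))
    if not boot_vals:
        raise ScopeSizeError(f"scope ({outcome}, {group}): every bootstrap replicate failed")

    # mean and standard error across bootstraps; CI = mean +/- 1.96 SE
    boot = np.asarray(boot_vals)
    se = float(boot.std(ddof=1) / np.sqrt(boot.size)) if boot.size > 1 else 0.0
    ci = (float(boot.mean() - 1.96 * se), float(boot.mean() + 1.96 * se))
    return AEqResult(
        outcome=outcome,
        group=group,
        aeq=float(boot.mean()),
        boot_values=boot,
        ci95=ci,
        n_boot=len(boot),
        n_scope=feats.shape[0],
        flags=sorted(flags | {BOOTSTRAP_CAVEAT}),
        config_fingerprint=config.fingerprint(),
        curve=curve,
        seed=seed,
    )


def compare_aeq(a: AEqResult, b: AEqResult, family_size: int = 1) -> AEqComparison:
    """Two-sample t test on bootstrap AEq values, plus a delta CI.

    When both scopes carry the same number of replicates (the standard
    protocol pairs them by index), the CI comes from paired per-replicate
    differences; otherwise from unpaired resampling of the two lists.
    """
    va, vb = np.asarray(a.boot_values), np.asarray(b.boot_values)
    if va.size < 2 or vb.size < 2:
        raise ValueError("compare_aeq needs >= 2 bootstrap values per scope")
    delta = float(a.aeq - b.aeq)
    if va.shape == vb.shape and np.allclose(va, vb) and a.scope == b.scope:
        p_raw = 1.0
    else:
        t_res = stats.ttest_ind(va, vb, equal_var=False)
        p_raw = float(t_res.pvalue)
        if np.isnan(p_raw):  # zero variance in both samples
            p_raw = 1.0 if np.isclose(va.mean(), vb.mean()) else 0.0
    if va.size == vb.size:
        diffs = va - vb
        se = float(diffs.std(ddof=1) / np.sqrt(diffs.size))
        ci = (float(diffs.mean() - 1.96 * se), float(diffs.mean() + 1.96 * se))
        test = "welch-t/paired-se-ci"
    else:
        se = float(np.sqrt(va.var(ddof=1) / va.size + vb.var(ddof=1) / vb.size))
        ci = (delta - 1.96 * se, delta + 1.96 * se)
        test = "welch-t/unpaired-se-ci"
    return AEqComparison(
        scope_a=a.scope,
        scope_b=b.scope,
        delta=delta,
        ci95=ci,
        p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * max(1, family_size)),
        test=test,
        flags=[BOOTSTRAP_CAVEAT],
    )


def compare_aeq_family(
    results: Sequence[AEqResult], family_size: int | None = None
) -> tuple[list[AEqComparison], dict]:
    """All pairwise comparisons plus a one-way ANOVA across scopes.

    ``family_size`` defaults to the number of pairwise tests; every
    pairwise p value is Bonferroni-adjusted by it.
    """
    results = list(results)
    if not results:
        raise ValueError("compare_aeq_family needs at least one result")
    n_pairs = len(results) * (len(results) - 1) // 2
    fam = family_size if family_size is not None else max(1, n_pairs)
    if family_size is not None and family_size < n_pairs:
        raise ValueError(f"family_size {family_size} < {n_pairs} pairwise tests")
    comparisons = [
        compare_aeq(results[i], results[j], family_size=fam)
        for i in range(len(results))
        for j in range(i + 1, len(results))
    ]
    anova: dict = {"test": "one-way-anova", "flags": [BOOTSTRAP_CAVEAT]}
    if len(results) >= 3:
        f_stat, p = stats.f_oneway(*[np.asarray(r.boot_values) for r in results])
        anova.update(F=float(f_stat), p_raw=float(p), p_adjusted=min(1.0, float(p)))
    else:
        anova.update(F=None, p_raw=None, p_adjusted=None, note="ANOVA needs >= 3 scopes")
    return comparisons, anova
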