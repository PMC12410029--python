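"""Seeded synthetic cohorts with known, injected bias mechanisms.

Each scenario plants exactly one (or one pair of) bias mechanism(s) so the
diagnosis and curation claims can be tested against ground truth:

- ``none``       — two groups drawn i.i.d. from one distribution, equal n.
- ``sampling``   — one shared distribution, groups drawn at an unequal
                   rate (default 4:1): pure under-representation.
- ``complexity`` — the disadvantaged group carries more latent subclusters
                   (default 4 vs 1) and a weaker outcome signal in a
                   rotated direction, so it is intrinsically harder to
                   learn and under-served by a pooled model.
- ``label``      — a proxy outcome whose relation to the true-need outcome
                   differs by group: the proxy threshold for the target
                   group sits several severity bands higher, emulating
                   cost-style proxies that understate need for one group.
- ``mixed``      — complexity structure plus the label distortion.

Features are Gaussian mixtures; outcomes come from a logistic link.
Scenario geometry (cluster directions, signal direction) is fixed once,
independent of the cohort seed, so a scenario means the same data-
generating process at every seed; the seed drives sampling only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["ScenarioConfig", "GroundTruth", "generate"]

Scenario = Literal["none", "sampling", "complexity", "label", "mixed"]

# Geometry RNG: fixed so the scenario is the same generative process at
# every cohort seed.
_GEOMETRY_SEED = 20240917


class ScenarioConfigError(ValueError):
    """Contradictory or invalid scenario knobs."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic cohort generator.

    Only the knobs a scenario activates may be moved away from neutral;
    anything else raises. Defaults are the package's canonical study
    conditions (see docs/methods.md for the rationale).
    """

    scenario: Scenario = "none"
    n_per_group: int = 8000
    feature_dim: int = 10
    n_clusters_a: int | None = None  # advantaged group "A"
    n_clusters_b: int | None = None  # disadvantaged group "B"
    cluster_sep: float = 3.0
    class_signal: float = 2.0
    cluster_label_offset: float = 0.0
    minority_signal: float = 0.8  # class-signal strength for group B (complexity/mixed)
    signal_rotation_deg: float = 60.0  # angle between the groups' outcome directions
    group_ratio: float = 4.0  # sampling scenario, majority:minority
    label_deficit: float = 3.0  # proxy-threshold shift for group B, in severity bands
    label_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("none", "sampling", "complexity", "label", "mixed"):
            raise ScenarioConfigError(f"unknown scenario '{self.scenario}'")
        if self.n_per_group < 2:
            raise ScenarioConfigError("n_per_group must be >= 2")
        if self.feature_dim < 2:
            raise ScenarioConfigError("feature_dim must be >= 2")
        if self.group_ratio < 1:
            raise ScenarioConfigError("group_ratio must be >= 1")
        ka, kb = self.clusters()
        if self.scenario in ("none", "sampling", "label") and ka != kb:
            raise ScenarioConfigError(
                f"scenario '{self.scenario}' draws both groups from one distribution; "
                f"cluster counts must match (got {ka} vs {kb})"
            )
        if self.scenario in ("complexity", "mixed") and kb <= ka:
            raise ScenarioConfigError(
                "complexity scenarios require more clusters in group B than A "
                f"(got A={ka}, B={kb})"
            )

    def clusters(self) -> tuple[int, int]:
        if self.scenario in ("complexity", "mixed"):
            ka = 1 if self.n_clusters_a is None else self.n_clusters_a
            kb = 4 if self.n_clusters_b is None else self.n_clusters_b
        elif self.scenario == "label":
            # shared severity bands along one axis
            ka = 6 if self.n_clusters_a is None else self.n_clusters_a
            kb = 6 if self.n_clusters_b is None else self.n_clusters_b
        else:
            ka = 1 if self.n_clusters_a is None else self.n_clusters_a
            kb = ka if self.n_clusters_b is None else self.n_clusters_b
        return ka, kb

    def group_counts(self) -> dict[str, int]:
        if self.scenario == "sampling":
            total = 2 * self.n_per_group
            n_a = int(round(total * self.group_ratio / (self.group_ratio + 1)))
            return {"A": n_a, "B": total - n_a}
        return {"A": self.n_per_group, "B": self.n_per_group}


@dataclass(frozen=True)
class GroundTruth:
    """Sidecar record of the injected mechanism, for test oracles."""

    scenario: str
    target_group: str | None
    clean_outcome: str | None
    distorted_outcome: str | None
    params: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "target_group": self.target_group,
                "clean_outcome": self.clean_outcome,
                "distorted_outcome": self.distorted_outcome,
                "params": self.params,
            },
            **kw,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _geometry(config: ScenarioConfig) -> dict:
    """Fixed scenario geometry: cluster means, signal direction, offsets."""
    rng = np.random.default_rng(_GEOMETRY_SEED)
    d = config.feature_dim
    ka, kb = config.clusters()
    w = _unit(np.ones(d))  # class-signal direction
    if config.scenario == "label":
        # Severity bands along e1, each with its own orthogonal offset so
        # a stratum spanning several bands is genuinely multi-cluster
        # (bands on a single axis would be a trivially compressible 1-D
        # manifold and band count would not affect learnability).
        e1 = np.zeros(d)
        e1[0] = 1.0
        ka, _ = config.clusters()
        means = []
        for i in range(ka):
            off = rng.standard_normal(d)
            off[0] = 0.0
            off = config.cluster_sep * _unit(off) if i > 0 else np.zeros(d)
            means.append(i * config.cluster_sep * e1 + off)
        return {"w": e1, "means_a": means, "means_b": means}
    means_a = [np.zeros(d)]
    if ka > 1:
        dirs = rng.standard_normal((ka - 1, d))
        means_a += [config.cluster_sep * _unit(v) for v in dirs]
    means_b = list(means_a[: min(ka, kb)])
    if kb > len(means_b):
        dirs = rng.standard_normal((kb - len(means_b), d))
        means_b += [config.cluster_sep * _unit(v) for v in dirs]
    if config.scenario in ("none", "sampling"):
        means_b = means_a
    offsets_b = (
        config.cluster_label_offset * rng.choice([-1.0, 1.0], size=kb)
        if config.scenario in ("complexity", "mixed")
        else np.zeros(kb)
    )
    # In complexity scenarios the heterogeneous group's outcome direction
    # is rotated away from the shared signal and attenuated: a pooled
    # model dominated by the majority's stronger gradients then fits the
    # majority's direction, and only re-weighting training data toward
    # the minority moves the fit toward its optimum — under-represented
    # heterogeneity that data collection, not capacity, must fix.
    w_b = w
    if config.scenario in ("complexity", "mixed"):
        theta = np.deg2rad(config.signal_rotation_deg)
        ortho = rng.standard_normal(d)
        ortho -= (ortho @ w) * w
        w_b = np.cos(theta) * w + np.sin(theta) * _unit(ortho)
    return {"w": w, "w_b": w_b, "means_a": means_a, "means_b": means_b, "offsets_b": offsets_b}


def _draw_group(
    rng: np.random.Generator, n: int, means: list[np.ndarray], d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a group's features: exact-proportion cluster assignment.

    Cluster counts are stratified (equal shares up to remainder, then
    shuffled) rather than multinomial: mixture-weight fluctuations between
    groups would otherwise inject genuine between-group learnability
    differences into scenarios that are supposed to be exchangeable.
    """
    k = len(means)
    base = np.repeat(np.arange(k), n // k)
    extra = rng.choice(k, size=n - base.size, replace=False) if n % k else np.empty(0, int)
    assignment = rng.permuted(np.concatenate([base, extra]).astype(int))
    x = rng.standard_normal((n, d)) + np.stack(means)[assignment]
    return x, assignment


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate(config: ScenarioConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a seeded cohort plus its ground-truth mechanism record."""
    rng = np.random.default_rng(config.seed)
    geo = _geometry(config)
    d = config.feature_dim
    counts = config.group_counts()
    w = geo["w"]

    frames = []
    sid = 0
    truth_params: dict = {"counts": counts, "feature_dim": d}

    for g in ("A", "B"):
        n = counts[g]
        means = geo["means_a"] if g == "A" else geo["means_b"]
        x, assign = _draw_group(rng, n, means, d)
        df = pd.DataFrame(x, columns=[f"f{j}" for j in range(d)])
        df.insert(0, "group", g)
        df.insert(0, "subject_id", [f"S{config.seed:04d}{sid + i:06d}" for i in range(n)])
        sid += n

        if config.scenario == "label":
            # Labels key off the latent severity band. True need turns
            # positive from band 2 up, identically for both groups; the
            # target group's proxy only fires `label_deficit` bands
            # higher. At equal proxy label the target group's positive
            # stratum is therefore a structurally different (sicker,
            # narrower) population — the cost-style distortion.
            need_band = 2
            need = (assign >= need_band).astype(int)
            deficit = int(round(config.label_deficit)) if g == "B" else 0
            proxy = (assign >= need_band + deficit).astype(int)
            need = np.where(rng.random(n) < config.label_noise, 1 - need, need)
            df["y_need"] = need
            df["y_proxy"] = proxy
        elif config.scenario == "mixed":
            if g == "B":
                z = config.minority_signal * (x @ geo["w_b"]) + geo["offsets_b"][assign]
            else:
                z = config.class_signal * (x @ w)
            need = (rng.random(n) < _sigmoid(z)).astype(int)
            # proxy: feature-dependent deficit — the target group needs a
            # strictly higher latent score before the proxy turns positive
            shift = config.label_deficit * config.class_signal if g == "B" else 0.0
            proxy = (rng.random(n) < _sigmoid(z - shift)).astype(int)
            df["y_need"] = need
            df["y_proxy"] = np.minimum(proxy, need) if g == "B" else proxy
        else:
            if config.scenario == "complexity" and g == "B":
                z = config.minority_signal * (x @ geo["w_b"]) + geo["offsets_b"][assign]
            else:
                z = config.class_signal * (x @ w)
            df["y_outcome"] = (rng.random(n) < _sigmoid(z)).astype(int)
        frames.append(df)

    data = pd.concat(frames, ignore_index=True)
    data = data.iloc[rng.permutation(len(data))].reset_index(drop=True)
    cohort = Cohort(data, [f"f{j}" for j in range(d)])

    target = {"none": None, "sampling": "B", "complexity": "B", "label": "B", "mixed": "B"}[
        config.scenario
    ]
    clean = "need" if config.scenario in ("label", "mixed") else None
    distorted = "proxy" if config.scenario in ("label", "mixed") else None
    truth = GroundTruth(
        scenario=config.scenario,
        target_group=target,
        clean_outcome=clean,
        distorted_outcome=distorted,
        params=truth_params,
    )
    return cohort, truth
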