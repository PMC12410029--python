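"""Reconstruction-loss learning curves and their convergence point.

The pipeline is: train the compressive head at a geometric grid of sample
sizes, record validation reconstruction loss per (size, bootstrap
replicate), fit the decay curve ``L(n) = a + b * n^(-c)``, and find the
sample size at which the curve's second derivative (taken in ``u =
log2(n)``) falls below a curvature tolerance. The log2 of that size is the
AEq value for the scope the data came from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .autoencoder import AutoencoderConfig, train_replicates
from .encoders import Encoder

__all__ = [
    "DEFAULT_GRID",
    "LearningCurve",
    "CurveFitError",
    "ScopeSizeError",
    "loss_at_sizes",
    "fit_decay_curve",
    "fit_power_law",
    "convergence_size",
]

DEFAULT_GRID: tuple[int, ...] = (16, 32, 64, 128, 256, 512, 1024)
LN2 = float(np.log(2.0))

# validation examples beyond this add cost but no appreciable precision
_VAL_CAP = 256
# fraction of replicates allowed to fail (non-finite loss) before erroring
_MAX_FAIL_FRAC = 0.2


class CurveFitError(RuntimeError):
    """Decay-curve fit failed at every start."""


class ScopeSizeError(ValueError):
    """A scope has too few examples for the requested grid."""


@dataclass
class LearningCurve:
    """Validation loss versus training-set size for one scope."""

    grid: tuple[int, ...]
    losses: np.ndarray  # (n_boot, n_sizes), NaN = failed replicate
    scope: str = ""
    seed: int | None = None
    fit_params: tuple[float, float, float] | None = None  # (a, b, c)
    curve_rmse: float | None = None
    n_star: float | None = None
    aeq: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        grid = tuple(int(g) for g in self.grid)
        if len(grid) < 4:
            raise ValueError("learning-curve grid needs at least 4 sizes")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid sizes must be strictly increasing")
        self.grid = grid
        self.losses = np.asarray(self.losses, dtype=np.float64)
        if self.losses.ndim != 2 or self.losses.shape[1] != len(grid):
            raise ValueError("losses must be (n_boot, len(grid))")
        finite = self.losses[np.isfinite(self.losses)]
        if (finite < 0).any():
            raise ValueError("reconstruction losses must be >= 0")

    @property
    def mean_losses(self) -> np.ndarray:
        return np.nanmean(self.losses, axis=0)

    def size_weights(self) -> np.ndarray | None:
        """Inverse replicate-SD fit weights; None for a single replicate."""
        if self.losses.shape[0] < 3:
            return None
        sd = np.nanstd(self.losses, axis=0, ddof=1)
        floor = max(np.nanmedian(sd) * 0.2, 1e-9)
        return 1.0 / np.maximum(sd, floor)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "grid": list(self.grid),
            "loss_matrix": np.where(np.isfinite(self.losses), self.losses, None).tolist(),
            "fit": None
            if self.fit_params is None
            else dict(zip(("a", "b", "c"), map(float, self.fit_params))),
            "curve_rmse": self.curve_rmse,
            "n_star": self.n_star,
            "aeq": self.aeq,
            "flags": list(self.flags),
            "seed": self.seed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _standardize(train: np.ndarray, *others: np.ndarray) -> tuple[np.ndarray, ...]:
    """Z-score by training-split statistics (constant columns left centred)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train, *others))


def loss_at_sizes(
    data: np.ndarray,
    encoder: Encoder,
    grid: Sequence[int] = DEFAULT_GRID,
    n_boot: int = 50,
    seed: int = 0,
    ae_config: AutoencoderConfig | None = None,
    scope: str = "",
    sample_cap: int | None = None,
    balance_blocks: Sequence[tuple[int, int]] | None = None,
) -> LearningCurve:
    """Populate the loss matrix for one scope.

    Each replicate bootstraps the whole scope: it resamples
    ``min(n, sample_cap)`` examples with replacement, takes the first 60%
    of the resample as its training pool (grid sizes are nested prefixes
    of it) and the next 20% as its validation set, fixed across grid
    sizes so the curve is internally comparable. ``sample_cap`` equalises
    the effective audit-subset size across scopes of unequal pools while
    every replicate still draws from the whole scope, so the subset draw
    averages out of the point estimate and shows up in the replicate
    spread. ``balance_blocks`` (row ranges, e.g. one per group in a
    pooled scope) makes each replicate draw equally from every block.
    Each (size, replicate) cell trains the head from a fresh seeded
    initialisation and records the early-stopped validation loss.
    Deterministic given (seed, grid, n_boot, data order).
    """
    if ae_config is None:
        ae_config = AutoencoderConfig()
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D (n_examples, n_features) array")
    grid = tuple(int(g) for g in grid)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    n = data.shape[0]
    n_eff = min(n, sample_cap) if sample_cap is not None else n
    n_train = int(np.floor(0.6 * n_eff))
    n_val = int(np.floor(0.2 * n_eff))
    if max(grid) > n_train:
        raise ScopeSizeError(
            f"scope {scope or '<unnamed>'}: grid size {max(grid)} exceeds the "
            f"{n_train} examples in the 60% training split of {n_eff} available "
            f"(deficit {max(grid) - n_train})"
        )

    # standardize on the scope, embed once; bootstrap draws reuse rows
    (z,) = _standardize(data)
    h = encoder.embed(z)

    # Each replicate is a full-scope bootstrap: resample n_eff rows with
    # replacement, use the first 60% as the training pool (grid sizes are
    # nested prefixes, so cross-size noise is shared within a replicate)
    # and the following 20% as the replicate's validation set.
    losses = np.empty((n_boot, len(grid)))
    draw_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    if balance_blocks:
        per_block = n_eff // len(balance_blocks)
        parts = [
            draw_rng.integers(lo, hi, size=(n_boot, per_block))
            for lo, hi in balance_blocks
        ]
        boot_idx = np.concatenate(parts, axis=1)
        boot_idx = draw_rng.permuted(boot_idx, axis=1)
    else:
        boot_idx = draw_rng.integers(0, n, size=(n_boot, n_eff))
    train_idx = boot_idx[:, :n_train]
    v_size = min(n_val, _VAL_CAP)
    val_sets = h[boot_idx[:, n_train : n_train + v_size]]  # (R, v, d)
    for j, size in enumerate(grid):
        batches = h[train_idx[:, :size]]  # (R, size, d)
        train_seed = int(draw_rng.integers(0, 2**31 - 1))
        # At small sizes the loss is dominated by initialisation noise;
        # average a few independent inits there (training at tiny n is
        # cheap, so this costs little and stabilises the curve's head).
        k = 4 if size <= 48 else (2 if size <= 96 else 1)
        if k == 1:
            losses[:, j] = train_replicates(batches, val_sets, ae_config, train_seed)
        else:
            rep_batches = np.repeat(batches, k, axis=0)
            rep_vals = np.repeat(val_sets, k, axis=0)
            li = train_replicates(rep_batches, rep_vals, ae_config, train_seed)
            losses[:, j] = np.nanmean(li.reshape(n_boot, k), axis=1)

    n_fail = int(np.isnan(losses).sum())
    if n_fail > _MAX_FAIL_FRAC * losses.size:
        raise CurveFitError(
            f"scope {scope or '<unnamed>'}: {n_fail}/{losses.size} replicate "
            "trainings produced non-finite losses"
        )
    curve = LearningCurve(grid=grid, losses=losses, scope=scope, seed=seed)
    if n_fail:
        curve.flags.append(f"dropped-{n_fail}-failed-replicates")
    return curve


# Fixed multi-start grid for the decay-curve fit: c is the hard parameter,
# so spread its starts log-uniformly over the admissible range.
_C_STARTS = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0)
_C_STARTS_REFIT = (0.25, 1.0, 3.0)


def fit_power_law(
    sizes: np.ndarray,
    losses: np.ndarray,
    fixed_a: float | None = None,
    fixed_b: float | None = None,
    weights: np.ndarray | None = None,
) -> tuple[tuple[float, float, float], float]:
    """Constrained least-squares fit of ``L(n) = a + b * n^(-c)``.

    Bounds: a >= 0, b >= 0, c in [0.05, 5]. Multi-start over a fixed list
    of c values, keeping the best objective. ``fixed_a`` / ``fixed_b`` pin
    the floor and amplitude (used when refitting single bootstrap
    replicates against the scope's pooled estimates, leaving only the
    decay rate free). ``weights`` (per point, typically inverse replicate
    standard deviations) turn the objective into heteroscedastic least
    squares: losses at small n are intrinsically noisier than the tail
    and would otherwise dominate the decay-rate estimate.
    Returns ((a, b, c), rmse) with rmse on the unweighted scale.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    losses = np.asarray(losses, dtype=np.float64)
    w = np.ones_like(sizes) if weights is None else np.asarray(weights, dtype=np.float64)
    ok = np.isfinite(losses) & np.isfinite(w)
    sizes, losses, w = sizes[ok], losses[ok], w[ok]
    if sizes.size < 4:
        raise CurveFitError("need >= 4 finite loss points to fit the decay curve")
    if fixed_b is not None and fixed_a is None:
        raise ValueError("fixed_b requires fixed_a")
    w = w / w.mean()

    lo, hi = float(losses.min()), float(losses.max())
    spread = max(hi - lo, 1e-12)

    def unpack(p: np.ndarray) -> tuple[float, float, float]:
        if fixed_a is None:
            return p[0], p[1], p[2]
        if fixed_b is None:
            return fixed_a, p[0], p[1]
        return fixed_a, fixed_b, p[0]

    def resid(p: np.ndarray) -> np.ndarray:
        a, b, c = unpack(p)
        return w * (a + b * sizes ** (-c) - losses)

    best = None
    starts = _C_STARTS if fixed_a is None else _C_STARTS_REFIT
    for c0 in starts:
        # choose a0/b0 so the start passes near the first and last points
        b0 = max(spread / max(sizes[0] ** (-c0) - sizes[-1] ** (-c0), 1e-12), 1e-9)
        a0 = max(lo - b0 * sizes[-1] ** (-c0), 0.0)
        if fixed_a is None:
            x0, lb, ub = [a0, b0, c0], [0.0, 0.0, 0.05], [np.inf, np.inf, 5.0]
        elif fixed_b is None:
            x0, lb, ub = [b0, c0], [0.0, 0.05], [np.inf, 5.0]
        else:
            x0, lb, ub = [c0], [0.05], [5.0]
        try:
            sol = least_squares(
                resid, x0=x0, bounds=(lb, ub), method="trf",
                xtol=1e-11, ftol=1e-11, gtol=1e-11,
            )
        except Exception:
            continue
        if sol.success or sol.status > 0:
            sse = float(np.sum(sol.fun**2))
            params = unpack(sol.x)
            if best is None or sse < best[1]:
                best = (tuple(float(v) for v in params), sse)
    if best is None:
        raise CurveFitError("decay-curve fit failed at every start")
    params, _ = best
    a, b, c = params
    resid_raw = a + b * sizes ** (-c) - losses
    rmse = float(np.sqrt(np.mean(resid_raw**2)))
    return params, rmse


def marginal_floor(
    sizes: np.ndarray, losses: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Profile-marginalised estimate of the loss floor ``a``.

    For each decay rate c on a dense grid the conditional (a, b) fit is a
    two-variable weighted linear least-squares problem with a closed
    form; the returned floor averages a(c) with likelihood weights
    ``exp(-dSSE / (2 sigma^2))``. Where the full fit is bistable between
    near-tied decay rates — which flips the fitted floor discontinuously —
    this estimator varies smoothly, so it anchors the per-replicate
    refits without injecting winner-take-all noise.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    losses = np.asarray(losses, dtype=np.float64)
    w = np.ones_like(sizes) if weights is None else np.asarray(weights, dtype=np.float64)
    ok = np.isfinite(losses) & np.isfinite(w)
    sizes, losses, w = sizes[ok], losses[ok], w[ok]
    if sizes.size < 4:
        raise CurveFitError("need >= 4 finite loss points to estimate the floor")
    w = w / w.mean()
    cs = np.geomspace(0.05, 5.0, 80)
    a_c = np.empty_like(cs)
    sse_c = np.empty_like(cs)
    for i, c in enumerate(cs):
        x = sizes ** (-c)
        # weighted LSQ of losses ~ a + b x, constrained a, b >= 0
        W = w * w
        sw, swx, swx2 = W.sum(), (W * x).sum(), (W * x * x).sum()
        swy, swxy = (W * losses).sum(), (W * x * losses).sum()
        det = sw * swx2 - swx * swx
        if det <= 1e-12:
            a, b = max(losses.min(), 0.0), 0.0
        else:
            a = (swx2 * swy - swx * swxy) / det
            b = (sw * swxy - swx * swy) / det
            if b < 0:
                b, a = 0.0, swy / sw
            if a < 0:
                a, b = 0.0, swxy / swx2
        a_c[i], sse_c[i] = a, float((W * (a + b * x - losses) ** 2).sum())
    sse_min = sse_c.min()
    dof = max(sizes.size - 3, 1)
    sigma2 = max(sse_min / dof, 1e-18)
    lw = np.exp(-0.5 * (sse_c - sse_min) / sigma2)
    return float((lw * a_c).sum() / lw.sum())


def fit_decay_curve(curve: LearningCurve) -> LearningCurve:
    """Fit the decay curve to the mean loss per grid size (in place).

    When several replicates are present the fit is weighted by the
    inverse of each size's replicate standard deviation (small-n losses
    are noisier and would otherwise dominate).
    """
    params, rmse = fit_power_law(
        np.array(curve.grid, dtype=float), curve.mean_losses, weights=curve.size_weights()
    )
    curve.fit_params = params
    curve.curve_rmse = rmse
    return curve


def _flat_threshold(a: float, loss_scale: float) -> float:
    return max(1e-12, 1e-4 * max(a, loss_scale, 1e-6))


def convergence_size(
    curve: LearningCurve,
    epsilon: float | None = None,
    *,
    scan_step: float = 0.01,
    refine_tol: float = 1e-6,
) -> LearningCurve:
    """Locate the convergence sample size n* and set ``aeq = log2(n*)``.

    With ``u = log2 n`` the fitted loss is ``l(u) = a + b * 2^(-c u)`` and
    its second derivative is ``l''(u) = b (c ln 2)^2 2^(-c u)``. n* is the
    smallest u >= log2(min grid) with ``|l''(u)| <= epsilon``, located by a
    dense scan (step 0.01 in u) plus bisection refinement.

    ``epsilon=None`` uses the relative default ``0.01 * b`` so the
    tolerance tracks the magnitude of the decaying component.
    """
    if curve.fit_params is None:
        raise ValueError("fit_decay_curve must run before convergence_size")
    a, b, c = curve.fit_params
    if epsilon is not None and epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")

    u_min = float(np.log2(curve.grid[0]))
    u_max = float(np.log2(curve.grid[-1]))
    loss_scale = float(np.nanmean(curve.mean_losses))

    def set_result(u_star: float, flags: list[str]) -> LearningCurve:
        curve.n_star = float(2.0**u_star)
        curve.aeq = float(u_star)
        for f in flags:
            if f not in curve.flags:
                curve.flags.append(f)
        if u_star > u_max and "extrapolated" not in curve.flags:
            curve.flags.append("extrapolated")
        return curve

    if b <= _flat_threshold(a, loss_scale):
        return set_result(u_min, ["degenerate-flat"])
    eps = 0.01 * b if epsilon is None else float(epsilon)

    def curvature(u: float | np.ndarray):
        return b * (c * LN2) ** 2 * np.exp2(-c * u)

    if curvature(u_min) <= eps:
        return set_result(u_min, [])

    # dense scan for the first bracketing step, then bisection
    u_cap = u_max + 20.0
    us = np.arange(u_min, u_cap + scan_step, scan_step)
    below = curvature(us) <= eps
    if not below.any():
        return set_result(u_cap, ["not-converged-on-scan"])
    j = int(np.argmax(below))
    lo_u, hi_u = us[j - 1], us[j]
    while hi_u - lo_u > refine_tol:
        mid = 0.5 * (lo_u + hi_u)
        if curvature(mid) <= eps:
            hi_u = mid
        else:
            lo_u = mid
    return set_result(hi_u, [])
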