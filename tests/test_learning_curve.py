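import numpy as np
import pytest
from scipy.stats import spearmanr

from aequity.autoencoder import AutoencoderConfig
from aequity.encoders import identity_encoder
from aequity.learning_curve import (
    LearningCurve,
    ScopeSizeError,
    convergence_size,
    fit_decay_curve,
    fit_power_law,
    loss_at_sizes,
)

LN2 = np.log(2.0)
GRID6 = (16, 32, 64, 128, 256, 512)


def closed_form_ustar(a: float, b: float, c: float, eps: float, u_min: float) -> float:
    """Analytic convergence point: solve b (c ln2)^2 2^(-c u) = eps."""
    u = np.log2(b * (c * LN2) ** 2 / eps) / c
    return max(u, u_min)


def synth_curve(a, b, c, grid=GRID6, n_boot=1):
    losses = np.tile(a + b * np.asarray(grid, float) ** (-c), (n_boot, 1))
    return LearningCurve(grid=grid, losses=losses)


class TestFitDecayCurve:
    @pytest.mark.parametrize("a,b,c", [(0.1, 2.0, 0.5), (0.0, 1.0, 1.0), (0.3, 5.0, 1.5)])
    def test_noiseless_recovery(self, a, b, c):
        """Exact generating parameters are recovered from noiseless tables."""
        curve = fit_decay_curve(synth_curve(a, b, c))
        fa, fb, fc = curve.fit_params
        assert abs(fa - a) <= 1e-3 * max(a, 1e-3)
        assert abs(fb - b) <= 1e-3 * b
        assert abs(fc - c) <= 1e-3 * c

    def test_constant_losses_give_flat_fit(self):
        curve = fit_decay_curve(synth_curve(0.3, 0.0, 1.0))
        fa, fb, _ = curve.fit_params
        assert abs(fa - 0.3) < 1e-6
        assert fb < 1e-6

    def test_noisy_c_recovery_median_within_10pct(self):
        """With sigma=0.01 additive noise, the decay rate is recovered
        within 10% in the median over 20 seeds (on the half-octave grid
        density the audit actually uses)."""
        a, b, c = 0.1, 2.0, 0.5
        grid = np.asarray((16, 23, 32, 45, 64, 91, 128, 181, 256, 362, 512), float)
        rels = []
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0, 0.01, len(grid))
            losses = a + b * grid ** (-c) + noise
            (fa, fb, fc), _ = fit_power_law(grid, np.abs(losses))
            rels.append(abs(fc - c) / c)
        assert np.median(rels) <= 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(Exception):
            fit_power_law(np.array([16.0, 32.0, 64.0]), np.array([1.0, 0.8, 0.7]))


class TestConvergenceSize:
    def test_flat_curve_converges_at_grid_floor(self):
        curve = fit_decay_curve(synth_curve(0.3, 0.0, 1.0))
        convergence_size(curve)
        assert curve.aeq == pytest.approx(np.log2(GRID6[0]))
        assert "degenerate-flat" in curve.flags

    def test_closed_form_c1(self):
        """For a=0, b=1, c=1: curvature (ln2)^2 2^(-u) crosses eps at
        u* = log2((ln2)^2 / eps)."""
        curve = fit_decay_curve(synth_curve(0.0, 1.0, 1.0))
        eps = (LN2**2) * 2.0 ** (-8.0)  # places u* at exactly 8
        convergence_size(curve, epsilon=eps)
        assert curve.aeq == pytest.approx(8.0, abs=0.01)

    @pytest.mark.parametrize("a,b,c,eps", [(0.0, 1.0, 1.0, 1e-3), (0.05, 3.0, 0.7, 1e-2),
                                           (0.0, 0.5, 1.8, 1e-4)])
    def test_closed_form_general(self, a, b, c, eps):
        curve = fit_decay_curve(synth_curve(a, b, c))
        convergence_size(curve, epsilon=eps)
        expected = closed_form_ustar(a, b, c, eps, np.log2(GRID6[0]))
        assert curve.aeq == pytest.approx(expected, abs=0.01)

    def test_grid_doubling_shifts_aeq_by_one(self):
        """Relabeling n -> 2n shifts the convergence point by exactly +1
        for a pure power law with a fixed absolute tolerance."""
        b, c, eps = 2.0, 0.8, 1e-3
        base = fit_decay_curve(synth_curve(0.0, b, c))
        convergence_size(base, epsilon=eps)
        doubled_grid = tuple(2 * g for g in GRID6)
        losses = base.losses.copy()  # same loss table, relabeled sizes
        shifted = LearningCurve(grid=doubled_grid, losses=losses)
        fit_decay_curve(shifted)
        convergence_size(shifted, epsilon=eps)
        assert shifted.aeq - base.aeq == pytest.approx(1.0, abs=0.02)

    def test_aeq_nonincreasing_in_epsilon(self):
        curve = fit_decay_curve(synth_curve(0.1, 2.0, 0.5))
        aeqs = []
        for eps in (1e-4, 1e-3, 1e-2, 1e-1):
            convergence_size(curve, epsilon=eps)
            aeqs.append(curve.aeq)
        assert all(x >= y - 1e-9 for x, y in zip(aeqs, aeqs[1:]))

    def test_power_law_recovery_within_002_over_seeds(self):
        """Noiseless synthetic curves: recovered u* within 0.02 of the
        analytic value across 20 random parameter draws."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            b = float(rng.uniform(0.5, 5.0))
            c = float(rng.uniform(0.3, 2.0))
            eps = float(rng.uniform(1e-4, 1e-2))
            curve = fit_decay_curve(synth_curve(0.0, b, c))
            convergence_size(curve, epsilon=eps)
            expected = closed_form_ustar(0.0, b, c, eps, np.log2(GRID6[0]))
            assert abs(curve.aeq - expected) <= 0.02

    def test_invalid_epsilon_rejected(self):
        curve = fit_decay_curve(synth_curve(0.1, 2.0, 0.5))
        with pytest.raises(ValueError):
            convergence_size(curve, epsilon=-1.0)


class TestLossAtSizes:
    GRID = (16, 32, 64, 128)

    def test_degenerate_constant_data_near_zero_loss(self):
        data = np.ones((400, 5))
        curve = loss_at_sizes(data, identity_encoder(5), grid=self.GRID, n_boot=4, seed=0)
        assert np.nanmax(curve.losses) < 1e-3

    def test_same_seed_identical_losses(self, rng):
        data = rng.standard_normal((400, 5))
        c1 = loss_at_sizes(data, identity_encoder(5), grid=self.GRID, n_boot=4, seed=9)
        c2 = loss_at_sizes(data, identity_encoder(5), grid=self.GRID, n_boot=4, seed=9)
        np.testing.assert_array_equal(c1.losses, c2.losses)

    def test_loss_decreases_with_n_vs_converged_oracle(self, rng):
        """Isotropic Gaussian data: validation loss trends down with n,
        in agreement with a long-trained (oracle) rerun."""
        data = rng.standard_normal((700, 6))
        ae = AutoencoderConfig(bottleneck_dim=5)
        fast = loss_at_sizes(data, identity_encoder(6), grid=(16, 32, 64, 128, 256),
                             n_boot=6, seed=2, ae_config=ae)
        long = AutoencoderConfig(bottleneck_dim=5, max_epochs=1000, patience=50)
        slow = loss_at_sizes(data, identity_encoder(6), grid=(16, 32, 64, 128, 256),
                             n_boot=6, seed=2, ae_config=long)
        for curve in (fast, slow):
            rho = spearmanr(np.arange(5), curve.mean_losses).statistic
            assert rho < 0  # weakly decreasing trend
        # the two protocols agree on the ordering of sizes
        assert spearmanr(fast.mean_losses, slow.mean_losses).statistic > 0.7

    def test_grid_exceeding_data_rejected(self, rng):
        data = rng.standard_normal((100, 5))
        with pytest.raises(ScopeSizeError):
            loss_at_sizes(data, identity_encoder(5), grid=(16, 32, 64, 128), n_boot=2, seed=0)

    def test_grid_shorter_than_four_rejected(self, rng):
        data = rng.standard_normal((200, 5))
        with pytest.raises(ValueError):
            loss_at_sizes(data, identity_encoder(5), grid=(16, 32, 64), n_boot=2, seed=0)
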