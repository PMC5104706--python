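import numpy as np
import pytest

from sedlm import (
    Envelope,
    mahalanobis_sq,
    normalize_and_summarize,
    posterior_from_surfaces,
)
from sedlm.posterior import PosteriorError, batch_posterior_means, likelihood_grid
from sedlm.surface import SurfacePoint, SurfaceSet


def _sp(f, sigma, loc=(0.0, 0.0)):
    return SurfacePoint(loc, np.asarray(f, float), np.asarray(sigma, float), 1.0)


def _lattice(env, n):
    pts = Envelope(env.entry_min, env.entry_max, env.exit_min, env.exit_max,
                   n_cells_x=n, n_cells_y=n).cell_centers(0)
    return pts


def _surfaces(env, points, f_hat, sigma):
    n = len(points)
    return SurfaceSet(
        points=np.asarray(points, float),
        f_hat=np.asarray(f_hat, float),
        sigma_hat=np.broadcast_to(np.asarray(sigma, float),
                                  (n, *np.shape(sigma))).copy()
        if np.ndim(sigma) == 2 else np.asarray(sigma, float),
        effective_weight=np.ones(n),
        envelope=env,
    )


class TestMahalanobis:
    def test_identity_metric(self):
        sp = _sp([0.0, 0.0], np.eye(2))
        assert mahalanobis_sq([3.0, 4.0], sp) == pytest.approx(25.0)

    def test_zero_residual(self):
        sp = _sp([1.0, 2.0], np.eye(2))
        assert mahalanobis_sq([1.0, 2.0], sp) == 0.0

    def test_diagonal_metric(self):
        sp = _sp([0.0, 0.0], np.diag([4.0, 1.0]))
        assert mahalanobis_sq([2.0, 1.0], sp) == pytest.approx(2.0)

    def test_singular_covariance_names_point(self):
        sp = _sp([0.0, 0.0], np.zeros((2, 2)), loc=(0.003, -0.001))
        with pytest.raises(PosteriorError, match="0.003"):
            mahalanobis_sq([1.0, 0.0], sp)


class TestLikelihoodGrid:
    def test_likelihood_ratio_for_known_distances(self):
        """Equal |Sigma|: two points with d2 = 0 and 2 have ratio e."""
        env = Envelope(n_cells_x=2, n_cells_y=1)
        pts = np.array([[-0.01, 0.0], [0.01, 0.0]])
        beta = np.array([0.0, 0.0])
        f_hat = np.array([[0.0, 0.0], [1.0, 1.0]])  # d2: 0 and 2
        surf = _surfaces(env, pts, f_hat, np.eye(2))
        vals = likelihood_grid(beta, surf)
        assert vals[0] / vals[1] == pytest.approx(np.e)

    def test_point_outside_envelope_is_zero(self):
        env = Envelope(n_cells_x=2, n_cells_y=2)
        pts = np.array([[0.0, 0.0], [0.05, 0.0]])  # second outside S
        surf = _surfaces(env, pts, np.zeros((2, 2)), np.eye(2))
        vals = likelihood_grid(np.zeros(2), surf)
        assert vals[1] == 0.0 and vals[0] > 0.0

    def test_argmax_where_beta_lies_on_surface(self):
        env = Envelope(n_cells_x=4, n_cells_y=4)
        pts = env.cell_centers(0)
        f_hat = np.column_stack([pts[:, 0] * 100, pts[:, 1] * 100])
        surf = _surfaces(env, pts, f_hat, np.eye(2))
        target = 5
        vals = likelihood_grid(f_hat[target], surf)
        assert int(np.argmax(vals)) == target

    def test_determinant_weighting(self):
        """Equal d2=0 but larger |Sigma| gives smaller likelihood."""
        env = Envelope(n_cells_x=2, n_cells_y=1)
        pts = np.array([[-0.01, 0.0], [0.01, 0.0]])
        surf = _surfaces(env, pts, np.zeros((2, 2)),
                         np.stack([np.eye(2), 4.0 * np.eye(2)]))
        vals = likelihood_grid(np.zeros(2), surf)
        assert vals[0] / vals[1] == pytest.approx(4.0)  # sqrt(det) ratio


class TestNormalizeAndSummarize:
    def test_uniform_values_give_uniform_posterior(self):
        env = Envelope(n_cells_x=8, n_cells_y=8)
        pts = env.cell_centers(0)
        area = env.h * env.h_y
        grid = normalize_and_summarize(np.ones(len(pts)), pts, area)
        assert grid.density.sum() * area == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(grid.density, grid.density[0])
        assert grid.point_estimate[0] == pytest.approx(0.0, abs=1e-12)
        assert grid.point_estimate[1] == pytest.approx(0.0, abs=1e-12)

    def test_marginals_integrate_to_one(self):
        env = Envelope(n_cells_x=6, n_cells_y=6)
        pts = env.cell_centers(0)
        vals = np.exp(-((pts[:, 0] * 200) ** 2))
        grid = normalize_and_summarize(vals, pts, env.h * env.h_y)
        de = grid.entry_grid[1] - grid.entry_grid[0]
        dx = grid.exit_grid[1] - grid.exit_grid[0]
        assert grid.marginal_entry.sum() * de == pytest.approx(1.0)
        assert grid.marginal_exit.sum() * dx == pytest.approx(1.0)

    def test_gaussian_bump_mean_and_hpd(self):
        """Brute-force oracle: a narrow Gaussian bump at (0.004, -0.002);
        the discrete posterior mean matches the direct weighted sum and
        the HPD intervals bracket the bump."""
        env = Envelope(n_cells_x=32, n_cells_y=32)
        pts = env.cell_centers(0)
        mu = np.array([0.004, -0.002])
        sd = 0.002
        vals = np.exp(-np.sum((pts - mu) ** 2, axis=1) / (2 * sd**2))
        area = env.h * env.h_y
        grid = normalize_and_summarize(vals, pts, area)
        # independent oracle: direct discrete summation
        w = vals / vals.sum()
        oracle = w @ pts
        assert grid.point_estimate[0] == pytest.approx(oracle[0], abs=1e-12)
        assert grid.point_estimate[1] == pytest.approx(oracle[1], abs=1e-12)
        assert grid.point_estimate[0] == pytest.approx(0.004, abs=env.h)
        assert grid.point_estimate[1] == pytest.approx(-0.002, abs=env.h)
        (lo, hi), = grid.hpd_entry
        assert lo < 0.004 < hi
        (lo, hi), = grid.hpd_exit
        assert lo < -0.002 < hi
        # ~95% of a Gaussian within +-1.96 sd
        assert grid.hpd_entry[0][1] - grid.hpd_entry[0][0] == pytest.approx(
            2 * 1.96 * sd, rel=0.2)

    def test_bimodal_hpd_warns_and_splits(self):
        env = Envelope(n_cells_x=16, n_cells_y=2)
        pts = env.cell_centers(0)
        vals = (np.exp(-((pts[:, 0] + 0.012) / 0.002) ** 2)
                + np.exp(-((pts[:, 0] - 0.012) / 0.002) ** 2))
        with pytest.warns(UserWarning, match="non-contiguous"):
            grid = normalize_and_summarize(vals, pts, env.h * env.h_y)
        assert len(grid.hpd_entry) == 2

    def test_all_zero_rejected(self):
        env = Envelope(n_cells_x=2, n_cells_y=2)
        pts = env.cell_centers(0)
        with pytest.raises(PosteriorError):
            normalize_and_summarize(np.zeros(len(pts)), pts, env.h**2)


class TestEndToEndPosterior:
    def test_batch_means_agree_with_per_record_posterior(self, rng):
        env = Envelope(n_cells_x=8, n_cells_y=8)
        pts = env.cell_centers(1)
        f_hat = np.column_stack([pts[:, 0] * 50, pts[:, 1] * 50,
                                 pts[:, 0] * 10 + pts[:, 1] * 20])
        sigma = np.stack([np.eye(3) * (0.5 + 0.1 * k % 3)
                          for k in range(len(pts))])
        surf = SurfaceSet(points=pts, f_hat=f_hat, sigma_hat=sigma,
                          effective_weight=np.ones(len(pts)), envelope=env)
        betas = rng.normal(scale=0.3, size=(5, 3))
        batch = batch_posterior_means(betas, surf)
        for r in range(5):
            grid = posterior_from_surfaces(betas[r], surf)
            np.testing.assert_allclose(batch[r], grid.point_estimate,
                                       atol=1e-10)

    def test_posterior_concentrates_on_truth(self, tiny_campaign):
        """Feed a coefficient vector that sits on the smoothed surface:
        the posterior mean lands near that surface point."""
        from sedlm import smooth_surfaces

        env = tiny_campaign.envelope
        pts = env.cell_centers(1)
        surf = smooth_surfaces(tiny_campaign, pts)
        k = len(pts) // 2
        grid = posterior_from_surfaces(surf.f_hat[k], surf)
        assert abs(grid.point_estimate[0] - pts[k, 0]) < 3 * env.h
        assert abs(grid.point_estimate[1] - pts[k, 1]) < 3 * env.h_y
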