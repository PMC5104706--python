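import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedlm import Envelope, epanechnikov_weight, smooth_surfaces
from sedlm.campaign import CampaignResult
from sedlm.dlm import DLMSpec
from sedlm.surface import SurfaceError


class TestEpanechnikovWeight:
    def test_zero_distance_is_three_quarters(self):
        assert epanechnikov_weight([[0.0, 0.0]], (0.0, 0.0), 1.0)[0] == 0.75

    def test_support_boundary(self):
        assert epanechnikov_weight([[1.0, 0.0]], (0.0, 0.0), 1.0)[0] == 0.0

    def test_half_span(self):
        w = epanechnikov_weight([[0.5, 0.0]], (0.0, 0.0), 1.0)[0]
        assert w == pytest.approx(0.75 * (1 - 0.25))  # 0.5625

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            epanechnikov_weight([[0.0, 0.0]], (0.0, 0.0), 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ax=st.floats(-2, 2), ay=st.floats(-2, 2),
        px=st.floats(-2, 2), py=st.floats(-2, 2),
        h=st.floats(0.01, 3.0),
    )
    def test_bounds_and_support(self, ax, ay, px, py, h):
        w = epanechnikov_weight([[ax, ay]], (px, py), h)[0]
        assert 0.0 <= w <= 0.75
        dist = np.hypot(px - ax, py - ay)
        if dist >= h:
            assert w == 0.0
        elif dist < h * 0.999:
            assert w > 0.0


def _campaign_from(locs, beta, env, spec_df=None):
    """Wrap raw (location, coefficient) arrays as a CampaignResult."""
    locs = np.asarray(locs, float)
    beta = np.atleast_2d(np.asarray(beta, float))
    cells = [env.cell_of(e, x) for e, x in locs]
    recs = pd.DataFrame({
        "true_entry": locs[:, 0], "true_exit": locs[:, 1],
        "mlt": 5.0,
        "cell_i": [c[0] for c in cells], "cell_j": [c[1] for c in cells],
        "fold": 0,
    })
    for j in range(beta.shape[1]):
        recs[f"beta_star_{j}"] = beta[:, j]
    recs["sum_of_lags"] = beta.sum(axis=1)
    recs["fit_ok"] = True
    return CampaignResult(
        envelope=env, dlm_spec=DLMSpec(3, ("none",)), records=recs,
        seed=0, n_folds=1, alpha_entry=np.log(50.0))


def _dense_grid(env, per_axis):
    g = np.linspace(0, 1, per_axis, endpoint=False) + 0.5 / per_axis
    e = env.entry_min + g * (env.entry_max - env.entry_min)
    x = env.exit_min + g * (env.exit_max - env.exit_min)
    ge, gx = np.meshgrid(e, x, indexing="ij")
    return np.column_stack([ge.ravel(), gx.ravel()])


class TestSmoothSurfaces:
    def test_constant_field_reproduced_exactly(self):
        env = Envelope(n_cells_x=4, n_cells_y=4)
        locs = _dense_grid(env, 12)
        v = np.array([1.0, -2.0, 0.5])
        camp = _campaign_from(locs, np.tile(v, (len(locs), 1)), env)
        surf = smooth_surfaces(camp, env.cell_centers(1))
        np.testing.assert_allclose(surf.f_hat, np.tile(v, (len(surf), 1)),
                                   atol=1e-12)
        assert np.abs(surf.sigma_hat).max() < 1e-12

    def test_linear_field_recovered_at_interior_points(self):
        """A coefficient field linear in (entry, exit), densely sampled,
        is reproduced by the kernel mean at interior lattice points to
        O(h^2)."""
        env = Envelope(n_cells_x=6, n_cells_y=6)
        locs = _dense_grid(env, 48)
        A = np.array([[3.0, -1.0], [0.5, 2.0]])
        beta = locs @ A.T + np.array([0.1, -0.2])
        camp = _campaign_from(locs, beta, env)
        pts = env.cell_centers(1)
        surf = smooth_surfaces(camp, pts)
        expected = pts @ A.T + np.array([0.1, -0.2])
        scale = np.abs(A).max() * env.h
        np.testing.assert_allclose(surf.f_hat, expected, atol=0.05 * scale)

    def test_matches_naive_all_records_computation(self, rng):
        """Dual route: for cell-center test points the 3x3-neighbourhood
        shortcut must equal the naive weight-over-everything average
        (every record within span h is inside the neighbourhood)."""
        env = Envelope(n_cells_x=5, n_cells_y=5)
        locs = np.column_stack([
            rng.uniform(env.entry_min, env.entry_max, 400),
            rng.uniform(env.exit_min, env.exit_max, 400)])
        beta = rng.normal(size=(400, 3))
        camp = _campaign_from(locs, beta, env)
        pts = env.cell_centers(1)
        surf = smooth_surfaces(camp, pts, ridge_scale=0.0)
        for k, p in enumerate(pts):
            w = epanechnikov_weight(locs, p, env.h)
            f = (w @ beta) / w.sum()
            np.testing.assert_allclose(surf.f_hat[k], f, atol=1e-12)
            r = beta - f
            sig = (r.T * w) @ r / w.sum()
            np.testing.assert_allclose(surf.sigma_hat[k], sig, atol=1e-12)

    def test_weighted_covariance_recovers_known_sigma(self, rng):
        """iid coefficient noise with known covariance: the average local
        covariance estimate converges to it."""
        env = Envelope(n_cells_x=4, n_cells_y=4)
        locs = _dense_grid(env, 40)
        S0 = np.array([[2.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(S0)
        beta = rng.normal(size=(len(locs), 2)) @ L.T
        camp = _campaign_from(locs, beta, env)
        surf = smooth_surfaces(camp, env.cell_centers(1))
        avg = surf.sigma_hat.mean(axis=0)
        np.testing.assert_allclose(avg, S0, rtol=0.15)

    def test_invariant_to_record_order_and_duplication(self, rng):
        env = Envelope(n_cells_x=3, n_cells_y=3)
        locs = np.column_stack([
            rng.uniform(env.entry_min, env.entry_max, 90),
            rng.uniform(env.exit_min, env.exit_max, 90)])
        beta = rng.normal(size=(90, 2))
        pts = env.cell_centers(1)
        base = smooth_surfaces(_campaign_from(locs, beta, env), pts)
        perm = rng.permutation(90)
        shuffled = smooth_surfaces(_campaign_from(locs[perm], beta[perm], env), pts)
        np.testing.assert_allclose(shuffled.f_hat, base.f_hat, atol=1e-12)
        doubled = smooth_surfaces(
            _campaign_from(np.vstack([locs, locs]), np.vstack([beta, beta]), env),
            pts)
        np.testing.assert_allclose(doubled.f_hat, base.f_hat, atol=1e-12)
        np.testing.assert_allclose(doubled.sigma_hat, base.sigma_hat, atol=1e-12)

    def test_empty_neighbourhood_raises(self):
        env = Envelope(n_cells_x=6, n_cells_y=6)
        # records only in the far corner cell
        locs = np.tile([[env.entry_min + 1e-4, env.exit_min + 1e-4]], (5, 1))
        camp = _campaign_from(locs, np.ones((5, 2)), env)
        with pytest.raises(SurfaceError, match="no records"):
            smooth_surfaces(camp, np.array([[0.015, 0.015]]))

    def test_point_outside_envelope_rejected(self, tiny_campaign):
        with pytest.raises(ValueError, match="inside"):
            smooth_surfaces(tiny_campaign, np.array([[1.0, 0.0]]))

    def test_failed_fits_excluded(self):
        env = Envelope(n_cells_x=3, n_cells_y=3)
        locs = _dense_grid(env, 9)
        beta = np.ones((len(locs), 2))
        camp = _campaign_from(locs, beta, env)
        bad = camp.records.index[:3]
        camp.records.loc[bad, "fit_ok"] = False
        camp.records.loc[bad, "beta_star_0"] = 1e9
        surf = smooth_surfaces(camp, env.cell_centers(1))
        assert np.abs(surf.f_hat - 1.0).max() < 1e-9

    def test_surface_frame_export(self, tiny_campaign):
        env = tiny_campaign.envelope
        surf = smooth_surfaces(tiny_campaign, env.cell_centers(1))
        frame = surf.to_frame()
        assert {"entry", "exit", "f_0", "sigma_0_0", "effective_weight"} <= set(
            frame.columns)
        assert len(frame) == len(surf)
        # covariances are symmetric PSD
        eig = np.linalg.eigvalsh(surf.sigma_hat)
        assert (eig > -1e-12).all()
        assert (surf.effective_weight > 0).all()
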