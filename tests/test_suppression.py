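import numpy as np
import pytest

from cloudband.errors import DegenerateDataError, EmptySurroundError
from cloudband.gabor import ResponseGrid
from cloudband.suppression import (ModelFit, SuppressionBounds, SuppressionParams,
                                   center_response, fit_scaling, fit_suppression,
                                   modulation_from_responses, r2_mean_corrected,
                                   recruitment_fit, suppression_predict,
                                   surround_average, tuning_only_predict)
from conftest import ORI_BINS, make_structured_grids


def uniform_grid(value=0.3, n_sites=9, n_ori=5, n_sf=2, n_frames=2, patch_deg=30.0):
    m = np.full((n_ori, n_sf, n_frames, n_sites, n_sites), value)
    return ResponseGrid(m=m, orientations_deg=ORI_BINS[:n_ori],
                        sfs_cpd=(0.01, 0.02)[:n_sf],
                        spacing_deg=patch_deg / (n_sites - 1))


# ---------------------------------------------------------------------------
# scaling and tuning-only model
# ---------------------------------------------------------------------------

def test_fit_scaling_reproduces_worked_example():
    # grand means 0.01622 dF/F over 0.1627 AU -> 0.0997
    w_t = fit_scaling(np.full(10, 0.01622), np.full(10, 0.1627))
    assert round(w_t, 4) == 0.0997


def test_fit_scaling_identity_and_linearity():
    rng = np.random.default_rng(0)
    c = rng.uniform(0.05, 0.3, (5, 2))
    assert fit_scaling(c, c) == pytest.approx(1.0)
    assert fit_scaling(2 * c, c) == pytest.approx(2 * fit_scaling(c, c))


def test_tuning_only_inverts_the_worked_example():
    assert tuning_only_predict(0.1627, 0.0997) == pytest.approx(0.01622, abs=5e-5)
    assert np.all(tuning_only_predict(np.zeros(5), 0.5) == 0)


def test_center_response_is_sf_and_frame_mean():
    g = uniform_grid()
    vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    m = g.m.copy()
    cy, cx = g.center
    m[0, :, :, cy, cx] = np.array([0.1, 0.5])[:, None]  # two SFs
    g2 = ResponseGrid(m=m, orientations_deg=g.orientations_deg, sfs_cpd=g.sfs_cpd,
                      spacing_deg=g.spacing_deg)
    c = center_response(g2)
    assert c[0] == pytest.approx(0.3)
    assert np.allclose(c[1:], 0.3)
    # hand summation on a tiny grid
    assert c[0] == pytest.approx(m[0, :, :, cy, cx].sum() / m[0, :, :, cy, cx].size)


# ---------------------------------------------------------------------------
# surround averaging
# ---------------------------------------------------------------------------

def test_surround_average_uniform_grid():
    g = uniform_grid(value=0.25, n_sites=11)
    s, n = surround_average(g, 8.0, 14.0)
    assert np.allclose(s, 0.25)
    assert n > 0


def test_surround_count_matches_brute_force():
    g = uniform_grid(n_sites=13, patch_deg=30.0)
    spacing = g.spacing_deg
    for li, lo in ((7.5, 15.0), (8.0, 12.0), (9.7, 10.3)):
        c = (13 - 1) // 2
        count = 0
        for x in range(13):
            for y in range(13):
                d = np.hypot(x - c, y - c)
                if li / spacing < d < lo / spacing:
                    count += 1
        if count == 0:
            with pytest.raises(EmptySurroundError):
                surround_average(g, li, lo)
        else:
            _, n = surround_average(g, li, lo)
            assert n == count


def test_empty_annulus_raises():
    g = uniform_grid(n_sites=5, patch_deg=30.0)  # spacing 7.5 deg
    with pytest.raises(EmptySurroundError):
        surround_average(g, 7.6, 7.4 + 0.3)  # no site strictly inside


# ---------------------------------------------------------------------------
# suppression predictions
# ---------------------------------------------------------------------------

def test_ws_zero_reduces_to_scaled_center():
    g = make_structured_grids()["narrow"]
    params = SuppressionParams(8.0, 14.0, 3.0, 0.0, 0.1)
    pred = suppression_predict(g, params)
    assert np.allclose(pred, 3.0 * center_response(g))


def test_rectified_surround_inactive_below_threshold():
    g = uniform_grid(value=0.2)
    inactive = suppression_predict(g, SuppressionParams(8.0, 14.0, 2.0, 50.0, -0.5))
    ws_zero = suppression_predict(g, SuppressionParams(8.0, 14.0, 2.0, 0.0, -0.5))
    assert np.allclose(inactive, ws_zero)


def test_prediction_monotone_nonincreasing_in_ws():
    g = make_structured_grids()["narrow"]
    preds = [suppression_predict(g, SuppressionParams(8.0, 14.0, 2.0, ws, 0.05)).sum()
             for ws in (0.0, 1.0, 10.0)]
    assert preds[0] > preds[1] > preds[2]


def test_suppression_nests_tuning_only():
    g = make_structured_grids()["broad"]
    w_t = 0.42
    pred = suppression_predict(g, SuppressionParams(8.0, 14.0, w_t, 0.0, 0.0))
    assert np.allclose(pred, tuning_only_predict(center_response(g), w_t))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_generating_parameters(structured_grids):
    true = SuppressionParams(9.0, 13.0, 5.0, 40.0, -0.05)
    targets = np.column_stack([suppression_predict(g, true)
                               for g in structured_grids.values()])
    fit = fit_suppression(structured_grids, targets, n_restarts=30, seed=1)
    assert fit.loss < 1e-8
    assert fit.params.w_c == pytest.approx(true.w_c, rel=0.15)
    assert fit.params.lim_o_deg == pytest.approx(true.lim_o_deg, rel=0.15)
    assert fit.r2 > 0.999


def test_fit_deterministic_and_best_of_restarts(structured_grids):
    true = SuppressionParams(10.0, 14.0, 2.0, 20.0, 0.0)
    targets = np.column_stack([suppression_predict(g, true)
                               for g in structured_grids.values()])
    f1 = fit_suppression(structured_grids, targets, n_restarts=8, seed=3)
    f2 = fit_suppression(structured_grids, targets, n_restarts=8, seed=3)
    assert f1.params == f2.params
    assert f1.loss <= np.nanmin(f1.restart_losses) + 1e-15


# ---------------------------------------------------------------------------
# recruitment regression, R^2, modulation
# ---------------------------------------------------------------------------

def test_recruitment_slope_closed_form():
    assert recruitment_fit([1.0, 2.0], [2.0, 4.0]) == pytest.approx(2.0)
    assert recruitment_fit([1.0, 2.0], [1.0, 1.0]) == pytest.approx(3.0 / 5.0)
    assert recruitment_fit([1.0, 2.0], [3.0, 3.0]) == pytest.approx(3 * 3.0 / 5.0)
    with pytest.raises(DegenerateDataError):
        recruitment_fit([0.0, 0.0], [1.0, 2.0])


def test_r2_mean_corrected_reference_values():
    assert r2_mean_corrected([0, 1, 2], [0, 1, 2]) == pytest.approx(1.0)
    assert r2_mean_corrected([0, 1, 2], [1, 1, 1]) == pytest.approx(0.0)
    assert r2_mean_corrected([0, 1, 2], [2, 1, 0]) == pytest.approx(-3.0)
    with pytest.raises(DegenerateDataError):
        r2_mean_corrected([1, 1, 1], [0, 1, 2])


def test_modulation_from_responses_matches_omi_operator():
    narrow = np.array([1.0, 2.0, 0.0])
    broad = np.array([1.0, 6.0, 1.0])
    out = modulation_from_responses(narrow, broad)
    assert out[0] == pytest.approx(0.0)
    assert out[1] == pytest.approx(0.5)
    assert out[2] == pytest.approx(1.0)  # zero narrow response -> +1
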