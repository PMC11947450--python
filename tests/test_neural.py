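import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cloudband.errors import DegenerateDataError, InsufficientDataError
from cloudband.neural import (bandwidth_selectivity, lme_regression,
                              modulation_index, preferred_orientation,
                              responsive_test, roc_auc,
                              shuffle_null_classification, sparse_noise_rf,
                              summarize_neuron, surround_modulation_index,
                              trial_amplitudes)


# ---------------------------------------------------------------------------
# amplitudes
# ---------------------------------------------------------------------------

def test_constant_trace_gives_zero_amplitudes():
    traces = np.full((2, 300), 0.7)
    events = pd.DataFrame({"time_s": [2.0, 6.0], "condition_id": ["a", "a"]})
    table = trial_amplitudes(traces, fs_hz=30.0, events=events)
    assert np.allclose(table["stim_value"] - table["baseline_value"], 0.0)


def test_injected_step_recovered_exactly():
    fs = 30.0
    traces = np.zeros((1, 600))
    onsets = [3.0, 10.0]
    for t0 in onsets:
        a, b = int(t0 * fs), int((t0 + 2.0) * fs)
        traces[0, a:b] += 0.25
    events = pd.DataFrame({"time_s": onsets, "condition_id": ["a", "a"]})
    table = trial_amplitudes(traces, fs, events, stim_window_s=2.0)
    amp = table["stim_value"] - table["baseline_value"]
    assert np.allclose(amp, 0.25)


def test_median_amplitude_matches_sorting_oracle():
    rng = np.random.default_rng(0)
    vals = rng.normal(0.1, 0.05, 9)
    table = pd.DataFrame({
        "neuron_id": 0, "condition_id": "a", "trial_index": np.arange(9),
        "baseline_value": 0.0, "stim_value": vals,
    })
    summ = summarize_neuron(table, 0)
    assert summ.amplitude["a"] == pytest.approx(sorted(vals)[4])


def test_window_outside_trace_raises():
    events = pd.DataFrame({"time_s": [0.1], "condition_id": ["a"]})
    with pytest.raises(IndexError):
        trial_amplitudes(np.zeros((1, 100)), 30.0, events)


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------

def test_complete_separation_is_highly_significant():
    stim = np.arange(10, 20, dtype=float)
    base = np.arange(0, 10, dtype=float)
    p, flag = responsive_test(stim, base)
    assert p < 0.001 and flag
    # exact enumeration oracle: U = 100 of 100 possible pairs -> p = C(20,10)^-1-scale
    assert p == pytest.approx(1.0 / 184756, rel=1e-6)


def test_identical_arrays_not_responsive():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.warns(UserWarning):
        p, flag = responsive_test(np.ones(4), np.ones(4))
    assert not flag
    p, flag = responsive_test(x, x)
    assert not flag


def test_type_i_error_calibration():
    """Null data: the 5% one-sided test flags ~5% of simulated neurons."""
    rng = np.random.default_rng(42)
    n_sim = 2000
    hits = 0
    for _ in range(n_sim):
        p, flag = responsive_test(rng.normal(size=15), rng.normal(size=15))
        hits += flag
    assert 0.035 < hits / n_sim < 0.065


# ---------------------------------------------------------------------------
# selectivity and modulation indices
# ---------------------------------------------------------------------------

def test_bandwidth_selectivity_arithmetic():
    out = bandwidth_selectivity(2.0, 1.0, 1.0)
    assert out["narrow"] == pytest.approx(1.0 / 3.0)
    assert bandwidth_selectivity(1.0, 1.0, 1.0)["narrow"] == pytest.approx(0.0)
    assert bandwidth_selectivity(1.0, 0.0, 0.0)["narrow"] == pytest.approx(1.0)
    with pytest.raises(DegenerateDataError):
        bandwidth_selectivity(0.0, 0.0, 0.0)


@given(st.tuples(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.01, 10)))
def test_bw_si_bounded(r):
    out = bandwidth_selectivity(*r)
    for v in out.values():
        assert -1.0 <= v <= 1.0


def test_modulation_index_examples():
    assert modulation_index(1.0, 1.0) == 0.0
    assert modulation_index(0.0, 2.0) == 1.0
    assert modulation_index(1.0, 3.0) == pytest.approx(0.5)
    assert modulation_index(3.0, 1.0) == -modulation_index(1.0, 3.0)


def test_surround_modulation_index_examples():
    assert surround_modulation_index(1.0, 1.0) == 0.0
    assert surround_modulation_index(0.0, 2.0) == -1.0
    assert surround_modulation_index(3.0, 4.0) == pytest.approx(-1.0 / 7.0)


def test_shuffle_classification_detects_planted_selectivity():
    rng = np.random.default_rng(7)
    signal = 0.2
    hits = 0
    n_sim = 30
    for k in range(n_sim):
        resp = {
            "narrow": 3 * signal + rng.normal(0, 0.25 * signal, 20),
            "mid": signal + rng.normal(0, 0.25 * signal, 20),
            "broad": signal + rng.normal(0, 0.25 * signal, 20),
        }
        res = shuffle_null_classification(resp, n_shuffles=500, seed=k)
        hits += res.classification == "narrow"
    assert hits / n_sim > 0.9


def test_shuffle_classification_deterministic():
    rng = np.random.default_rng(1)
    resp = {b: rng.normal(0.1, 0.05, 15) for b in ("narrow", "mid", "broad")}
    r1 = shuffle_null_classification(resp, n_shuffles=200, seed=5)
    r2 = shuffle_null_classification(resp, n_shuffles=200, seed=5)
    assert r1.classification == r2.classification
    assert r1.bw_si == r2.bw_si


def test_shuffle_classification_needs_trials():
    with pytest.raises(InsufficientDataError):
        shuffle_null_classification({"narrow": [1.0], "mid": [1.0], "broad": [1.0]})


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_auc_complete_separation_and_identity():
    res = roc_auc([0, 1, 2], [5, 6, 7])
    assert res.auc == 1.0 and res.auc_abs == 1.0
    res = roc_auc([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.auc == pytest.approx(0.5)
    assert res.auc_abs == pytest.approx(0.0)


@settings(max_examples=200, deadline=None)
@given(
    st.lists(st.integers(0, 6), min_size=1, max_size=12),
    st.lists(st.integers(0, 6), min_size=1, max_size=12),
)
def test_auc_equals_pair_counting_oracle(a, b):
    res = roc_auc(a, b)
    pairs = sum(1.0 if y > x else 0.5 if y == x else 0.0 for x in a for y in b)
    assert res.auc == pytest.approx(pairs / (len(a) * len(b)))
    assert res.auc_abs == pytest.approx(abs(res.auc - 0.5) * 2)


# ---------------------------------------------------------------------------
# tuning curves and receptive fields
# ---------------------------------------------------------------------------

def test_preferred_orientation_at_sampled_peak():
    tc = preferred_orientation([0.1, 0.8, 0.4, 0.3, 0.2])
    assert tc.preferred_deg == pytest.approx(-22.5, abs=0.5)


def test_preferred_orientation_tie_breaks_to_zero_then_negative():
    tc = preferred_orientation([0.1, 0.8, 0.2, 0.8, 0.1])
    assert tc.preferred_deg == pytest.approx(-22.5, abs=0.5)
    tc2 = preferred_orientation([0.8, 0.1, 0.2, 0.1, 0.8])
    assert tc2.preferred_deg == pytest.approx(-45.0, abs=0.5)


def test_von_mises_neuron_recovered_within_sampling_resolution():
    # piecewise-linear interpolation localizes the peak to within half the
    # 22.5-degree sample spacing across the sampled range
    oris = np.array([-45.0, -22.5, 0.0, 22.5, 45.0])
    for true_pref in (-30.0, -10.0, 0.0, 10.0, 35.0):
        resp = np.exp(-0.5 * ((oris - true_pref) / 20.0) ** 2)
        tc = preferred_orientation(resp)
        assert abs(tc.preferred_deg - true_pref) <= 11.25


def test_tuned_flag_against_population_median():
    tc = preferred_orientation([0.0, 0.0, 1.0, 0.0, 0.0], population_median_depth=0.5)
    assert tc.tuned
    tc = preferred_orientation([0.2, 0.2, 0.3, 0.2, 0.2], population_median_depth=0.5)
    assert not tc.tuned


def _rf_table(rng, hot=None, n_rep=8, grid=3):
    rows = []
    for r in range(grid):
        for c in range(grid):
            mu = 0.5 if hot == (r, c) else 0.0
            for k in range(n_rep):
                rows.append((r, c, mu + rng.normal(0, 0.05), rng.normal(0, 0.05)))
    return pd.DataFrame(rows, columns=["row", "col", "stim_value", "baseline_value"])


def test_sparse_noise_finds_planted_location():
    rng = np.random.default_rng(3)
    center, pmap, size = sparse_noise_rf(_rf_table(rng, hot=(1, 2)))
    assert center == (1, 2)
    assert size == pytest.approx(2 * np.sqrt(144 / np.pi), rel=0.5)


def test_sparse_noise_uniform_nonresponder():
    rng = np.random.default_rng(4)
    center, pmap, size = sparse_noise_rf(_rf_table(rng, hot=None))
    assert center is None and size is None


# ---------------------------------------------------------------------------
# mixed-effects regression
# ---------------------------------------------------------------------------

def _lme_table(rng, beta=(0.1, 0.5, 0.0, 0.2), animal_sd=0.0, n_per=40, n_animals=5):
    rows = []
    for a in range(n_animals):
        u = rng.normal(0, animal_sd) if animal_sd > 0 else 0.0
        X = rng.normal(size=(n_per, 3))
        eps = rng.normal(0, 0.3, n_per)
        if animal_sd == 0:
            eps -= eps.mean()  # exact zero between-animal variance
        y = beta[0] + X @ np.array(beta[1:]) + u + eps
        for i in range(n_per):
            rows.append((y[i], X[i, 0], X[i, 1], X[i, 2], a))
    return pd.DataFrame(rows, columns=["Rm", "Sm", "Ot", "Cr", "animal_id"])


def test_lme_matches_ols_with_zero_animal_variance():
    import statsmodels.api as sm

    rng = np.random.default_rng(10)
    table = _lme_table(rng, animal_sd=0.0)
    res = lme_regression(table)
    X = sm.add_constant(table[["Sm", "Ot", "Cr"]].to_numpy())
    ols = sm.OLS(table["Rm"].to_numpy(), X).fit()
    for i, name in enumerate(("const", "Sm", "Ot", "Cr")):
        assert abs(res.fixed_effects[name] - ols.params[i]) < 1e-6


def test_lme_recovers_planted_effect_across_simulations():
    rng = np.random.default_rng(11)
    n_ok = 0
    n_sim = 60
    for _ in range(n_sim):
        table = _lme_table(rng, beta=(0.0, 0.5, 0.0, 0.0), animal_sd=0.2, n_per=50)
        res = lme_regression(table)
        se = 0.5 / max(abs(res.t_values["Sm"]), 1e-9)
        n_ok += abs(res.fixed_effects["Sm"] - 0.5) < 2 * se
    assert n_ok / n_sim >= 0.9


def test_lme_single_animal_falls_back_to_ols():
    rng = np.random.default_rng(12)
    table = _lme_table(rng, n_animals=1)
    with pytest.warns(UserWarning):
        res = lme_regression(table)
    assert res.method == "ols-fallback"


def test_lme_null_lrt_not_anticonservative():
    rng = np.random.default_rng(13)
    rejections = 0
    n_sim = 40
    for _ in range(n_sim):
        table = _lme_table(rng, beta=(0.0, 0.0, 0.0, 0.0), animal_sd=0.2, n_per=30)
        res = lme_regression(table)
        rejections += res.lrt_p < 0.05
    assert rejections / n_sim < 0.15
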