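"""Trial-locked statistics: onsets, tensor extraction, baseline pooling,
Welch tests, BH thresholding, z-scores, incremental updates, live mode."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from ecogmap.exceptions import ConfigError
from ecogmap.mapping import (
    IncrementalMapper,
    LiveActivation,
    MapConfig,
    TrialTensor,
    bh_threshold,
    bin_statistics,
    compute_map,
    detect_trial_onsets,
    extract_trial_tensor,
    pool_baseline,
    zscore_map,
)
from ecogmap.spectral import BurgConfig, FeatureSeries


def make_features(values, state, slide_ms=20.0):
    values = np.atleast_2d(values)
    cfg = BurgConfig(slide_ms=slide_ms)
    times = np.arange(values.shape[1]) * slide_ms / 1000.0
    return FeatureSeries(values, times, np.asarray(state, dtype=np.uint32), cfg)


def make_tensor(values, slide_ms=20.0, t0_ms=-1000.0):
    values = np.asarray(values, dtype=np.float64)
    n_bins = values.shape[2]
    times = t0_ms + slide_ms * np.arange(n_bins)
    return TrialTensor(
        values=values,
        bin_times_ms=times,
        stimulus_codes=np.zeros(values.shape[0], dtype=int),
        onset_steps=np.zeros(values.shape[0], dtype=int),
        bin_offsets=np.round(times / slide_ms).astype(int),
        slide_ms=slide_ms,
    )


# -- onsets -----------------------------------------------------------------

def test_onset_detection_examples():
    assert detect_trial_onsets(np.array([0, 0, 1, 1, 0, 2, 2, 0])) == [(2, 1), (5, 2)]
    assert detect_trial_onsets(np.zeros(10)) == []
    assert detect_trial_onsets(np.array([])) == []
    assert detect_trial_onsets(np.array([3, 3, 0, 1])) == [(0, 3), (3, 1)]


def test_onsets_recovered_on_fixture(default_session, default_run):
    assert len(default_run.onsets) == default_session.config.n_trials
    codes = [code for _, code in default_run.onsets]
    assert set(codes) <= set(default_session.config.stimulus_codes)


# -- tensor extraction ------------------------------------------------------

def test_tensor_bin_count_inclusive_grid(rng):
    feats = make_features(rng.normal(size=(2, 400)), np.zeros(400))
    tensor = extract_trial_tensor(feats, [(200, 1)], MapConfig())
    assert tensor.values.shape == (1, 2, 151)  # (2000 - (-1000)) / 20 + 1
    assert tensor.bin_times_ms[0] == -1000.0
    assert tensor.bin_times_ms[-1] == 2000.0


def test_tensor_reads_correct_steps(rng):
    values = np.arange(400, dtype=float)[None, :]
    feats = make_features(values, np.zeros(400))
    tensor = extract_trial_tensor(feats, [(100, 1)], MapConfig())
    # bin at -1000 ms with a 20 ms slide reads step 100 - 50
    assert tensor.values[0, 0, 0] == 50.0
    assert tensor.values[0, 0, -1] == 200.0


def test_edge_trial_dropped_others_kept(rng, caplog):
    feats = make_features(rng.normal(size=(1, 400)), np.zeros(400))
    tensor = extract_trial_tensor(feats, [(10, 1), (100, 2), (200, 3)], MapConfig())
    assert tensor.n_trials == 2
    assert tensor.n_dropped == 1
    np.testing.assert_array_equal(tensor.stimulus_codes, [2, 3])


def test_no_usable_trials_errors(rng):
    feats = make_features(rng.normal(size=(1, 80)), np.zeros(80))
    with pytest.raises(ConfigError, match="no trial"):
        extract_trial_tensor(feats, [(5, 1)], MapConfig())


# -- baseline ---------------------------------------------------------------

def test_baseline_pool_size_and_bins(rng):
    tensor = make_tensor(rng.normal(size=(7, 3, 151)))
    baseline = pool_baseline(tensor, MapConfig())
    # -1000..-200 ms inclusive at 20 ms slide = 41 bins per trial
    assert baseline.pool.shape == (3, 7 * 41)
    assert baseline.testable.all()


def test_constant_baseline_flagged_untestable():
    values = np.random.default_rng(0).normal(size=(5, 2, 151))
    values[:, 1, :60] = 4.2  # constant over the whole baseline window
    tensor = make_tensor(values)
    baseline = pool_baseline(tensor, MapConfig())
    assert baseline.mean[1] == pytest.approx(4.2)
    assert not baseline.testable[1]
    assert baseline.testable[0]


def test_min_trials_enforced(rng):
    tensor = make_tensor(rng.normal(size=(1, 2, 151)))
    with pytest.raises(ConfigError, match="trials"):
        pool_baseline(tensor, MapConfig())


# -- bin statistics ---------------------------------------------------------

def welch_oracle(a, b):
    """Textbook Welch statistic and two-tailed p, written independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sstats.t.sf(abs(t), df)
    return t, p


def test_welch_hand_case():
    from ecogmap.mapping import BaselineDistribution

    bin_sample = np.array([1.0, 2.0, 3.0])
    pool = np.array([0.0, 0.5, 1.0, 1.5])
    baseline = BaselineDistribution(
        pool=pool[None, :],
        mean=np.array([pool.mean()]),
        sd=np.array([pool.std(ddof=1)]),
        testable=np.array([True]),
    )
    small = make_tensor(bin_sample[:, None, None], t0_ms=0.0)
    t, p = bin_statistics(small, baseline)
    t_ref, p_ref = welch_oracle(bin_sample, pool)
    assert t[0, 0] == pytest.approx(t_ref, abs=1e-12)
    assert p[0, 0] == pytest.approx(p_ref, abs=1e-12)


def test_identical_samples_give_t0_p1():
    from ecogmap.mapping import BaselineDistribution

    sample = np.array([1.0, 2.0, 3.0, 4.0])
    baseline = BaselineDistribution(
        pool=sample[None, :],
        mean=np.array([sample.mean()]),
        sd=np.array([sample.std(ddof=1)]),
        testable=np.array([True]),
    )
    t, p = bin_statistics(make_tensor(sample[:, None, None], t0_ms=0.0), baseline)
    assert t[0, 0] == 0.0
    assert p[0, 0] == 1.0


def test_separated_samples_large_positive_t():
    from ecogmap.mapping import BaselineDistribution

    pool = np.array([0.0, 1e-6, -1e-6, 2e-6])
    baseline = BaselineDistribution(
        pool=pool[None, :],
        mean=np.array([pool.mean()]),
        sd=np.array([pool.std(ddof=1)]),
        testable=np.array([True]),
    )
    bins = np.full(4, 2.0) + np.array([0, 1e-9, -1e-9, 2e-9])
    t, p = bin_statistics(make_tensor(bins[:, None, None], t0_ms=0.0), baseline)
    assert t[0, 0] > 100
    assert p[0, 0] < 1e-6


def test_t_sign_positive_when_bin_exceeds_baseline(default_run):
    res = default_run.result
    z = res.z_display
    ok = np.isfinite(z)
    assert np.all(np.sign(z[ok][res.t_stat[ok] != 0]) == np.sign(res.t_stat[ok][res.t_stat[ok] != 0]))


# -- BH ---------------------------------------------------------------------

def bh_oracle(p, q):
    """Brute-force step-up: try every k explicitly."""
    flat = np.sort(p.ravel())
    m = flat.size
    k_star = 0
    for k in range(1, m + 1):
        if flat[k - 1] <= k * q / m:
            k_star = k
    if k_star == 0:
        return np.zeros_like(p, dtype=bool)
    return p <= flat[k_star - 1]


def test_bh_worked_example():
    p = np.array([0.001, 0.011, 0.02, 0.04, 0.6])
    mask = bh_threshold(p, 0.05)
    np.testing.assert_array_equal(mask, [True, True, True, True, False])


def test_bh_all_ones_empty_mask():
    assert not bh_threshold(np.ones((4, 5)), 0.05).any()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_bh_equals_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=(6, 25)) ** rng.uniform(0.5, 3)
    q = rng.uniform(0.01, 0.2)
    np.testing.assert_array_equal(bh_threshold(p, q), bh_oracle(p, q))


def test_bh_matches_statsmodels():
    multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
    rng = np.random.default_rng(17)
    p = rng.uniform(size=300) ** 2
    ours = bh_threshold(p, 0.05)
    ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
    np.testing.assert_array_equal(ours, ref)


def test_bh_respects_testable_mask():
    p = np.array([[0.001, 0.2], [0.001, 0.3]])
    testable = np.array([[True, True], [False, False]])
    mask = bh_threshold(p, 0.05, testable)
    assert not mask[1].any()
    assert mask[0, 0]


# -- z-scores ---------------------------------------------------------------

def test_zscore_definition(rng):
    tensor = make_tensor(rng.normal(size=(10, 2, 151)))
    config = MapConfig()
    baseline = pool_baseline(tensor, config)
    z = zscore_map(tensor, baseline)
    bin_mean = tensor.values.mean(axis=0)
    np.testing.assert_allclose(
        z, (bin_mean - baseline.mean[:, None]) / baseline.sd[:, None]
    )
    # shifting one bin's values by exactly sigma_b moves its z by one
    shifted = tensor.values.copy()
    shifted[:, 0, 60] += baseline.sd[0]
    z2 = zscore_map(make_tensor(shifted), baseline)
    assert z2[0, 60] - z[0, 60] == pytest.approx(1.0, abs=1e-9)


def test_zscore_untestable_channel_flagged_nan():
    values = np.random.default_rng(1).normal(size=(5, 2, 151))
    values[:, 0, :] = 7.0
    tensor = make_tensor(values)
    baseline = pool_baseline(tensor, MapConfig())
    z = zscore_map(tensor, baseline)
    assert np.isnan(z[0]).all()
    assert np.isfinite(z[1]).all()


# -- incremental updating ---------------------------------------------------

def test_incremental_equals_batch_every_prefix(rng):
    values = rng.normal(size=(12, 3, 151))
    values[:, 1, 70:90] += 1.5  # an effect on one channel
    tensor = make_tensor(values)
    config = MapConfig()
    mapper = IncrementalMapper(config, tensor.bin_times_ms, tensor.slide_ms)
    for n in range(12):
        out = mapper.add_trial(values[n])
        assert mapper.trial_count == n + 1
        if n + 1 < config.min_trials:
            assert out is None
            continue
        batch = compute_map(make_tensor(values[: n + 1]), config)
        np.testing.assert_array_equal(out.significant, batch.significant)
        assert np.nanmax(np.abs(out.z_display - batch.z_display)) <= 1e-9
        assert out.n_trials == n + 1


def test_incremental_grid_mismatch_rejected(rng):
    mapper = IncrementalMapper(MapConfig(), np.arange(-1000.0, 2001.0, 20.0), 20.0)
    mapper.add_trial(rng.normal(size=(3, 151)))
    with pytest.raises(ConfigError):
        mapper.add_trial(rng.normal(size=(3, 150)))


# -- live mode --------------------------------------------------------------

def test_live_constant_input_z_goes_to_zero():
    live = LiveActivation(2, step_s=0.02, tau_s=1.0)
    z = None
    for _ in range(200):
        z, _ = live.update(np.array([5.0, -3.0]))
    np.testing.assert_allclose(z, 0.0)
    assert live.warmed_up


def test_live_step_change_reads_in_sd_units_then_decays():
    rng = np.random.default_rng(8)
    live = LiveActivation(1, step_s=0.02, tau_s=2.0)
    for _ in range(800):
        live.update(rng.normal(size=1))
    sd = np.sqrt(live._var[0])
    z_first, warmed = live.update(np.array([live._mean[0] + 3 * sd]))
    assert warmed
    assert z_first[0] == pytest.approx(3.0, abs=1e-9)
    z_later = None
    for _ in range(2000):
        z_later, _ = live.update(np.array([live._mean[0]]))
    assert abs(z_later[0]) < 0.5


def test_live_infinite_tau_reproduces_fixed_baseline():
    """With tau -> infinity the running statistics are the cumulative sample
    moments, i.e. fixed-baseline z-scoring against all past data."""
    rng = np.random.default_rng(9)
    x = rng.normal(2.0, 1.5, size=500)
    live = LiveActivation(1, step_s=0.02, tau_s=1e12)
    for v in x[:-1]:
        live.update(np.array([v]))
    mean, var = x[:-1].mean(), x[:-1].var()
    z, _ = live.update(np.array([x[-1]]))
    assert z[0] == pytest.approx((x[-1] - mean) / np.sqrt(var), abs=1e-6)


# -- fixture-level behaviour ------------------------------------------------

def test_significant_mask_subset_of_alpha(default_run):
    res = default_run.result
    assert np.all(res.p_value[res.significant] <= MapConfig().fdr_q)


def test_permuting_onsets_destroys_significance(default_run):
    """Uniformly shuffled trial onsets decouple the tensor from the bursts:
    the median rejected-bin count over permutations is 0."""
    rng = np.random.default_rng(123)
    feats = default_run.features
    config = MapConfig()
    n_steps = feats.values.shape[1]
    lo, hi = 50, n_steps - 101
    counts = []
    for _ in range(15):
        fake = sorted(rng.choice(np.arange(lo, hi), size=30, replace=False))
        tensor = extract_trial_tensor(feats, [(int(s), 1) for s in fake], config)
        counts.append(compute_map(tensor, config).significant.sum())
    assert np.median(counts) == 0
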