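"""Lag alignment, greedy trimming, DTW and matrix aggregation, each
checked against independent brute-force oracles."""

import numpy as np
import pytest

import physioclust as pc
from physioclust import ChannelKind
from physioclust.dissimilarity import channel_pair_distance, compute_raw_tensor, subset_matrix


# --- independent oracles ---------------------------------------------------


def brute_force_lag(x, y, max_lag):
    """Scan every lag, Pearson correlation of the mean-removed overlap."""
    best_val, best_lag = -np.inf, 0
    order = sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l > 0))
    for lag in order:
        a, b = max(0, -lag), min(len(x), len(y) - lag)
        if b - a < 2:
            continue
        xa = np.asarray(x[a:b], float)
        ya = np.asarray(y[a + lag : b + lag], float)
        xa = xa - xa.mean()
        ya = ya - ya.mean()
        den = np.linalg.norm(xa) * np.linalg.norm(ya)
        if den == 0:
            continue
        val = float(np.dot(xa, ya) / den)
        if val > best_val:
            best_val, best_lag = val, lag
    return best_lag


def greedy_trim_sim(xa, ya, budget):
    """Hand simulation of the end-trimming rule."""
    i, j = 0, len(xa)
    removals = []
    for _ in range(budget):
        dl, dr = abs(xa[i] - ya[i]), abs(xa[j - 1] - ya[j - 1])
        if dl == 0 and dr == 0:
            break
        if dl >= dr:
            removals.append("left")
            i += 1
        else:
            removals.append("right")
            j -= 1
    return i, j, removals


def dtw_enumerate(x, y):
    """Exhaustive enumeration of all monotone warping paths."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, acc):
        acc += abs(x[i] - y[j])
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def dtw_memo(x, y):
    """Top-down memoized DTW (independent of the package's bottom-up DP)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        c = abs(x[i] - y[j])
        if i == 0 and j == 0:
            return c
        opts = []
        if i > 0:
            opts.append(rec(i - 1, j))
        if j > 0:
            opts.append(rec(i, j - 1))
        if i > 0 and j > 0:
            opts.append(rec(i - 1, j - 1))
        return c + min(opts)

    return rec(len(x) - 1, len(y) - 1)


# --- optimal_lag -----------------------------------------------------------


def test_lag_identity_is_zero():
    x = np.sin(np.linspace(0, 20, 300))
    assert pc.optimal_lag(x, x, 50) == 0


def test_lag_recovers_known_delay():
    rng = np.random.default_rng(0)
    t = np.arange(400) / 100.0
    base = np.sin(2 * np.pi * 1.7 * t) + 0.1 * rng.standard_normal(400)
    x = base
    y = np.roll(base, 17)  # y[t] = x[t - 17]: y must be advanced by 17
    lag = pc.optimal_lag(x, y, 40)
    assert lag == brute_force_lag(x, y, 40)
    assert lag == 17


def test_lag_matches_brute_force_on_random_pairs():
    rng = np.random.default_rng(4)
    for _ in range(20):
        nx, ny = rng.integers(30, 80, 2)
        x = rng.standard_normal(nx)
        y = rng.standard_normal(ny)
        ml = int(rng.integers(0, 15))
        assert pc.optimal_lag(x, y, ml) == brute_force_lag(x, y, ml)


def test_lag_anticorrelated_forced_zero():
    x = np.sin(np.linspace(0, 10, 100))
    assert pc.optimal_lag(x, -x, 0) == 0


def test_lag_constant_sequence_warns():
    with pytest.warns(RuntimeWarning):
        assert pc.optimal_lag(np.ones(50), np.arange(50.0), 10) == 0


# --- align_and_trim --------------------------------------------------------


def test_trim_noop_on_identical_sequences():
    x = np.sin(np.linspace(0, 10, 120))
    res = pc.align_and_trim(x, x, 0, trim_frac=0.1)
    assert len(res.x_trimmed) == 120
    np.testing.assert_array_equal(res.x_trimmed, res.y_trimmed)


def test_trim_spike_fixture_matches_greedy_simulation():
    rng = np.random.default_rng(2)
    y = rng.standard_normal(100)
    x = y + 0.01 * rng.standard_normal(100)  # small nonzero diffs everywhere
    x[0] += 10.0  # large spike at the left boundary
    res = pc.align_and_trim(x, y, 0, trim_frac=0.05)
    i, j, removals = greedy_trim_sim(x, y, 5)
    assert len(removals) == 5
    assert removals[0] == "left"
    assert len(res.x_trimmed) == 95
    np.testing.assert_array_equal(res.x_trimmed, x[i:j])
    np.testing.assert_array_equal(res.y_trimmed, y[i:j])


def test_trim_zero_budget_is_pure_overlap():
    x = np.arange(50.0)
    y = np.arange(50.0) + 1
    res = pc.align_and_trim(x, y, 5, trim_frac=0.0)
    assert len(res.x_trimmed) == 45
    assert res.lag_samples == 5


def test_trim_rejects_short_overlap():
    with pytest.raises(ValueError):
        pc.align_and_trim(np.arange(12.0), np.arange(12.0), 5)


# --- dtw_distance ----------------------------------------------------------


def test_dtw_identity_zero():
    x = np.array([0.2, 0.5, 0.9])
    assert pc.dtw_distance(x, x) == 0.0


def test_dtw_hand_examples():
    assert pc.dtw_distance([1.0, 3.0], [2.0]) == pytest.approx(
        dtw_enumerate([1.0, 3.0], [2.0])
    )
    assert pc.dtw_distance([1.0, 3.0], [2.0]) == 2.0
    assert pc.dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0]) == 0.0


def test_dtw_matches_enumeration_on_random_short_pairs():
    rng = np.random.default_rng(5)
    for _ in range(40):
        nx, ny = rng.integers(1, 7, 2)
        x = rng.uniform(0, 1, nx)
        y = rng.uniform(0, 1, ny)
        assert pc.dtw_distance(x, y) == pytest.approx(dtw_enumerate(list(x), list(y)))


def test_dtw_symmetry():
    rng = np.random.default_rng(6)
    for _ in range(10):
        x = rng.uniform(0, 1, 30)
        y = rng.uniform(0, 1, 25)
        assert pc.dtw_distance(x, y) == pytest.approx(pc.dtw_distance(y, x))


def test_dtw_rejects_empty():
    with pytest.raises(ValueError):
        pc.dtw_distance([], [1.0])


# --- pair vectors and matrix -----------------------------------------------


def test_pair_vector_self_is_zero(tiny_preprocessed):
    vec = pc.pair_distance_vector(tiny_preprocessed[0], tiny_preprocessed[0], "both")
    np.testing.assert_allclose(vec, 0.0, atol=1e-12)


def test_pair_vector_modality_selection(tiny_preprocessed):
    a, b = tiny_preprocessed[:2]
    assert len(pc.pair_distance_vector(a, b, "acc")) == 3
    assert len(pc.pair_distance_vector(a, b, "ecg")) == 2
    assert len(pc.pair_distance_vector(a, b, "both")) == 5


def test_pair_vector_isolates_changed_modality(tiny_preprocessed):
    a = tiny_preprocessed[0]
    rng = np.random.default_rng(8)
    channels = dict(a.channels)
    for kind in (ChannelKind.ECG_1, ChannelKind.ECG_2):
        ch = channels[kind]
        channels[kind] = pc.SignalChannel(
            kind=kind, samples=np.clip(ch.samples + 0.2 * rng.standard_normal(len(ch.samples)), 0, 1),
            rate=ch.rate, units=ch.units,
        )
    b = pc.Trial(trial_id="mut", subject_id=a.subject_id, activity=a.activity, channels=channels)
    vec = pc.pair_distance_vector(a, b, "both")
    np.testing.assert_allclose(vec[:3], 0.0, atol=1e-12)
    assert np.all(vec[3:] > 0)


def test_pair_vector_rejects_rate_mismatch(tiny_preprocessed, tiny_cohort):
    _, raw_trials = tiny_cohort
    with pytest.raises(ValueError):
        pc.pair_distance_vector(tiny_preprocessed[0], raw_trials[1], "ecg")


def test_normalization_endpoints_and_aggregate_bound():
    rng = np.random.default_rng(9)
    n, m = 6, 3
    raw = np.zeros((n, n, m))
    iu = np.triu_indices(n, 1)
    for k in range(m):
        vals = rng.uniform(1, 10, len(iu[0]))
        raw[iu[0], iu[1], k] = vals
        raw[iu[1], iu[0], k] = vals
    ids = tuple(f"t{i}" for i in range(n))
    mat = pc.normalize_and_aggregate(raw, ("a", "b", "c"), ids, "acc")
    for k, name in enumerate(("a", "b", "c")):
        normed = (raw[iu[0], iu[1], k] - mat.channel_stats[name][0]) / (
            mat.channel_stats[name][1] - mat.channel_stats[name][0]
        )
        assert normed.min() == pytest.approx(0.0)
        assert normed.max() == pytest.approx(1.0)
    assert np.all(mat.values >= 0)
    assert np.all(mat.values <= np.sqrt(m) + 1e-12)
    np.testing.assert_allclose(mat.values, mat.values.T)
    np.testing.assert_allclose(np.diag(mat.values), 0.0)


def test_aggregate_unit_vector_gives_sqrt_m():
    # one pair attains the per-channel max on all five channels -> D = sqrt(5)
    n = 3
    raw = np.zeros((n, n, 5))
    iu = ([0, 0, 1], [1, 2, 2])
    for k in range(5):
        vals = np.array([1.0, 5.0, 3.0])
        raw[iu[0], iu[1], k] = vals
        raw[iu[1], iu[0], k] = vals
    mat = pc.normalize_and_aggregate(raw, tuple("abcde"), ("t0", "t1", "t2"), "both")
    assert mat.values[0, 2] == pytest.approx(np.sqrt(5.0))
    assert mat.values[0, 1] == pytest.approx(0.0)


def test_degenerate_channel_warns_and_zeroes():
    n = 3
    raw = np.zeros((n, n, 1))
    with pytest.warns(RuntimeWarning):
        mat = pc.normalize_and_aggregate(raw, ("flat",), ("a", "b", "c"), "acc")
    np.testing.assert_array_equal(mat.values, 0.0)


def test_toy_matrix_matches_straight_line_reference():
    """Full pipeline on 4 synthetic trials vs an independently coded
    lag-scan + greedy-trim + memoized-DTW reference."""
    rng = np.random.default_rng(12)
    n, length = 4, 16
    seqs = {
        (i, kind): rng.uniform(0, 1, length)
        for i in range(n)
        for kind in pc.dissimilarity.MODALITY_CHANNELS["acc"]
    }
    trials = []
    for i in range(n):
        channels = {}
        for kind in ChannelKind:
            if kind in pc.dissimilarity.MODALITY_CHANNELS["acc"]:
                samples = seqs[(i, kind)]
            else:
                samples = np.zeros(length)
            channels[kind] = pc.SignalChannel(kind=kind, samples=samples, rate=10.0, units="g")
        trials.append(
            pc.Trial(trial_id=f"t{i}", subject_id=f"s{i}", activity=pc.ActivityLabel.RESTING,
                     channels=channels)
        )
    params = pc.DissimilarityParams(max_lag_frac=0.2, trim_frac=0.05)
    mat = pc.build_matrix(trials, "acc", params)

    # straight-line reference
    kinds = pc.dissimilarity.MODALITY_CHANNELS["acc"]
    raw_ref = np.zeros((n, n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            for k, kind in enumerate(kinds):
                x, y = seqs[(i, kind)], seqs[(j, kind)]
                lag = brute_force_lag(x, y, int(np.floor(0.2 * length)))
                a, b = max(0, -lag), min(len(x), len(y) - lag)
                xa, ya = x[a:b], y[a + lag : b + lag]
                lo, hi, _ = greedy_trim_sim(xa, ya, int(np.floor(0.05 * (b - a))))
                d = dtw_memo(tuple(xa[lo:hi]), tuple(ya[lo:hi]))
                raw_ref[i, j, k] = raw_ref[j, i, k] = d
    iu = np.triu_indices(n, 1)
    ref = np.zeros((n, n))
    for k in range(3):
        vals = raw_ref[iu[0], iu[1], k]
        span = vals.max() - vals.min()
        normed = (raw_ref[:, :, k] - vals.min()) / span
        ref += normed**2
    ref = np.sqrt(ref)
    np.fill_diagonal(ref, 0.0)
    np.testing.assert_allclose(mat.values, ref, atol=1e-10)


def test_build_matrix_minimal_and_errors(tiny_preprocessed):
    mat = pc.build_matrix(tiny_preprocessed[:2], "acc")
    assert mat.n == 2
    assert mat.values[0, 1] == mat.values[1, 0]
    with pytest.raises(ValueError):
        pc.build_matrix(tiny_preprocessed[:1], "acc")


def test_subset_matrix_renormalizes(tiny_preprocessed):
    mat = pc.build_matrix(tiny_preprocessed[:5], "acc")
    sub = subset_matrix(mat, np.array([0, 2, 4]))
    assert sub.n == 3
    iu = np.triu_indices(3, 1)
    for k, name in enumerate(sub.channels):
        vals = sub.raw[iu[0], iu[1], k]
        lo, hi = sub.channel_stats[name]
        if hi > lo:
            assert vals.min() == pytest.approx(lo)
            assert vals.max() == pytest.approx(hi)


def test_matrix_io_roundtrip(tmp_path, tiny_preprocessed):
    mat = pc.build_matrix(tiny_preprocessed[:3], "acc")
    pc.dissimilarity.save_matrix(mat, tmp_path / "m.tsv")
    loaded = pc.dissimilarity.load_matrix(tmp_path / "m.tsv")
    np.testing.assert_allclose(loaded.values, mat.values, atol=1e-12)
    assert loaded.trial_ids == mat.trial_ids
    assert loaded.channel_stats == mat.channel_stats
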