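"""Windowing, superclass mapping, decimation and robust scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import equigait as eg
from equigait.io import AccelStream, LabelTrack, SessionRecord
from equigait.preprocessing import (
    RATES_HZ,
    WINDOW_SIZES_S,
    RobustWindowScaler,
    WindowConfig,
    decimate,
    extract_pure_windows,
    fit_scaler,
    to_superclass,
    window_length,
)


class TestSuperclass:
    @pytest.mark.parametrize(
        "fine,expected",
        [
            ("halt", "halt"),
            ("collected walk", "walk"),
            ("medium walk", "walk"),
            ("normal trot", "trot"),
            ("collected trot", "trot"),
            ("normal canter", "canter"),
        ],
    )
    def test_eleven_fine_labels_collapse(self, fine, expected):
        assert to_superclass(fine) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            to_superclass("gallop")


class TestWindowLength:
    @pytest.mark.parametrize(
        "w,r,n", [(4, 25, 100), (0.6, 5, 3), (6, 50, 300), (2.2, 10, 22)]
    )
    def test_exact_sample_counts(self, w, r, n):
        assert window_length(w, r) == n

    def test_whole_grid_is_integral(self):
        for w in WINDOW_SIZES_S:
            for r in RATES_HZ:
                assert window_length(w, r) == round(w * r)

    def test_non_integral_product_rejected(self):
        with pytest.raises(ValueError):
            window_length(0.7, 5)


class TestDecimate:
    def test_50_to_25_keeps_even_indices(self):
        x = np.arange(300)
        out = decimate(x, 50, 25)
        assert len(out) == 150
        assert np.array_equal(out, x[::2])

    def test_identity_at_same_rate(self):
        x = np.arange(10)
        assert np.array_equal(decimate(x, 50, 50), x)

    def test_non_divisor_rejected(self):
        with pytest.raises(ValueError):
            decimate(np.arange(10), 50, 20)

    def test_factor_composition(self, rng):
        x = rng.normal(size=(600, 3))
        via_25 = decimate(decimate(x, 50, 25), 25, 5)
        assert np.array_equal(via_25, decimate(x, 50, 5))


def _session(bout_spec, rate=50.0, horse="h1"):
    """Session from (duration_s, activity) tuples tiling from t=0."""
    t0 = 0.0
    intervals = []
    for dur, act in bout_spec:
        intervals.append((t0, t0 + dur, act))
        t0 += dur
    n = int(round(t0 * rate))
    ts = np.arange(n) / rate
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.1, size=(n, 3))
    return SessionRecord(
        horse_id=horse,
        rider_id="r1",
        location="knee",
        stream=AccelStream(t=ts, a=a, rate_hz=rate),
        labels=LabelTrack(intervals),
    )


def brute_force_window_count(super_labels, L, step):
    """O(n^2) oracle: test every start index for purity."""
    count = 0
    n = len(super_labels)
    starts_used = []
    i = 0
    while i <= n - L:
        seg = super_labels[i : i + L]
        if seg[0] is not None and all(s == seg[0] for s in seg):
            # only placements aligned to the sliding scheme inside a bout
            count += 1
            starts_used.append(i)
            i += step
        else:
            # jump to next potential bout start
            i += 1
    return count


class TestExtractPureWindows:
    def test_bout_arithmetic(self):
        sess = _session([(10, "normal walk"), (6.3, "normal trot")])
        ds = extract_pure_windows(sess, WindowConfig(4, 50))
        # floor((10-4)/4)+1 = 2 walk, floor((6.3-4)/4)+1 = 1 trot
        assert sorted(ds.y) == ["trot", "walk", "walk"]

    def test_bout_shorter_than_window_yields_nothing(self):
        sess = _session([(3.9, "normal walk")])
        ds = extract_pure_windows(sess, WindowConfig(4, 50))
        assert len(ds) == 0

    def test_windows_never_cross_bout_boundaries(self):
        sess = _session([(5, "normal walk"), (5, "normal trot"), (5, "normal walk")])
        ds = extract_pure_windows(sess, WindowConfig(2, 50))
        assert len(ds) == 6  # 2 per 5 s bout with 2 s windows
        # re-annotate each window's sample range for purity
        labs = eg.annotate(sess.stream, sess.labels)
        supers = np.array([to_superclass(lab) for lab in labs], dtype=object)
        L = 100
        for k in range(len(ds)):
            matches = [
                i
                for i in range(0, len(supers) - L + 1)
                if np.allclose(sess.stream.a[i : i + L], ds.X[k])
            ]
            assert matches, "window not found in stream"
            seg = supers[matches[0] : matches[0] + L]
            assert set(seg) == {ds.y[k]}

    def test_overlap_fraction_halves_the_step(self):
        sess = _session([(10, "normal walk")])
        no_overlap = extract_pure_windows(sess, WindowConfig(4, 50, 0.0))
        half = extract_pure_windows(sess, WindowConfig(4, 50, 0.5))
        assert len(no_overlap) == 2
        assert len(half) == 4  # floor((500-200)/100)+1

    def test_unlabelled_spans_yield_nothing(self):
        sess = _session([(10, "normal walk")])
        sess = SessionRecord(
            horse_id="h1",
            rider_id="r1",
            location="knee",
            stream=sess.stream,
            labels=LabelTrack([(0, 4, "normal walk")]),  # rest unlabelled
        )
        ds = extract_pure_windows(sess, WindowConfig(4, 50))
        assert len(ds) == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_count_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        acts = ["halt", "normal walk", "collected trot", "medium canter"]
        bouts = [
            (float(rng.uniform(0.5, 9)), acts[int(rng.integers(4))])
            for _ in range(int(rng.integers(3, 10)))
        ]
        sess = _session(bouts)
        w, r = 2, 25
        ds = extract_pure_windows(sess, WindowConfig(w, r))
        sub_labs = eg.annotate(
            AccelStream(
                t=decimate(sess.stream.t, 50, r),
                a=decimate(sess.stream.a, 50, r),
                rate_hz=r,
            ),
            sess.labels,
        )
        supers = [
            to_superclass(lab) if lab != "unlabelled" else None for lab in sub_labs
        ]
        assert len(ds) == brute_force_window_count(supers, w * r, w * r)

    def test_window_count_monotone_in_window_size(self, small_cohort):
        sess = small_cohort[0]
        counts = [
            len(extract_pure_windows(sess, WindowConfig(w, 25)))
            for w in (1, 2, 4)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRobustScaler:
    def test_closed_form_five_values(self):
        # one channel {1..5}: median 3, IQR 2 -> 5 maps to 1.0
        X = np.zeros((5, 1, 3))
        X[:, 0, 0] = [1, 2, 3, 4, 5]
        X[:, 0, 1] = [1, 2, 3, 4, 5]
        X[:, 0, 2] = 7.0  # constant channel
        sc = RobustWindowScaler().fit(X)
        out = sc.transform(X)
        assert out[4, 0, 0] == pytest.approx(1.0)
        assert np.allclose(out[:, 0, 2], 0.0)  # constant -> all zeros

    def test_train_median_zero_iqr_one(self, rng):
        X = rng.normal(2.0, 3.0, size=(40, 25, 3))
        out = RobustWindowScaler().fit(X).transform(X)
        flat = out.reshape(-1, 3)
        assert np.allclose(np.median(flat, axis=0), 0.0, atol=1e-6)
        q75, q25 = np.percentile(flat, [75, 25], axis=0)
        assert np.allclose(q75 - q25, 1.0, atol=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_independent_quantile_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(13, 7, 3)) * rng.uniform(0.1, 5)
        sc = RobustWindowScaler().fit(X)
        flat = X.reshape(-1, 3)
        med = np.quantile(flat, 0.5, axis=0, method="linear")
        iqr = np.quantile(flat, 0.75, axis=0) - np.quantile(flat, 0.25, axis=0)
        expected = (X - med) / iqr
        assert np.allclose(sc.transform(X), expected, atol=1e-9)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_scaler(np.empty((0, 10, 3)))

    def test_sklearn_get_set_params_round_trip(self):
        sc = RobustWindowScaler()
        sc.set_params(**sc.get_params())
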