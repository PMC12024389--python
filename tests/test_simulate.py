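"""Synthetic cohort generator: determinism, label tiling, spectral content."""

import numpy as np
import pytest
from scipy.signal import periodogram

import equigait as eg
from equigait.preprocessing import to_superclass
from equigait.simulate import (
    DEFAULT_GAIT_MIX,
    GaitProfile,
    default_gait_profiles,
    default_location_transfers,
)


@pytest.fixture(scope="module")
def profiles():
    return default_gait_profiles()


@pytest.fixture(scope="module")
def transfers():
    return default_location_transfers()


class TestDefaultProfiles:
    def test_four_superclasses_covered(self, profiles):
        assert set(profiles) == {"halt", "walk", "trot", "canter"}

    def test_halt_is_gravity_plus_noise_only(self, profiles):
        assert np.all(profiles["halt"].harmonic_amps == 0)

    def test_stride_frequencies_ordered(self, profiles):
        assert 0 < profiles["walk"].stride_freq_hz < profiles["trot"].stride_freq_hz
        assert profiles["walk"].stride_freq_hz < profiles["canter"].stride_freq_hz

    def test_physiologic_range_enforced(self):
        with pytest.raises(ValueError, match="physiologic"):
            GaitProfile("walk", 4.0, np.full((3, 2), 0.1), noise_sd=0.02)


def _session(horse, location, profiles, **cfg_kwargs):
    cfg = eg.CohortConfig(**{"session_length_s": 60.0, "seed": 5, **cfg_kwargs})
    return eg.simulate_session(horse, location, profiles, cfg)


class TestSimulateSession:
    def test_sample_count(self, profiles, transfers):
        sess = _session(eg.HorseSpec("h"), transfers["knee"], profiles)
        assert len(sess.stream) == 3000  # 60 s x 50 Hz

    def test_labels_tile_session_exactly(self, profiles, transfers):
        sess = _session(eg.HorseSpec("h"), transfers["arm"], profiles)
        assert sess.labels.total_duration_s == pytest.approx(60.0)
        for (_, e0, _), (s1, _, _) in zip(sess.labels, sess.labels.intervals[1:]):
            assert s1 == pytest.approx(e0)

    def test_degenerate_mix_all_walk(self, profiles, transfers):
        horse = eg.HorseSpec("h", gait_mix={"walk": 1.0})
        sess = _session(horse, transfers["knee"], profiles)
        assert {to_superclass(lab) for _, _, lab in sess.labels} == {"walk"}

    def test_same_seed_bit_identical(self, profiles, transfers):
        a = _session(eg.HorseSpec("h"), transfers["chest"], profiles)
        b = _session(eg.HorseSpec("h"), transfers["chest"], profiles)
        assert np.array_equal(a.stream.a, b.stream.a)
        assert a.labels.intervals == b.labels.intervals

    def test_halt_only_session_gravity_and_no_peak(self, profiles, transfers):
        horse = eg.HorseSpec("h", gait_mix={"halt": 1.0})
        sess = _session(horse, transfers["knee"], profiles)
        x = sess.stream.a[:, 0]
        assert 0.9 <= x.mean() <= 1.1
        assert x.std() <= 3 * (
            profiles["halt"].noise_sd + transfers["knee"].rider_noise_sd
        )
        # independent FFT oracle: no spectral line above the noise floor
        f, p = periodogram(x - x.mean(), fs=50.0)
        assert p.max() < 50 * p.mean()

    def test_locomotion_spectral_peak_at_scaled_stride(self, profiles, transfers):
        horse = eg.HorseSpec("h", stride_scale=1.05, gait_mix={"canter": 1.0})
        sess = _session(horse, transfers["knee"], profiles, session_length_s=120.0)
        x = sess.stream.a[:, 0]
        f, p = periodogram(x - x.mean(), fs=50.0)
        f0 = profiles["canter"].stride_freq_hz * 1.05
        assert abs(f[np.argmax(p)] - f0) < 0.05

    def test_unknown_gait_in_mix_rejected(self, profiles, transfers):
        horse = eg.HorseSpec("h", gait_mix={"walk": 1.0})
        with pytest.raises(ValueError, match="missing"):
            eg.simulate_session(
                horse,
                transfers["knee"],
                {"halt": profiles["halt"]},
                eg.CohortConfig(),
            )

    def test_locations_share_the_same_ride(self, profiles, transfers):
        horse = eg.HorseSpec("h")
        knee = _session(horse, transfers["knee"], profiles)
        chest = _session(horse, transfers["chest"], profiles)
        assert knee.labels.intervals == chest.labels.intervals


class TestSimulateCohort:
    def test_cartesian_structure(self):
        sessions = eg.simulate_cohort(
            eg.CohortConfig(n_horses=5, session_length_s=30, seed=2)
        )
        assert len(sessions) == 20
        horses = {s.horse_id for s in sessions}
        assert len(horses) == 5
        for h in horses:
            locs = {s.location for s in sessions if s.horse_id == h}
            assert locs == {"knee", "backbone", "chest", "arm"}

    def test_default_mix_matches_reference_imbalance(self):
        assert DEFAULT_GAIT_MIX["walk"] == pytest.approx(575_269 / 1_324_424, abs=5e-4)
        assert sum(DEFAULT_GAIT_MIX.values()) == pytest.approx(1.0)

    def test_aggregate_proportions_near_target(self, default_cohort):
        time_per = {g: 0.0 for g in ("halt", "walk", "trot", "canter")}
        for s in default_cohort:
            for a, b, lab in s.labels:
                time_per[to_superclass(lab)] += b - a
        total = sum(time_per.values())
        for gait, target in DEFAULT_GAIT_MIX.items():
            assert abs(time_per[gait] / total - target) < 0.05

    def test_seed_determinism(self):
        cfg = eg.CohortConfig(n_horses=2, session_length_s=20, seed=9)
        a = eg.simulate_cohort(cfg)
        b = eg.simulate_cohort(cfg)
        assert all(
            np.array_equal(x.stream.a, y.stream.a) for x, y in zip(a, b)
        )

    def test_too_few_horses_rejected(self):
        with pytest.raises(ValueError, match="2 horses"):
            eg.simulate_cohort(eg.CohortConfig(n_horses=1))

    def test_halt_free_horse_has_no_halt(self):
        sessions = eg.simulate_cohort(
            eg.CohortConfig(n_horses=3, session_length_s=120, seed=4),
            halt_free_horse=True,
        )
        last = [s for s in sessions if s.horse_id == "horse02"]
        labs = {lab for s in last for _, _, lab in s.labels}
        assert "halt" not in labs


class TestSpectralSeparability:
    def test_dominant_peak_classifies_moving_gaits(self, default_cohort, profiles):
        """Independent oracle: at the knee, the location of the dominant
        x-axis spectral peak alone sorts walk/trot/canter windows with >= 95%
        accuracy (each gait's band scaled by the horse's stride scale is
        distinct)."""
        cfg = eg.WindowConfig(4, 50)
        correct = total = 0
        bands = {
            "walk": profiles["walk"].stride_freq_hz,  # fundamental dominates
            "trot": 2 * profiles["trot"].stride_freq_hz,  # 2nd harmonic
            "canter": profiles["canter"].stride_freq_hz,
        }
        for sess in default_cohort:
            if sess.location != "knee":
                continue
            ds = eg.extract_pure_windows(sess, cfg)
            for k in range(len(ds)):
                if ds.y[k] == "halt":
                    continue
                x = ds.X[k][:, 0]
                f, p = periodogram(x - x.mean(), fs=50.0)
                fpeak = f[np.argmax(p)]
                # nearest expected dominant line over the plausible
                # per-horse stride-scale range
                guess = min(
                    bands,
                    key=lambda g: min(
                        abs(fpeak - bands[g] * s) for s in np.linspace(0.85, 1.15, 13)
                    ),
                )
                correct += guess == ds.y[k]
                total += 1
        assert total > 100
        assert correct / total >= 0.95
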