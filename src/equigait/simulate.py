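"""Synthetic rider-worn accelerometer cohorts.

The simulator emulates the statistical structure of mounted riding sessions:
bout-structured activity sequences (lognormal bout durations with a 6.3 s
median), four gait superclasses with distinct stride fundamentals and harmonic
signatures, class imbalance matching the reference cohort (walk 43.4%, trot
39.6%, canter 13.6%, halt 3.4% of samples), four sensor locations whose
coupling to the horse's motion differs (knee best, chest worst), and per-horse
variability in stride frequency and amplitude.  It makes no attempt at
biomechanically faithful rider–horse coupled dynamics: each moving gait is a
sum of phase-locked harmonics of a stride fundamental plus Gaussian noise,
and halt is gravity plus noise.

Axis convention: x points toward the ground (gravity = +1 g at rest), z away
from the rider.  All accelerations are in g.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    LOCATIONS,
    AccelStream,
    LabelTrack,
    SessionRecord,
    write_accel_csv,
    write_labels,
    write_manifest,
)

__all__ = [
    "GAITS",
    "DEFAULT_GAIT_MIX",
    "GaitProfile",
    "LocationTransfer",
    "HorseSpec",
    "CohortConfig",
    "default_gait_profiles",
    "default_location_transfers",
    "simulate_session",
    "simulate_cohort",
    "write_cohort",
]

GAITS: tuple[str, ...] = ("halt", "walk", "trot", "canter")

#: Default target share of samples per superclass, mirroring the reference
#: cohort's class imbalance (fractions of 1,324,424 total samples).
DEFAULT_GAIT_MIX: dict[str, float] = {
    "walk": 0.434,
    "trot": 0.396,
    "canter": 0.136,
    "halt": 0.034,
}

_VARIANTS = ("collected", "medium", "normal")


@dataclass
class GaitProfile:
    """Spectral signature of one gait.

    ``harmonic_amps`` has shape (3 axes, n_harmonics): amplitude in g of the
    stride fundamental and its overtones on each axis.  Halt has all
    amplitudes zero — only gravity and noise.
    """

    gait: str
    stride_freq_hz: float
    harmonic_amps: np.ndarray
    noise_sd: float
    amp_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.gait not in GAITS:
            raise ValueError(f"unknown gait {self.gait!r}")
        self.harmonic_amps = np.atleast_2d(np.asarray(self.harmonic_amps, float))
        if self.harmonic_amps.shape[0] != 3:
            raise ValueError("harmonic_amps must have one row per axis (3)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.gait == "halt":
            if np.any(self.harmonic_amps != 0):
                raise ValueError("halt must have zero harmonic amplitudes")
        elif not 0.5 <= self.stride_freq_hz <= 3.0:
            raise ValueError("stride fundamental outside physiologic 0.5-3 Hz")


@dataclass
class LocationTransfer:
    """How a rider body site couples to the horse's motion.

    ``coupling_gain`` multiplies all gait harmonics; ``rider_noise_sd`` adds
    rider-motion noise on top of the sensor noise floor.
    """

    location: str
    coupling_gain: float
    rider_noise_sd: float

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if not 0 < self.coupling_gain <= 1:
            raise ValueError("coupling_gain must be in (0, 1]")
        if self.rider_noise_sd < 0:
            raise ValueError("rider_noise_sd must be >= 0")


@dataclass
class HorseSpec:
    """Per-horse multipliers and gait usage."""

    horse_id: str
    stride_scale: float = 1.0
    amp_scale: float = 1.0
    gait_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAIT_MIX)
    )

    def __post_init__(self) -> None:
        if self.stride_scale <= 0 or self.amp_scale <= 0:
            raise ValueError("stride_scale and amp_scale must be positive")
        unknown = set(self.gait_mix) - set(GAITS)
        if unknown:
            raise ValueError(f"unknown gait(s) in mix: {sorted(unknown)}")
        total = sum(self.gait_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"gait_mix must sum to 1, got {total}")


@dataclass
class CohortConfig:
    """Cohort-level simulation settings; ``seed`` fully determines the output."""

    n_horses: int = 5
    session_length_s: float = 600.0
    bout_median_s: float = 6.3
    bout_sigma: float = 0.5
    sample_rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_length_s <= 0:
            raise ValueError("session_length_s must be positive")
        if self.bout_median_s <= 0 or self.bout_sigma <= 0:
            raise ValueError("bout parameters must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


def default_gait_profiles() -> dict[str, GaitProfile]:
    """Spectrally separable default profiles for the four superclasses.

    Walk is a 0.9 Hz fundamental with weak overtones; trot (ridden rising, so
    the rider imprints the stride rhythm strongly) is 1.3 Hz with a dominant
    second harmonic at 2.6 Hz; canter is 1.7 Hz with an asymmetric three-beat
    overtone mix.  Amplitudes also grow with gait speed, so both the dominant
    spectral peak and the signal power separate the classes.
    """
    amps = {
        "halt": np.zeros((3, 3)),
        "walk": np.array(
            [
                [0.25, 0.08, 0.02],
                [0.10, 0.04, 0.01],
                [0.12, 0.05, 0.01],
            ]
        ),
        # rising trot: boosted fundamental, dominant 2nd harmonic (2-beat gait)
        "trot": np.array(
            [
                [0.22, 0.55, 0.10],
                [0.08, 0.20, 0.05],
                [0.10, 0.26, 0.06],
            ]
        ),
        "canter": np.array(
            [
                [0.65, 0.28, 0.14],
                [0.25, 0.10, 0.06],
                [0.30, 0.14, 0.07],
            ]
        ),
    }
    freqs = {"halt": 0.0, "walk": 0.9, "trot": 1.3, "canter": 1.7}
    return {
        g: GaitProfile(
            gait=g,
            stride_freq_hz=freqs[g],
            harmonic_amps=amps[g],
            noise_sd=0.03,
            amp_jitter=0.0 if g == "halt" else 0.1,
        )
        for g in GAITS
    }


def default_location_transfers() -> dict[str, LocationTransfer]:
    """Default coupling per sensor site: knee >= arm > backbone >= chest."""
    params = {
        "knee": (1.00, 0.01),
        "arm": (0.85, 0.03),
        "backbone": (0.70, 0.06),
        "chest": (0.60, 0.08),
    }
    return {
        loc: LocationTransfer(loc, gain, noise) for loc, (gain, noise) in params.items()
    }


def _derived_seed(*parts) -> int:
    """Stable sub-2^31 seed from arbitrary string-able parts (CRC32-based)."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def _ride_plan(horse: HorseSpec, profiles, config: CohortConfig):
    """Draw the ride itself: bout tiling plus per-bout harmonic draws.

    The plan is a function of (config.seed, horse) only: the four sensors on
    a rider record the *same* ride simultaneously, so every location shares
    the bout schedule, fine-activity variants, amplitude jitters and phases,
    and differs only through its coupling gain and noise.

    Gaits are drawn with probability equal to the target mix (bout durations
    are identically distributed across gaits, so expected time share equals
    the mix); durations are lognormal with the configured median and shape,
    truncated at 1 s.  The final bout is clipped to the session end.
    """
    rng = np.random.default_rng(_derived_seed(config.seed, horse.horse_id, "ride"))
    gaits = [g for g in GAITS if horse.gait_mix.get(g, 0.0) > 0]
    probs = np.array([horse.gait_mix[g] for g in gaits])
    probs = probs / probs.sum()
    mu = np.log(config.bout_median_s)
    plan = []
    t = 0.0
    prev = None
    while t < config.session_length_s:
        gait = gaits[rng.choice(len(gaits), p=probs)]
        if gait == prev and len(gaits) > 1:
            # merge-avoidance: resample once so adjacent bouts tend to differ
            gait = gaits[rng.choice(len(gaits), p=probs)]
        dur = max(1.0, float(rng.lognormal(mu, config.bout_sigma)))
        end = min(t + dur, config.session_length_s)
        prof = profiles[gait]
        variant = "" if gait == "halt" else _VARIANTS[rng.choice(3)] + " "
        jitter = max(0.1, 1.0 + prof.amp_jitter * rng.standard_normal())
        n_harm = prof.harmonic_amps.shape[1]
        phases = rng.uniform(0, 2 * np.pi, size=(3, n_harm))
        plan.append(
            {
                "start": t,
                "end": end,
                "gait": gait,
                "label": f"{variant}{gait}",
                "jitter": jitter,
                "phases": phases,
            }
        )
        prev = gait
        t = end
    return plan


def simulate_session(
    horse: HorseSpec,
    location: LocationTransfer,
    profiles: dict[str, GaitProfile],
    config: CohortConfig,
    rider_id: str = "rider",
) -> SessionRecord:
    """Simulate one (horse, location) session.

    The stream is sampled at ``config.sample_rate_hz``; label intervals tile
    the session with no gaps or overlaps.  During locomotion bouts each axis
    is a sum of harmonics of ``stride_freq_hz * horse.stride_scale`` plus
    noise; during halt the x axis reads gravity (+1 g) plus noise.  Sessions
    of the same horse at different locations share the underlying ride (bouts,
    variants, phases); the same (config.seed, horse, location) triple always
    yields bit-identical output.
    """
    missing = set(horse.gait_mix) - set(profiles)
    if missing:
        raise ValueError(f"profiles missing for gaits: {sorted(missing)}")
    noise_rng = np.random.default_rng(
        _derived_seed(config.seed, horse.horse_id, location.location, "noise")
    )

    n = int(round(config.session_length_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    a = np.zeros((n, 3))
    a[:, 0] = 1.0  # gravity on x

    intervals = []
    for bout in _ride_plan(horse, profiles, config):
        gait = bout["gait"]
        prof = profiles[gait]
        intervals.append((bout["start"], bout["end"], bout["label"]))
        sl = slice(
            int(np.ceil(bout["start"] * config.sample_rate_hz - 1e-9)),
            int(np.ceil(bout["end"] * config.sample_rate_hz - 1e-9)),
        )
        tb = t[sl]
        if gait != "halt":
            f0 = prof.stride_freq_hz * horse.stride_scale
            amp = (
                prof.harmonic_amps
                * horse.amp_scale
                * location.coupling_gain
                * bout["jitter"]
            )
            phases = bout["phases"]
            for axis in range(3):
                for h in range(amp.shape[1]):
                    a[sl, axis] += amp[axis, h] * np.sin(
                        2 * np.pi * f0 * (h + 1) * tb + phases[axis, h]
                    )
        noise_sd = prof.noise_sd + location.rider_noise_sd
        a[sl] += noise_rng.normal(0.0, noise_sd, size=(len(tb), 3))

    stream = AccelStream(t=t, a=a, rate_hz=config.sample_rate_hz)
    labels = LabelTrack(intervals)
    return SessionRecord(
        horse_id=horse.horse_id,
        rider_id=rider_id,
        location=location.location,
        stream=stream,
        labels=labels,
        session_id=f"{horse.horse_id}_{location.location}",
    )


def simulate_cohort(
    config: CohortConfig,
    profiles: dict[str, GaitProfile] | None = None,
    transfers: dict[str, LocationTransfer] | None = None,
    gait_mix: dict[str, float] | None = None,
    aberrant_horse: bool = False,
    halt_free_horse: bool = False,
) -> list[SessionRecord]:
    """Simulate ``n_horses`` horses, each recorded at all four locations.

    Per-horse stride and amplitude scales are drawn reproducibly from the
    cohort seed.  ``aberrant_horse=True`` gives the first horse a stride
    scale of 1.5 (an outlier locomotion pattern, as one horse in the
    reference cohort dominates and degrades its own held-out fold);
    ``halt_free_horse=True`` removes halt from the last horse's mix
    (emulating a horse that never halted).
    """
    if config.n_horses < 2:
        raise ValueError("need at least 2 horses (subject-exclusive CV needs >= 2)")
    profiles = profiles or default_gait_profiles()
    transfers = transfers or default_location_transfers()
    mix = dict(gait_mix or DEFAULT_GAIT_MIX)

    rng = np.random.default_rng(_derived_seed(config.seed, "cohort"))
    horses = []
    for i in range(config.n_horses):
        horse_mix = dict(mix)
        stride = float(rng.uniform(0.9, 1.1))
        amp = float(rng.uniform(0.85, 1.15))
        if aberrant_horse and i == 0:
            stride = 1.5
        if halt_free_horse and i == config.n_horses - 1 and "halt" in horse_mix:
            halt_p = horse_mix.pop("halt")
            horse_mix["walk"] = horse_mix.get("walk", 0.0) + halt_p
        horses.append(
            HorseSpec(
                horse_id=f"horse{i:02d}",
                stride_scale=stride,
                amp_scale=amp,
                gait_mix=horse_mix,
            )
        )

    sessions = []
    for i, horse in enumerate(horses):
        rider = f"rider{i % 5:02d}"
        for loc in LOCATIONS:
            sessions.append(
                simulate_session(horse, transfers[loc], profiles, config, rider)
            )
    return sessions


def write_cohort(sessions: list[SessionRecord], outdir) -> Path:
    """Write session fixtures (accel CSV + label TSV) and a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in sessions:
        accel = outdir / f"{s.session_id}_accel.csv"
        labs = outdir / f"{s.session_id}_labels.tsv"
        write_accel_csv(s.stream, accel)
        write_labels(s.labels, labs)
        entries.append(
            {
                "horse_id": s.horse_id,
                "rider_id": s.rider_id,
                "location": s.location,
                "session_id": s.session_id,
                "accel_csv": accel.name,
                "labels": labs.name,
            }
        )
    manifest = outdir / "manifest.yaml"
    write_manifest(entries, manifest)
    return manifest
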