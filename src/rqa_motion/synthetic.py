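"""Synthetic multi-sensor sessions with labeled stereotypy bouts.

The generator emulates the recording design the pipeline targets: three
body-worn 3-axis accelerometers (left wrist, right wrist, torso), each
session carrying labeled oscillatory bouts of three stereotypical motor
movement classes over a background of non-stereotyped movement:

* ``rock`` — slow torso-dominant oscillation (default 0.4–1.5 Hz),
  mechanically coupled into the wrists at reduced amplitude;
* ``flap`` — fast wrist-dominant oscillation (default 2.5–5 Hz),
  coupled into the torso at reduced amplitude;
* ``flaprock`` — the superposition of one component from each band.

Bouts are placed by a seeded renewal process with overlap rejection.
Every sample receives white Gaussian sensor noise, a slow smooth drift,
and a constant 1-g gravity vector; optionally one random orthogonal
matrix per (session, sensor) rotates the gravity-bearing signal, which
the recurrence features must be — and are — invariant to.  Everything is
deterministic given the configuration seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal.windows import tukey
from scipy.stats import ortho_group

from .io_streams import (
    SENSOR_POSITIONS,
    AccelerometerStream,
    AnnotationTrack,
    Session,
    ValidationError,
)

_GRAVITY_DIRECTION = np.array([0.0, 0.0, 1.0])
_BOUT_MARGIN_S = 0.5  # minimum gap between consecutive bouts
_PLACEMENT_ATTEMPTS = 200


@dataclass(frozen=True)
class BoutParams:
    """Oscillation parameters of one movement class.

    ``wrist_gain`` / ``torso_gain`` scale the bout amplitude on the two
    sensor groups; the smaller of the two models the mechanical coupling
    through the body (arm motion leaking into the torso and vice versa).
    ``harmonic_jitter`` is the relative amplitude of a second-harmonic
    component that keeps bouts from being pure sinusoids.
    """

    rate_per_min: float
    duration_range_s: tuple
    freq_range_hz: tuple
    amplitude_range_g: tuple
    wrist_gain: float
    torso_gain: float
    harmonic_jitter: float = 0.25


ROCK_DEFAULT = BoutParams(
    rate_per_min=1.0, duration_range_s=(3.0, 12.0),
    freq_range_hz=(0.4, 1.5), amplitude_range_g=(0.3, 0.8),
    wrist_gain=0.3, torso_gain=1.0,
)
FLAP_DEFAULT = BoutParams(
    rate_per_min=1.0, duration_range_s=(2.0, 8.0),
    freq_range_hz=(2.5, 5.0), amplitude_range_g=(0.3, 1.0),
    wrist_gain=1.0, torso_gain=0.3,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings.

    Defaults describe a desk-scale cohort: 6 participants, 2 sessions
    each, 120 s per session at 60 Hz, roughly a quarter of the time
    covered by SMM bouts, 0.05 g sensor noise, 1 g gravity, and a random
    sensor orientation per (session, sensor).
    """

    n_participants: int = 6
    sessions_per_participant: int = 2
    session_length_s: float = 120.0
    sampling_rate_hz: float = 60.0
    rock: BoutParams = ROCK_DEFAULT
    flap: BoutParams = FLAP_DEFAULT
    flaprock_rate_per_min: float = 0.4
    flaprock_duration_range_s: tuple = (3.0, 10.0)
    noise_sd_g: float = 0.05
    drift_sd_g: float = 0.05
    gravity_g: float = 1.0
    random_orientation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flap.freq_range_hz[0] <= self.rock.freq_range_hz[1]:
            raise ValidationError(
                "flap frequency band must lie strictly above the rock band"
            )
        rates = (self.rock.rate_per_min, self.flap.rate_per_min,
                 self.flaprock_rate_per_min)
        if any(r < 0 for r in rates):
            raise ValidationError("bout rates must be >= 0")
        if self.session_length_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValidationError("session length and rate must be positive")


def torso_only(config: SyntheticConfig) -> SyntheticConfig:
    """Variant whose class signal reaches only the torso channel.

    Wrist gains are zeroed for every class, so wrist streams carry
    nothing but noise, drift and (rotated) gravity — useful for testing
    that sensor ablation and feature importance find the informative
    position.
    """
    return replace(config,
                   rock=replace(config.rock, wrist_gain=0.0),
                   flap=replace(config.flap, wrist_gain=0.0))


def _seed_sequence(seed: int, *parts) -> np.random.SeedSequence:
    tag = zlib.crc32("|".join(str(p) for p in parts).encode())
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_orthogonal(rng: np.random.Generator) -> np.ndarray:
    """A Haar-random 3x3 orthogonal matrix (determinant +1 or -1)."""
    return ortho_group.rvs(3, random_state=rng)


def apply_rotation_and_gravity(stream: AccelerometerStream,
                               Q: np.ndarray,
                               g: np.ndarray) -> AccelerometerStream:
    """Map every sample a -> Q(a + g) for orthogonal Q and constant g.

    This is exactly the transformation a re-mounted sensor applies to
    the true motion, and the one the recurrence features are invariant
    to; pairwise distances between samples are preserved.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (3, 3) or not np.allclose(Q.T @ Q, np.eye(3), atol=1e-10):
        raise ValidationError("Q must be orthogonal (Q^T Q = I to 1e-10)")
    g = np.broadcast_to(np.asarray(g, dtype=float), (3,))
    return AccelerometerStream(
        sensor_position=stream.sensor_position,
        sampling_rate_hz=stream.sampling_rate_hz,
        t=stream.t.copy(),
        xyz=(stream.xyz + g) @ Q.T,
    )


def _place_bouts(rng: np.random.Generator, length_s: float,
                 specs) -> list:
    """Seeded renewal placement with overlap rejection.

    ``specs`` is a sequence of (label, rate_per_min, duration_range);
    bout counts are Poisson in the configured rate, starts uniform, and
    candidates are rejected until they clear existing bouts by a margin.
    """
    placed = []
    for label, rate, (dmin, dmax) in specs:
        n_bouts = int(rng.poisson(rate * length_s / 60.0))
        for _ in range(n_bouts):
            for _attempt in range(_PLACEMENT_ATTEMPTS):
                dur = rng.uniform(dmin, dmax)
                if dur >= length_s:
                    continue
                start = rng.uniform(0.0, length_s - dur)
                end = start + dur
                if all(start >= e + _BOUT_MARGIN_S
                       or end <= s - _BOUT_MARGIN_S
                       for s, e, _ in placed):
                    placed.append((start, end, label))
                    break
            else:
                raise ValueError(
                    "bout rates too high to place bouts without overlap; "
                    "lower the per-class rates or lengthen the session"
                )
    return sorted(placed)


def _add_bout(signals: dict, t: np.ndarray, sl: slice,
              params: BoutParams, rng: np.random.Generator) -> None:
    freq = rng.uniform(*params.freq_range_hz)
    amp = rng.uniform(*params.amplitude_range_g)
    envelope = tukey(sl.stop - sl.start, alpha=0.2)
    tt = t[sl]
    for sensor in SENSOR_POSITIONS:
        gain = params.torso_gain if sensor == "torso" else params.wrist_gain
        if gain == 0.0:
            continue
        axis1 = _random_unit(rng)
        axis2 = _random_unit(rng)
        phase1 = rng.uniform(0.0, 2.0 * np.pi)
        phase2 = rng.uniform(0.0, 2.0 * np.pi)
        wave = (
            np.sin(2.0 * np.pi * freq * tt + phase1)[:, None] * axis1
            + params.harmonic_jitter
            * np.sin(4.0 * np.pi * freq * tt + phase2)[:, None] * axis2
        )
        signals[sensor][sl] += gain * amp * envelope[:, None] * wave


def generate_session(config: SyntheticConfig, participant_id: str,
                     session_id: str) -> Session:
    """One deterministic session: 3 streams + exact bout annotations."""
    rng = np.random.default_rng(
        _seed_sequence(config.seed, "session", participant_id, session_id)
    )
    rate = config.sampling_rate_hz
    n = int(round(config.session_length_s * rate))
    t = np.arange(n) / rate

    intervals = _place_bouts(rng, config.session_length_s, [
        ("rock", config.rock.rate_per_min, config.rock.duration_range_s),
        ("flap", config.flap.rate_per_min, config.flap.duration_range_s),
        ("flaprock", config.flaprock_rate_per_min,
         config.flaprock_duration_range_s),
    ])

    signals = {s: np.zeros((n, 3)) for s in SENSOR_POSITIONS}
    for start, end, label in intervals:
        sl = slice(int(round(start * rate)), int(round(end * rate)))
        if label in ("rock", "flaprock"):
            _add_bout(signals, t, sl, config.rock, rng)
        if label in ("flap", "flaprock"):
            _add_bout(signals, t, sl, config.flap, rng)

    gravity = config.gravity_g * _GRAVITY_DIRECTION
    streams = {}
    for sensor in SENSOR_POSITIONS:
        sig = signals[sensor] + rng.normal(0.0, config.noise_sd_g, (n, 3))
        drift = gaussian_filter1d(rng.normal(size=(n, 3)),
                                  sigma=2.0 * rate, axis=0, mode="reflect")
        sd = drift.std(axis=0, keepdims=True)
        drift = drift / np.where(sd > 0, sd, 1.0) * config.drift_sd_g
        sig = sig + drift + gravity
        if config.random_orientation:
            Q = random_orthogonal(rng)
            sig = sig @ Q.T
        streams[sensor] = AccelerometerStream(
            sensor_position=sensor, sampling_rate_hz=rate, t=t, xyz=sig,
        )

    return Session(
        participant_id=participant_id,
        session_id=session_id,
        streams=streams,
        annotations=AnnotationTrack(list(intervals)),
    )


def _perturbed(params: BoutParams, freq_mult: float,
               amp_mult: float) -> BoutParams:
    return replace(
        params,
        freq_range_hz=(params.freq_range_hz[0] * freq_mult,
                       params.freq_range_hz[1] * freq_mult),
        amplitude_range_g=(params.amplitude_range_g[0] * amp_mult,
                           params.amplitude_range_g[1] * amp_mult),
    )


def generate_cohort(config: SyntheticConfig) -> list:
    """Sessions for every participant, with per-participant variation.

    Each participant gets mild seeded multiplicative offsets to bout
    frequencies and amplitudes (within ±10 % / ±20 %), so participants
    differ while sharing the class structure — the situation a
    person-independent classifier must cope with.
    """
    sessions = []
    for i in range(config.n_participants):
        pid = f"p{i + 1}"
        prng = np.random.default_rng(
            _seed_sequence(config.seed, "participant", pid)
        )
        freq_mult = prng.uniform(0.9, 1.1)
        amp_mult = prng.uniform(0.8, 1.2)
        pconf = replace(
            config,
            rock=_perturbed(config.rock, freq_mult, amp_mult),
            flap=_perturbed(config.flap, freq_mult, amp_mult),
        )
        for j in range(config.sessions_per_participant):
            sessions.append(generate_session(pconf, pid, f"s{j + 1}"))
    return sessions
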