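"""Seeded synthetic canine-motion generator.

Emits labelled 100 Hz six-channel inertial streams with the statistical
structure the pipeline assumes, without claiming biomechanical fidelity:

* static postures (lay, sit, stand) are gravity-dominated — the
  accelerometer reads the 1 g gravity vector rotated by a posture-specific
  device attitude (pitch tips gravity between a_x and a_z, roll brings in
  a_y), the gyroscope reads only noise, so the three postures differ by
  attitude alone and are invisible to angular-velocity channels;
* gaits (walk, trot, canter, gallop) superimpose a harmonic series of a
  stride frequency on every channel, with frequency and amplitude
  increasing with activity level; canter and gallop deliberately overlap
  (wide per-segment lognormal jitter on both) so they are genuinely hard to
  tell apart;
* every dog carries persistent multiplicative frequency/amplitude factors
  and an attitude offset (lognormal/normal, width sigma_ind), and the two
  breeds shift the template means in opposite directions, so within-dog
  consistency exceeds between-dog consistency by construction;
* behaviours are separated by short unlabelled transition gaps, emulating
  interrupted annotation.

Everything is deterministic under a seed: a study spawns one child seed per
(dog, session) from the master seed, so two sessions of a dog share the
profile but not the noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .sensor_io import (
    BehaviorCategory,
    CATEGORIES,
    InertialRecording,
    LabelInterval,
    LabelTrack,
    ValidationError,
)

__all__ = [
    "BehaviorTemplate",
    "default_templates",
    "separable_templates",
    "BreedOffset",
    "BREED_OFFSETS",
    "DogProfile",
    "SessionScript",
    "default_script",
    "short_script",
    "Measurement",
    "make_population",
    "generate_session",
    "generate_study",
    "simulate_second_coder",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class BehaviorTemplate:
    """Signal-generation parameters of one behaviour category.

    Static templates use the attitude angles (degrees); gait templates use
    stride_freq (Hz) with per-axis base amplitudes (g for acceleration,
    deg/s for angular velocity) decaying as 1/h over *harmonics* partials.
    Per-segment lognormal jitter (sd in log space) on frequency and
    amplitude creates realistic trial-to-trial variation and the deliberate
    canter/gallop overlap.  Optional panting adds a small oscillation to
    static postures.
    """

    category: BehaviorCategory
    kind: str  # "static" | "gait"
    attitude_pitch: float = 0.0
    attitude_roll: float = 0.0
    stride_freq: float = 0.0
    freq_jitter_sd: float = 0.0
    amp_jitter_sd: float = 0.0
    acc_amp: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_amp: tuple[float, float, float] = (0.0, 0.0, 0.0)
    harmonics: int = 3
    noise_acc_sd: float = 0.02
    noise_gyro_sd: float = 2.0
    panting: tuple[float, float, float] | None = None  # (freq, acc amp, gyro amp)
    #: lock all harmonic phases to zero: the waveform (and the envelope of
    #: vector norms and dot products) becomes identical across sessions,
    #: which known-answer control populations rely on
    phase_lock: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("static", "gait"):
            raise ValidationError("template kind must be 'static' or 'gait'")
        if self.kind == "gait" and self.stride_freq <= 0:
            raise ValidationError("gait templates need stride_freq > 0")
        if self.kind == "static" and (any(self.acc_amp) or any(self.gyro_amp)):
            raise ValidationError("static templates must have zero stride amplitude")


def default_templates() -> dict[BehaviorCategory, BehaviorTemplate]:
    """Default per-category templates.

    Stride frequencies and amplitudes rise monotonically with activity
    level; the canter/gallop frequency gap (3.8 vs 4.2 Hz) is narrow
    relative to their jitter and the individual variation so their
    distributions overlap heavily, while the gaps between activity levels
    are wide enough to survive both.  The values are
    plausible-by-construction knobs, not claims about real dogs.
    """
    B = BehaviorCategory
    return {
        B.LAY: BehaviorTemplate(B.LAY, "static", attitude_pitch=0.0,
                                attitude_roll=10.0),
        B.SIT: BehaviorTemplate(B.SIT, "static", attitude_pitch=35.0),
        B.STAND: BehaviorTemplate(B.STAND, "static", attitude_pitch=5.0),
        B.WALK: BehaviorTemplate(
            B.WALK, "gait", stride_freq=1.5,
            freq_jitter_sd=0.04, amp_jitter_sd=0.05,
            acc_amp=(0.25, 0.15, 0.30), gyro_amp=(25.0, 20.0, 15.0),
            noise_acc_sd=0.05, noise_gyro_sd=5.0,
        ),
        B.TROT: BehaviorTemplate(
            B.TROT, "gait", stride_freq=3.0,
            freq_jitter_sd=0.04, amp_jitter_sd=0.05,
            acc_amp=(0.50, 0.25, 0.60), gyro_amp=(50.0, 40.0, 30.0),
            noise_acc_sd=0.05, noise_gyro_sd=5.0,
        ),
        B.CANTER: BehaviorTemplate(
            B.CANTER, "gait", stride_freq=3.8,
            freq_jitter_sd=0.09, amp_jitter_sd=0.15,
            acc_amp=(0.75, 0.40, 0.90), gyro_amp=(90.0, 70.0, 55.0),
            noise_acc_sd=0.06, noise_gyro_sd=6.0,
        ),
        B.GALLOP: BehaviorTemplate(
            B.GALLOP, "gait", stride_freq=4.2,
            freq_jitter_sd=0.09, amp_jitter_sd=0.15,
            acc_amp=(0.85, 0.45, 1.00), gyro_amp=(100.0, 78.0, 62.0),
            noise_acc_sd=0.06, noise_gyro_sd=6.0,
        ),
    }


def separable_templates() -> dict[BehaviorCategory, BehaviorTemplate]:
    """Noiseless, jitter-free templates with well-separated stride
    frequencies — a control population on which a correct classifier must
    be perfect.  Frequencies are integer Hz so they sit exactly on the
    one-second window's FFT bins: no spectral leakage, hence fully
    phase-invariant spectral features."""
    B = BehaviorCategory
    out = {}
    freqs = {B.WALK: 2.0, B.TROT: 4.0, B.CANTER: 6.0, B.GALLOP: 9.0}
    for cat, tpl in default_templates().items():
        tpl = replace(tpl, noise_acc_sd=0.0, noise_gyro_sd=0.0,
                      freq_jitter_sd=0.0, amp_jitter_sd=0.0, phase_lock=True)
        if tpl.kind == "gait":
            tpl = replace(tpl, stride_freq=freqs[cat], harmonics=1)
        if cat is B.GALLOP:  # amplitude scale too, not only frequency
            tpl = replace(tpl, acc_amp=(1.8, 1.0, 2.1),
                          gyro_amp=(220.0, 170.0, 140.0))
        out[cat] = tpl
    return out


@dataclass(frozen=True)
class BreedOffset:
    """Multiplicative/additive shifts applied to template means per breed."""

    freq_factor: float = 1.0
    amp_factor: float = 1.0
    pitch_offset: float = 0.0  # degrees


BREED_OFFSETS: dict[str, BreedOffset] = {
    "Malinois": BreedOffset(1.06, 1.10, 2.0),
    "Labrador": BreedOffset(0.94, 0.92, -2.0),
}


@dataclass(frozen=True)
class DogProfile:
    """Persistent per-individual deviations from the breed template."""

    dog_id: str
    breed: str
    freq_factor: float = 1.0
    amp_factor: float = 1.0
    attitude_jitter: float = 0.0  # degrees, added to every pitch

    def __post_init__(self) -> None:
        if self.freq_factor <= 0 or self.amp_factor <= 0:
            raise ValidationError("profile factors must be positive")


@dataclass(frozen=True)
class SessionScript:
    """Ordered (category, duration) items separated by unlabelled gaps."""

    items: tuple[tuple[BehaviorCategory, float], ...]
    gap: float = 2.0

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError("session script must contain items")
        if any(dur <= 0 for _, dur in self.items):
            raise ValidationError("script durations must be positive")


def default_script() -> SessionScript:
    """A ~10-minute guided session: one long block per behaviour followed by
    a shorter second round (annotation is interrupted by 2 s gaps)."""
    B = BehaviorCategory
    items = [
        (B.SIT, 45.0), (B.LAY, 45.0), (B.STAND, 45.0),
        (B.WALK, 60.0), (B.TROT, 60.0), (B.CANTER, 45.0), (B.GALLOP, 45.0),
        (B.WALK, 30.0), (B.TROT, 30.0), (B.STAND, 30.0),
        (B.CANTER, 30.0), (B.GALLOP, 30.0),
    ]
    return SessionScript(tuple(items))


def short_script(seconds_per_item: float = 12.0, gap: float = 2.0) -> SessionScript:
    """One item per category — a compact session for small experiments."""
    return SessionScript(
        tuple((cat, seconds_per_item) for cat in CATEGORIES), gap=gap
    )


@dataclass(frozen=True)
class Measurement:
    """One session of one dog: recording plus its aligned label track."""

    recording: InertialRecording
    track: LabelTrack


def make_population(
    n_per_breed: int = 12,
    sigma_ind: float = 0.15,
    seed: int = 0,
    breeds: Sequence[str] = ("Malinois", "Labrador"),
) -> list[DogProfile]:
    """Draw a deterministic population of dog profiles.

    Individual frequency/amplitude factors are lognormal with log-sd
    *sigma_ind*; the attitude offset is normal with sd ``30 * sigma_ind``
    degrees, so sigma_ind = 0 makes all same-breed dogs identical.
    """
    rng = np.random.default_rng(seed)
    profiles: list[DogProfile] = []
    for breed in breeds:
        prefix = breed[0].upper()
        for k in range(n_per_breed):
            profiles.append(
                DogProfile(
                    dog_id=f"{prefix}{k + 1:02d}",
                    breed=breed,
                    freq_factor=float(np.exp(rng.normal(0.0, sigma_ind))),
                    amp_factor=float(np.exp(rng.normal(0.0, sigma_ind))),
                    attitude_jitter=float(rng.normal(0.0, 30.0 * sigma_ind)),
                )
            )
    return profiles


def _gravity(pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Gravity vector (in g) in the body frame for a pitch/roll attitude."""
    p, r = pitch_deg * _DEG, roll_deg * _DEG
    return np.array([
        math.sin(p),
        -math.cos(p) * math.sin(r),
        -math.cos(p) * math.cos(r),
    ])


def _static_segment(n, t, tpl, pitch, rng):
    grav = _gravity(pitch, tpl.attitude_roll)
    acc = grav[None, :] + rng.normal(0.0, tpl.noise_acc_sd, size=(n, 3))
    gyro = rng.normal(0.0, tpl.noise_gyro_sd, size=(n, 3))
    if tpl.panting is not None:
        f, aa, ga = tpl.panting
        phase = rng.uniform(0, 2 * math.pi)
        osc = np.sin(2 * math.pi * f * t + phase)
        acc[:, 2] += aa * osc
        gyro[:, 1] += ga * osc
    return acc, gyro


def _gait_segment(n, t, tpl, profile, breed, pitch, rng):
    eff_freq = (tpl.stride_freq * breed.freq_factor * profile.freq_factor
                * float(np.exp(rng.normal(0.0, tpl.freq_jitter_sd))))
    eff_amp = (breed.amp_factor * profile.amp_factor
               * float(np.exp(rng.normal(0.0, tpl.amp_jitter_sd))))
    grav = _gravity(pitch, 0.0)
    acc = grav[None, :] + rng.normal(0.0, tpl.noise_acc_sd, size=(n, 3))
    gyro = rng.normal(0.0, tpl.noise_gyro_sd, size=(n, 3))
    for h in range(1, tpl.harmonics + 1):
        omega = 2 * math.pi * eff_freq * h
        for j in range(3):
            pa = 0.0 if tpl.phase_lock else rng.uniform(0, 2 * math.pi)
            pw = 0.0 if tpl.phase_lock else rng.uniform(0, 2 * math.pi)
            acc[:, j] += tpl.acc_amp[j] * eff_amp / h * np.sin(omega * t + pa)
            gyro[:, j] += tpl.gyro_amp[j] * eff_amp / h * np.sin(omega * t + pw)
    return acc, gyro


def generate_session(
    profile: DogProfile,
    script: SessionScript | None = None,
    sample_rate: float = 100.0,
    seed: int | np.random.SeedSequence = 0,
    templates: Mapping[BehaviorCategory, BehaviorTemplate] | None = None,
) -> Measurement:
    """Generate one labelled session for one dog.

    Labels exactly tile the behaviour segments; the leading/inter-item gaps
    carry messier, unlabelled stand-like motion.  Deterministic under the
    seed.
    """
    script = script or default_script()
    templates = dict(templates or default_templates())
    rng = np.random.default_rng(seed)
    breed = BREED_OFFSETS.get(profile.breed, BreedOffset())
    gap_n = int(round(script.gap * sample_rate))
    acc_parts, gyro_parts = [], []
    intervals: list[LabelInterval] = []
    cursor = 0  # in samples
    gap_tpl = BehaviorTemplate(
        BehaviorCategory.STAND, "static",
        attitude_pitch=templates[BehaviorCategory.STAND].attitude_pitch,
        noise_acc_sd=max(0.10, templates[BehaviorCategory.STAND].noise_acc_sd),
        noise_gyro_sd=max(10.0, templates[BehaviorCategory.STAND].noise_gyro_sd),
    )
    for cat, dur in script.items:
        tpl = templates[cat]
        # unlabelled transition gap before every item
        if gap_n:
            t = (cursor + np.arange(gap_n)) / sample_rate
            a, g = _static_segment(gap_n, t, gap_tpl,
                                   gap_tpl.attitude_pitch + breed.pitch_offset
                                   + profile.attitude_jitter, rng)
            acc_parts.append(a)
            gyro_parts.append(g)
            cursor += gap_n
        n = int(round(dur * sample_rate))
        t = (cursor + np.arange(n)) / sample_rate
        pitch = tpl.attitude_pitch + breed.pitch_offset + profile.attitude_jitter
        if tpl.kind == "static":
            a, g = _static_segment(n, t, tpl, pitch, rng)
        else:
            base_pitch = breed.pitch_offset + profile.attitude_jitter
            a, g = _gait_segment(n, t, tpl, profile, breed, base_pitch, rng)
        acc_parts.append(a)
        gyro_parts.append(g)
        intervals.append(
            LabelInterval(cursor / sample_rate, (cursor + n) / sample_rate, cat)
        )
        cursor += n
    acc = np.vstack(acc_parts)
    gyro = np.vstack(gyro_parts)
    t_all = np.arange(cursor) / sample_rate
    rec = InertialRecording(
        t=t_all, a_x=acc[:, 0], a_y=acc[:, 1], a_z=acc[:, 2],
        w_roll=gyro[:, 0], w_pitch=gyro[:, 1], w_yaw=gyro[:, 2],
        sample_rate=sample_rate,
        dog_id=profile.dog_id, breed=profile.breed,
    )
    return Measurement(rec, LabelTrack(tuple(intervals)))


def generate_study(
    population: Sequence[DogProfile],
    script: SessionScript | None = None,
    sessions_per_dog: int = 2,
    seed: int = 0,
    templates: Mapping[BehaviorCategory, BehaviorTemplate] | None = None,
    sample_rate: float = 100.0,
) -> list[Measurement]:
    """Generate the full study: *sessions_per_dog* sessions per profile.

    Sessions of the same dog share the profile but use independent child
    seeds, so within-dog feature consistency exceeds between-dog by
    construction.  Session indices start at 1.
    """
    measurements: list[Measurement] = []
    for d, profile in enumerate(population):
        for s in range(sessions_per_dog):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(d, s))
            m = generate_session(profile, script, sample_rate, child, templates)
            rec = replace(m.recording, session_index=s + 1)
            measurements.append(Measurement(rec, m.track))
    return measurements


def simulate_second_coder(
    track: LabelTrack,
    seed: int = 0,
    boundary_jitter_sd: float = 0.3,
    confusion: Mapping[BehaviorCategory, tuple[BehaviorCategory, float]] | None = None,
) -> LabelTrack:
    """Emulate an independent human coder re-annotating the same session.

    Interval boundaries are jittered (normal, sd in seconds, clamped so
    intervals stay valid and non-overlapping), and for categories with a
    confusable partner a uniformly drawn trailing fraction of the interval
    (up to the per-pair maximum) is relabelled to that partner — by default
    canter<->gallop most, stand<->lay a little, the pairs hardest to tell
    apart on video.  This yields high but imperfect agreement with the
    off-diagonal mass concentrated on those pairs.
    """
    B = BehaviorCategory
    if confusion is None:
        confusion = {
            B.CANTER: (B.GALLOP, 0.25),
            B.GALLOP: (B.CANTER, 0.25),
            B.STAND: (B.LAY, 0.12),
            B.LAY: (B.STAND, 0.12),
        }
    rng = np.random.default_rng(seed)
    new: list[LabelInterval] = []
    prev_end = -math.inf
    for iv in track.intervals:
        start = round(iv.start + rng.normal(0.0, boundary_jitter_sd), 3)
        end = round(iv.end + rng.normal(0.0, boundary_jitter_sd), 3)
        start = max(start, prev_end, 0.0)
        if end <= start + 0.2:  # coder dropped an unusably short cue
            continue
        cat = iv.category
        split = None
        if cat in confusion:
            alt, max_frac = confusion[cat]
            tail = rng.uniform(0.0, max_frac) * (end - start)
            if tail > 0.25:
                split = (round(end - tail, 3), alt)
        if split is not None and split[0] > start + 0.2:
            new.append(LabelInterval(start, split[0], cat))
            new.append(LabelInterval(split[0], end, split[1]))
        else:
            new.append(LabelInterval(start, end, cat))
        prev_end = new[-1].end
    return LabelTrack(tuple(new), coder_id="secondary")
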