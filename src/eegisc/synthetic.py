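"""Synthetic multi-subject EEG cohorts and keypoint tracks with known truth.

The generator emulates a two-group naturalistic-viewing study: every subject
receives the *same* small set of latent source signals (the stimulus-evoked
activity), mixed into channel space through fixed scalp topographies, scaled
by a per-subject response gain that differs between groups, plus independent
channel noise.  Patients are modelled with a reduced shared-response gain and,
optionally, a subject-unique source.  Because the latent structure is known,
downstream component recovery and group-contrast detection can be tested
quantitatively.

A companion generator produces pose-keypoint tracks (BODY_25 layout) with
scripted limb-movement epochs, sub-threshold camera jitter and single-frame
scene-cut jumps, together with per-frame ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (
    HEALTHY,
    MONTAGE_10_20_19,
    PATIENT,
    KeypointTrack,
    MultiSubjectEEG,
)

ARM = "arm"
LEG = "leg"
BOTH = "both"
NEITHER = "neither"

# BODY_25 keypoint indices for the limbs of interest.
BODY25_ARM_KEYPOINTS = (3, 4, 6, 7)       # RElbow, RWrist, LElbow, LWrist
BODY25_LEG_KEYPOINTS = (10, 11, 13, 14)   # RKnee, RAnkle, LKnee, LAnkle
BODY25_N_KEYPOINTS = 25


class ConfigurationError(ValueError):
    """Raised when a cohort or artifact specification is inconsistent."""


@dataclass
class ArtifactSpec:
    """Rates of injected artifacts, all per subject per video.

    ``ocular_events`` counts low-frequency frontal transients (blink-like,
    loaded asymmetrically on the frontal electrodes); ``bad_channels`` counts
    channels rescaled to pathological power; ``spikes`` counts isolated
    high-amplitude outlier samples.
    """

    ocular_events: int = 0
    bad_channels: int = 0
    spikes: int = 0
    ocular_amplitude: float = 20.0   # multiples of the channel SD (blink-scale)
    ocular_duration: float = 0.5     # seconds
    bad_channel_factor: float = 10.0  # amplitude scale for bad channels
    spike_amplitude: float = 50.0    # multiples of the channel SD


@dataclass
class CohortSpec:
    """Design of a synthetic two-group cohort.

    Defaults mirror a study with 19 common electrodes sampled at 500 Hz and
    four six-minute video blocks; healthy children carry a stronger shared
    stimulus response than patients (``gain_healthy > gain_patient``).
    """

    n_healthy: int = 23
    n_patient: int = 23
    n_channels: int = 19
    fs: float = 500.0
    duration: float = 360.0
    n_videos: int = 4
    n_sources: int = 3
    mixing: np.ndarray | None = None
    gain_healthy: float = 1.0
    gain_patient: float = 0.4
    patient_unique_gain: float = 0.0
    noise_sd: float = 1.0
    alpha_fraction: float = 0.2
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    source_band: tuple[float, float] = (1.0, 45.0)
    channel_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 1 or self.n_channels < self.n_sources:
            raise ConfigurationError(
                f"need n_channels >= n_sources >= 1; got "
                f"{self.n_channels} channels, {self.n_sources} sources"
            )
        if self.fs <= 0 or self.duration <= 0 or self.n_videos < 1:
            raise ConfigurationError("fs, duration and n_videos must be positive")
        if min(self.gain_healthy, self.gain_patient) < 0 or self.noise_sd < 0:
            raise ConfigurationError("gains and noise_sd must be non-negative")
        if not 0.0 <= self.alpha_fraction <= 1.0:
            raise ConfigurationError("alpha_fraction must lie in [0, 1]")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=np.float64)
            if self.mixing.shape != (self.n_channels, self.n_sources):
                raise ConfigurationError(
                    f"mixing must be {self.n_channels} x {self.n_sources}; "
                    f"got {self.mixing.shape}"
                )
        if self.channel_labels is not None and len(self.channel_labels) != self.n_channels:
            raise ConfigurationError("channel_labels length must equal n_channels")

    @property
    def n_subjects(self) -> int:
        return self.n_healthy + self.n_patient

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def resolve_channel_labels(self) -> list[str]:
        if self.channel_labels is not None:
            return list(self.channel_labels)
        if self.n_channels == len(MONTAGE_10_20_19):
            return list(MONTAGE_10_20_19)
        return [f"CH{i + 1}" for i in range(self.n_channels)]


@dataclass
class CohortGroundTruth:
    """Latent structure behind a generated cohort."""

    source_timecourses: list[np.ndarray]   # per video: (K_true, T)
    true_mixing: np.ndarray                # (D, K_true)
    subject_gains: np.ndarray              # (N,)
    groups: list[str]


@dataclass
class MovementGroundTruth:
    """Per-frame limb-state labels for a generated keypoint track."""

    labels: np.ndarray        # (n_frames,) of {arm, leg, both, neither}
    scene_cuts: np.ndarray    # frame indices of injected cuts


@dataclass
class ArtifactLog:
    """Positions of injected artifacts (indices into one video block)."""

    ocular: list[tuple[int, int]] = field(default_factory=list)   # (subject, sample)
    ocular_waveform: np.ndarray | None = None
    bad_channels: list[tuple[int, int]] = field(default_factory=list)  # (subject, channel)
    spikes: list[tuple[int, int, int]] = field(default_factory=list)   # (subject, channel, sample)


def _bandlimited_noise(rng: np.random.Generator, band: tuple[float, float],
                       fs: float, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    x = rng.standard_normal(shape)
    nyq = fs / 2.0
    lo = max(band[0], 1e-3) / nyq
    hi = min(band[1], nyq * 0.99) / nyq
    sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
    y = sps.sosfiltfilt(sos, x, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def generate_cohort(spec: CohortSpec) -> tuple[list[MultiSubjectEEG], CohortGroundTruth]:
    """Generate one aligned multi-subject tensor per video block.

    Each subject's channel data is ``gain_i * mixing @ sources + noise``.
    Sources are shared by *all* subjects of both groups (they encode the
    stimulus); the per-subject gain is the group gain.  The channel noise is
    white Gaussian with an ``alpha_fraction`` of its power moved into the
    8-12 Hz band, so the spectral stage has a realistic alpha covariate.

    Returns the list of per-video :class:`MultiSubjectEEG` blocks and the
    generating ground truth.  A fixed ``spec.seed`` makes the output
    bit-identical across calls.
    """
    rng = np.random.default_rng(spec.seed)
    d, k = spec.n_channels, spec.n_sources
    t = spec.n_samples
    n = spec.n_subjects

    if spec.mixing is not None:
        mixing = spec.mixing
    else:
        mixing = rng.standard_normal((d, k))
        mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)

    groups = [HEALTHY] * spec.n_healthy + [PATIENT] * spec.n_patient
    subject_ids = [f"H{i + 1}" for i in range(spec.n_healthy)] + [
        f"P{i + 1}" for i in range(spec.n_patient)
    ]
    gains = np.where(
        np.array(groups) == HEALTHY, spec.gain_healthy, spec.gain_patient
    ).astype(np.float64)
    labels = spec.resolve_channel_labels()

    videos: list[MultiSubjectEEG] = []
    sources_per_video: list[np.ndarray] = []
    for v in range(spec.n_videos):
        sources = _bandlimited_noise(rng, spec.source_band, spec.fs, (k, t))
        sources_per_video.append(sources)
        shared = mixing @ sources                     # (D, T)
        data = np.empty((n, d, t))
        for i in range(n):
            x = gains[i] * shared
            if spec.noise_sd > 0:
                # noise shares the source band so the band-pass stage is
                # neutral on artifact-free cohorts
                white = _bandlimited_noise(rng, spec.source_band, spec.fs, (d, t))
                if spec.alpha_fraction > 0:
                    alpha = _bandlimited_noise(rng, (8.0, 12.0), spec.fs, (d, t))
                    noise = (
                        np.sqrt(1.0 - spec.alpha_fraction) * white
                        + np.sqrt(spec.alpha_fraction) * alpha
                    )
                else:
                    noise = white
                x = x + spec.noise_sd * noise
            if groups[i] == PATIENT and spec.patient_unique_gain > 0:
                unique = _bandlimited_noise(rng, spec.source_band, spec.fs, (1, t))
                direction = rng.standard_normal(d)
                direction /= np.linalg.norm(direction)
                x = x + spec.patient_unique_gain * np.outer(direction, unique[0])
            data[i] = x
        videos.append(
            MultiSubjectEEG(
                data=data,
                fs=spec.fs,
                channel_labels=labels,
                subject_ids=subject_ids,
                groups=list(groups),
                video_id=v + 1,
            )
        )

    truth = CohortGroundTruth(
        source_timecourses=sources_per_video,
        true_mixing=mixing,
        subject_gains=gains,
        groups=list(groups),
    )
    return videos, truth


def inject_artifacts(
    eeg: MultiSubjectEEG, spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[MultiSubjectEEG, ArtifactLog]:
    """Insert ocular transients, bad channels and outlier spikes.

    The requested counts (``spec.artifact_spec``) are inserted per subject at
    random positions and returned in an :class:`ArtifactLog` so recovery can
    be verified downstream.  With all rates zero the input is returned
    unchanged (same object).
    """
    art = spec.artifact_spec
    if art.ocular_events == 0 and art.bad_channels == 0 and art.spikes == 0:
        return eeg, ArtifactLog()
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)

    out = eeg.copy()
    log = ArtifactLog()
    t = out.n_samples
    fs = out.fs
    oc_len = int(round(art.ocular_duration * fs))
    if art.ocular_events * oc_len > t:
        raise ConfigurationError("ocular events do not fit in the recording")
    if art.bad_channels >= out.n_channels:
        raise ConfigurationError("cannot mark every channel bad")

    # Blink-like raised-cosine bump, asymmetric across the frontal pair so a
    # frontal-difference proxy sees it.
    window = 0.5 * (1 - np.cos(2 * np.pi * np.arange(oc_len) / max(oc_len - 1, 1)))
    log.ocular_waveform = window
    frontal_gain = {"Fp1": 1.0, "Fp2": 0.55, "F3": 0.3, "F4": 0.25, "F7": 0.2, "F8": 0.15}
    gains = np.zeros(out.n_channels)
    named = False
    for ci, lab in enumerate(out.channel_labels):
        if lab in frontal_gain:
            gains[ci] = frontal_gain[lab]
            named = True
    if not named:           # unnamed montage: load the first two channels
        gains[0] = 1.0
        if out.n_channels > 1:
            gains[1] = 0.55

    for i in range(out.n_subjects):
        ch_sd = out.data[i].std(axis=1)
        scale = float(np.median(ch_sd)) or 1.0
        for _ in range(art.ocular_events):
            s = int(rng.integers(0, t - oc_len))
            out.data[i, :, s : s + oc_len] += (
                art.ocular_amplitude * scale * np.outer(gains, window)
            )
            log.ocular.append((i, s))
        if art.bad_channels:
            chans = rng.choice(out.n_channels, size=art.bad_channels, replace=False)
            for c in chans:
                out.data[i, c] *= art.bad_channel_factor
                log.bad_channels.append((i, int(c)))
        for _ in range(art.spikes):
            c = int(rng.integers(0, out.n_channels))
            s = int(rng.integers(0, t))
            out.data[i, c, s] += art.spike_amplitude * max(ch_sd[c], scale)
            log.spikes.append((i, c, s))
    return out, log


# ---------------------------------------------------------------------------
# Keypoint tracks


@dataclass
class MovementEpoch:
    """A scripted limb movement spanning frames ``start..end`` inclusive."""

    start: int
    end: int
    limb: str   # "arm" or "leg"

    def __post_init__(self) -> None:
        if self.limb not in (ARM, LEG):
            raise ConfigurationError(f"limb must be 'arm' or 'leg', got {self.limb!r}")
        if self.end < self.start:
            raise ConfigurationError("epoch end before start")


def _base_skeleton(frame_size: tuple[int, int]) -> np.ndarray:
    """A plausible static BODY_25 pose centred in the frame."""
    w, h = frame_size
    cx, cy = w / 2.0, h / 2.0
    pose = np.tile([cx, cy], (BODY25_N_KEYPOINTS, 1)).astype(float)
    offsets = {
        0: (0, -180), 1: (0, -120),                       # nose, neck
        2: (-60, -120), 3: (-90, -40), 4: (-100, 40),     # right arm
        5: (60, -120), 6: (90, -40), 7: (100, 40),        # left arm
        8: (0, 20), 9: (-35, 20), 12: (35, 20),           # hips
        10: (-40, 120), 11: (-45, 210),                   # right leg
        13: (40, 120), 14: (45, 210),                     # left leg
    }
    for idx, (dx, dy) in offsets.items():
        pose[idx] += (dx, dy)
    return pose


def generate_keypoint_tracks(
    frames: int,
    fps: float,
    script: list[MovementEpoch],
    *,
    lower_threshold: float = 2.0,
    upper_threshold: float = 30.0,
    scene_cuts: list[int] | None = None,
    frame_size: tuple[int, int] = (1280, 720),
    n_people: int = 1,
    seed: int = 0,
) -> tuple[KeypointTrack, MovementGroundTruth]:
    """Generate a keypoint track with scripted movement and known labels.

    Within a scripted epoch the moving limb's keypoints step by a per-frame
    displacement drawn strictly between the two detection thresholds; outside
    epochs every keypoint jitters below ``lower_threshold`` (camera shake);
    ``scene_cuts`` are single-frame jumps above ``upper_threshold`` on all
    keypoints.  Ground-truth labels are per frame; frame ``f`` is labelled by
    the transition from ``f-1`` (frame 0 is «neither»).
    """
    if frames < 2:
        raise ConfigurationError("need at least two frames")
    if not 0 <= lower_threshold < upper_threshold:
        raise ConfigurationError("need 0 <= lower < upper threshold")
    for ep in script:
        if ep.start < 1 or ep.end >= frames:
            raise ConfigurationError(
                f"epoch {ep.start}..{ep.end} outside frame range 1..{frames - 1}"
            )
    cuts = sorted(set(scene_cuts or []))
    for c in cuts:
        if not 1 <= c < frames:
            raise ConfigurationError(f"scene cut at frame {c} outside 1..{frames - 1}")

    rng = np.random.default_rng(seed)
    w, h = frame_size
    people = np.zeros((frames, n_people, BODY25_N_KEYPOINTS, 3))
    limb_sets = {ARM: np.array(BODY25_ARM_KEYPOINTS), LEG: np.array(BODY25_LEG_KEYPOINTS)}

    arm_moving = np.zeros(frames, dtype=bool)
    leg_moving = np.zeros(frames, dtype=bool)
    for ep in script:
        flag = arm_moving if ep.limb == ARM else leg_moving
        flag[ep.start : ep.end + 1] = True
    # scene-cut frames cannot be movement frames: the jump dominates
    for c in cuts:
        arm_moving[c] = False
        leg_moving[c] = False

    # movement only injected for person 0; extras are static jitterers
    pos = np.empty((n_people, BODY25_N_KEYPOINTS, 2))
    for p in range(n_people):
        base = _base_skeleton(frame_size)
        base += rng.uniform(-80, 80, size=2)  # place people apart
        pos[p] = np.clip(base, [10, 10], [w - 10, h - 10])
    people[0, :, :, :2] = pos
    people[0, :, :, 2] = 1.0

    margin = 0.15 * (upper_threshold - lower_threshold)

    def _step(magnitude: float, cur: np.ndarray) -> np.ndarray:
        theta = rng.uniform(0, 2 * np.pi)
        step = magnitude * np.array([np.cos(theta), np.sin(theta)])
        nxt = cur + step
        # bounce off frame bounds without changing the step magnitude
        for ax, hi in ((0, w - 5), (1, h - 5)):
            if nxt[ax] < 5 or nxt[ax] > hi:
                step[ax] = -step[ax]
                nxt = cur + step
        return nxt

    for f in range(1, frames):
        if f in cuts:
            # single-frame jump of the whole scene above the upper threshold
            jump_mag = rng.uniform(1.5, 2.5) * upper_threshold
            centre = np.array([w / 2.0, h / 2.0])
            for p in range(n_people):
                direction = centre - pos[p].mean(axis=0)
                norm = np.linalg.norm(direction)
                direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0])
                pos[p] = pos[p] + jump_mag * direction
                pos[p] = np.clip(pos[p], [5, 5], [w - 5, h - 5])
        else:
            for p in range(n_people):
                for kp in range(BODY25_N_KEYPOINTS):
                    moving = p == 0 and (
                        (arm_moving[f] and kp in limb_sets[ARM])
                        or (leg_moving[f] and kp in limb_sets[LEG])
                    )
                    if moving:
                        mag = rng.uniform(
                            lower_threshold + margin, upper_threshold - margin
                        )
                    else:
                        mag = rng.uniform(0, 0.8 * lower_threshold)
                    pos[p, kp] = _step(mag, pos[p, kp])
        people[f, :, :, :2] = pos
        people[f, :, :, 2] = 1.0

    labels = np.full(frames, NEITHER, dtype=object)
    labels[arm_moving & leg_moving] = BOTH
    labels[arm_moving & ~leg_moving] = ARM
    labels[~arm_moving & leg_moving] = LEG
    labels[0] = NEITHER

    track = KeypointTrack(people=people, fps=fps, frame_size=frame_size)
    truth = MovementGroundTruth(labels=labels, scene_cuts=np.array(cuts, dtype=int))
    return track, truth


def load_scores_fixture() -> pd.DataFrame:
    """Load the packaged patient demographics/clinical-scores table.

    23 patients with columns Code, Age, Sex, Diagnosis, Paresis, CNS Damage,
    DMD, GMD, Attention, Auditory Memory, Visual Memory, Story.
    """
    ref = resources.files("eegisc").joinpath("data/patient_scores.tsv")
    with ref.open("r") as fh:
        table = pd.read_csv(fh, sep="\t")
    expected = [
        "Code", "Age", "Sex", "Diagnosis", "Paresis", "CNS Damage", "DMD",
        "GMD", "Attention", "Auditory Memory", "Visual Memory", "Story",
    ]
    if list(table.columns) != expected or len(table) != 23:
        raise RuntimeError("patient scores fixture is corrupt")
    return table
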