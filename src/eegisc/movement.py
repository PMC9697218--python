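"""Limb-movement annotation of video stimuli from pose keypoints.

Per frame transition, the displacement of each limb class (arm, leg) is the
maximum Euclidean displacement over its configured keypoints and over all
detected people.  A transition counts as movement when that displacement lies
strictly *between* two thresholds: displacements at or below the lower one
are camera jitter, displacements at or above the upper one are scene cuts.
Analysis windows are then labelled «arm», «leg», «both» or «neither» by the
modal per-frame joint state, and the labels are aligned with the
time-resolved ISC for the mixed-model stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import KeypointTrack
from .corrca import WindowISC
from .synthetic import (
    ARM,
    BOTH,
    BODY25_ARM_KEYPOINTS,
    BODY25_LEG_KEYPOINTS,
    LEG,
    NEITHER,
)

logger = logging.getLogger(__name__)

LABELS = (ARM, LEG, BOTH, NEITHER)
#: tie-break priority when window states are equally frequent
_TIE_PRIORITY = (BOTH, ARM, LEG, NEITHER)


@dataclass
class MovementConfig:
    """Thresholds (pixels/frame) and keypoint assignment for annotation.

    The thresholds have no universal default scale — they depend on frame
    resolution and camera — so they are explicit configuration, chosen per
    stimulus set.
    """

    lower_threshold: float
    upper_threshold: float
    arm_keypoints: tuple[int, ...] = BODY25_ARM_KEYPOINTS
    leg_keypoints: tuple[int, ...] = BODY25_LEG_KEYPOINTS
    confidence_min: float = 0.1
    dominance_rule: str = "modal"

    def __post_init__(self) -> None:
        if not 0 <= self.lower_threshold < self.upper_threshold:
            raise ValueError("need 0 <= lower_threshold < upper_threshold")
        if not self.arm_keypoints or not self.leg_keypoints:
            raise ValueError("keypoint lists must be non-empty")
        if set(self.arm_keypoints) & set(self.leg_keypoints):
            raise ValueError("arm and leg keypoint lists must be disjoint")
        if self.dominance_rule != "modal":
            raise ValueError(f"unknown dominance rule {self.dominance_rule!r}")


@dataclass
class MovementAnnotation:
    """Per-frame limb flags and per-window labels."""

    arm_moving: np.ndarray          # (n_frames,) bool
    leg_moving: np.ndarray          # (n_frames,) bool
    fps: float
    window_labels: np.ndarray = field(default=None)   # (n_windows,) str
    window_times: np.ndarray = field(default=None)

    @property
    def frame_labels(self) -> np.ndarray:
        out = np.full(self.arm_moving.shape, NEITHER, dtype=object)
        out[self.arm_moving & self.leg_moving] = BOTH
        out[self.arm_moving & ~self.leg_moving] = ARM
        out[~self.arm_moving & self.leg_moving] = LEG
        return out


def limb_displacement(
    track: KeypointTrack, config: MovementConfig
) -> dict[str, np.ndarray]:
    """Per-frame displacement of each limb class.

    Returns arrays of length ``n_frames``; entry ``f`` (``f >= 1``) is the
    maximum keypoint displacement between frames ``f-1`` and ``f`` over the
    limb's keypoints and all people, considering only keypoints detected
    with confidence >= ``confidence_min`` in both frames.  Entry 0 and
    transitions with no valid keypoint are NaN.
    """
    if track.n_frames < 2:
        raise ValueError("need at least two frames")
    xy = track.people[..., :2]          # (F, P, K, 2)
    conf = track.people[..., 2]
    valid = (conf[1:] >= config.confidence_min) & (conf[:-1] >= config.confidence_min)
    disp = np.linalg.norm(xy[1:] - xy[:-1], axis=-1)      # (F-1, P, K)
    disp = np.where(valid, disp, np.nan)
    out = {}
    for limb, kps in ((ARM, config.arm_keypoints), (LEG, config.leg_keypoints)):
        sel = disp[:, :, list(kps)]                       # (F-1, P, k)
        with np.errstate(all="ignore"):
            flat = sel.reshape(sel.shape[0], -1)
            m = np.full(track.n_frames, np.nan)
            any_valid = ~np.isnan(flat).all(axis=1)
            m[1:][any_valid] = np.nanmax(flat[any_valid], axis=1)
        out[limb] = m
    return out


def detect_movement(
    distances: dict[str, np.ndarray], config: MovementConfig, fps: float
) -> MovementAnnotation:
    """Dual-threshold rule: movement iff ``lower < distance < upper``.

    Strict inequalities on both sides: a displacement exactly at a threshold
    is not movement.  NaN distances (missing detections) are not movement.
    """
    def flag(d: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (d > config.lower_threshold) & (d < config.upper_threshold)

    return MovementAnnotation(
        arm_moving=flag(distances[ARM]), leg_moving=flag(distances[LEG]), fps=fps
    )


def annotate_track(
    track: KeypointTrack, config: MovementConfig
) -> MovementAnnotation:
    """Displacement + dual-threshold detection in one call."""
    return detect_movement(limb_displacement(track, config), config, track.fps)


def label_windows(
    annotation: MovementAnnotation, window_times: np.ndarray
) -> MovementAnnotation:
    """Assign each analysis window the modal per-frame joint state.

    ``window_times`` is the (n_windows, 2) start/end grid in seconds from the
    windowed-ISC stage.  Frames are mapped to windows by time; ties between
    states resolve deterministically as both > arm > leg > neither (logged).
    """
    frame_states = np.asarray(
        [
            2 * int(a) + int(l)
            for a, l in zip(annotation.arm_moving, annotation.leg_moving)
        ]
    )  # 0 neither, 1 leg, 2 arm, 3 both
    code_to_label = {0: NEITHER, 1: LEG, 2: ARM, 3: BOTH}
    times = np.arange(frame_states.size) / annotation.fps
    labels = np.empty(window_times.shape[0], dtype=object)
    for w, (t0, t1) in enumerate(window_times):
        in_win = (times >= t0) & (times < t1)
        if not in_win.any():
            labels[w] = NEITHER
            continue
        counts = np.bincount(frame_states[in_win], minlength=4)
        best = counts.max()
        tied = [code_to_label[c] for c in range(4) if counts[c] == best]
        if len(tied) > 1:
            choice = next(lbl for lbl in _TIE_PRIORITY if lbl in tied)
            logger.info("window %d: tie %s resolved as %s", w, tied, choice)
            labels[w] = choice
        else:
            labels[w] = tied[0]
    return MovementAnnotation(
        arm_moving=annotation.arm_moving,
        leg_moving=annotation.leg_moving,
        fps=annotation.fps,
        window_labels=labels,
        window_times=np.asarray(window_times, dtype=float),
    )


def align_annotation_isc(
    annotation: MovementAnnotation,
    window_isc: WindowISC,
    scores: pd.DataFrame | None = None,
    k_report: int = 3,
    patients_only: bool = True,
) -> pd.DataFrame:
    """One row per subject per window: ISC, movement label, clinical scores.

    This long table is the input of the mixed-model stage.  ``scores`` (the
    patient table, keyed by ``Code``) is joined on the subject id; with
    ``patients_only`` the healthy reference subjects are dropped.
    """
    if annotation.window_labels is None:
        annotation = label_windows(annotation, window_isc.window_times)
    if annotation.window_labels.shape[0] != window_isc.n_windows:
        raise ValueError(
            f"annotation has {annotation.window_labels.shape[0]} windows, "
            f"ISC has {window_isc.n_windows}"
        )
    if len(set(annotation.window_labels)) == 1:
        logger.warning(
            "movement annotation has a single level (%s); the mixed model "
            "will drop the movement term", annotation.window_labels[0],
        )
    frame = window_isc.to_frame(k_report=k_report)
    frame["movement"] = frame["window"].map(
        dict(enumerate(annotation.window_labels))
    )
    if patients_only:
        frame = frame[frame["group"] == "patient"].reset_index(drop=True)
    if scores is not None:
        frame = frame.merge(
            scores, how="left", left_on="subject", right_on="Code"
        ).drop(columns=["Code"])
    return frame
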