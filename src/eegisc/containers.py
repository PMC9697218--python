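"""In-memory containers shared across the pipeline.

The central object is :class:`MultiSubjectEEG`, an aligned tensor of
``N subjects x D channels x T samples`` for one video block, carrying the
sampling rate, the channel montage and per-subject group labels.  A cohort
watching several videos is simply a list of these, one per block, with
identical subject ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19-channel subset of the international 10-20 system used as the
#: default common montage (both recording systems in a two-site study must
#: share it; the identity of the shared electrodes is configurable).
MONTAGE_10_20_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

HEALTHY = "healthy"
PATIENT = "patient"


@dataclass
class MultiSubjectEEG:
    """Aligned multi-subject EEG for a single video block.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, n_channels, n_samples)``.  Microvolts
        before z-scoring, unitless afterwards.
    fs
        Sampling frequency in Hz.
    channel_labels
        ``n_channels`` channel names (10-20 system).
    subject_ids
        ``n_subjects`` unique identifiers.
    groups
        Per-subject group label, each ``"healthy"`` or ``"patient"``.
    video_id
        Identifier of the video block (1-based).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_ids: list[str]
    groups: list[str]
    video_id: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (subjects, channels, samples); got shape {self.data.shape}"
            )
        n, d, t = self.data.shape
        if t == 0:
            raise ValueError("zero-length recordings")
        if len(self.channel_labels) != d:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {d} channels"
            )
        if len(self.subject_ids) != n or len(self.groups) != n:
            raise ValueError("subject_ids/groups length must match data")
        bad = set(self.groups) - {HEALTHY, PATIENT}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Length of the block in seconds."""
        return self.n_samples / self.fs

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group], dtype=int)

    def subset_subjects(self, idx) -> "MultiSubjectEEG":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            data=self.data[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            groups=[self.groups[i] for i in idx],
        )

    def copy(self) -> "MultiSubjectEEG":
        return replace(self, data=self.data.copy())


@dataclass
class CorrCAModel:
    """Fitted correlated-components model.

    ``W`` holds the spatial filters (columns, strongest first), ``a`` the
    corresponding forward-model scalp projections, and ``eigenvalues`` the
    generalized eigenvalues of ``inv(Rw_reg) @ Rb`` in descending order.
    """

    w: np.ndarray              # (D, K) projection vectors
    eigenvalues: np.ndarray    # (K,) descending
    a: np.ndarray              # (D, K) forward model
    shrinkage: float
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.w.shape[1]


@dataclass
class CovariancePair:
    """Between- (Rb) and within-subject (Rw) covariance matrices."""

    rb: np.ndarray
    rw: np.ndarray
    n_subjects: int
    n_samples: int

    def __post_init__(self) -> None:
        self.rb = np.asarray(self.rb, dtype=np.float64)
        self.rw = np.asarray(self.rw, dtype=np.float64)
        if self.rb.shape != self.rw.shape or self.rb.ndim != 2:
            raise ValueError("Rb and Rw must be square matrices of equal shape")


@dataclass
class KeypointTrack:
    """Pose-estimator keypoint output for one video.

    ``people`` has shape ``(n_frames, n_people, n_keypoints, 3)`` with
    ``(x, y, confidence)`` triples; missing detections carry confidence 0.
    """

    people: np.ndarray
    fps: float
    frame_size: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        self.people = np.asarray(self.people, dtype=np.float64)
        if self.people.ndim != 4 or self.people.shape[-1] != 3:
            raise ValueError(
                "people must be (frames, people, keypoints, 3); got "
                f"{self.people.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.people.shape[0]

    @property
    def n_people(self) -> int:
        return self.people.shape[1]

    @property
    def n_keypoints(self) -> int:
        return self.people.shape[2]
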