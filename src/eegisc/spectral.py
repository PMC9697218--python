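"""Relative alpha power of component time courses.

For each subject and video, the data are projected onto the strongest
correlated components; per component the relative alpha power is the
integrated 8-12 Hz spectral power divided by the integrated broadband power.
Values are averaged across videos and summed over the three strongest
components, giving one attention-related covariate per subject.  The spectral
estimate is an averaged periodogram (Welch, Hann taper, 2 s segments, 50%
overlap); being a power ratio it is invariant to amplitude scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import CorrCAModel, MultiSubjectEEG
from .corrca import project

logger = logging.getLogger(__name__)


@dataclass
class AlphaPowerResult:
    """Per-subject relative alpha power (summed over the top components)."""

    per_component: np.ndarray     # (N, K_report): across-video mean per component
    summed: np.ndarray            # (N,)
    subject_ids: list[str]
    groups: list[str]
    band: tuple[float, float]
    broadband: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_ids,
                "group": self.groups,
                "alpha_power": self.summed,
            }
        )


def relative_band_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (8.0, 12.0),
    broadband: tuple[float, float] | None = None,
    segment_seconds: float = 2.0,
) -> float:
    """Integrated power in ``band`` over integrated power in ``broadband``.

    ``broadband`` defaults to the full representable range [0, fs/2].
    Returns NaN (logged) when the broadband power is zero.
    """
    if broadband is None:
        broadband = (0.0, fs / 2.0)
    if not (broadband[0] <= band[0] < band[1] <= broadband[1]):
        raise ValueError("need band within broadband within [0, fs/2]")
    nperseg = min(int(round(segment_seconds * fs)), x.shape[-1])
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_broad = (freqs >= broadband[0]) & (freqs <= broadband[1])
    denom = np.trapezoid(psd[in_broad], freqs[in_broad])
    if denom <= 0:
        logger.warning("zero broadband power; relative power undefined")
        return float("nan")
    return float(np.trapezoid(psd[in_band], freqs[in_band]) / denom)


def component_alpha(
    videos: list[MultiSubjectEEG],
    model: CorrCAModel,
    k_report: int = 3,
    band: tuple[float, float] = (8.0, 12.0),
    broadband: tuple[float, float] | None = None,
    segment_seconds: float = 2.0,
) -> AlphaPowerResult:
    """Relative alpha power per subject: per component, per video, averaged
    across videos, then summed over the ``k_report`` strongest components."""
    first = videos[0]
    n = first.n_subjects
    kr = min(k_report, model.n_components)
    acc = np.zeros((n, kr))
    for video in videos:
        proj = project(video, model)    # (N, K, T)
        for i in range(n):
            for c in range(kr):
                acc[i, c] += relative_band_power(
                    proj[i, c], video.fs, band=band, broadband=broadband,
                    segment_seconds=segment_seconds,
                )
    per_component = acc / len(videos)
    return AlphaPowerResult(
        per_component=per_component,
        summed=per_component.sum(axis=1),
        subject_ids=list(first.subject_ids),
        groups=list(first.groups),
        band=band,
        broadband=broadband if broadband is not None else (0.0, first.fs / 2.0),
    )
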