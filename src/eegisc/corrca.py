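"""Correlated components analysis (CorrCA) and intersubject correlation.

CorrCA finds electrode weightings ``w`` that maximize the correlation of the
projected signals between subjects: the ratio ``w' Rb w / w' Rw w`` of the
between-subjects covariance ``Rb`` to the within-subjects covariance ``Rw``.
Its maximizers are the eigenvectors of ``inv(Rw) Rb``.  With the pairwise
cross-covariance ``R_kl`` between subjects ``k`` and ``l``,

    Rw = (1/N)        sum_k  R_kk
    Rb = (1/(N(N-1))) sum_{k != l} R_kl

Covariances are computed per video block and pooled (averaged) over blocks so
a single set of projection vectors serves all stimuli.  Intersubject
correlation (ISC) of a subject is then the mean Pearson correlation of its
component time courses with those of a reference cohort, leaving the subject
itself out; the headline statistic is the sum over the strongest three
components.  A windowed variant computes the same quantity on short sliding
windows using the projection vectors fitted on the whole recording.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import HEALTHY, CorrCAModel, CovariancePair, MultiSubjectEEG

logger = logging.getLogger(__name__)


def compute_covariances(eeg: MultiSubjectEEG) -> CovariancePair:
    """Between- and within-subject covariance of one aligned video block.

    Uses the algebraic identity ``sum_{k != l} R_kl = S S' / T - sum_k R_kk``
    with ``S`` the subject-summed centred data, avoiding the O(N^2) pair loop.
    """
    if eeg.n_subjects < 2:
        raise ValueError("covariance computation needs at least two subjects")
    n, _, t = eeg.data.shape
    if t < 2:
        raise ValueError("zero/one-sample data has no covariance")
    centred = eeg.data - eeg.data.mean(axis=2, keepdims=True)
    d = centred.shape[1]
    flat = np.ascontiguousarray(np.swapaxes(centred, 0, 1)).reshape(d, n * t)
    rww = flat @ flat.T / t                                       # sum_k R_kk
    s = centred.sum(axis=0)                                       # (D, T)
    total = s @ s.T / t                                           # sum_{k,l} R_kl
    rw = rww / n
    rb = (total - rww) / (n * (n - 1))
    return CovariancePair(rb=rb, rw=rw, n_subjects=n, n_samples=t)


def pool_covariances(pairs: list[CovariancePair]) -> CovariancePair:
    """Element-wise mean of Rb and Rw over video blocks (equal weight)."""
    if not pairs:
        raise ValueError("no covariance pairs to pool")
    d = pairs[0].rb.shape[0]
    if any(p.rb.shape[0] != d for p in pairs):
        raise ValueError("covariance dimensions differ across videos")
    rb = np.mean([p.rb for p in pairs], axis=0)
    rw = np.mean([p.rw for p in pairs], axis=0)
    return CovariancePair(
        rb=rb,
        rw=rw,
        n_subjects=pairs[0].n_subjects,
        n_samples=int(np.mean([p.n_samples for p in pairs])),
    )


def fit_corrca(
    pooled: CovariancePair,
    k: int | None = None,
    shrinkage: float = 0.1,
    channel_labels: list[str] | None = None,
) -> CorrCAModel:
    """Solve the generalized eigenproblem ``inv(Rw_reg) Rb w = lambda w``.

    ``Rw`` is shrunk toward a scaled identity,
    ``Rw_reg = (1 - g) Rw + g mean(diag(Rw)) I``, which keeps the problem
    well-posed when zero-filled channels make ``Rw`` rank-deficient.  The
    non-symmetric problem is solved through the symmetric equivalent on the
    ``Rw_reg^{-1/2}`` transform.  Columns of ``W`` are ordered by descending
    eigenvalue and sign-fixed so the largest-magnitude entry of each
    forward-model column ``A = Rw W (W' Rw W)^{-1}`` is positive.
    """
    d = pooled.rw.shape[0]
    if k is None:
        k = d
    if not 1 <= k <= d:
        raise ValueError(f"k must be in 1..{d}, got {k}")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")

    rw = 0.5 * (pooled.rw + pooled.rw.T)
    rb = 0.5 * (pooled.rb + pooled.rb.T)
    mean_diag = float(np.trace(rw)) / d
    rw_reg = (1.0 - shrinkage) * rw + shrinkage * mean_diag * np.eye(d)

    evals, evecs = np.linalg.eigh(rw_reg)
    tol = d * np.finfo(float).eps * max(evals.max(), 0.0)
    if evals.min() <= tol:
        raise np.linalg.LinAlgError(
            "within-subject covariance is singular; increase shrinkage"
        )
    # symmetric reduction: M = Rw^{-1/2} Rb Rw^{-1/2}
    inv_sqrt = evecs @ np.diag(evals ** -0.5) @ evecs.T
    m = inv_sqrt @ rb @ inv_sqrt
    m = 0.5 * (m + m.T)
    lam, v = np.linalg.eigh(m)
    order = np.argsort(lam)[::-1][:k]
    lam = lam[order]
    w = inv_sqrt @ v[:, order]

    wr = w.T @ rw @ w
    a = rw @ w @ np.linalg.pinv(wr)
    # deterministic sign: strongest forward-model entry positive
    for j in range(a.shape[1]):
        i_max = int(np.argmax(np.abs(a[:, j])))
        if a[i_max, j] < 0:
            a[:, j] = -a[:, j]
            w[:, j] = -w[:, j]
    return CorrCAModel(
        w=w,
        eigenvalues=lam,
        a=a,
        shrinkage=shrinkage,
        channel_labels=list(channel_labels) if channel_labels else [],
    )


def fit_corrca_videos(
    videos: list[MultiSubjectEEG],
    k: int | None = None,
    shrinkage: float = 0.1,
) -> CorrCAModel:
    """Fit CorrCA on covariances pooled over video blocks."""
    pairs = [compute_covariances(v) for v in videos]
    pooled = pool_covariances(pairs)
    return fit_corrca(
        pooled, k=k, shrinkage=shrinkage, channel_labels=videos[0].channel_labels
    )


def project(eeg: MultiSubjectEEG, model: CorrCAModel) -> np.ndarray:
    """Project channel data onto the components: ``(N, K, T)`` time courses."""
    if eeg.n_channels != model.w.shape[0]:
        raise ValueError(
            f"model has {model.w.shape[0]} channels, data has {eeg.n_channels}"
        )
    return np.einsum("dk,ndt->nkt", model.w, eeg.data)


def _pairwise_mean_correlation(
    target: np.ndarray, refs: np.ndarray
) -> np.ndarray:
    """Mean Pearson correlation of one subject's components vs references.

    ``target``: (K, T); ``refs``: (R, K, T).  Pairs in which either time
    course has zero variance are skipped; a component with no valid pair
    yields NaN.
    """
    k, t = target.shape
    tc = target - target.mean(axis=1, keepdims=True)
    rc = refs - refs.mean(axis=2, keepdims=True)
    t_sd = np.sqrt((tc ** 2).sum(axis=1))
    r_sd = np.sqrt((rc ** 2).sum(axis=2))
    num = np.einsum("kt,rkt->rk", tc, rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / (t_sd[None, :] * r_sd)
    valid = (t_sd[None, :] > 0) & (r_sd > 0)
    out = np.full(k, np.nan)
    n_valid = valid.sum(axis=0)
    for j in range(k):
        if n_valid[j] == 0:
            logger.warning("component %d: all reference pairs degenerate", j + 1)
            continue
        out[j] = corr[valid[:, j], j].mean()
    return out


def loo_isc(
    projections: np.ndarray,
    target: int,
    reference: np.ndarray | list[int],
) -> np.ndarray:
    """Leave-one-out ISC of one subject for one video.

    ``projections`` is the ``(N, K, T)`` component tensor; the target is
    correlated against every reference subject (itself excluded if present)
    and the pairwise Pearson correlations are averaged per component.
    """
    reference = np.asarray(reference, dtype=int)
    reference = reference[reference != target]
    if reference.size == 0:
        raise ValueError("reference set empty after excluding the target")
    return _pairwise_mean_correlation(projections[target], projections[reference])


@dataclass
class ISCResult:
    """Per-subject, per-video, per-component leave-one-out ISC.

    ``values`` has shape ``(n_subjects, n_videos, K)``; ``topk_sum`` is the
    across-video mean per component summed over the first ``k_report``
    components, one number per subject.
    """

    values: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    video_ids: list[int]
    k_report: int = 3
    reference_group: str = HEALTHY
    component_mean: np.ndarray = field(init=False)
    topk_sum: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            self.component_mean = np.nanmean(self.values, axis=1)  # (N, K)
        kr = min(self.k_report, self.values.shape[2])
        self.topk_sum = self.component_mean[:, :kr].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n, v, k = self.values.shape
        for i in range(n):
            for j in range(v):
                for c in range(k):
                    rows.append(
                        {
                            "subject": self.subject_ids[i],
                            "group": self.groups[i],
                            "video": self.video_ids[j],
                            "component": c + 1,
                            "isc": self.values[i, j, c],
                            "topk_sum": self.topk_sum[i],
                        }
                    )
        return pd.DataFrame(
            rows, columns=["subject", "group", "video", "component", "isc", "topk_sum"]
        )


def cohort_isc(
    videos: list[MultiSubjectEEG],
    model: CorrCAModel,
    k_report: int = 3,
    reference_group: str = HEALTHY,
) -> ISCResult:
    """Leave-one-out ISC of every subject against a reference cohort.

    For each video, every subject (healthy or patient) is correlated against
    the members of ``reference_group``; members of that group leave
    themselves out.  Per-component values are averaged across videos before
    the top-``k_report`` summation.
    """
    first = videos[0]
    ref_idx = first.group_indices(reference_group)
    if ref_idx.size < 2:
        raise ValueError(f"reference group {reference_group!r} needs >= 2 members")
    n = first.n_subjects
    k = model.n_components
    values = np.full((n, len(videos), k), np.nan)
    for j, video in enumerate(videos):
        proj = project(video, model)
        centred = proj - proj.mean(axis=2, keepdims=True)
        norm = np.linalg.norm(centred, axis=2)              # (N, K)
        valid = norm > 0
        safe = np.where(valid, norm, 1.0)
        y = centred / safe[:, :, None]
        in_ref = np.zeros(n, dtype=bool)
        in_ref[ref_idx] = True
        for c in range(k):
            corr = y[:, c, :] @ y[:, c, :].T                # (N, N) pairwise
            pair_ok = np.outer(valid[:, c], valid[:, c] & in_ref)
            np.fill_diagonal(pair_ok, False)
            counts = pair_ok.sum(axis=1)
            sums = np.where(pair_ok, corr, 0.0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                values[counts > 0, j, c] = (
                    sums[counts > 0] / counts[counts > 0]
                )
            if (counts == 0).any():
                logger.warning(
                    "video %d component %d: %d subject(s) without valid "
                    "reference pairs", video.video_id, c + 1, int((counts == 0).sum()),
                )
    return ISCResult(
        values=values,
        subject_ids=list(first.subject_ids),
        groups=list(first.groups),
        video_ids=[v.video_id for v in videos],
        k_report=k_report,
        reference_group=reference_group,
    )


def within_group_isc(
    videos: list[MultiSubjectEEG],
    group: str,
    k_report: int = 3,
    shrinkage: float = 0.1,
) -> ISCResult:
    """Refit CorrCA on one group alone and score its members' mutual ISC."""
    idx = videos[0].group_indices(group)
    if idx.size < 3:
        raise ValueError("within-group ISC needs at least three group members")
    sub = [v.subset_subjects(idx) for v in videos]
    model = fit_corrca_videos(sub, shrinkage=shrinkage)
    return cohort_isc(sub, model, k_report=k_report, reference_group=group)


# ---------------------------------------------------------------------------
# Time-resolved (windowed) ISC


@dataclass
class WindowISC:
    """Sliding-window leave-one-out ISC with the whole-recording filters.

    ``values`` has shape ``(n_subjects, n_windows, K)``; ``window_times``
    holds (start, end) seconds per window.
    """

    values: np.ndarray
    window_times: np.ndarray
    window_length: float
    step: float
    subject_ids: list[str]
    groups: list[str]
    video_id: int = 1

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def to_frame(self, k_report: int = 3) -> pd.DataFrame:
        n, m, k = self.values.shape
        kr = min(k_report, k)
        rows = []
        for i in range(n):
            for wdx in range(m):
                rows.append(
                    {
                        "subject": self.subject_ids[i],
                        "group": self.groups[i],
                        "video": self.video_id,
                        "window": wdx,
                        "t_start": self.window_times[wdx, 0],
                        "t_end": self.window_times[wdx, 1],
                        "topk_sum": self.values[i, wdx, :kr].sum(),
                    }
                )
        return pd.DataFrame(rows)


def window_grid(t_sec: float, window_length: float, step: float) -> np.ndarray:
    """Start/end times of the sliding-window grid.

    ``n_windows = floor((t_sec - window_length)/step) + 1``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if window_length > t_sec:
        raise ValueError("window longer than the recording")
    n = int(math.floor((t_sec - window_length) / step + 1e-9)) + 1
    starts = np.arange(n) * step
    return np.column_stack([starts, starts + window_length])


def time_resolved_isc(
    eeg: MultiSubjectEEG,
    model: CorrCAModel,
    window_length: float = 1.5,
    overlap: float = 1.2,
    reference_group: str = HEALTHY,
    max_zero_fraction: float = 0.5,
) -> WindowISC:
    """Leave-one-out ISC on overlapping windows, W fixed from the whole fit.

    ``step = window_length - overlap``.  Windows in which more than
    ``max_zero_fraction`` of a subject's channel samples are zero-filled
    (artifact-blanked) are set missing for that subject.
    """
    step = window_length - overlap
    if step <= 0:
        raise ValueError("overlap must be smaller than the window length")
    grid = window_grid(eeg.duration, window_length, step)
    win = int(round(window_length * eeg.fs))
    hop = int(round(step * eeg.fs))
    proj = project(eeg, model)
    ref_idx = eeg.group_indices(reference_group)
    n, k = eeg.n_subjects, model.n_components
    m = grid.shape[0]
    values = np.full((n, m, k), np.nan)
    zero_frac = None
    if max_zero_fraction is not None:
        zeros = (eeg.data == 0.0).mean(axis=1)     # (N, T) fraction of channels
    for wdx in range(m):
        s = wdx * hop
        chunk = proj[:, :, s : s + win]
        if max_zero_fraction is not None:
            zero_frac = zeros[:, s : s + win].mean(axis=1)
        for i in range(n):
            if zero_frac is not None and zero_frac[i] > max_zero_fraction:
                logger.warning(
                    "subject %s window %d mostly zero-filled; ISC set missing",
                    eeg.subject_ids[i], wdx,
                )
                continue
            values[i, wdx] = loo_isc(chunk, i, ref_idx)
    return WindowISC(
        values=values,
        window_times=grid,
        window_length=window_length,
        step=step,
        subject_ids=list(eeg.subject_ids),
        groups=list(eeg.groups),
        video_id=eeg.video_id,
    )
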