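"""Readers and writers for every external format the pipeline touches.

EEG comes in as EDF (read through MNE) or as a tab-delimited channel-by-sample
matrix with a JSON sidecar carrying the sampling rate and labels.  Pose
keypoints come in as OpenPose-style per-frame JSON (``people`` ->
``pose_keypoints_2d`` flat ``[x, y, confidence]`` triples, BODY_25 ordering).
Results leave as TSV tables.  Readers validate rather than coerce: mismatched
sampling rates or missing montage channels are hard errors, and every writer
round-trips losslessly (EDF up to its 16-bit quantization).
"""

from __future__ import annotations

import json
import logging
import re
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MONTAGE_10_20_19, KeypointTrack, MultiSubjectEEG
from .corrca import ISCResult

logger = logging.getLogger(__name__)

_EDF_PATIENT_RE = re.compile(r"^(?P<sid>\S+)\s+(?P<group>healthy|patient)")


# ---------------------------------------------------------------------------
# EDF


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_labels: list[str],
    subject_id: str = "X",
    group: str = "healthy",
) -> None:
    """Write one subject's ``(D, T)`` data as a 16-bit EDF file.

    One-second data records; ``T`` must be an integer number of seconds.
    The subject id and group are stored in the patient-identification field
    so a round trip preserves them.  Physical units are microvolts.
    """
    data = np.asarray(data, dtype=np.float64)
    d, t = data.shape
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if t % spr:
        raise ValueError(
            f"{t} samples is not a whole number of 1 s records at fs={fs}"
        )
    n_rec = t // spr

    phys_max = np.abs(data).max(axis=1)
    phys_max = np.where(phys_max > 0, phys_max, 1.0)
    dig_max, dig_min = 32767, -32768
    scaled = np.round(data / phys_max[:, None] * dig_max).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii", "replace")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad(f"{subject_id} {group}", 80),
            pad("eegisc synthetic recording", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (d + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(d), 4),
        ]
    )
    fields = [
        (16, channel_labels),
        (80, [""] * d),
        (8, ["uV"] * d),
        (8, [f"{-m:.6g}"[:8] for m in phys_max]),
        (8, [f"{m:.6g}"[:8] for m in phys_max]),
        (8, [str(dig_min)] * d),
        (8, [str(dig_max)] * d),
        (80, [""] * d),
        (8, [str(spr)] * d),
        (32, [""] * d),
    ]
    sig_header = b"".join(
        b"".join(pad(str(v), n) for v in values) for n, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            chunk = scaled[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())


def _read_edf_one(path: Path) -> tuple[np.ndarray, float, list[str], str, str]:
    """Read one EDF file via MNE; returns (data uV, fs, labels, sid, group)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    with open(path, "rb") as fh:
        fh.seek(8)
        patient = fh.read(80).decode("ascii", "replace").strip()
    m = _EDF_PATIENT_RE.match(patient)
    sid, group = (m.group("sid"), m.group("group")) if m else (path.stem, "healthy")
    return data, float(raw.info["sfreq"]), list(raw.ch_names), sid, group


# ---------------------------------------------------------------------------
# Delimited matrix + JSON sidecar


def write_matrix(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_labels: list[str],
    subject_id: str = "X",
    group: str = "healthy",
    video_id: int = 1,
) -> None:
    """Write ``(D, T)`` data as TSV (rows = channels) plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(data), delimiter="\t", fmt="%.10g")
    sidecar = {
        "fs": fs,
        "channel_labels": list(channel_labels),
        "subject_id": subject_id,
        "group": group,
        "video_id": video_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _read_matrix_one(path: Path) -> tuple[np.ndarray, float, list[str], str, str]:
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar {sidecar_path} missing for {path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return (
        data,
        float(meta["fs"]),
        list(meta["channel_labels"]),
        str(meta.get("subject_id", path.stem)),
        str(meta.get("group", "healthy")),
    )


# ---------------------------------------------------------------------------
# Multi-subject assembly


def read_eeg(
    paths: list[str | Path],
    layout: str = "edf",
    montage: tuple[str, ...] = MONTAGE_10_20_19,
    video_id: int = 1,
) -> MultiSubjectEEG:
    """Read one file per subject and assemble an aligned tensor.

    Channels are restricted to ``montage`` (extra channels dropped, order
    canonical); a file missing montage channels is a hard error listing
    them, as is any sampling-rate mismatch.  Subjects are truncated to the
    shortest common length.
    """
    if not paths:
        raise ValueError("no input files")
    readers = {"edf": _read_edf_one, "matrix": _read_matrix_one}
    if layout not in readers:
        raise ValueError(f"unknown layout {layout!r}; use one of {sorted(readers)}")
    read_one = readers[layout]

    loaded = []
    fs_seen: dict[float, Path] = {}
    for p in paths:
        p = Path(p)
        data, fs, labels, sid, group = read_one(p)
        missing = [ch for ch in montage if ch not in labels]
        if missing:
            raise ValueError(f"{p}: montage channels missing: {', '.join(missing)}")
        order = [labels.index(ch) for ch in montage]
        if len(labels) != len(montage):
            logger.info(
                "%s: dropping %d channel(s) outside the montage",
                p, len(labels) - len(montage),
            )
        loaded.append((data[order], fs, sid, group, p))
        fs_seen.setdefault(fs, p)
    if len(fs_seen) > 1:
        desc = "; ".join(f"{p} at {fs} Hz" for fs, p in fs_seen.items())
        raise ValueError(f"mixed sampling rates: {desc}")

    t_min = min(x[0].shape[1] for x in loaded)
    if any(x[0].shape[1] != t_min for x in loaded):
        logger.info("truncating all subjects to common length %d samples", t_min)
    return MultiSubjectEEG(
        data=np.stack([x[0][:, :t_min] for x in loaded]),
        fs=loaded[0][1],
        channel_labels=list(montage),
        subject_ids=[x[2] for x in loaded],
        groups=[x[3] for x in loaded],
        video_id=video_id,
    )


def write_cohort(
    videos: list[MultiSubjectEEG], out_dir: str | Path, layout: str = "edf"
) -> list[Path]:
    """Write one file per subject per video; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"edf": ".edf", "matrix": ".tsv"}[layout]
    paths = []
    for video in videos:
        for i, sid in enumerate(video.subject_ids):
            path = out_dir / f"{sid}_video{video.video_id}{ext}"
            if layout == "edf":
                write_edf(
                    path, video.data[i], video.fs, video.channel_labels,
                    subject_id=sid, group=video.groups[i],
                )
            else:
                write_matrix(
                    path, video.data[i], video.fs, video.channel_labels,
                    subject_id=sid, group=video.groups[i], video_id=video.video_id,
                )
            paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# OpenPose-style keypoints


def write_keypoints(track: KeypointTrack, out_dir: str | Path, prefix: str = "video") -> None:
    """Write per-frame OpenPose-style JSON files (BODY_25 flat triples)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for f in range(track.n_frames):
        people = []
        for p in range(track.n_people):
            kp = track.people[f, p]
            if (kp[:, 2] == 0).all():
                continue
            people.append({"pose_keypoints_2d": [round(v, 4) for v in kp.ravel()]})
        doc = {"version": 1.3, "people": people}
        (out_dir / f"{prefix}_{f:012d}_keypoints.json").write_text(json.dumps(doc))


def read_keypoints(
    directory: str | Path, fps: float = 25.0, n_keypoints: int = 25
) -> KeypointTrack:
    """Read a directory of per-frame OpenPose JSON files into a track.

    Frames are ordered by the index embedded in the file name; frames with
    ``"people": []`` become all-missing (confidence 0).  Malformed JSON is
    an error naming the frame.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*_keypoints.json"))
    if not files:
        raise FileNotFoundError(f"no *_keypoints.json files in {directory}")
    frames = []
    max_people = 1
    for f in files:
        try:
            doc = json.loads(f.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed keypoint JSON in frame file {f.name}: {exc}")
        persons = []
        for person in doc.get("people", []):
            flat = np.asarray(person["pose_keypoints_2d"], dtype=float)
            if flat.size != n_keypoints * 3:
                raise ValueError(
                    f"{f.name}: expected {n_keypoints * 3} values, got {flat.size}"
                )
            persons.append(flat.reshape(n_keypoints, 3))
        frames.append(persons)
        max_people = max(max_people, len(persons))
    people = np.zeros((len(frames), max_people, n_keypoints, 3))
    for i, persons in enumerate(frames):
        for j, kp in enumerate(persons):
            people[i, j] = kp
    return KeypointTrack(people=people, fps=fps)


# ---------------------------------------------------------------------------
# Result tables


def write_isc_table(result: ISCResult, path: str | Path) -> None:
    """Write per-subject/video/component ISC rows (plus top-K sum) as TSV."""
    result.to_frame().to_csv(path, sep="\t", index=False)


def read_isc_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
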