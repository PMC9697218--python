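"""End-to-end orchestration: simulate/load -> preprocess -> CorrCA -> ISC ->
alpha power -> movement alignment -> statistics.

The run is driven by a single :class:`PipelineConfig` (YAML/JSON on disk).
Components are always fitted on the two groups pooled — concatenating
patients and healthy children per video keeps the optimization unbiased with
respect to group — while the leave-one-out reference cohort is always the
healthy group, for healthy targets (self-excluded) and patients alike.
Every run writes a manifest listing its outputs, the seed and a config hash,
so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .containers import HEALTHY, PATIENT
from .corrca import cohort_isc, fit_corrca_videos, time_resolved_isc, within_group_isc
from .movement import MovementConfig, align_annotation_isc, annotate_track, label_windows
from .preprocessing import PreprocessConfig, preprocess
from .spectral import component_alpha
from .stats import (
    fit_mixed,
    kendall_tau,
    pearson_r,
    results_frame,
    welch_t,
    wilcoxon_one_sample,
    ancova_group_cov,
)
from .synthetic import (
    CohortSpec,
    MovementEpoch,
    generate_cohort,
    generate_keypoint_tracks,
    inject_artifacts,
    load_scores_fixture,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of the two modes is active."""

    mode: str = "synthetic"                      # "synthetic" | "files"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_paths: list[str] = field(default_factory=list)
    input_layout: str = "edf"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    run_preprocess: bool = True
    k_report: int = 3
    shrinkage: float = 0.1
    window_length: float = 1.5
    overlap: float = 1.2
    window_sizes_sensitivity: list[float] = field(default_factory=list)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    broadband: tuple[float, float] | None = None
    movement: MovementConfig | None = None
    keypoint_dir: str | None = None
    video_fps: float = 25.0
    output_dir: str = "eegisc_output"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.input_paths:
            raise ValueError("files mode requires input_paths")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = dict(raw)
    if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
        kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
    if "preprocess" in kwargs and isinstance(kwargs["preprocess"], dict):
        kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
    if "movement" in kwargs and isinstance(kwargs["movement"], dict):
        kwargs["movement"] = MovementConfig(**kwargs["movement"])
    return PipelineConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _default_script(n_frames: int, rng: np.random.Generator) -> list[MovementEpoch]:
    """A plausible stimulus script: alternating arm/leg bursts with gaps."""
    script: list[MovementEpoch] = []
    f = max(1, n_frames // 20)
    limbs = ["arm", "leg"]
    i = 0
    while f + n_frames // 10 < n_frames - 1:
        length = int(rng.integers(n_frames // 20, n_frames // 10))
        script.append(MovementEpoch(f, min(f + length, n_frames - 1), limbs[i % 2]))
        f += length + int(rng.integers(n_frames // 20, n_frames // 10))
        i += 1
    return script


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    partial = out_dir / ".partial"
    partial.write_text("run in progress\n")
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "mode": config.mode,
        "outputs": [],
    }
    stage = "load"
    try:
        # ---------------- load / simulate
        truth = None
        if config.mode == "synthetic":
            spec = dataclasses.replace(config.cohort, seed=config.seed)
            videos, truth = generate_cohort(spec)
            art = spec.artifact_spec
            if art.ocular_events or art.bad_channels or art.spikes:
                rng = np.random.default_rng(config.seed + 1)
                videos = [inject_artifacts(v, spec, rng)[0] for v in videos]
        else:
            by_video: dict[int, list[Path]] = {}
            for p in config.input_paths:
                p = Path(p)
                vid = 1
                if "_video" in p.stem:
                    vid = int(p.stem.rsplit("_video", 1)[1])
                by_video.setdefault(vid, []).append(p)
            videos = [
                eio.read_eeg(sorted(paths), layout=config.input_layout, video_id=vid)
                for vid, paths in sorted(by_video.items())
            ]

        # ---------------- preprocess
        stage = "preprocess"
        if config.run_preprocess:
            pp = dataclasses.replace(config.preprocess, seed=config.seed)
            videos = preprocess(videos, pp)

        # ---------------- CorrCA on pooled groups
        stage = "corrca"
        model = fit_corrca_videos(videos, shrinkage=config.shrinkage)
        fm = pd.DataFrame(
            model.a[:, : config.k_report],
            index=videos[0].channel_labels,
            columns=[f"component_{i+1}" for i in range(min(config.k_report, model.n_components))],
        )
        fm_path = out_dir / "forward_model.tsv"
        fm.to_csv(fm_path, sep="\t", index_label="channel")
        manifest["outputs"].append(str(fm_path))

        # ---------------- leave-one-out ISC vs healthy reference
        stage = "isc"
        isc = cohort_isc(videos, model, k_report=config.k_report, reference_group=HEALTHY)
        isc_path = out_dir / "isc.tsv"
        eio.write_isc_table(isc, isc_path)
        manifest["outputs"].append(str(isc_path))

        # ---------------- within-patient ISC
        stage = "within_patient_isc"
        patient_isc = None
        n_patients = len(videos[0].group_indices(PATIENT))
        if n_patients >= 3:
            patient_isc = within_group_isc(
                videos, PATIENT, k_report=config.k_report, shrinkage=config.shrinkage
            )
            wp_path = out_dir / "within_patient_isc.tsv"
            eio.write_isc_table(patient_isc, wp_path)
            manifest["outputs"].append(str(wp_path))

        # ---------------- windowed ISC (first video) + sensitivity lengths
        stage = "windowed_isc"
        win = time_resolved_isc(
            videos[0], model,
            window_length=config.window_length, overlap=config.overlap,
        )
        win_path = out_dir / "window_isc_video1.tsv"
        eio.write_table(win.to_frame(config.k_report), win_path)
        manifest["outputs"].append(str(win_path))
        for wl in config.window_sizes_sensitivity:
            alt = time_resolved_isc(
                videos[0], model, window_length=wl, overlap=wl * 0.8
            )
            alt_path = out_dir / f"window_isc_video1_w{int(round(wl * 1000))}ms.tsv"
            eio.write_table(alt.to_frame(config.k_report), alt_path)
            manifest["outputs"].append(str(alt_path))

        # ---------------- alpha power
        stage = "alpha"
        alpha = component_alpha(
            videos, model, k_report=config.k_report,
            band=config.alpha_band, broadband=config.broadband,
        )
        alpha_path = out_dir / "alpha.tsv"
        eio.write_table(alpha.to_frame(), alpha_path)
        manifest["outputs"].append(str(alpha_path))

        # ---------------- movement annotation + alignment
        stage = "annotation"
        aligned = None
        movement = config.movement or MovementConfig(lower_threshold=2.0, upper_threshold=30.0)
        if config.keypoint_dir:
            track = eio.read_keypoints(config.keypoint_dir, fps=config.video_fps)
        elif config.mode == "synthetic":
            rng = np.random.default_rng(config.seed + 2)
            n_frames = int(round(videos[0].duration * config.video_fps))
            track, _ = generate_keypoint_tracks(
                n_frames, config.video_fps, _default_script(n_frames, rng),
                lower_threshold=movement.lower_threshold,
                upper_threshold=movement.upper_threshold,
                seed=config.seed + 3,
            )
        else:
            track = None
        if track is not None and track.n_frames >= 2:
            ann = annotate_track(track, movement)
            ann = label_windows(ann, win.window_times)
            ann_path = out_dir / "window_labels.tsv"
            eio.write_table(
                pd.DataFrame(
                    {
                        "window": np.arange(ann.window_labels.size),
                        "t_start": ann.window_times[:, 0],
                        "t_end": ann.window_times[:, 1],
                        "label": ann.window_labels,
                    }
                ),
                ann_path,
            )
            manifest["outputs"].append(str(ann_path))
            scores = _matching_scores(videos[0].subject_ids)
            aligned = align_annotation_isc(ann, win, scores, k_report=config.k_report)
            al_path = out_dir / "aligned_window_table.tsv"
            eio.write_table(aligned, al_path)
            manifest["outputs"].append(str(al_path))

        # ---------------- statistics
        stage = "stats"
        results = {}
        healthy = np.asarray(isc.topk_sum)[videos[0].group_indices(HEALTHY)]
        patients = np.asarray(isc.topk_sum)[videos[0].group_indices(PATIENT)]
        if healthy.size >= 2 and patients.size >= 2:
            results["group_welch"] = welch_t(healthy, patients)
            anc = ancova_group_cov(
                np.asarray(isc.topk_sum), videos[0].groups, alpha.summed
            )
            results["ancova_alpha_group"] = anc["group"]
            results["ancova_alpha_interaction"] = anc.get("interaction")
            results["alpha_isc_healthy"] = pearson_r(
                alpha.summed[videos[0].group_indices(HEALTHY)], healthy
            )
            results["alpha_isc_patient"] = pearson_r(
                alpha.summed[videos[0].group_indices(PATIENT)], patients
            )
        if patient_isc is not None and patient_isc.topk_sum.size >= 5:
            results["within_patient_wilcoxon"] = wilcoxon_one_sample(
                patient_isc.topk_sum, alternative="greater"
            )
        scores = _matching_scores(videos[0].subject_ids)
        if scores is not None:
            merged = pd.DataFrame(
                {"subject": videos[0].subject_ids, "isc": isc.topk_sum}
            ).merge(scores, left_on="subject", right_on="Code")
            if len(merged) >= 5:
                for col in ("CNS Damage", "DMD", "Paresis"):
                    results[f"kendall_{col.lower().replace(' ', '_')}"] = kendall_tau(
                        merged[col], merged["isc"]
                    )
                results["pearson_gmd"] = pearson_r(merged["GMD"], merged["isc"])
        results = {k: v for k, v in results.items() if v is not None}
        if aligned is not None and aligned["movement"].nunique() >= 1 and len(aligned) > 10:
            try:
                mixed, _ = fit_mixed(
                    aligned, score_columns=[c for c in ("GMD",) if c in aligned.columns]
                )
                results.update({f"mixed_{k}": v for k, v in mixed.items()})
            except Exception as exc:
                logger.warning("mixed model stage skipped: %s", exc)
        stats_path = out_dir / "stats.tsv"
        eio.write_table(results_frame(results), stats_path)
        manifest["outputs"].append(str(stats_path))
    except Exception:
        logger.error("pipeline aborted in stage %r", stage)
        partial.write_text(f"aborted in stage {stage}\n")
        raise
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    partial.unlink(missing_ok=True)
    return manifest


def _matching_scores(subject_ids: list[str]) -> pd.DataFrame | None:
    """Patient score rows matching the cohort's subject ids, if any."""
    scores = load_scores_fixture()
    if not set(scores["Code"]) & set(subject_ids):
        return None
    return scores
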