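"""End-to-end orchestration: video -> signals -> blinks -> matrices -> report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blink_detect import (
    BlinkCandidate,
    BlinkClip,
    blink_statistics,
    detect_candidates,
    extract_clips,
    filter_candidates,
)
from .blinkmatrix import BlinkMatrix, build_matrix, render_projection
from .config import PipelineConfig
from .eyelid import estimate_clip
from .phases import BlinkRecord, NotABlinkError, analyze_trace, displacement_trace
from .signals import mean_intensity_profile, simulate_events
from .video_io import FrameSequence, load_video

__all__ = ["AnalyzedBlink", "PipelineResult", "analyze_sequence", "run_pipeline"]

log = logging.getLogger("blinkscope")


@dataclass
class AnalyzedBlink:
    """One accepted blink taken through the full chain."""

    clip: BlinkClip
    matrix: BlinkMatrix
    record: BlinkRecord


@dataclass
class PipelineResult:
    candidates: list[BlinkCandidate]
    blinks: list[AnalyzedBlink]
    summary: dict
    failures: list[tuple[int, str]] = field(default_factory=list)


def analyze_sequence(seq: FrameSequence, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis in memory; the artifact-writing layer wraps this."""
    cfg = config or PipelineConfig()
    t_start = time.perf_counter()
    intensity = mean_intensity_profile(seq)
    events = simulate_events(seq, cfg.event_threshold, cfg.event_downsample)
    cands = detect_candidates(
        intensity,
        events,
        smooth_window=cfg.smooth_window,
        prominence_scale=cfg.prominence_scale,
        baseline_return_frac=cfg.baseline_return_frac,
        require_two_bursts=cfg.require_two_bursts,
    )
    filter_candidates(cands, seq.fps)
    clips = extract_clips(seq, cands, pad=cfg.pad_frames)

    blinks: list[AnalyzedBlink] = []
    failures: list[tuple[int, str]] = []
    for i, clip in enumerate(clips):
        try:
            est = estimate_clip(
                clip.frames,
                degree=cfg.poly_degree,
                tol=cfg.fit_tol_px,
                max_iter=cfg.fit_max_iter,
                margin=cfg.roi_margin,
                per_frame_threshold=cfg.per_frame_threshold,
            )
            bm = build_matrix(est.curves, seq.fps, fallback_aperture_px=est.roi.height)
            trace = displacement_trace(bm, center_width=cfg.center_width)
            record = analyze_trace(trace, reopen_frac=cfg.reopen_frac)
        except (NotABlinkError, ValueError) as exc:
            failures.append((i, str(exc)))
            log.warning("blink %d failed analysis: %s", i, exc)
            continue
        blinks.append(AnalyzedBlink(clip=clip, matrix=bm, record=record))

    summary = blink_statistics(
        cands,
        seq.duration_s,
        durations_ms=[b.record.params["total_duration_ms"] for b in blinks] or None,
        labels=[b.record.label for b in blinks] or None,
    )
    summary["elapsed_s"] = time.perf_counter() - t_start
    return PipelineResult(candidates=cands, blinks=blinks, summary=summary, failures=failures)


def _candidate_rows(cands: list[BlinkCandidate], fps: float) -> list[dict]:
    return [
        {
            "x1": c.x1, "x2": c.x2, "x3": c.x3,
            "t1_s": c.x1 / fps, "t2_s": c.x2 / fps, "t3_s": c.x3 / fps,
            "y1": c.y1, "y2": c.y2, "y3": c.y3,
            "status": c.status, "reject_reason": c.reject_reason,
        }
        for c in cands
    ]


def run_pipeline(
    video_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "blinkscope_report",
    fps_override: float | None = None,
) -> PipelineResult:
    """Analyze a video file/directory and write the report bundle.

    Writes candidates, per-blink parameter table and JSON records,
    projection PNGs, a summary, a run manifest and a log into ``out_dir``.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        seq = load_video(video_path, fps_override=fps_override)
        log.info("loaded %s: %d frames at %.1f fps", video_path, len(seq), seq.fps)
        result = analyze_sequence(seq, cfg)
        log.info(
            "detected %d candidates, %d accepted, %d analyzed",
            len(result.candidates),
            sum(c.status == "accepted" for c in result.candidates),
            len(result.blinks),
        )
        for i, rr in result.failures:
            log.warning("clip %d not analyzable: %s", i, rr)

        (out / "blinks.json").write_text(
            json.dumps(_candidate_rows(result.candidates, seq.fps), indent=2)
        )
        rows = []
        for i, b in enumerate(result.blinks):
            p = b.record.params
            rows.append(
                {
                    "blink": i,
                    "start_s": b.clip.source_span[0] / seq.fps,
                    "label": b.record.label,
                    **{k: p[k] for k in (
                        "total_duration_ms", "closing_ms", "closed_ms", "opening_ms",
                        "closed_ratio_pct", "closing_speed", "opening_speed",
                        "total_displacement", "min_displacement",
                    )},
                }
            )
            render_projection(b.matrix, str(out / f"blink_{i:03d}.png"))
            np.savetxt(
                out / f"blink_{i:03d}_matrix.csv", b.matrix.m, delimiter=",",
                header=f"fps={b.matrix.fps} norm_params={b.matrix.norm_params}",
            )
        pd.DataFrame(rows).to_csv(out / "parameters.csv", index=False)
        (out / "summary.json").write_text(json.dumps(result.summary, indent=2))
        cfg_yaml = cfg.to_yaml()
        manifest = {
            "blinkscope_version": __version__,
            "config": cfg.to_dict(),
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "input": str(video_path),
            "n_frames": len(seq),
            "fps": seq.fps,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
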