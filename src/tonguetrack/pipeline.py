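"""End-to-end pipeline: frames → contours → measurements → correlation.

The pipeline follows the acquisition-to-analysis order of the measurement
protocol: per vowel, the snake's initial points are selected once from the
frame with the largest oral cavity, every frame is tracked from those
points, frames whose snake fails to converge within the iteration budget
are skipped (too blurred), and the tracked contours are reduced to per-
frame TTCL/TBCL/LA and per-vowel summaries. Audio (synthetic vowels, or
user WAV files) yields formant summaries, and the articulatory means are
correlated with F1/F2 per gender.

All tabular outputs are UTF-8 CSV with headers and '.' decimals; rerunning
with the same inputs and seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import (FormantSettings, average_formants,
                        correlate_articulatory_acoustic)
from .articulatory import VOWELS, measure_parameters, summarize_frames
from .config import PipelineConfig
from .phantom import ARCHETYPES, generate_frame_sequence, synthesize_vowel
from .preprocess import cavity_area, preprocess_frame
from .snake import movable_points, run_snake
from .tables import load_formant_table

log = logging.getLogger("tonguetrack")

#: canonical formant targets (Hz) used when synthesizing phantom audio;
#: taken from the bundled published means so that phantom acoustics carry
#: realistic vowel structure
_SKIP_NON_CONVERGED = "snake_not_converged"


@dataclass
class RunReport:
    frames_processed: int
    frames_skipped: list[tuple[str, int, str]]
    outputs: dict[str, str]


def _track_vowel(vowel: str, cfg: PipelineConfig, seed: int):
    """Generate, preprocess and track one phantom vowel sequence."""
    from dataclasses import replace as _replace
    arch = ARCHETYPES[vowel]
    if cfg.noise_sd > 0:
        arch = _replace(arch, noise_sd=cfg.noise_sd)
    seq = generate_frame_sequence(arch, n_frames=cfg.n_frames,
                                  jitter=cfg.jitter, seed=seed,
                                  size=cfg.frame_size)
    # initial points once, from the frame with the largest oral cavity
    areas = [cavity_area(fr, truth.jaw_mask, cfg.preprocess)
             for fr, truth in seq]
    ref = int(np.argmax(areas))
    init = preprocess_frame(seq[ref][0], seq[ref][1].jaw_mask, cfg.preprocess)
    results = []
    for fr, truth in seq:
        res = run_snake(fr, init, cfg.snake)
        results.append((fr, truth, res))
    return results


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run the phantom-driven pipeline and write all outputs.

    Writes per-frame contour CSVs, a measurement CSV, a per-vowel summary
    CSV mirroring the published table layout, formant summaries and the
    articulatory–acoustic correlation report into ``cfg.output_dir``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    contour_rows, meas_rows, skipped = [], [], []
    summaries = []
    processed = 0
    for vowel in VOWELS:
        seed_v = int(rng.integers(0, 2 ** 31 - 1))
        values = {"TTCL": [], "TBCL": [], "LA": []}
        for fr, truth, res in _track_vowel(vowel, cfg, seed_v):
            if not res.converged:
                log.warning("skipping vowel %s frame %d: %s", vowel,
                            fr.frame_index, _SKIP_NON_CONVERGED)
                skipped.append((vowel, fr.frame_index, _SKIP_NON_CONVERGED))
                continue
            processed += 1
            pts = movable_points(res.state)
            for j, (r, c) in enumerate(pts):
                contour_rows.append({"vowel": vowel,
                                     "frame_index": fr.frame_index,
                                     "point_index": j,
                                     "x_px": int(c), "y_px": int(r),
                                     "movable": True})
            m = measure_parameters(pts.astype(float), truth.palate_trace,
                                   truth.upper_lip, truth.lower_lip,
                                   truth.plane, fr.resolution,
                                   distance_mode=cfg.articulatory.distance_mode,
                                   tip_fraction=cfg.articulatory.tip_fraction,
                                   frame_index=fr.frame_index)
            for param, val in (("TTCL", m.ttcl), ("TBCL", m.tbcl), ("LA", m.la)):
                values[param].append(val)
                meas_rows.append({"vowel": vowel, "gender": "phantom",
                                  "parameter": param,
                                  "frame": fr.frame_index,
                                  "value_mm": round(val, 4)})
        for param, vals in values.items():
            if vals:
                summaries.append(summarize_frames(vals, vowel, "phantom", param))

    contours_csv = out / "contours.csv"
    pd.DataFrame(contour_rows).to_csv(contours_csv, index=False)
    meas_csv = out / "measurements.csv"
    pd.DataFrame(meas_rows).to_csv(meas_csv, index=False)
    summary_csv = out / "summary.csv"
    summary_df = pd.DataFrame([{
        "vowel": s.vowel, "gender": s.gender, "parameter": s.parameter,
        "mean": round(s.mean, 4), "std": round(s.std, 4),
        "variance": round(s.variance, 4)} for s in summaries])
    summary_df.to_csv(summary_csv, index=False)

    # acoustics: synthesize each vowel at the published male formant targets,
    # then re-estimate and correlate against the measured articulation
    targets = load_formant_table(long=True)
    targets = targets[targets["gender"] == "M"].set_index("vowel")
    fs = FormantSettings(max_formant=cfg.acoustics.max_formant,
                         n_formants=cfg.acoustics.n_formants,
                         window=cfg.acoustics.window,
                         dyn_range=cfg.acoustics.dyn_range)
    formant_rows = []
    for vowel in VOWELS:
        f1, f2 = float(targets.loc[vowel, "f1"]), float(targets.loc[vowel, "f2"])
        seg = synthesize_vowel(120.0, [f1, f2, 2800.0], duration=0.5,
                               seed=cfg.seed)
        s = average_formants(seg, fs, vowel=vowel, gender="phantom")
        formant_rows.append({"vowel": vowel, "gender": "phantom",
                             "f1": round(s.f_mean[0], 2) if s.f_mean else float("nan"),
                             "f2": round(s.f_mean[1], 2) if len(s.f_mean) > 1 else float("nan"),
                             "n_points": s.n_points})
    formants_csv = out / "formants.csv"
    formants_df = pd.DataFrame(formant_rows)
    formants_df.to_csv(formants_csv, index=False)

    artic_means = summary_df[["vowel", "gender", "parameter", "mean"]]
    report_df = correlate_articulatory_acoustic(artic_means, formants_df)
    report_csv = out / "correlation.csv"
    report_df.to_csv(report_csv, index=False)

    run_json = out / "run_report.json"
    report = RunReport(frames_processed=processed, frames_skipped=skipped,
                       outputs={"contours": str(contours_csv),
                                "measurements": str(meas_csv),
                                "summary": str(summary_csv),
                                "formants": str(formants_csv),
                                "correlation": str(report_csv)})
    run_json.write_text(json.dumps(dataclasses.asdict(report), indent=2),
                        encoding="utf-8")
    return report


def correlate_tables() -> pd.DataFrame:
    """Correlation report computed from the bundled published tables only."""
    from .tables import articulation_means
    return correlate_articulatory_acoustic(articulation_means(),
                                           load_formant_table(long=True))
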