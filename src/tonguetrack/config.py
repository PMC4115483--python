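"""Flat key=value configuration for the end-to-end pipeline.

Config files are plain text, one ``key=value`` per line, ``#`` comments,
'.' decimal separator. Keys mirror the dataclass fields of the stage
configs, prefixed by stage, e.g.::

    preprocess.threshold_factor = 0.06
    snake.alpha = 1.2
    snake.max_iter = 200
    articulatory.distance_mode = trace
    acoustics.max_formant = 5000
    seed = 0

Unprefixed preprocessing keys (``threshold_factor=0.06``) are accepted as
a shorthand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .preprocess import PreprocessConfig
from .snake import SnakeConfig


@dataclass
class ArticulatoryConfig:
    distance_mode: str = "trace"
    tip_fraction: float = 0.5


@dataclass
class AcousticsConfig:
    max_formant: float = 5000.0
    n_formants: int = 5
    window: float = 0.025
    dyn_range: float = 30.0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    snake: SnakeConfig = field(default_factory=SnakeConfig)
    articulatory: ArticulatoryConfig = field(default_factory=ArticulatoryConfig)
    acoustics: AcousticsConfig = field(default_factory=AcousticsConfig)
    output_dir: str = "tonguetrack_out"
    seed: int = 0
    n_frames: int = 7
    jitter: float = 2.0
    frame_size: tuple[int, int] = (256, 256)
    noise_sd: float = 0.0
    log_level: str = "INFO"


_SNAKE_WEIGHT_KEYS = {"alpha", "beta", "gamma", "sigma"}
_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _coerce(current, raw: str):
    if isinstance(current, bool):
        return _BOOL[raw.strip().lower()]
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    if isinstance(current, tuple):
        parts = [p for p in raw.replace(",", " ").split() if p]
        return tuple(type(current[0])(p) for p in parts)
    return raw.strip()


def parse_config(text: str) -> PipelineConfig:
    """Parse a flat key=value config into a :class:`PipelineConfig`."""
    cfg = PipelineConfig()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key=value, got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        _assign(cfg, key, raw, lineno)
    return cfg


def _assign(cfg: PipelineConfig, key: str, raw: str, lineno: int) -> None:
    stage, _, name = key.partition(".")
    if not name:  # unprefixed
        name = stage
        for obj in (cfg, cfg.preprocess):
            if hasattr(obj, name):
                setattr(obj, name, _coerce(getattr(obj, name), raw))
                return
        if name in _SNAKE_WEIGHT_KEYS:
            w = cfg.snake.weights
            setattr(w, name, float(raw))
            return
        raise ValueError(f"line {lineno}: unknown key {key!r}")
    target = {"preprocess": cfg.preprocess, "snake": cfg.snake,
              "articulatory": cfg.articulatory,
              "acoustics": cfg.acoustics}.get(stage)
    if target is None:
        raise ValueError(f"line {lineno}: unknown section {stage!r}")
    if stage == "snake" and name in _SNAKE_WEIGHT_KEYS:
        setattr(target.weights, name, float(raw))
        return
    if not hasattr(target, name):
        raise ValueError(f"line {lineno}: unknown key {key!r}")
    setattr(target, name, _coerce(getattr(target, name), raw))


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    return parse_config(Path(path).read_text(encoding="utf-8"))
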