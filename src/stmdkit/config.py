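"""YAML configuration mirroring the published coefficient names.

Keys are the transliterated parameter names (``sigma1``, ``n1``, ``tau1``,
..., ``theta``, ``upsilon``, ``a``, ``lambda_``, ``sigma4``); unknown keys are
rejected with the offending key named so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .feedback import FeedbackConfig
from .pathway import PathwayConfig
from .pipeline import PipelineConfig
from .suppression import SuppressionConfig

__all__ = ["pipeline_config_from_dict", "load_config", "dump_config"]

_PATHWAY_KEYS = {
    "sigma1": "sigma1",
    "gaussian_size": "gaussian_size",
    "n1": "n1", "tau1": "tau1", "n2": "n2", "tau2": "tau2",
    "bandpass_length": "bandpass_length",
    "n3": "n3", "tau3": "tau3", "delay_length": "delay_length",
    "sigma2": "sigma2", "sigma3": "sigma3",
    "e": "e", "rho": "rho", "phi": "phi", "psi": "psi",
    "inhibition_size": "inhibition_size",
}
_FEEDBACK_KEYS = {
    "theta": "candidate_threshold",
    "upsilon": "range_threshold",
    "a": "gain",
    "sigma_f": "sigma_f",
    "assoc_radius": "assoc_radius",
    "grace": "grace",
    "window": "window",
    "nms_radius": "nms_radius",
}
_SUPPRESSION_KEYS = {
    "lambda_": "strength",
    "sigma4": "sigma4",
    "suppression_size": "size",
    "final_threshold": "final_threshold",
}
_TOP_KEYS = {"mode", "seed"}


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a flat name->value mapping."""
    pw: dict = {}
    fb: dict = {}
    sp: dict = {}
    top: dict = {}
    for key, value in d.items():
        if key in _PATHWAY_KEYS:
            pw[_PATHWAY_KEYS[key]] = value
        elif key in _FEEDBACK_KEYS:
            fb[_FEEDBACK_KEYS[key]] = value
        elif key in _SUPPRESSION_KEYS:
            sp[_SUPPRESSION_KEYS[key]] = value
        elif key in _TOP_KEYS:
            top[key] = value
        else:
            raise KeyError(f"unknown configuration key: {key!r}")
    return PipelineConfig(
        pathway=PathwayConfig(**pw),
        feedback=FeedbackConfig(**fb),
        suppression=SuppressionConfig(**sp),
        **top,
    )


def load_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(d, dict):
        raise ValueError(f"config root must be a mapping, got {type(d).__name__}")
    return pipeline_config_from_dict(d)


def dump_config(cfg: PipelineConfig) -> dict:
    """Flat dict of a PipelineConfig with the published parameter names."""
    inv = {}
    for ext, internal in _PATHWAY_KEYS.items():
        inv[ext] = getattr(cfg.pathway, internal)
    for ext, internal in _FEEDBACK_KEYS.items():
        inv[ext] = getattr(cfg.feedback, internal)
    for ext, internal in _SUPPRESSION_KEYS.items():
        inv[ext] = getattr(cfg.suppression, internal)
    inv["mode"] = cfg.mode
    inv["seed"] = cfg.seed
    return inv
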