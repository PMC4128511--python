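"""YAML configuration: extension modifiers, compatibility weights, defaults.

Example::

    extensions:
      joined: positive
    compatibility:
      - [up, moderately_up, 0.5]
    propagation_mode: sound
    measure: bma
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .profiles import QualityVocabulary
from .propagation import MODES, SOUND
from .similarity import CompatibilityTable, default_compatibility


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a YAML mapping")
    return data


def vocabulary_from_config(cfg: dict[str, Any]) -> QualityVocabulary:
    ext = cfg.get("extensions")
    if ext is None:
        return QualityVocabulary()
    if not isinstance(ext, dict):
        raise ValueError("'extensions' must map modifier name -> polarity")
    return QualityVocabulary(extensions=ext)


def compatibility_from_config(cfg: dict[str, Any],
                              vocab: QualityVocabulary) -> CompatibilityTable:
    rows = cfg.get("compatibility")
    overrides = {}
    if rows is not None:
        for row in rows:
            if not (isinstance(row, (list, tuple)) and len(row) == 3):
                raise ValueError("'compatibility' entries must be [q1, q2, weight]")
            q1, q2, w = row
            overrides[(str(q1), str(q2))] = float(w)
    return default_compatibility(vocab, overrides=overrides or None)


def mode_from_config(cfg: dict[str, Any]) -> str:
    mode = cfg.get("propagation_mode", SOUND)
    if mode not in MODES:
        raise ValueError(f"propagation_mode must be one of {MODES}")
    return mode
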