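"""Shipped parameter profiles and config-file loading.

The package ships one profile, named after the study system
(``trypsin_bpti``), which collects every default the analyses use: the
reference-point residue ranges, the biased-dissociation protocol values,
the calibrated toy-landscape constants, the state thresholds, interaction
criteria and the umbrella schedule.  User config files for the pipeline are
plain YAML with per-stage blocks; anything absent falls back to the
profile.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from pathlib import Path

import yaml

logger = logging.getLogger("prebound")

DEFAULT_PROFILE = "trypsin_bpti"


def load_profile(name: str = DEFAULT_PROFILE) -> dict:
    """Load a packaged parameter profile by name."""
    ref = resources.files("prebound") / "profiles" / f"{name}.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return config


def config_hash(config: dict) -> str:
    """Stable hash of a config mapping (canonical YAML, sha256)."""
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
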