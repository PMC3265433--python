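"""Configuration defaults, YAML loading and validation.

All tunable parameters of the analysis live in a single nested dictionary.
A user YAML file overrides defaults key-by-key (deep merge); modules read
their own section and validate the values they consume.
"""
from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent configuration values."""


#: Default configuration. Units are embedded in key names where ambiguous.
DEFAULTS: dict[str, Any] = {
    # LGA softness classification bands on the E/C ratio (mm^2).
    # Each band is [label, lower_edge]; bands are closed on the lower edge and
    # must be listed with strictly decreasing edges. A ratio exactly on an
    # edge belongs to the softer (higher-ratio) band.
    "lga": {
        "bands": [["soft", 2000.0], ["medium", 1000.0], ["firm", 0.0]],
    },
    "body": {
        "preset": "HTM",
        # Mass and length fractions of the six lateral-lying segments
        # (head, shoulder/thorax, waist, pelvis, thigh, leg). Documented
        # modelling assumptions; overridable per subject.
        "mass_fractions": {
            "head": 0.08, "shoulder": 0.32, "waist": 0.12,
            "pelvis": 0.26, "thigh": 0.14, "leg": 0.08,
        },
        "extent_fractions": {
            "head": 0.15, "shoulder": 0.20, "waist": 0.10,
            "pelvis": 0.10, "thigh": 0.25, "leg": 0.20,
        },
        # Lateral half-widths (spine midline to mattress contact, mm).
        # pelvis = shoulder / shoulder_pelvis_ratio so the preset's width
        # ratio is realized exactly; waist = waist_to_pelvis * pelvis.
        "half_widths_mm": {"head": 90.0, "shoulder": 210.0, "thigh": 130.0, "leg": 85.0},
        "waist_to_pelvis": 0.95,
        # Fraction of the pelvis extent (cranial side) spanned by the
        # lumbar spine down to L5.
        "l5_pelvis_fraction": 0.3,
        # Posture constants recorded as metadata (lateral lying protocol).
        "trunk_angle_deg": 135.0,
        "knee_flexion_deg": 90.0,
    },
    "bed": {
        "n_zones": 6,
        "block_height_mm": 200.0,
        "block_width_mm": 1000.0,
        "block_length_mm": 100.0,
        # Foam densification stand-in: sag saturates at this fraction of
        # the block height.
        "max_compression_frac": 0.8,
        # Uniform-bed stiffness regimes (N/mm per block).
        "soft_stiffness": 2.0,
        "firm_stiffness": 100.0,
        # Zone-stiffness optimization: manufacturable spring range per block.
        "bounds": [2.0, 20.0],
        "coupling": 2.0,
        "tol_deg": 1.0e-4,
        "max_sweeps": 25,
    },
    "cohort": {
        "n_subjects": 25,
        "preset_mix": {"HTM": 0.25, "HSM": 0.25, "LTM": 0.25, "LSM": 0.25},
        "marker_noise_sd_mm": 2.0,
        "jitter_sd": 0.05,
        "repeats": 2,
    },
    "stats": {
        "alpha": 0.05,
        "strict_alpha": 0.001,
        "levene_center": "mean",
    },
    "imaging": {
        "intensity_threshold": 0.5,
        "min_area_px": 4,
        "ref_margin_mm": 30.0,
        "scale_mm_per_px": 2.0,
        "marker_radius_px": 4,
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_config() -> dict:
    """A fresh deep copy of the default configuration."""
    return copy.deepcopy(DEFAULTS)


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict:
    """Load configuration: defaults <- YAML file <- explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration for provenance records."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
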