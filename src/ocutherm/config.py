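"""Structured configuration: schema, validation and canonical hashing.

Configs are plain nested dicts (YAML on disk) with up to three sections —
``visco``, ``acoustic``, ``bioheat`` — whose keys mirror the simulation
parameter tables.  Validation collects *all* schema violations before
raising, so a bad file is reported in one pass.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["load_config", "validate_config", "dump_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


# key -> (required, predicate, description)
_POS = (lambda v: isinstance(v, (int, float)) and v > 0, "a positive number")
_NONNEG = (lambda v: isinstance(v, (int, float)) and v >= 0, "a nonnegative number")
_FRAC = (lambda v: isinstance(v, (int, float)) and 0 < v <= 1, "a number in (0, 1]")
_UNIT = (lambda v: isinstance(v, (int, float)) and 0 <= v <= 1, "a number in [0, 1]")
_POSINT = (lambda v: isinstance(v, int) and v >= 1, "an integer >= 1")
_STR = (lambda v: isinstance(v, str), "a string")

_VISCO_KEYS = {
    "model_kind": _STR,
    "load_kind": _STR,
    "excitation_frequency_hz": _NONNEG,
    "cycles_per_burst": _POSINT,
    "window_fraction": _FRAC,
    "applied_load_pa": _POS,
    "duration_s": _POS,
    "youngs_modulus_pa": _POS,
    "viscosity_pa_s": _POS,
    "tear_film_pa": _NONNEG,
    "iop_pa": _NONNEG,
    "dt_s": _POS,
    "mode": _STR,
}
_VISCO_REQUIRED = {
    "model_kind",
    "load_kind",
    "applied_load_pa",
    "duration_s",
    "youngs_modulus_pa",
    "viscosity_pa_s",
}

_ACOUSTIC_KEYS = {
    "aperture_radius_m": _POS,
    "curvature_radius_m": _POS,
    "frequency_hz": _POS,
    "surface_velocity_m_s": _POS,
    "standoff_m": _POS,
    "density_kg_m3": _POS,
    "sound_speed_m_s": _POS,
}
_ACOUSTIC_REQUIRED = {"aperture_radius_m", "frequency_hz"}

_BIOHEAT_SCALAR_KEYS = {
    "C_t": _POS,
    "k": _POS,
    "W_b": _NONNEG,
    "T_a": (lambda v: isinstance(v, (int, float)), "a number"),
    "Q_m": _NONNEG,
    "h_c": _NONNEG,
    "T_amb": (lambda v: isinstance(v, (int, float)), "a number"),
    "emissivity": _UNIT,
    "duty": _UNIT,
    "t_end_s": _POS,
    "dt_s": _POS,
    "far_boundary": _STR,
    "target_peak_dT_C": _POS,
}
_LAYER_KEYS = {
    "name": _STR,
    "thickness_m": _POS,
    "rho_kg_m3": _POS,
    "C_J_kgK": _POS,
    "k_W_mK": _POS,
    "W_b": _NONNEG,
    "alpha_np_m": _NONNEG,
    "c_sound_m_s": _POS,
}


def _check_section(name, section, schema, required, errors):
    if not isinstance(section, dict):
        errors.append(f"{name}: section must be a mapping")
        return
    for key in sorted(set(section) - set(schema)):
        errors.append(f"{name}.{key}: unknown key")
    for key in sorted(required - set(section)):
        errors.append(f"{name}.{key}: required key missing")
    for key, value in section.items():
        if key in schema:
            pred, desc = schema[key]
            if not pred(value):
                errors.append(f"{name}.{key}: must be {desc}, got {value!r}")


def validate_config(cfg: dict, require: tuple[str, ...] = ()) -> dict:
    """Validate a config dict, raising ConfigError with every violation.

    ``require`` names sections that must be present (e.g. a thermal command
    requires the ``bioheat`` block).
    """
    errors: list[str] = []
    if not isinstance(cfg, dict):
        raise ConfigError(["top level must be a mapping"])
    known = {"name", "visco", "acoustic", "bioheat"}
    for key in sorted(set(cfg) - known):
        errors.append(f"{key}: unknown top-level section")
    for sec in require:
        if sec not in cfg:
            errors.append(f"{sec}: section required for this command but missing")
    if "visco" in cfg:
        _check_section("visco", cfg["visco"], _VISCO_KEYS, _VISCO_REQUIRED, errors)
        v = cfg["visco"]
        if isinstance(v, dict) and v.get("load_kind") == "sinusoidal_burst":
            for key in ("excitation_frequency_hz", "cycles_per_burst"):
                if key not in v:
                    errors.append(f"visco.{key}: required for burst loads")
    if "acoustic" in cfg:
        _check_section("acoustic", cfg["acoustic"], _ACOUSTIC_KEYS, _ACOUSTIC_REQUIRED, errors)
    if "bioheat" in cfg:
        b = cfg["bioheat"]
        if not isinstance(b, dict):
            errors.append("bioheat: section must be a mapping")
        else:
            scalar = {k: v for k, v in b.items() if k != "layers"}
            _check_section("bioheat", scalar, _BIOHEAT_SCALAR_KEYS, set(), errors)
            layers = b.get("layers")
            if layers is not None:
                if not isinstance(layers, list) or not layers:
                    errors.append("bioheat.layers: must be a nonempty list")
                else:
                    for i, layer in enumerate(layers):
                        _check_section(
                            f"bioheat.layers[{i}]",
                            layer,
                            _LAYER_KEYS,
                            {"name", "thickness_m"},
                            errors,
                        )
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path, require: tuple[str, ...] = ()) -> dict:
    """Read and validate a YAML config file."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg, require=require)


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
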