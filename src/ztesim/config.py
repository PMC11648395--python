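"""YAML experiment configuration with a small validated schema.

All physical quantities use SI units: meters, seconds, T/m, Hz; the flip
angle is given in degrees (``flip_deg``) as on the scanner console.  Every
run is pure with respect to (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .physics import PhysicsConstants, PointOfInterest, PulseParams

__all__ = ["ConfigError", "ExperimentConfig", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid configuration; the message lists the offending keys."""


_PHANTOM_KEYS = {"kind", "shape", "fov_m", "radius_m", "center_m", "r0_m", "theta0_rad",
                 "amplitude", "antialias"}
_TRAJ_KEYS = {"n_spokes", "g_mag_t_per_m", "dead_time_s", "dwell_s", "te_s",
              "acceleration", "full_circle", "matrix"}
_PULSE_KEYS = {"tau_s", "flip_deg", "asymmetry", "nco_granularity_s"}
_SCHEME_KEYS = {"mode", "poi_m"}
_RECON_KEYS = {"oversampling", "kernel_width", "dcf_mode", "hamming", "shift_m"}
_TOP_KEYS = {"schema_version", "phantom", "trajectory", "pulse", "scheme", "recon",
             "metrics_segments", "gamma_bar_hz_per_t", "noise_sigma", "seed",
             "angles", "g_mag_list_t_per_m", "offsets_m"}


def _check_keys(section: str, d: dict, allowed: set) -> None:
    unknown = sorted(set(d) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {section}: {', '.join(unknown)}")


@dataclass
class ExperimentConfig:
    """Validated experiment description used by the CLI and the demos."""

    raw: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    pulse: PulseParams = field(default_factory=PulseParams)
    scheme_mode: str = "isocenter"
    poi: PointOfInterest | None = None
    recon: dict = field(default_factory=dict)
    metrics_segments: list = field(default_factory=list)
    constants: PhysicsConstants = field(default_factory=PhysicsConstants)
    noise_sigma: float = 0.0
    seed: int = 0
    angles: int = 180
    g_mag_list: list = field(default_factory=lambda: [0.020, 0.030])
    offsets: list = field(default_factory=lambda: [0.0, 0.05, 0.10])


def _build(d: dict) -> ExperimentConfig:
    _check_keys("top level", d, _TOP_KEYS)
    version = d.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version: {version}")

    cfg = ExperimentConfig(raw=d)

    ph = dict(d.get("phantom", {}))
    _check_keys("phantom", ph, _PHANTOM_KEYS)
    cfg.phantom = ph

    tr = dict(d.get("trajectory", {}))
    _check_keys("trajectory", tr, _TRAJ_KEYS)
    cfg.trajectory = tr

    pu = dict(d.get("pulse", {}))
    _check_keys("pulse", pu, _PULSE_KEYS)
    try:
        cfg.pulse = PulseParams(
            duration_tau=float(pu.get("tau_s", 8e-6)),
            flip_angle_alpha=math.radians(float(pu.get("flip_deg", 3.0))),
            asymmetry=float(pu.get("asymmetry", 0.53)),
            nco_granularity=float(pu.get("nco_granularity_s", 20e-6)),
        )
    except ValueError as e:
        raise ConfigError(f"pulse: {e}") from e

    sc = dict(d.get("scheme", {}))
    _check_keys("scheme", sc, _SCHEME_KEYS)
    cfg.scheme_mode = sc.get("mode", "isocenter")
    if cfg.scheme_mode not in ("ideal", "isocenter", "offcenter"):
        raise ConfigError(f"scheme.mode: unknown mode {cfg.scheme_mode!r}")
    if "poi_m" in sc:
        cfg.poi = PointOfInterest.from_array(sc["poi_m"])
    if cfg.scheme_mode == "offcenter" and cfg.poi is None:
        raise ConfigError("scheme: offcenter mode requires poi_m")

    rc = dict(d.get("recon", {}))
    _check_keys("recon", rc, _RECON_KEYS)
    cfg.recon = rc

    segs = d.get("metrics_segments", [])
    for i, seg in enumerate(segs):
        if not (isinstance(seg, dict) and "p0" in seg and "p1" in seg):
            raise ConfigError(f"metrics_segments[{i}]: each segment needs p0 and p1")
    cfg.metrics_segments = [(s["p0"], s["p1"]) for s in segs]

    try:
        cfg.constants = PhysicsConstants(
            gamma_bar=float(d.get("gamma_bar_hz_per_t", 42.577e6))
        )
    except ValueError as e:
        raise ConfigError(f"gamma_bar_hz_per_t: {e}") from e
    cfg.noise_sigma = float(d.get("noise_sigma", 0.0))
    cfg.seed = int(d.get("seed", 0))
    cfg.angles = int(d.get("angles", 180))
    cfg.g_mag_list = [float(g) for g in d.get("g_mag_list_t_per_m", [0.020, 0.030])]
    cfg.offsets = [float(x) for x in d.get("offsets_m", [0.0, 0.05, 0.10])]
    return cfg


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load and validate a YAML config; ``overrides`` update the raw mapping
    (shallow per top-level section) before validation."""
    d: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        d = loaded
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict) and isinstance(d.get(k), dict):
                d[k] = {**d[k], **v}
            else:
                d[k] = v
    return _build(d)
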