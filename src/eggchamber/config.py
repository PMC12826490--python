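"""Configuration loading, validation, packaged fixtures, presets and run
manifests.

All user-facing configuration is in the measurement units of the model
(µm, hours, mol); any internal rescaling is invisible here.  The packaged
fixtures are the staged egg-chamber dimension table and the kinetic
parameter set; both can be overridden from a YAML config file whose keys
are validated strictly (unknown keys are errors, out-of-range values of
parameters with published ranges produce warnings).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .geometry import GeometryTimeline
from .kinetics import KineticParams
from .simulator import Perturbations, SimulationConfig
from .source import SourceSpec

logger = logging.getLogger(__name__)

__all__ = [
    "load_config",
    "load_params",
    "default_config",
    "packaged_stage_table_path",
    "packaged_params_path",
    "verify_fixtures",
    "RunManifest",
    "PRESETS",
    "run_preset",
]

#: pinned digests of the packaged fixtures (tests fail if they are edited)
STAGE_TABLE_SHA256 = "b33f0e20f7f009f48ae97a16dfee6780fc863a61881d01d536e2b6e5dc8fc7d8"
PARAMS_SHA256 = "75bf8c6ee027f730d8fb7fa5b00c8507e6abf48c821ec3b05579bd8b846991f9"

#: published ranges for parameters given as ranges in the literature table
PARAM_RANGES = {
    "D": (36.0, 360000.0),
    "k_on": (6.0e22, 6.0e25),
    "k_er": (0.6, 6.0),
    "alpha_rec": (0.45, 0.7),
    "alpha_deg": (0.3, 0.55),
}

_PARAM_KEYS = {
    "D", "k_ec", "k_on", "k_off", "R0", "k_er", "alpha_rec", "alpha_deg",
    "k_rec", "k_deg", "k_d", "V0", "Q_r", "k_s", "H", "gamma_STY",
    "gamma_KEK1", "K", "K_prime", "k_STY", "k_dSTY", "k_KEK1", "k_dKEK1",
    "receptor_binding_sign",
}
_SOURCE_KEYS = {
    "V0", "ratio_dorsal_length", "ratio_posterior_width",
    "ratio_anterior_width", "band_meridian_frac", "reference_time",
}
_PERTURBATION_KEYS = {
    "nucleus_stop_time", "growth_stop_time", "fc_shift_enabled",
    "sty_fraction", "egfr_fraction", "grk_multiplier", "gamma_sty_zero_after",
}
_TOP_KEYS = {"mesh", "time", "params", "source", "perturbations", "geometry"}


class ConfigError(ValueError):
    """Malformed or invalid configuration."""


def packaged_stage_table_path() -> Path:
    return Path(resources.files("eggchamber.data") / "stage_dimensions.csv")


def packaged_params_path() -> Path:
    return Path(resources.files("eggchamber.data") / "kinetic_params.yaml")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def verify_fixtures() -> None:
    """Raise if a packaged fixture was modified."""
    if file_sha256(packaged_stage_table_path()) != STAGE_TABLE_SHA256:
        raise ConfigError("packaged stage-dimension table was modified")
    if file_sha256(packaged_params_path()) != PARAMS_SHA256:
        raise ConfigError("packaged kinetic-parameter file was modified")


def _check_keys(section: Optional[dict], allowed, where: str) -> dict:
    section = section or {}
    if not isinstance(section, dict):
        raise ConfigError(f"config section '{where}' must be a mapping")
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown keys in '{where}': {sorted(unknown)}")
    return section


def load_params(overrides: Optional[dict] = None) -> KineticParams:
    """Kinetic parameters: packaged defaults overlaid with overrides."""
    with open(packaged_params_path()) as fh:
        base = yaml.safe_load(fh)
    base.update(_check_keys(overrides, _PARAM_KEYS, "params"))
    params = KineticParams(**base)
    for key, (lo, hi) in PARAM_RANGES.items():
        v = getattr(params, key)
        if not (lo - 1e-12 <= v <= hi + 1e-12):
            logger.warning(
                "parameter %s = %g lies outside the published range [%g, %g]",
                key, v, lo, hi,
            )
    return params


def default_config(**kwargs) -> SimulationConfig:
    """Fully-defaulted configuration (packaged tables, wild type)."""
    cfg = SimulationConfig(
        timeline=GeometryTimeline.from_csv(packaged_stage_table_path()),
        params=load_params(),
        source=SourceSpec(),
    )
    return replace(cfg, **kwargs) if kwargs else cfg


def load_config(path: Optional[str] = None) -> SimulationConfig:
    """Load a simulation configuration from YAML (or the full defaults)."""
    if path is None:
        return default_config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

    geom = _check_keys(raw.get("geometry"), {"stage_table"}, "geometry")
    table = geom.get("stage_table", packaged_stage_table_path())
    timeline = GeometryTimeline.from_csv(table)

    params = load_params(raw.get("params"))

    src = _check_keys(raw.get("source"), _SOURCE_KEYS, "source")
    src.setdefault("V0", params.V0)
    source = SourceSpec(**src)

    mesh_sec = _check_keys(raw.get("mesh"), {"n"}, "mesh")
    time_sec = _check_keys(
        raw.get("time"),
        {"dt", "geometry_update_interval", "safety", "output_times", "t_end"},
        "time",
    )
    pert_sec = _check_keys(raw.get("perturbations"), _PERTURBATION_KEYS, "perturbations")

    return SimulationConfig(
        timeline=timeline,
        params=params,
        source=source,
        n=int(mesh_sec.get("n", 32)),
        dt=float(time_sec.get("dt", 5e-4)),
        geometry_update_interval=float(time_sec.get("geometry_update_interval", 0.05)),
        safety=float(time_sec.get("safety", 0.9)),
        output_times=time_sec.get("output_times"),
        t_end=time_sec.get("t_end"),
        perturbations=Perturbations(**pert_sec),
    )


# -- run manifest ----------------------------------------------------------

@dataclass
class RunManifest:
    """Record sufficient to reproduce a run bit-for-bit."""

    version: str
    timestamp: str
    config: dict
    input_digests: Dict[str, str]
    outputs: List[str]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _config_as_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["timeline"] = {
        "stages": [asdict(s) for s in config.timeline.stages],
        "anchor_time": config.timeline.anchor_time,
        "growth_stop_time": config.timeline.growth_stop_time,
        "nucleus_stop_time": config.timeline.nucleus_stop_time,
    }
    return d


def build_manifest(config: SimulationConfig, outputs: Optional[List[str]] = None,
                   extra_inputs: Optional[Dict[str, str]] = None) -> RunManifest:
    digests = {
        "stage_dimensions.csv": file_sha256(packaged_stage_table_path()),
        "kinetic_params.yaml": file_sha256(packaged_params_path()),
    }
    digests.update(extra_inputs or {})
    return RunManifest(
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config=_config_as_dict(config),
        input_digests=digests,
        outputs=list(outputs or []),
    )


# -- presets ---------------------------------------------------------------

PRESETS: Dict[str, Perturbations] = {
    "wt": Perturbations(),
    "nucleus-stop": Perturbations(nucleus_stop_time=10.5),
    "no-fc-shift": Perturbations(fc_shift_enabled=False),
    "growth-stop": Perturbations(growth_stop_time=10.5),
    "sty-rnai": Perturbations(sty_fraction=0.5),
    "egfr-rnai": Perturbations(egfr_fraction=0.5),
    "grk-1x": Perturbations(grk_multiplier=0.5),
    "grk-4x": Perturbations(grk_multiplier=2.0),
}

#: normalized dpERK threshold used for the elongation metric of the
#: perturbation figure
ELONGATION_THRESHOLD = 0.6
#: stage times reported in the perturbation metrics table
METRIC_MAX_TIMES = (10.5, 16.5, 19.5)
METRIC_ELONGATION_TIMES = (16.5, 19.5)


def run_preset(name: str, config: Optional[SimulationConfig] = None,
               wt_result=None):
    """Execute a named perturbation experiment and compute the metrics
    table (maximum dpERK per stage; elongation at S9/S10A in µm and %WT).

    Returns (result, metrics DataFrame).  The wild-type run used for the
    normalization can be passed to avoid recomputation.
    """
    import pandas as pd

    from .analysis import elongation, max_signal, stage_label
    from .simulator import run

    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    base = config if config is not None else default_config()
    result = run(replace(base, perturbations=PRESETS[name]))
    if name == "wt":
        wt = result
    elif wt_result is not None:
        wt = wt_result
    else:
        wt = run(replace(base, perturbations=PRESETS["wt"]))

    rows = []
    out_times = base.resolved_output_times()
    for t in METRIC_MAX_TIMES:
        if t in out_times:
            rows.append(
                {"metric": "max_dpERK", "stage": stage_label(t), "time_hr": t,
                 "value": max_signal(result, t),
                 "percent_wt": 100.0 * max_signal(result, t) / max(max_signal(wt, t), 1e-300)}
            )
    for t in METRIC_ELONGATION_TIMES:
        if t in out_times:
            e = elongation(result, t, ELONGATION_THRESHOLD,
                           reference_max=max_signal(wt, t))
            e_wt = elongation(wt, t, ELONGATION_THRESHOLD,
                              reference_max=max_signal(wt, t))
            rows.append(
                {"metric": "elongation_um", "stage": stage_label(t), "time_hr": t,
                 "value": e, "percent_wt": 100.0 * e / max(e_wt, 1e-300)}
            )
    return result, pd.DataFrame(rows)
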