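"""Model/results facade over the simulation and calibration machinery.

``EggChamberModel`` bundles a full simulation configuration; ``simulate``
runs the forward model (optionally under a named perturbation preset) and
``fit`` calibrates the two inhibitor strengths against reference intensity
curves, returning an ``EggChamberFit`` with the estimates, the error
surface and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence

import pandas as pd

from .analysis import CalibrationOutcome, calibrate_gammas, depletion_scan
from .simulator import Perturbations, SimulationConfig, SimulationResult, run

__all__ = ["EggChamberModel", "EggChamberFit"]


class EggChamberModel:
    """The egg-chamber signaling model with a fixed configuration."""

    def __init__(self, config: SimulationConfig):
        self.config = config

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_defaults(cls, **overrides) -> "EggChamberModel":
        from .config import default_config

        return cls(default_config(**overrides))

    @classmethod
    def from_config_file(cls, path) -> "EggChamberModel":
        from .config import load_config

        return cls(load_config(path))

    # -- forward simulation ----------------------------------------------
    def simulate(self, preset: Optional[str] = None,
                 perturbations: Optional[Perturbations] = None) -> SimulationResult:
        cfg = self.config
        if preset is not None:
            from .config import PRESETS, ConfigError

            if preset not in PRESETS:
                raise ConfigError(f"unknown preset {preset!r}")
            cfg = replace(cfg, perturbations=PRESETS[preset])
        elif perturbations is not None:
            cfg = replace(cfg, perturbations=perturbations)
        return run(cfg)

    # -- calibration ------------------------------------------------------
    def fit(
        self,
        ref_curves: Dict[float, pd.DataFrame],
        grid_sty: Sequence[float],
        grid_kek: Sequence[float],
        dosages: Sequence[float] = (0.5, 1.0, 2.0),
        sim_cache: Optional[Dict] = None,
    ) -> "EggChamberFit":
        """Grid calibration of (gamma_STY, gamma_KEK1) against AP/DV
        reference intensity curves at three grk dosages."""
        outcome = calibrate_gammas(
            self.config, grid_sty, grid_kek, ref_curves,
            dosages=dosages, sim_cache=sim_cache,
        )
        return EggChamberFit(model=self, outcome=outcome)

    def fit_depletion(self, target: str, ref_curves: pd.DataFrame,
                      fractions=(0.25, 0.5, 0.75), normalize: bool = True):
        return depletion_scan(self.config, target, ref_curves,
                              fractions=fractions, normalize=normalize)


@dataclass
class EggChamberFit:
    """Calibration result: inhibitor-strength estimates and diagnostics."""

    model: EggChamberModel
    outcome: CalibrationOutcome

    @property
    def params(self) -> Dict[str, float]:
        return {
            "gamma_STY": self.outcome.gamma_STY,
            "gamma_KEK1": self.outcome.gamma_KEK1,
        }

    @property
    def error_surface(self) -> pd.DataFrame:
        return self.outcome.error_surface

    def calibrated_model(self) -> EggChamberModel:
        """Model with the fitted inhibitor strengths installed (K and K'
        stay at their configured values, matching the calibration)."""
        p = replace(
            self.model.config.params.resolve(),
            gamma_STY=self.outcome.gamma_STY,
            gamma_KEK1=self.outcome.gamma_KEK1,
        )
        return EggChamberModel(replace(self.model.config, params=p))

    def summary(self) -> str:
        s = self.outcome
        lines = [
            "Egg-chamber EGFR signaling model - inhibitor calibration",
            "=" * 56,
            f"grid points evaluated : {len(s.error_surface)}",
            f"summed L1 rel. error  : {s.best_error:.4g}",
            f"gamma_STY  (Sprouty)  : {s.gamma_STY:g}",
            f"gamma_KEK1 (Kekkon1)  : {s.gamma_KEK1:g}",
            "",
            "error surface:",
            s.error_surface.to_string(index=False),
        ]
        return "\n".join(lines)

    # convenience passthroughs for downstream metrics
    def simulate(self, **kwargs) -> SimulationResult:
        return self.calibrated_model().simulate(**kwargs)
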