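"""Local reaction system: EGFR ligand-receptor trafficking with STY/KEK1
negative feedback.

Seven species live on the follicle-cell surface (surface densities,
mol µm^-2): free ligand L in the perivitelline space, free receptors R,
surface complexes C, internalized complexes Ci, signal S (dpERK), and the
inhibitors STY (Sprouty) and KEK1 (Kekkon1).  Binding converts L + R to C at
the KEK1-inhibited rate k̄_on; C internalizes to Ci (k_ec) or dissociates
(k_off); Ci is recycled (fraction alpha_rec at k_rec) or degraded (fraction
alpha_deg at k_deg); Ci drives signal production at the STY-inhibited rate
k̄_s; S decays at k_d and induces both inhibitors.

The feedback rates are

    k̄_on = k_on / (1 + gamma_KEK1 * KEK1 / K),
    k̄_s  = k_s  / (1 + gamma_STY  * STY  / K'),

so K and K' set the inhibitor scale at which feedback becomes strong.  By
default they are derived as the self-consistent steady-state inhibitor
scales of the wild-type working point (see ``KineticParams.resolve``), which
makes gamma the fold-reduction of the corresponding rate there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np

logger = logging.getLogger(__name__)

SPECIES = ("L", "C", "Ci", "R", "S", "STY", "KEK1")

__all__ = [
    "SPECIES",
    "KineticParams",
    "effective_rates",
    "reaction_rhs",
    "depletion_variant",
]


@dataclass(frozen=True)
class KineticParams:
    """All rate constants; units µm, hr, mol (see the packaged parameter
    file for provenance and published ranges)."""

    D: float = 3600.0
    k_ec: float = 6.0
    k_on: float = 6.0e23
    k_off: float = 6.0
    R0: float = 6.7e-22
    k_er: float = 0.6
    alpha_rec: float = 0.7
    alpha_deg: float = 0.3
    k_rec: float = 2.3
    k_deg: float = 2.3
    k_d: float = 2.3
    V0: float = 2.0e-21
    Q_r: float = 4.0e-22
    k_s: float = 1.0
    H: float = 0.5
    gamma_STY: float = 5.0e4
    gamma_KEK1: float = 1.0e3
    K: float = None
    K_prime: float = None
    k_STY: float = 1.0
    k_dSTY: float = 2.3
    k_KEK1: float = 1.0
    k_dKEK1: float = 2.3
    receptor_binding_sign: float = -1.0

    def __post_init__(self):
        for name in (
            "D", "k_ec", "k_on", "k_off", "R0", "k_er", "k_rec", "k_deg",
            "k_d", "V0", "Q_r", "k_s", "k_STY", "k_dSTY", "k_KEK1", "k_dKEK1",
            "gamma_STY", "gamma_KEK1",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be nonnegative")
        if self.H <= 0:
            raise ValueError("perivitelline thickness H must be positive")
        frac_sum = self.alpha_rec + self.alpha_deg
        if frac_sum > 1.25:
            raise ValueError("alpha_rec + alpha_deg too large")
        if abs(frac_sum - 1.0) > 1e-9:
            logger.warning(
                "alpha_rec + alpha_deg = %.3f differs from 1; internalized "
                "complexes are not fully partitioned", frac_sum,
            )

    def resolve(self) -> "KineticParams":
        """Fill derived feedback normalizations when unset.

        Reference scales at the wild-type working point: the secreted flux
        V0 must be disposed by degradation, Ci_ref = V0/(alpha_deg k_deg);
        the STY feedback then fixes the self-consistent signal scale
        S_ref = k_s Ci_ref / (k_d (1 + gamma_STY)); K and K' are the
        steady-state inhibitor levels at S_ref.
        """
        if self.K is not None and self.K_prime is not None:
            return self
        ci_ref = self.V0 / max(self.alpha_deg * self.k_deg, 1e-300)
        s_ref = self.k_s * ci_ref / max(self.k_d * (1.0 + self.gamma_STY), 1e-300)
        K = self.K
        Kp = self.K_prime
        if K is None:
            K = self.k_KEK1 / max(self.k_dKEK1, 1e-300) * s_ref
        if Kp is None:
            Kp = self.k_STY / max(self.k_dSTY, 1e-300) * s_ref
        # degenerate parameter sets (zero production chains) leave no
        # inhibitor scale; fall back to the receptor scale to stay finite
        if K is None or K <= 0:
            K = self.R0
        if Kp is None or Kp <= 0:
            Kp = self.R0
        return replace(self, K=K, K_prime=Kp)


def effective_rates(params: KineticParams, STY, KEK1) -> Tuple[np.ndarray, np.ndarray]:
    """Inhibitor-reduced binding and signal-production rates
    (k̄_on, k̄_s)."""
    STY = np.asarray(STY, dtype=float)
    KEK1 = np.asarray(KEK1, dtype=float)
    if np.any(STY < 0) or np.any(KEK1 < 0):
        raise ValueError("inhibitor concentrations must be nonnegative")
    p = params.resolve()
    k_on_bar = p.k_on / (1.0 + p.gamma_KEK1 * KEK1 / p.K)
    k_s_bar = p.k_s / (1.0 + p.gamma_STY * STY / p.K_prime)
    return k_on_bar, k_s_bar


def reaction_rhs(params: KineticParams, state: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Time derivatives of the reaction part (no transport, no source).

    ``state`` maps species names to arrays (or scalars); the result has the
    same keys and shapes.
    """
    p = params.resolve()
    L, C, Ci, R, S = (np.asarray(state[k], dtype=float) for k in ("L", "C", "Ci", "R", "S"))
    STY = np.asarray(state["STY"], dtype=float)
    KEK1 = np.asarray(state["KEK1"], dtype=float)
    k_on_bar, k_s_bar = effective_rates(p, STY, KEK1)
    bind = k_on_bar / p.H * R * L
    unbind = p.k_off * C
    recyc = p.alpha_rec * p.k_rec * Ci
    return {
        "L": -bind + unbind,
        "C": bind - unbind - p.k_ec * C + recyc,
        "Ci": p.k_ec * C - p.alpha_deg * p.k_deg * Ci - recyc,
        "R": p.receptor_binding_sign * bind + unbind - p.k_er * R + p.Q_r,
        "S": k_s_bar * Ci - p.k_d * S,
        "STY": p.k_STY * S - p.k_dSTY * STY,
        "KEK1": p.k_KEK1 * S - p.k_dKEK1 * KEK1,
    }


def depletion_variant(params: KineticParams, target: str, fraction: float) -> KineticParams:
    """RNAi-style depletion: ``sty`` scales the STY production rate k_STY;
    ``egfr`` scales both the initial receptor density R0 and the receptor
    production rate Q_r."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("depletion fraction must be in (0, 1]")
    p = params.resolve()  # freeze K/K' at wild-type scales before scaling
    if target == "sty":
        return replace(p, k_STY=p.k_STY * fraction)
    if target == "egfr":
        return replace(p, R0=p.R0 * fraction, Q_r=p.Q_r * fraction)
    raise ValueError(f"unknown depletion target {target!r} (use 'sty' or 'egfr')")
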