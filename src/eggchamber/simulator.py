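"""Operator-splitting integrator on the growing egg chamber.

Each outer *geometry step* (default 0.05 h) freezes the surface and its
operators; within it the model advances by forward-Euler *reaction steps*
(default 5e-4 h) in the split order of the method:

1. diffusion of the ligand L (explicit Euler on the cotangent
   Laplace-Beltrami, sub-cycled at the stability limit
   dt <= safety * 2 / (D * lambda_max)),
2. growth: at the geometry-step boundary every species is carried to the
   new spheroid by the coordinate-preserving map with the area-Jacobian
   dilution factor (old node area / new node area) — the discrete
   conservative form of the div(v P) transport,
3. follicle-cell shift: all species except L are advected by the tangential
   edge-tracking field w (conservative upwind),
4. reactions and secretion: local forward-Euler update with the feedback
   kinetics; the source flux V(t, x) is added to L.

Receptor-borne species (everything except L) are masked to the
FC-covered axial cap; the stretched-cell region is receptor-free.
Negative values produced by explicit stepping are floored at zero and
counted in the diagnostics.

The solver is deterministic: identical configurations produce bit-identical
results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .geometry import GeometryTimeline
from .kinetics import SPECIES, KineticParams, depletion_variant, reaction_rhs
from .mesh import CubedSpheroidMesh, build_mesh
from .operators import SurfaceOperators
from .source import SourceSpec, dosage_variant, reference_support_area_for, source_flux

logger = logging.getLogger(__name__)

__all__ = [
    "Perturbations",
    "SimulationConfig",
    "FieldState",
    "SimulationResult",
    "SolverDivergedError",
    "initial_state",
    "run",
    "step",
    "nondimensionalize",
    "redimensionalize",
]

#: species advected by the FC shift (the ligand is not cell-bound)
SHIFTED_SPECIES = ("C", "Ci", "R", "S", "STY", "KEK1")


class SolverDivergedError(RuntimeError):
    """NaN/Inf detected; carries the name of the offending sub-step."""

    def __init__(self, substep: str, t: float):
        super().__init__(f"solver diverged in sub-step '{substep}' at t={t:.4f} h")
        self.substep = substep


@dataclass(frozen=True)
class Perturbations:
    """Mechanistic and genetic perturbation switches."""

    nucleus_stop_time: Optional[float] = None
    growth_stop_time: Optional[float] = None
    fc_shift_enabled: bool = True
    sty_fraction: Optional[float] = None
    egfr_fraction: Optional[float] = None
    grk_multiplier: float = 1.0
    gamma_sty_zero_after: Optional[float] = None


@dataclass
class SimulationConfig:
    """Everything needed for one reproducible run."""

    timeline: GeometryTimeline
    params: KineticParams = field(default_factory=KineticParams)
    source: SourceSpec = field(default_factory=SourceSpec)
    n: int = 32
    dt: float = 5.0e-4
    geometry_update_interval: float = 0.05
    safety: float = 0.9
    perturbations: Perturbations = field(default_factory=Perturbations)
    output_times: Optional[Sequence[float]] = None
    t_end: Optional[float] = None
    seed: int = 0

    def resolved_output_times(self) -> List[float]:
        t_end = self.t_end if self.t_end is not None else self.timeline.t_end
        if self.output_times is not None:
            return [t for t in self.output_times if t <= t_end + 1e-9]
        stage_times = [s.time_hr for s in self.timeline.stages]
        return [t for t in stage_times if t <= t_end + 1e-9]


@dataclass
class FieldState:
    """The seven concentration fields at one time."""

    time_hr: float
    fields: Dict[str, np.ndarray]

    def copy(self) -> "FieldState":
        return FieldState(self.time_hr, {k: v.copy() for k, v in self.fields.items()})


@dataclass
class SimulationResult:
    config: SimulationConfig
    snapshots: List[FieldState]
    meshes: List[CubedSpheroidMesh]
    diagnostics: pd.DataFrame
    timeline: GeometryTimeline

    def snapshot_at(self, t: float) -> FieldState:
        for s in self.snapshots:
            if abs(s.time_hr - t) < 1e-6:
                return s
        raise KeyError(f"no snapshot stored at t={t} h")

    def mesh_at(self, t: float) -> CubedSpheroidMesh:
        for s, m in zip(self.snapshots, self.meshes):
            if abs(s.time_hr - t) < 1e-6:
                return m
        raise KeyError(f"no snapshot stored at t={t} h")


def resolve_inputs(config: SimulationConfig):
    """Apply perturbation switches to timeline, params and source."""
    pert = config.perturbations
    timeline = config.timeline.with_perturbations(
        growth_stop_time=pert.growth_stop_time,
        nucleus_stop_time=pert.nucleus_stop_time,
    )
    params = config.params.resolve()
    if pert.sty_fraction is not None:
        params = depletion_variant(params, "sty", pert.sty_fraction)
    if pert.egfr_fraction is not None:
        params = depletion_variant(params, "egfr", pert.egfr_fraction)
    source_spec = dosage_variant(config.source, pert.grk_multiplier)
    return timeline, params, source_spec


def fc_mask(timeline: GeometryTimeline, mesh: CubedSpheroidMesh, t: float) -> np.ndarray:
    """Columnar/cuboidal FC coverage: the axial cap z >= L_AP - L_FC."""
    d = timeline.dims_at(t)
    z_min = d.L_AP - d.L_FC
    return mesh.node_xyz[:, 2] >= z_min - 1e-9


def initial_state(config: SimulationConfig, mesh: Optional[CubedSpheroidMesh] = None) -> FieldState:
    """t = t_start: all species zero except R = R0 on the FC-covered cap."""
    timeline, params, _ = resolve_inputs(config)
    if mesh is None:
        a_ap, a_dv = timeline.semi_axes(timeline.t_start)
        mesh = build_mesh(config.n, a_ap, a_dv)
    fields = {k: np.zeros(mesh.n_nodes) for k in SPECIES}
    fields["R"] = params.R0 * fc_mask(timeline, mesh, timeline.t_start).astype(float)
    return FieldState(timeline.t_start, fields)


class _GeoContext:
    """Frozen-geometry working set for one geometry step."""

    def __init__(self, config, timeline, params, source_spec, t, mesh, ref_support_area,
                 eig_guess=None):
        self.t = t
        self.mesh = mesh
        self.ops = SurfaceOperators(mesh)
        self.chi = fc_mask(timeline, mesh, t).astype(float)
        self.source = source_flux(source_spec, timeline, mesh, t, ref_support_area)
        # feedback switch-off variant (sty-RNAi alternative description)
        gz = config.perturbations.gamma_sty_zero_after
        self.params = replace(params, gamma_STY=0.0) if (gz is not None and t > gz) else params
        # diffusion stability: largest eigenvalue of A^-1 K by power iteration
        self.eigvec, self.lam_max = self._power_iteration(eig_guess)
        # FC-shift transport matrix
        pert = config.perturbations
        w = timeline.fc_shift_velocity(
            t, mesh.eta, mesh.theta, enabled=pert.fc_shift_enabled
        )
        self.shift_matrix, self.shift_rate = self._build_shift(w)

    def _power_iteration(self, guess, iters: int = 12):
        ops = self.ops
        v = guess if guess is not None else self.mesh.node_xyz[:, 2].copy()
        v = v / np.linalg.norm(v)
        lam = 0.0
        for _ in range(iters):
            v = (ops.K @ v) / ops.area
            nrm = np.linalg.norm(v)
            if nrm == 0:
                break
            v /= nrm
        Kv = (ops.K @ v) / ops.area
        lam = float(v @ Kv)
        return v, lam * 1.1  # small headroom for unconverged iteration

    def _build_shift(self, w):
        if not np.any(w):
            return None, 0.0
        ii, jj, uflux = self.ops.transport_coefficients(w)
        # upwind divergence as a sparse matrix: div(w f) = P f
        up = uflux >= 0
        src = np.where(up, ii, jj)   # upwind donor node per dual face
        rows = np.concatenate([ii, jj])
        cols = np.concatenate([src, src])
        vals = np.concatenate([uflux, -uflux])
        P = sp.coo_matrix(
            (vals, (rows, cols)), shape=(self.mesh.n_nodes,) * 2
        ).tocsr()
        P = sp.diags(1.0 / self.ops.area) @ P
        rate = self.ops.max_outflux_rate((ii, jj, uflux))
        return P.tocsr(), rate

    def diffusion_stepper(self, D: float, dt_react: float, safety: float):
        """(matrix, n_sub): applying matrix n_sub times advances diffusion
        by dt_react within the stability limit."""
        if D <= 0:
            return None, 0
        dt_max = safety * 2.0 / (D * self.lam_max)
        n_sub = max(1, int(math.ceil(dt_react / dt_max)))
        dt_sub = dt_react / n_sub
        n = self.mesh.n_nodes
        M = sp.eye(n, format="csr") - dt_sub * D * (
            sp.diags(1.0 / self.ops.area) @ self.ops.K
        )
        return M.tocsr(), n_sub


def _check_finite(fields, substep, t):
    for k, v in fields.items():
        if not np.all(np.isfinite(v)):
            raise SolverDivergedError(substep, t)


def run(config: SimulationConfig, initial: Optional[FieldState] = None) -> SimulationResult:
    """Integrate from t_start to t_end, emitting snapshots at the scheduled
    output times."""
    timeline, params, source_spec = resolve_inputs(config)
    t0 = timeline.t_start
    t_end = config.t_end if config.t_end is not None else timeline.t_end
    out_times = config.resolved_output_times()

    a_ap, a_dv = timeline.semi_axes(t0)
    mesh = build_mesh(config.n, a_ap, a_dv)
    ref_area = reference_support_area_for(source_spec, timeline, mesh)

    state = initial.copy() if initial is not None else initial_state(config, mesh)
    f = state.fields

    n_geo = max(1, int(round((t_end - t0) / config.geometry_update_interval)))
    dt_geo = (t_end - t0) / n_geo
    n_react = max(1, int(round(dt_geo / config.dt)))
    dt_react = dt_geo / n_react

    snapshots: List[FieldState] = []
    meshes: List[CubedSpheroidMesh] = []
    diag_rows = []
    clip_total = 0
    eig_guess = None

    def maybe_snapshot(t, mesh):
        for ot in out_times:
            if abs(t - ot) < min(dt_geo, 1e-6) / 2 or abs(t - ot) < 1e-9:
                if not any(abs(s.time_hr - ot) < 1e-9 for s in snapshots):
                    snapshots.append(FieldState(ot, {k: v.copy() for k, v in f.items()}))
                    meshes.append(mesh)

    maybe_snapshot(t0, mesh)

    t = t0
    for _ in range(n_geo):
        ctx = _GeoContext(
            config, timeline, params, source_spec, t, mesh, ref_area, eig_guess
        )
        eig_guess = ctx.eigvec
        M_diff, n_sub = ctx.diffusion_stepper(ctx.params.D, dt_react, config.safety)
        shift_P = ctx.shift_matrix
        if shift_P is not None and ctx.shift_rate * dt_react > 1.0:
            logger.warning(
                "FC-shift CFL exceeded at t=%.3f (rate %.2f/hr); sub-cycling",
                t, ctx.shift_rate,
            )
        n_shift_sub = max(1, int(math.ceil(ctx.shift_rate * dt_react / 0.9))) if shift_P is not None else 0
        clip_step = 0

        for _ in range(n_react):
            # (1) diffusion of the ligand
            if M_diff is not None:
                L = f["L"]
                for _ in range(n_sub):
                    L = M_diff @ L
                f["L"] = L
            # (3) FC shift of cell-bound species (growth is sub-step 2,
            #     applied at the geometry-step boundary below)
            if shift_P is not None:
                dt_s = dt_react / n_shift_sub
                for k in SHIFTED_SPECIES:
                    v = f[k]
                    for _ in range(n_shift_sub):
                        v = v - dt_s * (shift_P @ v)
                    f[k] = v
            # (4) reactions + source
            rhs = reaction_rhs(ctx.params, f)
            for k in SPECIES:
                f[k] = f[k] + dt_react * rhs[k]
            f["L"] += dt_react * ctx.source
            f["R"] += dt_react * ctx.params.Q_r * (ctx.chi - 1.0)  # production only in FCs
            for k in SPECIES:
                neg = f[k] < 0
                nneg = int(np.count_nonzero(neg))
                if nneg:
                    clip_step += nneg
                    f[k][neg] = 0.0

        _check_finite(f, "reactions", t)
        t += dt_geo

        # (2) growth: carry all species to the new spheroid with the
        # area-Jacobian dilution of the coordinate-preserving map
        a_ap, a_dv = timeline.semi_axes(t)
        new_mesh = build_mesh(config.n, a_ap, a_dv)
        jac = mesh.node_area / new_mesh.node_area
        for k in SPECIES:
            f[k] = f[k] * jac
        _check_finite(f, "growth", t)
        mesh = new_mesh

        # receptor-borne species live only on the FC-covered cap
        chi = fc_mask(timeline, mesh, t).astype(float)
        for k in SHIFTED_SPECIES:
            f[k] = f[k] * chi

        clip_total += clip_step
        ops_area = mesh.node_area
        row = {"t": t, "clipped_nodes": clip_step, "max_S": float(f["S"].max())}
        for k in SPECIES:
            row[f"mass_{k}"] = float(2.0 * np.sum(f[k] * ops_area))
        diag_rows.append(row)
        maybe_snapshot(t, mesh)

    if clip_total:
        logger.warning(
            "negative concentrations floored at 0 on %d node-updates", clip_total
        )
    diagnostics = pd.DataFrame(diag_rows)
    return SimulationResult(config, snapshots, meshes, diagnostics, timeline)


def step(state: FieldState, t: float, dt: float, config: SimulationConfig) -> FieldState:
    """One full split step (diffusion, growth, shift, reactions) of size
    ``dt`` starting from ``state``; returns the new state on the time-(t+dt)
    spheroid.  Intended for verification against local oracles."""
    timeline, params, source_spec = resolve_inputs(config)
    a_ap, a_dv = timeline.semi_axes(t)
    mesh = build_mesh(config.n, a_ap, a_dv)
    ref_area = reference_support_area_for(source_spec, timeline, mesh)
    ctx = _GeoContext(config, timeline, params, source_spec, t, mesh, ref_area)
    f = {k: v.copy() for k, v in state.fields.items()}

    if ctx.params.D > 0:
        f["L"] = f["L"] + dt * ctx.params.D * ctx.ops.laplacian(f["L"])
    _check_finite(f, "diffusion", t)

    if ctx.shift_matrix is not None:
        for k in SHIFTED_SPECIES:
            f[k] = f[k] - dt * (ctx.shift_matrix @ f[k])
    _check_finite(f, "fc-shift", t)

    rhs = reaction_rhs(ctx.params, f)
    for k in SPECIES:
        f[k] = f[k] + dt * rhs[k]
    f["L"] += dt * ctx.source
    f["R"] += dt * ctx.params.Q_r * (ctx.chi - 1.0)
    _check_finite(f, "reactions", t)

    a_ap2, a_dv2 = timeline.semi_axes(t + dt)
    new_mesh = build_mesh(config.n, a_ap2, a_dv2)
    jac = mesh.node_area / new_mesh.node_area
    for k in SPECIES:
        f[k] = f[k] * jac
    _check_finite(f, "growth", t)
    return FieldState(t + dt, f)


# -- nondimensionalization ------------------------------------------------

@dataclass(frozen=True)
class ScaleRecord:
    """Scales used to bring the model to order-1 variables."""

    length: float       # µm, L_AP at the end of the window
    time: float         # hr
    concentration: float  # mol µm^-2, R0


def _scale_params(p: KineticParams, s: ScaleRecord, direction: float) -> KineticParams:
    """direction=+1 scales to nondimensional, -1 back."""
    lf = s.length ** direction
    cf = s.concentration ** direction
    return replace(
        p.resolve(),
        D=p.D / lf**2,
        k_on=p.k_on * cf / lf,
        R0=p.R0 / cf,
        V0=p.V0 / cf,
        Q_r=p.Q_r / cf,
        H=p.H / lf,
        K=p.resolve().K / cf,
        K_prime=p.resolve().K_prime / cf,
    )


def nondimensionalize(config: SimulationConfig):
    """Rescale to order-1 variables: concentrations by R0, lengths by
    L_AP(t_end), times already in hours.  Returns (scaled config, record)."""
    p = config.params.resolve()
    L_ref = config.timeline.dims_at(config.timeline.t_end).L_AP
    rec = ScaleRecord(length=L_ref, time=1.0, concentration=p.R0)
    from dataclasses import replace as drep

    def scale_stage(st):
        return drep(
            st,
            L_E=st.L_E / L_ref, L_FC=st.L_FC / L_ref, W_E=st.W_E / L_ref,
            L_O=None if st.L_O is None else st.L_O / L_ref,
            W_O=None if st.W_O is None else st.W_O / L_ref,
        )

    timeline = drep(
        config.timeline,
        stages=[scale_stage(s) for s in config.timeline.stages],
        _arc_cache={},
    )
    source_spec = drep(config.source, V0=config.source.V0 / p.R0)
    return (
        drep(config, timeline=timeline, params=_scale_params(p, rec, +1.0),
             source=source_spec),
        rec,
    )


def redimensionalize(config: SimulationConfig, rec: ScaleRecord) -> SimulationConfig:
    """Exact inverse of :func:`nondimensionalize`."""
    from dataclasses import replace as drep

    p = config.params

    def unscale_stage(st):
        L = rec.length
        return drep(
            st,
            L_E=st.L_E * L, L_FC=st.L_FC * L, W_E=st.W_E * L,
            L_O=None if st.L_O is None else st.L_O * L,
            W_O=None if st.W_O is None else st.W_O * L,
        )

    timeline = drep(
        config.timeline,
        stages=[unscale_stage(s) for s in config.timeline.stages],
        _arc_cache={},
    )
    source_spec = drep(config.source, V0=config.source.V0 * rec.concentration)
    return drep(
        config, timeline=timeline, params=_scale_params(p, rec, -1.0),
        source=source_spec,
    )
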