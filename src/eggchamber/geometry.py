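"""Continuous-time egg-chamber geometry.

The egg chamber is modeled as a prolate spheroid with semi-axes
``L_AP = L_E/2`` (along z, posterior pole at +z) and ``L_DV = W_E/2`` (along
x and y).  Six staged dimension measurements (S7 through S10A, 3 h to 19.5 h
of model time) are interpolated piecewise-linearly.  The module owns

* the dimension timeline and its growth/nucleus freeze switches,
* the oocyte-nucleus trajectory along the dorsal meridian (theta = 0),
* the normal-directed growth velocity field v of the coordinate-preserving
  growth map, and
* the tangential follicle-cell shift field w that tracks the measured
  columnar-FC extent L_FC(t).

Surface coordinates: eta in [0, pi] is the polar angle from the posterior
pole, theta the azimuth with theta = 0 on the dorsal midline.  A point is
(x, y, z) = (L_DV sin(eta) cos(theta), L_DV sin(eta) sin(theta),
L_AP cos(eta)).

Measured lengths (L_O, L_FC) are straight axial-projection measurements, so
the oocyte and FC domains are axial caps {z >= L_AP - L_O} and
{z >= L_AP - L_FC}; arc-lengths along the meridian are used for kinematics
and profile metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ellipe

__all__ = [
    "StageDimensions",
    "GeometryTimeline",
    "NucleusState",
    "meridian_circumference",
    "meridian_arc",
    "inverse_meridian_arc",
    "spheroid_normals",
    "meridian_tangents",
]

#: smallest oocyte axial extent (µm) used before the first measured stage
OOCYTE_MIN_LENGTH = 5.0

#: time (hr) at which the nucleus starts migrating off the posterior pole
NUCLEUS_MOVE_START = 7.5


@dataclass(frozen=True)
class StageDimensions:
    """Egg-chamber dimensions (µm) at one time point.

    ``L_O``/``W_O`` are ``None`` at S7 where the oocyte is too small to
    measure.
    """

    time_hr: float
    L_E: float
    L_FC: float
    W_E: float
    L_O: Optional[float] = None
    W_O: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("L_E", "L_FC", "W_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.L_FC > self.L_E + 1e-9:
            raise ValueError("L_FC cannot exceed L_E")
        if self.L_O is not None and self.L_O > self.L_E + 1e-9:
            raise ValueError("L_O cannot exceed L_E")
        if self.W_O is not None and self.W_O > self.W_E + 1e-9:
            raise ValueError("W_O cannot exceed W_E")

    @property
    def L_AP(self) -> float:
        """AP semi-axis (µm)."""
        return self.L_E / 2.0

    @property
    def L_DV(self) -> float:
        """DV semi-axis (µm)."""
        return self.W_E / 2.0


@dataclass(frozen=True)
class NucleusState:
    """Nucleus position on the spheroid surface."""

    eta: float
    theta: float
    position_3d: tuple


@dataclass
class GeometryTimeline:
    """Stage-indexed dimensions with continuous piecewise-linear interpolation.

    Parameters
    ----------
    stages
        Ordered stage measurements with strictly increasing times.
    anchor_time
        Time (hr) at which the nucleus reaches its dorsal-anterior anchor at
        the oocyte's anterior cortex (late S8).
    growth_stop_time, nucleus_stop_time
        Optional perturbation switches: all dimensions (resp. the nucleus
        angular position) are frozen at their value at that time.
    """

    stages: Sequence[StageDimensions]
    anchor_time: float = 10.5
    growth_stop_time: Optional[float] = None
    nucleus_stop_time: Optional[float] = None
    _arc_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        times = [s.time_hr for s in self.stages]
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("stage times must be strictly increasing")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_csv(cls, path, **kwargs) -> "GeometryTimeline":
        """Read a stage table (columns stage, time_hr, L_E, L_O, L_FC, W_E,
        W_O; extra standard-deviation columns are ignored)."""
        df = pd.read_csv(path)
        stages = []
        for _, row in df.iterrows():
            stages.append(
                StageDimensions(
                    time_hr=float(row["time_hr"]),
                    L_E=float(row["L_E"]),
                    L_FC=float(row["L_FC"]),
                    W_E=float(row["W_E"]),
                    L_O=None if pd.isna(row.get("L_O")) else float(row["L_O"]),
                    W_O=None if pd.isna(row.get("W_O")) else float(row["W_O"]),
                )
            )
        return cls(stages=stages, **kwargs)

    @classmethod
    def default(cls, **kwargs) -> "GeometryTimeline":
        """Timeline built from the packaged stage-dimension table."""
        from .config import packaged_stage_table_path

        return cls.from_csv(packaged_stage_table_path(), **kwargs)

    def with_perturbations(self, growth_stop_time=None, nucleus_stop_time=None):
        return replace(
            self,
            growth_stop_time=growth_stop_time,
            nucleus_stop_time=nucleus_stop_time,
            _arc_cache={},
        )

    # -- basic queries ----------------------------------------------------
    @property
    def t_start(self) -> float:
        return self.stages[0].time_hr

    @property
    def t_end(self) -> float:
        return self.stages[-1].time_hr

    def _check_range(self, t: float) -> None:
        if not (self.t_start - 1e-9 <= t <= self.t_end + 1e-9):
            raise ValueError(
                f"t={t} outside the modeled window "
                f"[{self.t_start}, {self.t_end}] hr"
            )

    def _effective_time(self, t: float) -> float:
        if self.growth_stop_time is not None:
            return min(t, self.growth_stop_time)
        return t

    def _interp(self, t: float, attr: str) -> Optional[float]:
        ts, vs = [], []
        for s in self.stages:
            v = getattr(s, attr)
            if v is not None:
                ts.append(s.time_hr)
                vs.append(v)
        if not ts or t < ts[0] - 1e-9:
            return None
        return float(np.interp(t, ts, vs))

    def dims_at(self, t: float) -> StageDimensions:
        """Piecewise-linear interpolation of the stage table; exact at the
        stage times; frozen after ``growth_stop_time`` when set."""
        self._check_range(t)
        te = self._effective_time(t)
        return StageDimensions(
            time_hr=te,
            L_E=self._interp(te, "L_E"),
            L_FC=self._interp(te, "L_FC"),
            W_E=self._interp(te, "W_E"),
            L_O=self._interp(te, "L_O"),
            W_O=self._interp(te, "W_O"),
        )

    def semi_axes(self, t: float) -> tuple:
        d = self.dims_at(t)
        return d.L_AP, d.L_DV

    def oocyte_length(self, t: float) -> float:
        """Axial oocyte extent (µm), back-extrapolated linearly before the
        first measured stage and floored at OOCYTE_MIN_LENGTH."""
        self._check_range(t)
        te = self._effective_time(t)
        ts, vs = [], []
        for s in self.stages:
            if s.L_O is not None:
                ts.append(s.time_hr)
                vs.append(s.L_O)
        if te >= ts[0]:
            val = float(np.interp(te, ts, vs))
        else:  # linear back-extrapolation from the first two measured stages
            slope = (vs[1] - vs[0]) / (ts[1] - ts[0])
            val = vs[0] + slope * (te - ts[0])
        return max(val, OOCYTE_MIN_LENGTH)

    # -- meridian arc-length ----------------------------------------------
    def _arc_table(self, t: float):
        key = round(self._effective_time(t), 9)
        tab = self._arc_cache.get(key)
        if tab is None:
            a_ap, a_dv = self.semi_axes(t)
            tab = _build_arc_table(a_ap, a_dv)
            if len(self._arc_cache) > 512:
                self._arc_cache.clear()
            self._arc_cache[key] = tab
        return tab

    def arc_from_pole(self, eta, t: float):
        """Meridian arc-length (µm) from the posterior pole to polar angle
        ``eta`` on the time-``t`` spheroid."""
        etas, arcs = self._arc_table(t)
        return np.interp(eta, etas, arcs)

    def eta_at_arc(self, s, t: float):
        """Inverse of :meth:`arc_from_pole`."""
        etas, arcs = self._arc_table(t)
        return np.interp(s, arcs, etas)

    def eta_of_axial_cap(self, axial_extent: float, t: float) -> float:
        """Polar angle of the boundary of the axial cap {z >= L_AP - extent}."""
        a_ap, _ = self.semi_axes(t)
        c = np.clip((a_ap - axial_extent) / a_ap, -1.0, 1.0)
        return float(np.arccos(c))

    def fc_edge_eta(self, t: float) -> float:
        """Polar angle of the columnar-FC anterior edge."""
        d = self.dims_at(t)
        return self.eta_of_axial_cap(d.L_FC, t)

    def oocyte_edge_eta(self, t: float) -> float:
        """Polar angle of the oocyte anterior boundary."""
        return self.eta_of_axial_cap(self.oocyte_length(t), t)

    # -- nucleus ----------------------------------------------------------
    def nucleus_position(self, t: float) -> NucleusState:
        """Nucleus position: posterior pole until S7's end, then migrating
        along the dorsal meridian to anchor at the oocyte's anterior
        boundary at ``anchor_time``; afterwards it stays at the (growing)
        oocyte anterior cortex.  ``nucleus_stop_time`` freezes the angular
        position."""
        self._check_range(t)
        te = t if self.nucleus_stop_time is None else min(t, self.nucleus_stop_time)
        if te <= NUCLEUS_MOVE_START:
            eta = 0.0
        else:
            eta_target = self.oocyte_edge_eta(te)
            s_target = self.arc_from_pole(eta_target, te)
            if te < self.anchor_time:
                frac = (te - NUCLEUS_MOVE_START) / (self.anchor_time - NUCLEUS_MOVE_START)
                eta = float(self.eta_at_arc(frac * s_target, te))
            else:
                eta = eta_target
        a_ap, a_dv = self.semi_axes(t)
        pos = (a_dv * math.sin(eta), 0.0, a_ap * math.cos(eta))
        return NucleusState(eta=eta, theta=0.0, position_3d=pos)

    # -- velocity fields --------------------------------------------------
    def semi_axis_rates(self, t: float, h: float = 1e-4) -> tuple:
        """d/dt of (L_AP, L_DV) of the (possibly frozen) timeline."""
        if self.growth_stop_time is not None and t >= self.growth_stop_time - 1e-12:
            return 0.0, 0.0
        t0 = max(self.t_start, t - h)
        t1 = min(self.t_end, t + h)
        a0 = self.semi_axes(t0)
        a1 = self.semi_axes(t1)
        dt = t1 - t0
        return (a1[0] - a0[0]) / dt, (a1[1] - a0[1]) / dt

    def growth_velocity(self, t: float, eta, theta):
        """Velocity (µm/hr) of the coordinate-preserving growth map: a point
        keeps (eta, theta) while the semi-axes change."""
        d_ap, d_dv = self.semi_axis_rates(t)
        eta = np.asarray(eta, dtype=float)
        theta = np.asarray(theta, dtype=float)
        v = np.empty(np.broadcast_shapes(eta.shape, theta.shape) + (3,))
        v[..., 0] = d_dv * np.sin(eta) * np.cos(theta)
        v[..., 1] = d_dv * np.sin(eta) * np.sin(theta)
        v[..., 2] = d_ap * np.cos(eta)
        return v

    def fc_edge_speed(self, t: float, h: float = 1e-3) -> float:
        """Meridian-arc speed (µm/hr) of the FC anterior edge *relative to
        the growing surface* (negative = posterior-ward).

        The edge must track L_FC(t); part of its lab-frame motion is already
        provided by the growth map, so the shift speed is the residual.
        """
        t0 = max(self.t_start, t - h)
        t1 = min(self.t_end, t + h)
        dt = t1 - t0
        if dt <= 0:
            return 0.0
        # lab-frame edge positions (arc on each instantaneous surface)
        s0 = self.arc_from_pole(self.fc_edge_eta(t0), t0)
        s1 = self.arc_from_pole(self.fc_edge_eta(t1), t1)
        # growth drift of a material point frozen at the time-t edge angle
        eta_e = self.fc_edge_eta(t)
        g0 = self.arc_from_pole(eta_e, t0)
        g1 = self.arc_from_pole(eta_e, t1)
        return float((s1 - s0) / dt - (g1 - g0) / dt)

    def fc_shift_velocity(self, t: float, eta, theta, enabled: bool = True):
        """Tangential FC-shift field w (µm/hr): meridional, zero at the
        posterior pole, magnitude linear in arc-length up to the FC edge and
        constant beyond it, scaled so the edge tracks L_FC(t)."""
        eta = np.asarray(eta, dtype=float)
        theta = np.asarray(theta, dtype=float)
        shape = np.broadcast_shapes(eta.shape, theta.shape)
        w = np.zeros(shape + (3,))
        if not enabled:
            return w
        speed_edge = self.fc_edge_speed(t)
        if speed_edge == 0.0:
            return w
        s_edge = self.arc_from_pole(self.fc_edge_eta(t), t)
        if s_edge <= 0:
            return w
        s = self.arc_from_pole(eta, t)
        mag = speed_edge * np.minimum(s / s_edge, 1.0)
        a_ap, a_dv = self.semi_axes(t)
        e_eta = meridian_tangents(eta, theta, a_ap, a_dv)
        return mag[..., None] * e_eta


def _build_arc_table(L_AP: float, L_DV: float, m: int = 2048):
    """Cumulative meridian arc-length table s(eta) for one spheroid."""
    etas = np.linspace(0.0, np.pi, m)
    ds = np.sqrt(
        (L_DV * np.cos(etas)) ** 2 + (L_AP * np.sin(etas)) ** 2
    )
    arcs = np.concatenate(
        [[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2.0 * np.diff(etas))]
    )
    return etas, arcs


def meridian_arc(eta, L_AP: float, L_DV: float):
    """Meridian arc-length from the posterior pole (standalone helper)."""
    etas, arcs = _build_arc_table(L_AP, L_DV)
    return np.interp(eta, etas, arcs)


def inverse_meridian_arc(s, L_AP: float, L_DV: float):
    etas, arcs = _build_arc_table(L_AP, L_DV)
    return np.interp(s, arcs, etas)


def meridian_circumference(dims: StageDimensions) -> float:
    """Perimeter (µm) of the full AP meridian ellipse with semi-axes
    L_E/2 and W_E/2, by the complete elliptic integral of the second kind."""
    a = max(dims.L_AP, dims.L_DV)
    b = min(dims.L_AP, dims.L_DV)
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(m))


def spheroid_normals(xyz: np.ndarray, L_AP: float, L_DV: float) -> np.ndarray:
    """Outward unit normals of the spheroid at points ``xyz`` (N, 3)."""
    g = np.column_stack(
        [xyz[:, 0] / L_DV**2, xyz[:, 1] / L_DV**2, xyz[:, 2] / L_AP**2]
    )
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def meridian_tangents(eta, theta, L_AP: float, L_DV: float) -> np.ndarray:
    """Unit tangent vectors along increasing eta (posterior -> anterior).

    Zero vector at the poles where the direction is undefined.
    """
    eta = np.asarray(eta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    tx = L_DV * np.cos(eta) * np.cos(theta)
    ty = L_DV * np.cos(eta) * np.sin(theta)
    tz = -L_AP * np.sin(eta)
    vec = np.stack(np.broadcast_arrays(tx, ty, tz), axis=-1)
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    sin_eta = np.abs(np.sin(eta))[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(sin_eta > 1e-9, vec / norm, 0.0)
    return unit
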