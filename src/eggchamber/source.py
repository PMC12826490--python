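"""GRK secretion source V(t, x).

GRK is translated around the oocyte nucleus and secreted into the
perivitelline space over a T-shaped support that travels with the nucleus:
a dorsal stripe running posterior from the nucleus along the dorsal midline
(the comet tail of the "T") plus a transverse band across the oocyte at the
nucleus.  The shape is parameterized by three measured ratios relative to
the oocyte's extent; their stage-resolved values are configuration inputs
(uniform 0.5 placeholders by default — production runs should override them
from measurements).

The secreted total is proportional to the oocyte surface area: V0 is the
per-area flux over the support at the reference stage (S10A), and the total
flux at time t is scaled by A_oocyte(t)/A_oocyte(t_ref).  The flux profile
over the support is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import quad

from .geometry import GeometryTimeline
from .mesh import CubedSpheroidMesh

__all__ = ["SourceSpec", "source_flux", "dosage_variant", "oocyte_area"]


@dataclass(frozen=True)
class SourceSpec:
    """Secretion geometry and amplitude.

    Ratios follow the source measurements: ``ratio_dorsal_length`` is the
    stripe length over the oocyte curved length; ``ratio_posterior_width``
    the stripe width over the oocyte width at the nucleus posterior;
    ``ratio_anterior_width`` the transverse-band curved width over the
    oocyte half-perimeter at the nucleus anterior.  Each ratio is either a
    single stage-constant value or a ``{time_hr: value}`` mapping that is
    interpolated piecewise-linearly.  ``band_meridian_frac`` sets the
    band's meridional thickness as a fraction of the oocyte curved length.
    """

    V0: float = 2.0e-21
    ratio_dorsal_length: object = 0.5
    ratio_posterior_width: object = 0.5
    ratio_anterior_width: object = 0.5
    band_meridian_frac: float = 0.1
    reference_time: float = 19.5

    def __post_init__(self):
        for name in (
            "ratio_dorsal_length",
            "ratio_posterior_width",
            "ratio_anterior_width",
        ):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else (v,)
            if not vals or not all(0.0 < x <= 1.0 for x in vals):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.V0 < 0:
            raise ValueError("V0 must be nonnegative")

    def ratio_at(self, name: str, t: float) -> float:
        """Ratio value at time ``t`` (stage-indexed mappings interpolated)."""
        v = getattr(self, name)
        if isinstance(v, dict):
            times = sorted(v)
            return float(np.interp(t, times, [v[k] for k in times]))
        return float(v)


def dosage_variant(spec: SourceSpec, multiplier: float) -> SourceSpec:
    """Scaled grk gene dosage: V0 times ``multiplier``, shape unchanged."""
    if multiplier < 0:
        raise ValueError("dosage multiplier must be nonnegative")
    return replace(spec, V0=spec.V0 * multiplier)


def oocyte_area(timeline: GeometryTimeline, t: float) -> float:
    """Surface area (µm²) of the oocyte-covered axial cap of the spheroid."""
    a_ap, a_dv = timeline.semi_axes(t)
    eta_o = timeline.oocyte_edge_eta(t)

    def ds(eta):
        r = a_dv * np.sin(eta)
        arc = np.sqrt((a_dv * np.cos(eta)) ** 2 + (a_ap * np.sin(eta)) ** 2)
        return 2.0 * np.pi * r * arc

    val, _ = quad(ds, 0.0, eta_o, limit=100)
    return float(val)


def support_mask(
    spec: SourceSpec,
    timeline: GeometryTimeline,
    mesh: CubedSpheroidMesh,
    t: float,
) -> np.ndarray:
    """Boolean node mask of the T-shaped support on the half mesh.

    The support is symmetric about the dorsal midline, so the y >= 0 half
    carries exactly half of it and all doubled integrals are consistent.
    """
    nuc = timeline.nucleus_position(t)
    s_nuc = float(timeline.arc_from_pole(nuc.eta, t))
    arc_oocyte = float(timeline.arc_from_pole(timeline.oocyte_edge_eta(t), t))
    s_nodes = np.asarray(timeline.arc_from_pole(mesh.eta, t))
    th = np.abs(mesh.theta)

    stripe_len = spec.ratio_at("ratio_dorsal_length", t) * arc_oocyte
    stripe_halfwidth = spec.ratio_at("ratio_posterior_width", t) * np.pi / 2.0
    band_halfwidth = spec.ratio_at("ratio_anterior_width", t) * np.pi / 2.0
    band_halfthick = spec.band_meridian_frac * arc_oocyte / 2.0

    stripe = (
        (s_nodes <= s_nuc + 1e-9)
        & (s_nodes >= s_nuc - stripe_len)
        & (th <= stripe_halfwidth)
    )
    band = (np.abs(s_nodes - s_nuc) <= band_halfthick) & (th <= band_halfwidth)
    mask = (stripe | band) & (s_nodes <= arc_oocyte + 1e-9)
    if not mask.any():
        # coarse-mesh fallback: deposit at the node closest to the nucleus
        d = np.linalg.norm(mesh.node_xyz - np.asarray(nuc.position_3d), axis=1)
        mask = np.zeros(mesh.n_nodes, dtype=bool)
        mask[int(np.argmin(d))] = True
    return mask


def source_flux(
    spec: SourceSpec,
    timeline: GeometryTimeline,
    mesh: CubedSpheroidMesh,
    t: float,
    reference_support_area: Optional[float] = None,
) -> np.ndarray:
    """Secretion flux field (mol µm^-2 hr^-1) on the mesh nodes.

    Total emitted flux is ``V0 * A_ref_support * A_oocyte(t)/A_oocyte(t_ref)``
    spread uniformly over the current support.  ``reference_support_area``
    (full-spheroid µm²) may be passed to avoid recomputing it per call.
    """
    mask = support_mask(spec, timeline, mesh, t)
    area_support = 2.0 * float(mesh.node_area[mask].sum())
    if reference_support_area is None:
        reference_support_area = reference_support_area_for(spec, timeline, mesh)
    # the reference oocyte area is always the *unperturbed* S10A one, so a
    # growth-stopped chamber keeps a constant, smaller total flux
    ref_tl = timeline.with_perturbations(None, timeline.nucleus_stop_time)
    total = (
        spec.V0
        * reference_support_area
        * oocyte_area(timeline, t)
        / oocyte_area(ref_tl, spec.reference_time)
    )
    flux = np.zeros(mesh.n_nodes)
    if area_support > 0:
        flux[mask] = total / area_support
    return flux


def reference_support_area_for(
    spec: SourceSpec, timeline: GeometryTimeline, mesh: CubedSpheroidMesh
) -> float:
    """Support area (µm², full spheroid) at the reference stage, evaluated
    on a mesh of the same resolution built for the reference geometry."""
    from .mesh import build_mesh

    # use an unperturbed copy of the timeline: the reference normalization is
    # the wild-type S10A support, also under growth-stop perturbations
    ref_tl = timeline.with_perturbations(None, timeline.nucleus_stop_time)
    a_ap, a_dv = ref_tl.semi_axes(spec.reference_time)
    ref_mesh = build_mesh(mesh.n, a_ap, a_dv)
    mask = support_mask(spec, ref_tl, ref_mesh, spec.reference_time)
    return 2.0 * float(ref_mesh.node_area[mask].sum())
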