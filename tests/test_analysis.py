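"""Profile extraction, elongation, L1 error, normalization, and the
synthetic reference generator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eggchamber.analysis import (
    AP_POINTS,
    DV_CENTRAL_FRACTION,
    DV_POINTS,
    IntensityProfile,
    calibrate_gammas,
    elongation,
    extract_ap_profile,
    extract_dv_profile,
    l1_relative_error,
    max_signal,
    normalize_to_reference,
    profiles_frame,
    read_profiles,
    synth_reference_curves,
    write_profiles,
)
from eggchamber.kinetics import SPECIES
from eggchamber.simulator import FieldState


def _constant_result(wt_run_n16, value=2.5):
    """Clone of a run whose final snapshot has a constant signal field."""
    res = wt_run_n16
    snap = res.snapshots[-1]
    fields = {k: v.copy() for k, v in snap.fields.items()}
    fields["S"] = np.full_like(fields["S"], value)
    patched = replace(res, snapshots=res.snapshots[:-1] + [FieldState(snap.time_hr, fields)])
    return patched, snap.time_hr


class TestProfiles:
    def test_constant_field_flat_profiles(self, wt_run_n16):
        res, t = _constant_result(wt_run_n16)
        ap = extract_ap_profile(res, t)
        dv = extract_dv_profile(res, t)
        assert ap.n_points == AP_POINTS and dv.n_points == DV_POINTS
        assert np.allclose(ap.values, 2.5, rtol=1e-9)
        assert np.allclose(dv.values, 2.5, rtol=1e-9)

    def test_ap_profile_spans_fc_cap_late(self, wt_run_n16):
        """From S9 on the AP profile covers the columnar-FC meridian arc."""
        t = 16.5
        tl = wt_run_n16.timeline
        expected = float(tl.arc_from_pole(tl.fc_edge_eta(t), t))
        ap = extract_ap_profile(wt_run_n16, t)
        assert ap.length == pytest.approx(expected, rel=1e-6)

    def test_ap_profile_spans_full_chamber_early(self, wt_run_n16):
        t = 7.5
        tl = wt_run_n16.timeline
        expected = float(tl.arc_from_pole(np.pi, t))
        ap = extract_ap_profile(wt_run_n16, t)
        assert ap.length == pytest.approx(expected, rel=1e-6)

    def test_missing_snapshot(self, wt_run_n16):
        with pytest.raises(KeyError):
            extract_ap_profile(wt_run_n16, 4.25)

    def test_dv_profile_symmetric_for_symmetric_field(self, wt_run_n16):
        """The simulated fields are mirror-symmetric in y, so the DV profile
        is symmetric about its center."""
        dv = extract_dv_profile(wt_run_n16, 19.5)
        assert np.allclose(dv.values, dv.values[::-1], rtol=1e-9)

    def test_dv_covers_central_30_percent(self, wt_run_n16):
        t = 19.5
        tl = wt_run_n16.timeline
        dv = extract_dv_profile(wt_run_n16, t)
        nuc = tl.nucleus_position(t)
        from eggchamber.analysis import DV_RING_OFFSET

        s_ring = float(tl.arc_from_pole(nuc.eta, t)) - DV_RING_OFFSET
        eta_ring = float(tl.eta_at_arc(s_ring, t))
        a_ap, a_dv = tl.semi_axes(t)
        half_circ = np.pi * a_dv * np.sin(eta_ring)
        assert dv.length == pytest.approx(DV_CENTRAL_FRACTION * half_circ, rel=1e-6)

    def test_diffusion_from_posterior_source_monotone(self, timeline):
        """Pure-diffusion oracle: with a posterior-pole delta source and no
        uptake, the profile decreases monotonically from the posterior."""
        from eggchamber.config import default_config
        from eggchamber.simulator import Perturbations, run
        from eggchamber.kinetics import KineticParams

        cfg = default_config(
            n=8,
            t_end=4.0,
            output_times=[4.0],
            perturbations=Perturbations(growth_stop_time=3.0, nucleus_stop_time=3.0,
                                        fc_shift_enabled=False),
        )
        # no uptake: receptors cannot bind
        cfg = replace(cfg, params=replace(cfg.params, k_on=0.0).resolve())
        res = run(cfg)
        ap = extract_ap_profile(res, 4.0, species="L")
        # positions run anterior -> posterior; values must increase
        v = ap.values
        assert v[-1] > v[0]
        sm = np.convolve(v, np.ones(5) / 5, mode="valid")  # smooth mesh noise
        assert np.all(np.diff(sm) >= -1e-3 * v.max())


class TestElongation:
    def test_zero_field(self, wt_run_n16):
        res, t = _constant_result(wt_run_n16, value=0.0)
        assert elongation(res, t, 0.6, reference_max=1.0) == 0.0

    def test_top_hat_width_recovered(self, wt_run_n16):
        """A synthetic band of known meridian arc is measured within a cell."""
        res = wt_run_n16
        t = 19.5
        snap = res.snapshot_at(t)
        mesh = res.mesh_at(t)
        tl = res.timeline
        s = np.asarray(tl.arc_from_pole(mesh.eta, t))
        lo, hi = 40.0, 160.0
        fields = {k: np.zeros_like(v) for k, v in snap.fields.items()}
        fields["S"] = ((s >= lo) & (s <= hi)).astype(float)
        # the band exists on dorsal and ventral branches of the ring
        patched = replace(
            res, snapshots=res.snapshots[:-1] + [FieldState(t, fields)]
        )
        e = elongation(patched, t, 0.6, reference_max=1.0)
        cell = mesh.h_min * 8
        assert e == pytest.approx(2 * (hi - lo), abs=cell)

    def test_monotone_in_threshold(self, wt_run_n16):
        es = [elongation(wt_run_n16, 19.5, th) for th in (0.2, 0.4, 0.6, 0.8)]
        assert all(b <= a + 1e-9 for a, b in zip(es, es[1:]))

    def test_grk_null_no_signal(self):
        from eggchamber.config import default_config
        from eggchamber.simulator import Perturbations, run

        cfg = default_config(n=8, t_end=7.5,
                             perturbations=Perturbations(grk_multiplier=0.0))
        res = run(cfg)
        assert max_signal(res, 7.5) == 0.0


class TestL1Error:
    def _profile(self, values, length=100.0):
        pos = np.linspace(0, length, len(values))
        return IntensityProfile(axis="AP", positions=pos, values=np.asarray(values),
                                time_hr=19.5, stage="S10A")

    def test_identical_zero(self):
        p = self._profile(np.linspace(1, 2, 50))
        assert l1_relative_error(p, p) == 0.0

    def test_double_is_one(self):
        ref = self._profile(np.linspace(1, 2, 50))
        sim = self._profile(2 * np.linspace(1, 2, 50))
        assert l1_relative_error(sim, ref) == pytest.approx(1.0)

    def test_constant_offset_closed_form(self):
        """sim = ref + c on length T with integral I gives error c*T/I."""
        vals = 1.0 + np.sin(np.linspace(0, np.pi, 200))
        T, c = 80.0, 0.37
        ref = self._profile(vals, length=T)
        sim = self._profile(vals + c, length=T)
        I = np.trapezoid(vals, np.linspace(0, T, 200))
        assert l1_relative_error(sim, ref) == pytest.approx(c * T / I, rel=1e-9)

    def test_zero_reference_rejected(self):
        ref = self._profile(np.zeros(10))
        sim = self._profile(np.ones(10))
        with pytest.raises(ZeroDivisionError):
            l1_relative_error(sim, ref)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_scale_covariance(self, a):
        vals = 1.0 + np.cos(np.linspace(0, 2, 60)) ** 2
        ref = self._profile(vals)
        sim = self._profile(vals * 1.3 + 0.1)
        e1 = l1_relative_error(sim, ref)
        e2 = l1_relative_error(sim.scaled(a), ref.scaled(a))
        assert e2 == pytest.approx(e1, rel=1e-9)


class TestNormalization:
    def _profset(self, scale=1.0):
        pos = np.linspace(0, 100, 100)
        vals = scale * (1 + np.exp(-((pos - 60) ** 2) / 300))
        p = IntensityProfile(axis="AP", positions=pos, values=vals,
                             time_hr=19.5, stage="S10A")
        q = IntensityProfile(axis="DV", positions=np.linspace(0, 50, 50),
                             values=np.full(50, scale), time_hr=19.5, stage="S10A")
        return {("AP", "S10A"): p, ("DV", "S10A"): q}

    def test_identity_factor(self):
        sims = self._profset()
        scaled, factor = normalize_to_reference(sims, self._profset())
        assert factor == pytest.approx(1.0)

    def test_triple_reference(self):
        sims = self._profset(1.0)
        refs = self._profset(3.0)
        scaled, factor = normalize_to_reference(sims, refs)
        assert factor == pytest.approx(3.0)
        assert np.allclose(scaled[("DV", "S10A")].values, 3.0)

    def test_anchor_equality_after_scaling(self):
        sims = self._profset(0.7)
        refs = self._profset(2.2)
        scaled, _ = normalize_to_reference(sims, refs)
        assert scaled[("AP", "S10A")].value_at_frac(0.2) == pytest.approx(
            refs[("AP", "S10A")].value_at_frac(0.2)
        )


class TestReferenceCurves:
    def test_noise_free_matches_extraction(self, default_cfg_n16, wt_run_n16):
        refs = synth_reference_curves(default_cfg_n16, 0.0, seed=1, dosages=(1.0,))
        df = refs[1.0]
        ap = df[(df.axis == "AP") & (df.stage == "S10A")]
        direct = extract_ap_profile(wt_run_n16, 19.5)
        assert np.allclose(ap["value"].to_numpy(), direct.values)

    def test_seed_reproducible(self, default_cfg_n16):
        cfg = replace(default_cfg_n16, n=8, t_end=8.0)
        a = synth_reference_curves(cfg, 0.05, seed=42, dosages=(1.0,))
        b = synth_reference_curves(cfg, 0.05, seed=42, dosages=(1.0,))
        pd.testing.assert_frame_equal(a[1.0], b[1.0])

    def test_csv_roundtrip(self, tmp_path, default_cfg_n16):
        cfg = replace(default_cfg_n16, n=8, t_end=8.0)
        refs = synth_reference_curves(cfg, 0.0, seed=0, dosages=(1.0,))
        path = tmp_path / "wt.csv"
        write_profiles(refs[1.0], path)
        df = read_profiles(path)
        assert list(df.columns) == list(refs[1.0].columns)
        assert np.allclose(df["value"], refs[1.0]["value"])

    def test_malformed_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"axis": ["AP"], "value": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_profiles(path)


class TestCalibrationBasics:
    def test_empty_grid_rejected(self, default_cfg_n16):
        with pytest.raises(ValueError):
            calibrate_gammas(default_cfg_n16, [], [1.0], {})

    def test_degenerate_single_point_grid(self, default_cfg_n16):
        """A 1-point grid returns that point."""
        cfg = replace(default_cfg_n16, n=8, t_end=8.0)
        p = cfg.params
        refs = synth_reference_curves(cfg, 0.0, seed=0, dosages=(1.0,))
        out = calibrate_gammas(
            cfg, [p.gamma_STY], [p.gamma_KEK1], refs, dosages=(1.0,)
        )
        assert out.gamma_STY == p.gamma_STY
        assert out.gamma_KEK1 == p.gamma_KEK1
        assert out.best_error == pytest.approx(0.0, abs=1e-9)
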