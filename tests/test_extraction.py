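"""CSW-pair subtraction, residual background removal, pseudocolor
assembly."""

import numpy as np
import pytest

from mcswv import (
    ColorPlot,
    ElectrodeModel,
    assemble_colorplot,
    csw_pair_difference,
    fit_all_segments,
    residual_background_subtract,
    segment_scan,
    simulate_scan,
)
from mcswv.segmentation import CapacitiveFit
from mcswv.waveform import PHASE_ANODIC, PHASE_CATHODIC


def fits_by_key(segments, fits, csw):
    return {
        (s.step_index, s.phase): f
        for s, f in zip(segments, fits)
        if s.csw_index == csw
    }


class TestPairDifference:
    def test_identical_csws_zero_difference(self, tiny_spec, tiny_wf, quiet_model):
        raw = simulate_scan(quiet_model, tiny_wf, 0.0)  # all CSWs identical
        segs = segment_scan(raw, tiny_wf)
        diff = csw_pair_difference(segs)
        assert len(diff) == tiny_spec.n_steps * 2
        for trace in diff.values():
            np.testing.assert_allclose(trace, 0.0, atol=1e-9)

    def test_default_pairing_is_2_minus_5(self, tiny_wf, quiet_model):
        raw = simulate_scan(quiet_model, tiny_wf, 150.0)
        segs = segment_scan(raw, tiny_wf)
        by_key = {(s.csw_index, s.step_index, s.phase): s for s in segs}
        diff = csw_pair_difference(segs)
        key = (5, PHASE_ANODIC)  # middle step, anodic
        expected = by_key[(2, 5, PHASE_ANODIC)].samples - by_key[(5, 5, PHASE_ANODIC)].samples
        np.testing.assert_array_equal(diff[key], expected)

    def test_depletion_recovers_csw2_faradaic(self, tiny_wf, quiet_model):
        """With depletion d the pair difference misses the CSW-2 Faradaic
        by exactly the d^3 still present at CSW 5."""
        d = quiet_model.depletion_factor
        far = (
            simulate_scan(quiet_model, tiny_wf, 150.0).current
            - simulate_scan(quiet_model, tiny_wf, 0.0).current
        )
        segs_f = segment_scan(
            simulate_scan(quiet_model, tiny_wf, 150.0), tiny_wf
        )
        diff = csw_pair_difference(segs_f)
        csw2_faradaic = {}
        for seg in segment_scan(
            simulate_scan(quiet_model, tiny_wf, 150.0), tiny_wf
        ):
            if seg.csw_index == 2:
                sel = (tiny_wf.csw_index == 2) & \
                      (tiny_wf.step_index == seg.step_index) & \
                      (tiny_wf.phase == seg.phase)
                csw2_faradaic[(seg.step_index, seg.phase)] = far[sel]
        for key, trace in diff.items():
            truth = csw2_faradaic[key]
            if np.abs(truth).max() < 1e-6:
                continue
            np.testing.assert_allclose(trace, truth * (1 - d**3), atol=1e-9)

    def test_missing_csw_rejected(self, tiny_wf, quiet_model):
        raw = simulate_scan(quiet_model, tiny_wf, 0.0)
        segs = segment_scan(raw, tiny_wf)
        with pytest.raises(ValueError, match="not present"):
            csw_pair_difference(segs, signal_csw=2, background_csw=9)


class TestResidualSubtract:
    def test_identical_fits_leave_diff_unchanged(self, tiny_wf, quiet_model):
        raw = simulate_scan(quiet_model, tiny_wf, 100.0)
        segs = segment_scan(raw, tiny_wf)
        fits = fit_all_segments(segs)
        diff = csw_pair_difference(segs)
        f2 = fits_by_key(segs, fits, 2)
        out, valid = residual_background_subtract(diff, f2, f2, 1e-5)
        for key in diff:
            np.testing.assert_allclose(out[key], diff[key], atol=1e-12)
            assert valid[key][f2[key].skip:].all()

    def test_zero_diff_yields_negated_model_difference(self):
        n, dt = 50, 1e-5
        diff = {(1, PHASE_ANODIC): np.zeros(n)}
        fa = CapacitiveFit(i0=100.0, tau_decay=5e-5, offset=3.0, rmse=0.0,
                           converged=True, skip=2)
        fb = CapacitiveFit(i0=80.0, tau_decay=6e-5, offset=9.0, rmse=0.0,
                           converged=True, skip=2)
        out, valid = residual_background_subtract(
            diff, {(1, PHASE_ANODIC): fa}, {(1, PHASE_ANODIC): fb}, dt
        )
        t = np.arange(n - 2) * dt
        expected = -(
            fa.evaluate(t, include_offset=False)
            - fb.evaluate(t, include_offset=False)
        )
        np.testing.assert_allclose(out[(1, PHASE_ANODIC)][2:], expected)
        np.testing.assert_array_equal(out[(1, PHASE_ANODIC)][:2], 0.0)
        assert not valid[(1, PHASE_ANODIC)][:2].any()

    def test_missing_fit_falls_back_to_diff(self):
        diff = {(1, PHASE_ANODIC): np.ones(20)}
        out, valid = residual_background_subtract(diff, {}, {}, 1e-5)
        np.testing.assert_array_equal(out[(1, PHASE_ANODIC)], diff[(1, PHASE_ANODIC)])
        assert not valid[(1, PHASE_ANODIC)].any()

    def test_drift_background_energy_reduced(self, tiny_spec, tiny_wf):
        """Across seeded drifting zero-analyte scans the residual model
        removes background energy in nearly all runs."""
        wins = 0
        n_runs = 40
        for seed in range(n_runs):
            model = ElectrodeModel(
                noise_sd=0.0, broadband_noise_sd=0.0,
                drift_rate=1e-3 + 1e-4 * seed, seed=seed,
            )
            raw = simulate_scan(model, tiny_wf, 0.0, scan_index=5)
            segs = segment_scan(raw, tiny_wf)
            fits = fit_all_segments(segs)
            diff = csw_pair_difference(segs)
            out, valid = residual_background_subtract(
                diff, fits_by_key(segs, fits, 2), fits_by_key(segs, fits, 5),
                1.0 / tiny_spec.sample_rate,
            )
            pre = sum(np.sum(diff[k][valid[k]] ** 2) for k in diff)
            post = sum(np.sum(out[k][valid[k]] ** 2) for k in diff)
            wins += post < pre
        assert wins >= 0.95 * n_runs


class TestColorPlot:
    def _traces(self, spec, value=0.0, spp=50):
        keys = [
            (s, ph)
            for s in range(1, spec.n_steps + 1)
            for ph in (PHASE_ANODIC, PHASE_CATHODIC)
        ]
        return {k: np.full(spp, value) for k in keys}

    def test_zero_traces_zero_plot(self, tiny_spec):
        plot = assemble_colorplot(self._traces(tiny_spec), tiny_spec, 1e-5)
        assert plot.current.shape == (100, tiny_spec.n_steps)
        assert not plot.current.any()

    def test_single_trace_lands_in_its_column_block(self, tiny_spec):
        traces = self._traces(tiny_spec)
        traces[(3, PHASE_ANODIC)] = np.ones(50)
        plot = assemble_colorplot(traces, tiny_spec, 1e-5)
        expected = np.zeros((100, tiny_spec.n_steps))
        expected[:50, 2] = 1.0
        np.testing.assert_array_equal(plot.current, expected)

    def test_charge_conservation(self, tiny_spec):
        rng = np.random.default_rng(5)
        traces = {
            k: rng.normal(0, 3, 50) for k in self._traces(tiny_spec)
        }
        dt = 1e-5
        plot = assemble_colorplot(traces, tiny_spec, dt)
        lhs = np.abs(plot.current).sum() * dt
        rhs = sum(np.abs(v).sum() * dt for v in traces.values())
        assert lhs == pytest.approx(rhs)

    def test_ragged_traces_rejected(self, tiny_spec):
        traces = self._traces(tiny_spec)
        traces[(1, PHASE_ANODIC)] = np.zeros(49)
        with pytest.raises(ValueError, match="ragged"):
            assemble_colorplot(traces, tiny_spec, 1e-5)

    def test_incomplete_traces_rejected(self, tiny_spec):
        traces = self._traces(tiny_spec)
        del traces[(1, PHASE_CATHODIC)]
        with pytest.raises(ValueError, match="missing"):
            assemble_colorplot(traces, tiny_spec, 1e-5)

    def test_axes_metadata(self, tiny_spec):
        plot = assemble_colorplot(self._traces(tiny_spec), tiny_spec, 1e-5)
        assert plot.step_potentials.size == tiny_spec.n_steps
        assert plot.samples_per_phase == 50
        assert plot.step_potentials[0] == tiny_spec.e_initial
        assert plot.step_potentials.max() == tiny_spec.e_peak


class TestPipelineLinearity:
    def test_scaling_raw_scan_scales_colorplot(self, tiny_spec, tiny_wf, quiet_model):
        """The extraction chain is linear: scaling the raw current by a
        scales the assembled plot by a (fits are re-done on scaled data)."""
        alpha = 2.5
        dt = 1.0 / tiny_spec.sample_rate

        def run(raw):
            segs = segment_scan(raw, tiny_wf)
            fits = fit_all_segments(segs)
            diff = csw_pair_difference(segs)
            out, valid = residual_background_subtract(
                diff, fits_by_key(segs, fits, 2), fits_by_key(segs, fits, 5), dt
            )
            return assemble_colorplot(out, tiny_spec, dt, valid=valid)

        raw = simulate_scan(quiet_model, tiny_wf, 150.0)
        scaled = type(raw)(
            current=alpha * raw.current, scan_index=0, timestamp=0.0
        )
        p1, p2 = run(raw), run(scaled)
        mask = p1.valid
        np.testing.assert_allclose(
            p2.current[mask], alpha * p1.current[mask], rtol=1e-3, atol=1e-6
        )


class TestExports:
    def test_colorplot_binary_round_trip(self, tiny_spec, tmp_path):
        from mcswv.extraction import (load_colorplot_binary,
                                      save_colorplot_binary,
                                      save_colorplot_text)

        rng = np.random.default_rng(1)
        plot = ColorPlot(
            current=rng.normal(0, 2, (10, tiny_spec.n_steps)),
            dt=1e-5,
            step_potentials=np.linspace(0, 0.1, tiny_spec.n_steps),
            scan_index=7,
            filtered=True,
        )
        p = tmp_path / "plot.npz"
        save_colorplot_binary(plot, p)
        back = load_colorplot_binary(p)
        np.testing.assert_array_equal(back.current, plot.current)
        assert back.scan_index == 7 and back.filtered

        t = tmp_path / "plot.txt"
        save_colorplot_text(plot, t)
        body = np.loadtxt(t, delimiter="\t")
        np.testing.assert_allclose(body, plot.current)

    def test_fit_diagnostics_table(self, tiny_wf, quiet_model):
        from mcswv import fit_all_segments, segment_scan, simulate_scan
        from mcswv.segmentation import fit_diagnostics_frame

        raw = simulate_scan(quiet_model, tiny_wf, 100.0)
        segs = segment_scan(raw, tiny_wf)
        fits = fit_all_segments(segs)
        df = fit_diagnostics_frame(segs, fits, scan_index=3)
        assert len(df) == len(segs)
        assert set(df["phase"]) == {"anodic", "cathodic"}
        assert (df["scan"] == 3).all()
        assert (df["tau_decay_s"] > 0).all()
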