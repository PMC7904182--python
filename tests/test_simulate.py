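"""Synthetic generator: trace shapes, event ordering, coupling, rendering."""

import math

import numpy as np
import pytest

import necroquant as nq
from necroquant.geometry import ring_annulus
from necroquant.simulate import CRT1_PEAK_CAP, NECROTIC_PEAK_RANGE


class TestCaTrace:
    def test_no_peaks_no_noise_is_flat_baseline(self):
        t = nq.default_time_grid()
        trace = nq.simulate_ca_trace(nq.TraceParams(), t)
        assert np.all(trace.values == 1.0)

    def test_uncapped_peak_reaches_programmed_amplitude(self):
        t = nq.default_time_grid()
        params = nq.TraceParams(peak_amplitudes=(5.0,), peak_times=(640.0,))
        trace = nq.simulate_ca_trace(params, t)
        imax = int(np.argmax(trace.values))
        assert trace.values[imax] == pytest.approx(5.0, rel=1e-12)
        assert abs(trace.times[imax] - 640.0) <= 2.5

    def test_cap_truncates_peak(self):
        t = nq.default_time_grid()
        params = nq.TraceParams(peak_amplitudes=(5.0,), peak_times=(640.0,), peak_cap=1.2)
        trace = nq.simulate_ca_trace(params, t)
        assert trace.values.max() <= 1.2

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            nq.simulate_ca_trace(nq.TraceParams(), np.array([1.0, 1.0, 2.0]))


class TestScenarioInvariants:
    def test_no_release_no_block_means_no_swelling(self):
        cfg = nq.ScenarioConfig(
            scenario_name="dead-channel", er_release_gain=0.0, reuptake_block=0.0, n_cells=3
        )
        for i in range(3):
            rec = nq.simulate_cell(cfg, i)
            assert rec.truth.swelling_onset is None
            assert np.all(rec.ps.values == 1.0)
            assert np.all(rec.radii == rec.radii[0])

    def test_event_ordering_in_swelling_cells(self):
        """Ca onset <= swelling onset <= PS onset in every swelling cell."""
        for seed in range(5):
            cfg = nq.scenario_config("mec-4(d)", n_cells=4, seed=seed)
            for i in range(4):
                truth = nq.simulate_cell(cfg, i).truth
                if truth.swelling_onset is not None:
                    assert truth.events.ordered()
                    assert truth.ca_onset is not None
                    assert truth.ps_onset is not None

    def test_necrotic_peak_amplitudes_within_published_range(self, necrotic_cohort):
        for rec in necrotic_cohort:
            peak = rec.ca.values.max()
            assert NECROTIC_PEAK_RANGE[0] <= peak <= NECROTIC_PEAK_RANGE[1] + 1e-9

    def test_crt1_like_traces_respect_cap(self):
        cfg = nq.scenario_config("crt-1", n_cells=6, seed=11)
        for i in range(6):
            assert nq.simulate_cell(cfg, i).ca.values.max() <= CRT1_PEAK_CAP

    def test_determinism(self):
        cfg = nq.scenario_config("mec-4(d)", n_cells=3, seed=7, noise_sd=0.05)
        table1, truth1, _ = nq.simulate_cohort([cfg])
        table2, truth2, _ = nq.simulate_cohort([cfg])
        assert table1.equals(table2)
        assert truth1.equals(truth2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            nq.ScenarioConfig(scenario_name="x", n_cells=0)
        with pytest.raises(ValueError):
            nq.ScenarioConfig(scenario_name="x", er_release_gain=-1.0)
        with pytest.raises(ValueError):
            nq.simulate_cohort([])
        cfg = nq.ScenarioConfig(scenario_name="dup")
        with pytest.raises(ValueError):
            nq.simulate_cohort([cfg, cfg])


class TestCoupling:
    def test_closed_form_log_linear_map(self):
        """Doubling the Ca integral shifts the log PS integral by slope*ln 2."""
        s, b = 1.7, 0.4
        lo = nq.coupled_ps_integral(100.0, s, b)
        hi = nq.coupled_ps_integral(200.0, s, b)
        assert math.log(hi) - math.log(lo) == pytest.approx(s * math.log(2), rel=1e-12)

    def test_plateau_ratio_for_matched_onsets(self):
        """Two noise-free cells with 2-fold different Ca integrals and the
        same PS onset have plateau enrichments in the ratio 2^slope."""
        t = nq.default_time_grid()
        base = dict(
            scenario_name="a", n_cells=1, swelling_threshold=5.0, ps_coupling_slope=1.3,
            n_peaks_range=(2, 2), peak_time_range=(620.0, 620.0),
            rise_width_range=(7.0, 7.0), decay_width_range=(20.0, 20.0), seed=0,
        )
        rec1 = nq.simulate_cell(nq.ScenarioConfig(**base), 0)
        # doubling the channel leak doubles every (Ca - 1) bump; the larger
        # cell crosses the threshold one 2.5-min sample earlier, so its PS
        # delay is lengthened by one sample to align the PS onsets
        rec2 = nq.simulate_cell(
            nq.ScenarioConfig(
                **{**base, "scenario_name": "b", "channel_leak": 2.0, "ps_delay": 45.0}
            ),
            0,
        )
        assert rec2.truth.ca_integral == pytest.approx(2 * rec1.truth.ca_integral, rel=1e-9)
        assert rec1.truth.ps_onset == rec2.truth.ps_onset
        ratio = rec2.truth.ps_plateau / rec1.truth.ps_plateau
        assert ratio == pytest.approx(2**1.3, rel=1e-9)

    def test_dose_monotonicity_noise_free(self):
        """Raising a dantrolene-like dose never increases any cell's Ca
        integral or PS plateau (noise off, shared seeds)."""
        doses = [0.0, 1.0, 2.0, 4.0]
        cells = {
            d: [
                nq.simulate_cell(
                    nq.ScenarioConfig(
                        scenario_name=f"d{d}",
                        er_release_gain=1.0 / (1.0 + 0.35 * d),
                        seed=5,
                    ),
                    i,
                )
                for i in range(4)
            ]
            for d in doses
        }
        for lo, hi in zip(doses, doses[1:]):
            for a, b in zip(cells[lo], cells[hi]):
                assert b.truth.ca_integral <= a.truth.ca_integral + 1e-12
                assert b.truth.ps_plateau <= a.truth.ps_plateau + 1e-12


class TestCohortTable:
    def test_long_table_passes_curve_inclusion_rule(self):
        cfg = nq.scenario_config("mec-4(d)", n_cells=4, seed=0)
        table, truth, _ = nq.simulate_cohort([cfg])
        counts = table.groupby("cell_id")["time_min"].count()
        assert (counts >= 10).all()
        assert set(table.columns) >= {"scenario", "cell_id", "time_min", "ca_r", "rps", "radius_px"}

    def test_dropout_preserves_support_and_thins_grid(self):
        cfg = nq.ScenarioConfig(scenario_name="drop", dropout_rate=0.5, seed=2)
        rec = nq.simulate_cell(cfg, 0)
        full = nq.default_time_grid()
        assert rec.times[0] == full[0] and rec.times[-1] == full[-1]
        assert rec.times.size < full.size


class TestRendering:
    def test_round_trip_no_enrichment(self):
        """A PS trace pinned at 1 quantifies to RPS = 1 from rendered frames."""
        cfg = nq.ScenarioConfig(scenario_name="live", er_release_gain=0.0, n_cells=1)
        rec = nq.simulate_cell(cfg, 0)
        fs = nq.render_frames([rec], nq.RenderGeometry(shape=(64, 64), centers=((32.0, 32.0),)))
        bg = nq.disk_polygon((32, 52), 5)
        ann = ring_annulus((32.0, 32.0), rec.radii[0], fs.ring_width)
        rps = nq.ps_relative_intensity(fs.frames["PS"][0], ann, bg).value
        assert rps == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_recovers_programmed_signals(self, rendered_cell):
        """Noise-free render -> quantify returns RPS and Ca_R within 2%."""
        rec, fs = rendered_cell
        bg = nq.disk_polygon((32, 52), 5)
        for ti in range(0, fs.times.size, 5):
            r = fs.radii[0, ti]
            ann = ring_annulus((32.0, 32.0), r, fs.ring_width)
            rps = nq.ps_relative_intensity(fs.frames["PS"][ti], ann, bg).value
            assert rps == pytest.approx(rec.ps.values[ti], rel=0.02)
            car = nq.ca_relative_intensity(
                fs.frames["Ca"][ti], nq.disk_polygon((32.0, 32.0), r, 96), bg
            ).value
            assert car == pytest.approx(rec.ca.values[ti], rel=0.02)

    def test_equivalent_disk_radius_tracks_truth(self, rendered_cell):
        """The area-equivalent radius of the rendered cell disk follows the
        programmed radius track (geometry identity)."""
        rec, fs = rendered_cell
        rr, cc = np.mgrid[0:64, 0:64]
        dist = np.hypot(rr - 32.0, cc - 32.0)
        for ti in (0, fs.times.size - 1):
            area = (dist <= fs.radii[0, ti]).sum()
            r_eq = np.sqrt(area / np.pi)
            assert r_eq == pytest.approx(fs.radii[0, ti], rel=0.15)
        assert fs.radii[0, -1] == pytest.approx(
            rec.truth.initial_radius * 2.5, rel=1e-6
        )

    def test_border_overlap_rejected(self):
        cfg = nq.scenario_config("mec-4(d)", n_cells=1, seed=0)
        rec = nq.simulate_cell(cfg, 0)
        with pytest.raises(ValueError, match="border"):
            nq.render_frames([rec], nq.RenderGeometry(shape=(24, 24), centers=((12.0, 12.0),)))

    def test_stack_save_round_trip(self, rendered_cell, tmp_path):
        import tifffile

        _, fs = rendered_cell
        written = fs.save(tmp_path / "frames")
        ca = tifffile.imread(written["Ca"])
        assert ca.shape == fs.frames["Ca"].shape
        np.testing.assert_allclose(ca, fs.frames["Ca"].astype(np.float32))


def test_scenario_config_json_round_trip():
    cfg = nq.scenario_config("thapsigargin", dose=3.0, seed=9)
    again = nq.ScenarioConfig.from_json(cfg.to_json())
    assert again == cfg
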