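import numpy as np
import pytest

from dgephys import features as ft
from dgephys import synthetic as syn
from dgephys.sweep_io import Sweep

from conftest import make_sweep, make_sweepset, paste_spike

DT = 0.05


class TestDetectSpikes:
    def test_subthreshold_sinusoid_ignored(self):
        t = np.arange(0, 500, DT)
        v = -40.0 + 20.0 * np.sin(2 * np.pi * t / 50.0)  # peaks at -20 mV
        assert ft.detect_spikes(make_sweep(v, DT)) == []

    def test_pasted_templates_found_at_known_times(self):
        v = np.full(int(500 / DT), -60.0)
        for t0 in (100.0, 200.0, 300.0):
            paste_spike(v, DT, t0, peak_mV=30.0)
        events = ft.detect_spikes(make_sweep(v, DT))
        assert len(events) == 3
        peaks = [e.peak_time_ms for e in events]
        for found, t0 in zip(peaks, (100.6, 200.6, 300.6)):
            assert found == pytest.approx(t0, abs=2 * DT)

    def test_attenuated_spikes_excluded_by_overshoot(self):
        """Spikes whose peaks fail to cross 0 mV are not events."""
        v = np.full(int(800 / DT), -60.0)
        peaks = [30.0] * 7 + [-5.0] * 3
        for k, pk in enumerate(peaks):
            paste_spike(v, DT, 100.0 + 50.0 * k, peak_mV=pk)
        events = ft.detect_spikes(make_sweep(v, DT))
        assert len(events) == 7

    def test_min_separation(self):
        v = np.full(int(100 / DT), -60.0)
        paste_spike(v, DT, 20.0, peak_mV=30.0)
        paste_spike(v, DT, 30.0, peak_mV=30.0)
        events = ft.detect_spikes(make_sweep(v, DT), min_sep_ms=2.0)
        assert len(events) == 2


class TestSpikeThreshold:
    def test_piecewise_linear_rise(self):
        """Rise at 5 mV/ms then 50 mV/ms switching at -45 mV: the criterion
        crossing sits at the switch point."""
        v = [-60.0]
        while v[-1] < -45.0:
            v.append(v[-1] + 5.0 * DT)
        while v[-1] < 20.0:
            v.append(v[-1] + 50.0 * DT)
        peak_idx = len(v) - 1
        v += [-60.0] * 100
        sweep = make_sweep(np.array(v), DT)
        t_thr, v_thr = ft.spike_threshold(sweep, peak_idx)
        assert v_thr == pytest.approx(-45.0, abs=5 * 5 * DT)

    def test_slow_spike_has_no_threshold(self):
        v = [-60.0]
        while v[-1] < 10.0:
            v.append(v[-1] + 8.0 * DT)  # max rise 8 mV/ms < criterion
        sweep = make_sweep(np.array(v + [-60.0] * 50), DT)
        with pytest.raises(ft.ThresholdNotFoundError):
            ft.spike_threshold(sweep, len(v) - 1)

    def test_recovers_generator_threshold(self, wt1_params):
        """Measured V_trh matches the generator's true VT within 0.5 mV."""
        prot = syn.firing_protocol()
        ss = syn.simulate_cell(wt1_params, prot, seed=1)
        io = ft.io_curve(ss)
        _, _, vtrh = ft.current_threshold_and_latency(io, ss)
        assert vtrh == pytest.approx(wt1_params.VT_mV, abs=0.5)


class TestIOCurve:
    def _set_with_spiketimes(self, times_per_amp, amps):
        n = int(800 / DT)
        volts = []
        for times in times_per_amp:
            v = np.full(n, -60.0)
            for t0 in times:
                paste_spike(v, DT, t0, peak_mV=30.0)
            volts.append(v)
        return make_sweepset(volts, amps, dt_ms=DT)

    def test_uniform_isis(self):
        # peaks at threshold time + 0.6 ms; uniform 10-ms spacing
        ss = self._set_with_spiketimes([[200.0, 210.0, 220.0, 230.0]], [50.0])
        io = ft.io_curve(ss)
        assert io.n_spikes[0] == 4
        np.testing.assert_allclose(io.isi_ms[0], [10.0, 10.0, 10.0], atol=2 * DT)
        assert io.avg_inst_freq_Hz[0] == pytest.approx(100.0, rel=0.02)

    def test_mean_of_reciprocal_isis(self):
        ss = self._set_with_spiketimes([[200.0, 210.0, 230.0]], [50.0])
        io = ft.io_curve(ss)
        assert io.avg_inst_freq_Hz[0] == pytest.approx(75.0, rel=0.02)
        io2 = ft.io_curve(ss, freq_mode="inverse_mean_isi")
        assert io2.avg_inst_freq_Hz[0] == pytest.approx(2 / 0.030, rel=0.02)

    def test_single_spike_frequency_undefined(self):
        ss = self._set_with_spiketimes([[200.0]], [50.0])
        io = ft.io_curve(ss)
        assert io.n_spikes[0] == 1
        assert io.isi_ms[0].size == 0
        assert np.isnan(io.avg_inst_freq_Hz[0])

    def test_uniform_identity(self):
        """avg_inst_freq = (count-1)/(t_last - t_first) for uniform ISIs."""
        times = [150.0 + 20.0 * k for k in range(6)]
        ss = self._set_with_spiketimes([times], [50.0])
        io = ft.io_curve(ss)
        expected = 1000.0 * 5 / (times[-1] - times[0])
        assert io.avg_inst_freq_Hz[0] == pytest.approx(expected, rel=0.02)

    def test_rheobase_and_latency(self):
        amps = [10.0, 20.0, 30.0, 40.0, 50.0]
        spikes = [[], [], [], [250.0], [200.0, 240.0, 280.0]]
        ss = self._set_with_spiketimes(spikes, amps)
        io = ft.io_curve(ss)
        itrh, lat, vtrh = ft.current_threshold_and_latency(io, ss)
        assert itrh == 40.0
        assert lat == pytest.approx(150.0, abs=0.5)  # threshold time - onset
        assert vtrh == pytest.approx(-48.0, abs=1.0)

    def test_no_rheobase(self):
        ss = self._set_with_spiketimes([[], []], [10.0, 20.0])
        io = ft.io_curve(ss)
        with pytest.raises(ft.NoRheobaseError):
            ft.current_threshold_and_latency(io, ss)

    def test_rheobase_monotone_in_spike_removal(self):
        """Silencing low-amplitude sweeps never lowers the rheobase."""
        amps = [10.0, 20.0, 30.0]
        ss_full = self._set_with_spiketimes([[200.0], [200.0], [200.0]], amps)
        ss_cut = self._set_with_spiketimes([[], [200.0], [200.0]], amps)
        i_full = ft.current_threshold_and_latency(ft.io_curve(ss_full), ss_full)[0]
        i_cut = ft.current_threshold_and_latency(ft.io_curve(ss_cut), ss_cut)[0]
        assert i_cut >= i_full


class TestAHPDecompose:
    def _constructed_trace(self, bump=True):
        """Spike at 200 ms, trough -60 at +3 ms, bump -55 at +15 ms,
        late minimum -59.5 inside the slow window."""
        n = int(500 / DT)
        v = np.full(n, -57.0)
        t = np.arange(n) * DT
        p = 200.6  # peak time after paste at threshold time 200
        rel = t - p
        post = rel > 1.4  # after the template fall
        trough = -60.0 + 2.0 * np.abs(rel - 3.0) ** 0.7
        v[post] = np.minimum(v[post], trough[post])
        if bump:
            bump_v = -55.0 - 0.35 * np.abs(rel - 15.0)
            mask = post & (rel > 5.0) & (rel < 40.0)
            v[mask] = np.maximum(v[mask], bump_v[mask])
        slow = -59.5 + 0.08 * np.abs(rel - 90.0)
        mask = post & (rel > 50.0)
        v[mask] = np.minimum(v[mask], slow[mask])
        paste_spike(v, DT, 200.0, peak_mV=30.0, thr_mV=-48.0, base=-58.0)
        sweep = make_sweep(v, DT)
        spike = ft.detect_spikes(sweep)[0]
        return sweep, spike

    def test_constructed_triphasic_values(self):
        sweep, spike = self._constructed_trace()
        ahp = ft.ahp_decompose(sweep, spike)
        assert ahp.fAHP_mV == pytest.approx(-60.0 - spike.thr_mV, abs=0.3)
        assert ahp.ADP_mV == pytest.approx(5.0, abs=0.3)
        assert ahp.sAHP_mV == pytest.approx(-59.5 - spike.thr_mV, abs=0.3)
        assert ahp.t_fAHP_ms < ahp.t_ADP_ms < ahp.t_sAHP_ms

    def test_monotonic_recovery_gives_zero_adp(self):
        """When the voltage keeps falling after the fast trough (no bump),
        the measured ADP is zero."""
        n = int(500 / DT)
        v = np.full(n, -58.0)
        t = np.arange(n) * DT
        rel = t - 200.6
        mask = rel > 1.4
        v[mask] = -58.0 - 4.0 * (1 - np.exp(-rel[mask] / 30.0))  # monotone fall
        paste_spike(v, DT, 200.0, peak_mV=30.0, base=-58.0)
        sweep = make_sweep(v, DT)
        spike = ft.detect_spikes(sweep)[0]
        ahp = ft.ahp_decompose(sweep, spike)
        assert ahp.ADP_mV == 0.0
        assert ahp.fAHP_mV <= 0.0 and ahp.sAHP_mV <= ahp.fAHP_mV

    def test_follower_spike_rejected(self):
        n = int(500 / DT)
        v = np.full(n, -58.0)
        paste_spike(v, DT, 200.0, peak_mV=30.0)
        paste_spike(v, DT, 260.0, peak_mV=30.0)
        sweep = make_sweep(v, DT)
        first = ft.detect_spikes(sweep)[0]
        with pytest.raises(ft.NotIsolatedError):
            ft.ahp_decompose(sweep, first)

    def test_sign_conventions_on_simulator_output(self, wt1_params, wt2_params):
        for params in (wt1_params, wt2_params):
            ss = syn.find_ahp_sweep(params, seed=5)
            prot = ss.protocol
            spike = ft.detect_spikes(
                ss.sweeps[0], window_ms=(prot.onset_ms, prot.offset_ms)
            )[0]
            ahp = ft.ahp_decompose(ss.sweeps[0], spike)
            assert ahp.fAHP_mV <= 0.0
            assert ahp.ADP_mV >= 0.0
            assert ahp.sAHP_mV <= 0.0


class TestMRP:
    def test_constant_trace(self):
        v = np.full(2000, -60.0)
        assert ft.measure_mrp(make_sweep(v, 0.5)) == -60.0

    def test_noisy_trace_averages_out(self):
        rng = np.random.default_rng(0)
        v = -60.0 + rng.normal(0, 1.0, 40_000)
        assert ft.measure_mrp(make_sweep(v, DT)) == pytest.approx(-60.0, abs=0.1)

    def test_spontaneous_spike_raises(self):
        v = np.full(int(500 / DT), -60.0)
        paste_spike(v, DT, 250.0, peak_mV=25.0)
        with pytest.raises(ft.SpontaneousFiringError):
            ft.measure_mrp(make_sweep(v, DT))


class TestPassiveProperties:
    def _linear_set(self, slope_mv_per_pa=0.4, n_amps=8):
        amps = np.arange(-120.0, -120.0 + 20.0 * n_amps, 20.0)
        n = int(400 / DT)
        volts = []
        for a in amps:
            v = np.full(n, -70.0)
            on, off = int(100 / DT), int(300 / DT)
            v[on:off] = -70.0 + slope_mv_per_pa * a
            volts.append(v)
        return make_sweepset(volts, amps, dt_ms=DT, onset_ms=100.0,
                             duration_ms=200.0, tail_ms=100.0, name="passive")

    def test_exact_line(self):
        rin, r2, flags = ft.estimate_rin(self._linear_set(0.4))
        assert rin == pytest.approx(400.0)
        assert r2 == pytest.approx(1.0)

    def test_flat_responses_flagged(self):
        rin, _, flags = ft.estimate_rin(self._linear_set(0.0))
        assert rin == pytest.approx(0.0, abs=1e-9)
        assert "nonpositive_slope" in flags

    def test_spiking_sweeps_excluded(self):
        ss = self._linear_set(0.4)
        paste_spike(ss.sweeps[-1].voltage_mV, DT, 150.0, peak_mV=30.0)
        rin, _, flags = ft.estimate_rin(ss)
        assert rin == pytest.approx(400.0, rel=1e-6)
        assert any(f.startswith("excluded") for f in flags)

    def test_too_few_points(self):
        ss = self._linear_set(0.4, n_amps=2)
        with pytest.raises(ft.InsufficientDataError):
            ft.estimate_rin(ss)

    def test_pure_exponential_tau(self):
        t = np.arange(0, 300, DT)
        v = -70.0 - 15.0 * (1 - np.exp(-np.clip(t - 100.0, 0, None) / 26.0))
        tau, resid = ft.estimate_tau(make_sweep(v, DT), 100.0)
        assert tau == pytest.approx(26.0, abs=0.1)
        assert resid < 1e-6

    def test_noiseless_simulator_recovery(self, wt1_params):
        ss = syn.simulate_cell(wt1_params, syn.passive_protocol(), seed=0)
        rin, r2, _ = ft.estimate_rin(ss)
        tau, _ = ft.estimate_tau(ss.sweep_at(-40.0), 100.0)
        assert rin == pytest.approx(wt1_params.R_MOhm, rel=0.01)
        assert tau == pytest.approx(wt1_params.tau_m_ms, rel=0.02)
        cm = ft.estimate_cm(tau, rin)
        assert cm == pytest.approx(wt1_params.C_pF, rel=0.03)

    def test_linear_ramp_flagged(self):
        t = np.arange(0, 300, DT)
        v = -70.0 - 0.05 * np.clip(t - 100.0, 0, None)
        try:
            tau, resid = ft.estimate_tau(make_sweep(v, DT), 100.0)
        except ft.FitError:
            return
        assert resid > 0.01 or tau > 1000.0

    @pytest.mark.parametrize(
        "tau,rin,expected",
        [(26.1, 443.3, 58.87), (40.0, 400.0, 100.0)],
    )
    def test_capacitance_closed_form(self, tau, rin, expected):
        assert ft.estimate_cm(tau, rin) == pytest.approx(expected, abs=0.01)

    def test_capacitance_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ft.estimate_cm(26.0, 0.0)


class TestCompositeExtraction:
    def test_full_battery_on_simulated_cell(self, wt1_params):
        from dgephys.sweep_io import CellMeta

        meta = CellMeta("c1", "a1", "WT")
        protos = {
            "mrp": syn.simulate_cell(wt1_params, syn.mrp_protocol(), seed=1, meta=meta),
            "passive": syn.simulate_cell(wt1_params, syn.passive_protocol(), seed=2, meta=meta),
            "firing": syn.simulate_cell(wt1_params, syn.firing_protocol(), seed=3, meta=meta),
            "ahp": syn.find_ahp_sweep(wt1_params, seed=4, meta=meta),
        }
        feats = ft.extract_cell_features(protos)
        assert feats.MRP_mV == pytest.approx(wt1_params.EL_mV, abs=0.5)
        assert feats.I_trh_pA == pytest.approx(30.0, abs=10.0)
        assert feats.V_trh_mV == pytest.approx(wt1_params.VT_mV, abs=1.0)
        assert 0 < feats.first_spike_latency_ms <= 500.0
        assert feats.passive.R_in_MOhm == pytest.approx(wt1_params.R_MOhm, rel=0.02)
        assert feats.ahp.fAHP_mV <= 0 <= feats.ahp.ADP_mV
        assert feats.qc is not None and feats.qc.passed

        df = ft.features_to_frame([feats], [meta])
        assert df.loc[0, "cell_id"] == "c1"
        assert "n_spikes_220pA" in df.columns
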