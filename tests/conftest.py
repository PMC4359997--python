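import numpy as np
import pytest

from dgephys import synthetic as syn
from dgephys.sweep_io import CellMeta, StepProtocol, Sweep, SweepSet


@pytest.fixture(scope="session")
def wt1_params():
    """Noiseless wild-type type I cell (preset means)."""
    p = dict(syn.group_presets()[("WT", "typeI")].means)
    p["noise_sd_pA"] = 0.0
    return syn.SimCellParams(**p)


@pytest.fixture(scope="session")
def wt2_params():
    """Noiseless wild-type type II cell (preset means)."""
    p = dict(syn.group_presets()[("WT", "typeII")].means)
    p["noise_sd_pA"] = 0.0
    return syn.SimCellParams(**p)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared default-noise cohort (~100 cells, all four groups)."""
    cfg = syn.CohortConfig(seed=11, n_animals_per_group=13,
                           cells_per_animal_range=(1, 3))
    cells, manifest, truth = syn.make_cohort(cfg)
    return cells, manifest, truth


def make_sweep(voltage, dt_ms=0.05, amplitude_pA=0.0):
    return Sweep(np.asarray(voltage, dtype=float), dt_ms, amplitude_pA)


def make_sweepset(voltages, amplitudes, dt_ms=0.05, onset_ms=100.0,
                  duration_ms=500.0, tail_ms=200.0, name="firing",
                  group="WT"):
    prot = StepProtocol(name=name, onset_ms=onset_ms, duration_ms=duration_ms,
                        amplitudes_pA=np.asarray(amplitudes, dtype=float),
                        tail_ms=tail_ms)
    meta = CellMeta(cell_id="c1", animal_id="a1", group=group)
    sweeps = [make_sweep(v, dt_ms, a) for v, a in zip(voltages, amplitudes)]
    return SweepSet(meta=meta, protocol=prot, sweeps=sweeps)


def paste_spike(voltage, dt_ms, t_ms, peak_mV, thr_mV=-48.0, rise_ms=0.6,
                fall_ms=1.4, base=None):
    """Paste a detector-compatible spike template at t_ms (threshold time).

    A sub-criterion ramp (8 mV/ms) leads from the baseline up to the
    threshold so the last dV/dt crossing sits inside the template rise,
    as it does for a physiological depolarization.
    """
    i0 = int(round(t_ms / dt_ms))
    n_r = int(round(rise_ms / dt_ms))
    n_f = int(round(fall_ms / dt_ms))
    if base is None:
        base = voltage[i0]
    if thr_mV > base:
        n_ramp = int(np.ceil((thr_mV - base) / (8.0 * dt_ms)))
        kr = np.arange(-n_ramp, 0)
        voltage[i0 + kr] = thr_mV + 8.0 * dt_ms * kr
    k = np.arange(1, n_r + 1)
    voltage[i0:i0 + n_r] = thr_mV + (peak_mV - thr_mV) * (k / n_r) ** 3
    k = np.arange(1, n_f + 1)
    voltage[i0 + n_r:i0 + n_r + n_f] = base + (peak_mV - base) * 0.5 * (
        1 + np.cos(np.pi * k / n_f)
    )
    return voltage
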