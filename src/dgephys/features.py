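"""Per-cell feature extraction from current-clamp sweeps.

Implements the standard current-clamp measurement battery for granule
neurons: overshooting-spike detection with a dV/dt voltage-threshold
criterion, input-output curves (spike counts, interspike intervals,
averaged instantaneous firing frequency), rheobase (I_trh) with first-spike
latency and V_trh, triphasic after-hyperpolarization decomposition
(fAHP / ADP / sAHP), resting potential, and passive properties (input
resistance from the steady-state V-I regression, membrane time constant
from a single-exponential fit, capacitance as tau / R_in).

Conventions
-----------
* Only spikes whose peak overshoots 0 mV count as events.
* V_trh is the voltage at the LAST upward crossing of dV/dt >= 10 mV/ms
  (central difference) within 5 ms before the peak; a depolarization whose
  rise never reaches the criterion is not a spike and is excluded.
* First-spike latency is referenced to the threshold-crossing time of the
  first spike at I_trh (spike initiation), not its peak.
* fAHP and sAHP are measured relative to V_trh; ADP relative to the fAHP
  trough.  Sign conventions: fAHP <= 0, ADP >= 0, sAHP <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .sweep_io import QCResult, Sweep, SweepSet

SLOPE_CRITERION_mV_per_ms = 10.0


class FeatureError(ValueError):
    """Base class for extraction failures."""


class ThresholdNotFoundError(FeatureError):
    """No dV/dt criterion crossing in the pre-peak search window."""


class NoRheobaseError(FeatureError):
    """No step amplitude elicited an overshooting spike."""


class NotIsolatedError(FeatureError):
    """Another spike follows within the AHP analysis window."""


class SpontaneousFiringError(FeatureError):
    """Overshooting spikes present where the trace must be quiescent."""


class InsufficientDataError(FeatureError):
    """Too few usable points for a regression."""


class FitError(FeatureError):
    """Nonlinear fit failed to converge."""


@dataclass
class SpikeEvent:
    """One detected action potential with peak and threshold annotations."""

    peak_time_ms: float
    peak_mV: float
    thr_time_ms: float
    thr_mV: float

    @property
    def overshoot(self) -> bool:
        return self.peak_mV > 0.0


@dataclass
class IOCurve:
    """Input-output relation: per-step spike counts, ISIs and firing rate.

    ``avg_inst_freq_Hz`` is the arithmetic mean of the reciprocal ISIs
    (NaN where fewer than two spikes); ``freq_mode="inverse_mean_isi"``
    selects the alternative convention (count-1)/(t_last-t_first).
    """

    amplitudes_pA: np.ndarray
    n_spikes: np.ndarray
    isi_ms: list  # one ordered array per amplitude
    avg_inst_freq_Hz: np.ndarray
    events: list = field(default_factory=list)  # per-amplitude SpikeEvent lists

    def count_at(self, amplitude_pA: float) -> int:
        idx = np.flatnonzero(self.amplitudes_pA == amplitude_pA)
        if idx.size == 0:
            raise KeyError(f"no step at {amplitude_pA} pA")
        return int(self.n_spikes[idx[0]])


@dataclass
class AHPMeasures:
    fAHP_mV: float
    ADP_mV: float
    sAHP_mV: float
    t_fAHP_ms: float
    t_ADP_ms: float
    t_sAHP_ms: float


@dataclass
class PassiveProperties:
    R_in_MOhm: float
    tau_ms: float
    C_m_pF: float
    r2: float
    tau_residual_mV: float
    flags: list = field(default_factory=list)


@dataclass
class CellFeatures:
    """Every per-cell derived quantity, one object per recorded cell."""

    cell_id: str
    MRP_mV: Optional[float] = None
    I_trh_pA: Optional[float] = None
    V_trh_mV: Optional[float] = None
    first_spike_latency_ms: Optional[float] = None
    io: Optional[IOCurve] = None
    ahp: Optional[AHPMeasures] = None
    passive: Optional[PassiveProperties] = None
    qc: Optional[QCResult] = None


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def spike_threshold(
    sweep: Sweep,
    peak_idx: int,
    slope_crit: float = SLOPE_CRITERION_mV_per_ms,
    search_ms: float = 5.0,
) -> tuple[float, float]:
    """Threshold time and voltage for the spike peaking at ``peak_idx``.

    Returns the last upward crossing of dV/dt >= ``slope_crit`` within
    ``search_ms`` before the peak; the derivative is a central difference.
    """
    v = sweep.voltage_mV
    dt = sweep.dt_ms
    lo = max(1, peak_idx - int(round(search_ms / dt)))
    hi = min(peak_idx, v.size - 1)
    if hi <= lo:
        raise ThresholdNotFoundError("empty search window")
    dv = (v[lo + 1 : hi + 1] - v[lo - 1 : hi - 1]) / (2 * dt)  # at lo..hi-1
    above = dv >= slope_crit
    if not above.any():
        raise ThresholdNotFoundError(
            f"rise never reached {slope_crit} mV/ms before peak at {peak_idx * dt:.2f} ms"
        )
    # upward crossings: below criterion at i-1, at/above at i
    cross = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if cross.size:
        k = lo + int(cross[-1])
    elif above[0]:
        k = lo  # already above at window start: take the window start
    else:
        raise ThresholdNotFoundError("no upward crossing in window")
    return k * dt, float(v[k])


def detect_spikes(
    sweep: Sweep,
    window_ms: Optional[tuple] = None,
    overshoot_mV: float = 0.0,
    min_sep_ms: float = 2.0,
    slope_crit: float = SLOPE_CRITERION_mV_per_ms,
    search_ms: float = 5.0,
) -> list[SpikeEvent]:
    """Overshooting spikes in ``window_ms`` (default: whole trace).

    Local maxima above ``overshoot_mV`` separated by >= ``min_sep_ms`` are
    candidate peaks; each must satisfy the dV/dt threshold criterion or it
    is discarded (e.g. smooth depolarized plateaus during depolarization
    block).
    """
    v = sweep.voltage_mV
    dt = sweep.dt_ms
    if window_ms is None:
        i0, i1 = 0, v.size
    else:
        i0 = int(round(window_ms[0] / dt))
        i1 = int(round(window_ms[1] / dt))
        i0 = max(0, i0)
        i1 = min(v.size, i1)
    if i1 <= i0:
        raise FeatureError("empty detection window")
    seg = v[i0:i1]
    distance = max(1, int(round(min_sep_ms / dt)))
    peaks, _ = find_peaks(seg, height=overshoot_mV, distance=distance)
    events = []
    for p in peaks:
        idx = i0 + int(p)
        try:
            thr_t, thr_v = spike_threshold(sweep, idx, slope_crit, search_ms)
        except ThresholdNotFoundError:
            continue
        events.append(
            SpikeEvent(
                peak_time_ms=idx * dt,
                peak_mV=float(v[idx]),
                thr_time_ms=thr_t,
                thr_mV=thr_v,
            )
        )
    return events


# ---------------------------------------------------------------------------
# input-output relation and rheobase
# ---------------------------------------------------------------------------

def io_curve(sweepset: SweepSet, freq_mode: str = "mean_inverse_isi") -> IOCurve:
    """Spike counts, ISIs and averaged instantaneous frequency per step."""
    if freq_mode not in ("mean_inverse_isi", "inverse_mean_isi"):
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    prot = sweepset.protocol
    window = (prot.onset_ms, prot.offset_ms)
    amps = prot.amplitudes_pA
    counts = np.zeros(amps.size, dtype=int)
    isis: list = []
    freqs = np.full(amps.size, np.nan)
    all_events = []
    for i, sweep in enumerate(sweepset.sweeps):
        events = detect_spikes(sweep, window_ms=window)
        all_events.append(events)
        counts[i] = len(events)
        times = np.array([e.peak_time_ms for e in events])
        isi = np.diff(times)
        isis.append(isi)
        if len(events) >= 2:
            if freq_mode == "mean_inverse_isi":
                freqs[i] = float(np.mean(1000.0 / isi))
            else:
                freqs[i] = 1000.0 * (len(events) - 1) / (times[-1] - times[0])
    return IOCurve(
        amplitudes_pA=amps.copy(),
        n_spikes=counts,
        isi_ms=isis,
        avg_inst_freq_Hz=freqs,
        events=all_events,
    )


def current_threshold_and_latency(
    io: IOCurve, sweepset: SweepSet
) -> tuple[float, float, float]:
    """(I_trh, first-spike latency, V_trh) from an input-output curve.

    I_trh is the smallest step amplitude with at least one overshooting
    spike; latency and V_trh come from that step's first spike, latency
    being the threshold-crossing time minus the step onset.
    """
    supra = np.flatnonzero(io.n_spikes >= 1)
    if supra.size == 0:
        raise NoRheobaseError("no spikes at any step amplitude")
    i = int(supra[0])
    first = io.events[i][0]
    latency = first.thr_time_ms - sweepset.protocol.onset_ms
    return float(io.amplitudes_pA[i]), float(latency), float(first.thr_mV)


# ---------------------------------------------------------------------------
# after-hyperpolarization decomposition
# ---------------------------------------------------------------------------

def ahp_decompose(
    sweep: Sweep,
    spike: SpikeEvent,
    w_f_ms: float = 10.0,
    s_window_ms: tuple = (60.0, 120.0),
) -> AHPMeasures:
    """Triphasic AHP of an isolated spike.

    fAHP = (minimum V within ``w_f_ms`` after the peak) - V_trh;
    ADP  = (maximum V between the fAHP trough and peak+60 ms) - trough;
    sAHP = (minimum V in peak + [60, 120] ms) - V_trh.

    Raises :class:`NotIsolatedError` when another overshooting spike occurs
    within ``s_window_ms[1]`` after the peak.
    """
    v = sweep.voltage_mV
    dt = sweep.dt_ms
    p = int(round(spike.peak_time_ms / dt))
    end = p + int(round(s_window_ms[1] / dt))
    if end >= v.size:
        raise FeatureError("AHP window extends past the end of the trace")
    followers = detect_spikes(
        sweep, window_ms=(spike.peak_time_ms + 1.0, spike.peak_time_ms + s_window_ms[1])
    )
    if followers:
        raise NotIsolatedError(
            f"spike at {followers[0].peak_time_ms:.1f} ms inside AHP window"
        )
    f0, f1 = p + 1, p + int(round(w_f_ms / dt)) + 1
    k_f = f0 + int(np.argmin(v[f0:f1]))
    v_f = float(v[k_f])
    a1 = p + int(round(s_window_ms[0] / dt)) + 1
    k_a = k_f + int(np.argmax(v[k_f:a1]))
    v_a = float(v[k_a])
    s0, s1 = p + int(round(s_window_ms[0] / dt)), p + int(round(s_window_ms[1] / dt)) + 1
    k_s = s0 + int(np.argmin(v[s0:s1]))
    v_s = float(v[k_s])
    return AHPMeasures(
        fAHP_mV=v_f - spike.thr_mV,
        ADP_mV=v_a - v_f,
        sAHP_mV=v_s - spike.thr_mV,
        t_fAHP_ms=k_f * dt,
        t_ADP_ms=k_a * dt,
        t_sAHP_ms=k_s * dt,
    )


# ---------------------------------------------------------------------------
# resting and passive properties
# ---------------------------------------------------------------------------

def measure_mrp(sweep: Sweep, window_ms: Optional[tuple] = None) -> float:
    """Mean resting potential over a zero-current window; spikes forbidden."""
    if window_ms is None:
        window_ms = (0.0, sweep.n_samples * sweep.dt_ms)
    spikes = detect_spikes(sweep, window_ms=window_ms)
    if spikes:
        raise SpontaneousFiringError(f"{len(spikes)} spikes in MRP window")
    i0 = int(round(window_ms[0] / sweep.dt_ms))
    i1 = min(sweep.n_samples, int(round(window_ms[1] / sweep.dt_ms)))
    return float(sweep.voltage_mV[i0:i1].mean())


def estimate_rin(
    sweepset: SweepSet, ss_window_ms: float = 50.0
) -> tuple[float, float, list]:
    """Input resistance from the steady-state V-I regression.

    The steady state is the mean voltage over the last ``ss_window_ms`` of
    the step; sweeps containing spikes are excluded.  Returns
    ``(R_in_MOhm, r2, flags)`` where the slope in mV/pA is scaled by 1000
    to megaohms.
    """
    prot = sweepset.protocol
    xs, ys = [], []
    flags: list = []
    for sweep in sweepset.sweeps:
        if detect_spikes(sweep):
            flags.append(f"excluded_{sweep.amplitude_pA:g}pA")
            continue
        j1 = int(round(prot.offset_ms / sweep.dt_ms))
        j0 = j1 - int(round(ss_window_ms / sweep.dt_ms))
        xs.append(sweep.amplitude_pA)
        ys.append(sweep.voltage_mV[j0:j1].mean())
    if len(xs) < 3:
        raise InsufficientDataError(f"only {len(xs)} usable steps")
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rin = float(slope * 1000.0)
    if rin <= 0:
        flags.append("nonpositive_slope")
    return rin, r2, flags


def estimate_tau(
    sweep: Sweep, onset_ms: float, fit_ms: float = 100.0
) -> tuple[float, float]:
    """Membrane time constant from a single-exponential fit.

    Fits V(t) = V_ss + (V_0 - V_ss) exp(-(t - t_on)/tau) over
    [onset, onset + fit_ms] on a (hyperpolarizing, spike-free) step.
    Returns (tau_ms, rms residual in mV).
    """
    if detect_spikes(sweep):
        raise FeatureError("spikes in tau-fit sweep")
    dt = sweep.dt_ms
    i0 = int(round(onset_ms / dt))
    i1 = min(sweep.n_samples, i0 + int(round(fit_ms / dt)))
    t = (np.arange(i0, i1) - i0) * dt
    y = sweep.voltage_mV[i0:i1]
    v0 = float(y[0])
    vss = float(y[-int(0.2 * y.size) :].mean())
    if abs(vss - v0) < 1e-9:
        raise FitError("flat response, tau undefined")

    def model(tt, v_ss, v_0, tau):
        return v_ss + (v_0 - v_ss) * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(vss, v0, max(fit_ms / 5.0, 1.0)),
            bounds=([-200.0, -200.0, 1e-3], [100.0, 100.0, 1e4]),
            xtol=1e-8,
            ftol=1e-8,
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    tau = float(popt[2])
    resid = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return tau, resid


def estimate_cm(tau_ms: float, R_in_MOhm: float) -> float:
    """Membrane capacitance from tau = R C: C [pF] = 1000 tau [ms] / R [MOhm]."""
    if tau_ms <= 0 or R_in_MOhm <= 0:
        raise ValueError("tau and R_in must be positive")
    return 1000.0 * tau_ms / R_in_MOhm


# ---------------------------------------------------------------------------
# whole-cell composite
# ---------------------------------------------------------------------------

def extract_cell_features(
    protocols: dict,
    tau_step_pA: float = -40.0,
    rule_mode: str = "or",
    freq_mode: str = "mean_inverse_isi",
) -> CellFeatures:
    """Full feature battery from a cell's protocol dictionary.

    ``protocols`` maps protocol names to SweepSets; recognized names are
    ``"mrp"`` (zero-current epoch), ``"passive"`` (subthreshold step
    family), ``"firing"`` (suprathreshold step family) and ``"ahp"``
    (single sweep holding one isolated spike).  Missing protocols leave the
    corresponding features as None.
    """
    from .sweep_io import qc_evaluate

    any_ss = next(iter(protocols.values()))
    feats = CellFeatures(cell_id=any_ss.meta.cell_id)

    spontaneous = None
    if "mrp" in protocols:
        ss = protocols["mrp"]
        sweep = ss.sweeps[0]
        try:
            feats.MRP_mV = measure_mrp(sweep)
            spontaneous = 0
        except SpontaneousFiringError:
            spontaneous = len(detect_spikes(sweep))
            # spikes contaminate the mean; report the median for bookkeeping
            feats.MRP_mV = float(np.median(sweep.voltage_mV))

    if "passive" in protocols:
        ss = protocols["passive"]
        flags: list = []
        try:
            rin, r2, rin_flags = estimate_rin(ss)
            flags.extend(rin_flags)
        except InsufficientDataError:
            rin, r2 = np.nan, np.nan
            flags.append("rin_failed")
        try:
            tau, resid = estimate_tau(ss.sweep_at(tau_step_pA), ss.protocol.onset_ms)
        except (KeyError, FeatureError):
            tau, resid = np.nan, np.nan
            flags.append("tau_failed")
        cm = (
            estimate_cm(tau, rin)
            if np.isfinite(tau) and np.isfinite(rin) and rin > 0
            else np.nan
        )
        feats.passive = PassiveProperties(
            R_in_MOhm=rin, tau_ms=tau, C_m_pF=cm, r2=r2, tau_residual_mV=resid, flags=flags
        )

    if "firing" in protocols:
        ss = protocols["firing"]
        io = io_curve(ss, freq_mode=freq_mode)
        feats.io = io
        try:
            itrh, lat, vtrh = current_threshold_and_latency(io, ss)
            feats.I_trh_pA = itrh
            feats.first_spike_latency_ms = lat
            feats.V_trh_mV = vtrh
        except NoRheobaseError:
            pass

    if "ahp" in protocols:
        ss = protocols["ahp"]
        sweep = ss.sweeps[0]
        prot = ss.protocol
        events = detect_spikes(sweep, window_ms=(prot.onset_ms, prot.offset_ms))
        if events:
            try:
                feats.ahp = ahp_decompose(sweep, events[0])
            except (NotIsolatedError, FeatureError):
                pass

    if feats.MRP_mV is not None:
        feats.qc = qc_evaluate(
            any_ss.meta,
            feats.MRP_mV,
            rule_mode=rule_mode,
            spontaneous_spikes=spontaneous,
            has_triphasic_ahp=None if feats.ahp is None else bool(
                feats.ahp.fAHP_mV <= 0 and feats.ahp.sAHP_mV <= 0
            ),
        )
    return feats


def features_to_frame(features: list, metas: Optional[list] = None) -> pd.DataFrame:
    """One row per cell: scalar features plus per-step spike-count columns."""
    rows = []
    for i, f in enumerate(features):
        row = {
            "cell_id": f.cell_id,
            "MRP_mV": f.MRP_mV,
            "I_trh_pA": f.I_trh_pA,
            "V_trh_mV": f.V_trh_mV,
            "first_spike_latency_ms": f.first_spike_latency_ms,
        }
        if metas is not None:
            m = metas[i]
            row["animal_id"] = m.animal_id
            row["group"] = m.group
        if f.passive is not None:
            row["R_in_MOhm"] = f.passive.R_in_MOhm
            row["tau_ms"] = f.passive.tau_ms
            row["C_m_pF"] = f.passive.C_m_pF
        if f.ahp is not None:
            row["fAHP_mV"] = f.ahp.fAHP_mV
            row["ADP_mV"] = f.ahp.ADP_mV
            row["sAHP_mV"] = f.ahp.sAHP_mV
        if f.qc is not None:
            row["qc_passed"] = f.qc.passed
            row["qc_reasons"] = ";".join(f.qc.reasons)
        if f.io is not None:
            for a, n, fq in zip(f.io.amplitudes_pA, f.io.n_spikes, f.io.avg_inst_freq_Hz):
                row[f"n_spikes_{a:g}pA"] = n
                row[f"freq_{a:g}pA_Hz"] = fq
        rows.append(row)
    return pd.DataFrame(rows)
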