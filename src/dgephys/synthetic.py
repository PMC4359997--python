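"""Generative model of granule-neuron current-clamp responses.

The simulator is a hybrid leaky integrate-and-fire neuron with an
adaptation current, spike-triggered AHP/ADP currents and a slow
availability variable, onto which a stereotyped 2-ms action-potential
template is pasted at each emission.  The hybrid design gives exact ground
truth for every quantity the measurement pipeline estimates (threshold
voltage, input resistance, membrane time constant, capacitance, spike
times), which makes end-to-end recovery testable without recorded data.

Dynamics (voltage in mV, current in pA, time in ms, C in pF, gL in nS)::

    C dV/dt = -gL (V - EL) + I_inj(t) + I_noise(t) - w + I_post(t)
    dw/dt   = -w / tau_w              (w += w_b at each spike)
    dh/dt   = (h_inf(V) - h) / h_tau  with h_inf = 1 / (1 + exp((V - h_V)/h_k))
    I_post  = -a_f e^(-t/tau_f) + a_d e^(-t/tau_d) - a_s e^(-t/tau_s)
              (amplitudes incremented at each spike)

When V crosses VT with h >= h_min a spike is emitted: the template (peak
VT + A*h) replaces the next 2 ms and V resets to Vr.  When V >= VT but
h < h_min no spike is emitted and V relaxes to a depolarized plateau —
this is the depolarization-block regime: successive spikes shrink as h
decays and eventually cease, the hallmark of type I (less mature) granule
cells at strong current injections.  Type II presets disable inactivation
(h_inf ~ 1 at all voltages) and fire throughout the step range.

Integration is fixed-step Euler (default 0.05 ms); spike-triggered
amplitudes decay by exact exponential factors.  Identical parameters and
seed give bit-identical output; zero noise gives deterministic traces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .sweep_io import (
    GROUPS,
    CellMeta,
    StepProtocol,
    Sweep,
    SweepSet,
    write_manifest,
    write_sweepset,
)

DEFAULT_DT_MS = 0.05
TEMPLATE_MS = 2.0
TEMPLATE_RISE_MS = 0.6


class ConfigurationError(ValueError):
    """Invalid simulation configuration (e.g. too coarse a time step)."""


class SimulationError(RuntimeError):
    """A requested phenomenon could not be produced (e.g. no isolated spike)."""


@dataclass
class SimCellParams:
    """Generative parameters of one synthetic neuron (ground truth).

    ``R = 1000/gL_nS`` MOhm and ``tau_m = C_pF/gL_nS`` ms are the implied
    passive truths; ``VT_mV`` is the true spike threshold recovered by the
    dV/dt detector.
    """

    C_pF: float = 59.0
    gL_nS: float = 2.256
    EL_mV: float = -59.6
    VT_mV: float = -48.4
    Vr_mV: float = -55.4
    A_mV: float = 90.0
    w_b_pA: float = 14.0
    tau_w_ms: float = 120.0
    h_tau_ms: float = 45.0
    h_V_mV: float = -46.0
    h_k_mV: float = 3.0
    h_min: float = 0.35
    a_f_pA: float = 55.0
    tau_f_ms: float = 6.0
    a_d_pA: float = 22.0
    tau_d_ms: float = 20.0
    a_s_pA: float = 38.0
    tau_s_ms: float = 100.0
    noise_sd_pA: float = 5.0
    holding_pA: float = 0.0

    @property
    def R_MOhm(self) -> float:
        return 1000.0 / self.gL_nS

    @property
    def tau_m_ms(self) -> float:
        return self.C_pF / self.gL_nS

    def violations(self) -> list[str]:
        out = []
        if not self.C_pF > 0:
            out.append("C_pF")
        if not self.gL_nS > 0:
            out.append("gL_nS")
        for name in ("tau_w_ms", "h_tau_ms", "tau_f_ms", "tau_d_ms", "tau_s_ms"):
            if not getattr(self, name) > 0:
                out.append(name)
        if not (0 <= self.h_min < 1):
            out.append("h_min")
        if not (self.tau_f_ms < self.tau_d_ms < self.tau_s_ms):
            out.append("tau_order")
        return out


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def firing_protocol(max_pA: float = 220.0) -> StepProtocol:
    """500-ms depolarizing step family, -20 pA upward in 10 pA increments."""
    return StepProtocol(
        name="firing",
        onset_ms=100.0,
        duration_ms=500.0,
        amplitudes_pA=np.arange(-20.0, max_pA + 1, 10.0),
        tail_ms=200.0,
    )


def passive_protocol() -> StepProtocol:
    """200-ms step family from -120 to +20 pA in 20 pA increments."""
    return StepProtocol(
        name="passive",
        onset_ms=100.0,
        duration_ms=200.0,
        amplitudes_pA=np.arange(-120.0, 21.0, 20.0),
        tail_ms=100.0,
    )


def mrp_protocol(duration_ms: float = 1200.0) -> StepProtocol:
    """Zero-current epoch for resting-potential and spontaneous-firing QC."""
    return StepProtocol(
        name="mrp", onset_ms=0.0, duration_ms=duration_ms, amplitudes_pA=np.array([0.0]),
        tail_ms=0.0,
    )


# ---------------------------------------------------------------------------
# integration kernel
# ---------------------------------------------------------------------------

def _template_shapes(dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit rise (cubic, ends at 1) and fall (half-cosine, ends at 0)."""
    n_rise = int(round(TEMPLATE_RISE_MS / dt_ms))
    n_fall = int(round((TEMPLATE_MS - TEMPLATE_RISE_MS) / dt_ms))
    k_r = np.arange(1, n_rise + 1)
    rise = (k_r / n_rise) ** 3
    k_f = np.arange(1, n_fall + 1)
    fall = 0.5 * (1 + np.cos(np.pi * k_f / n_fall))
    return rise, fall


@njit(cache=True)
def _integrate(
    amps, onset_i, offset_i, n, dt, noise,
    C, gL, EL, VT, Vr, A, w_b, tau_w,
    h_tau, h_V, h_k, h_min,
    a_f, tau_f, a_d, tau_d, a_s, tau_s,
    rise, fall, V0, holding, spiking,
):  # pragma: no cover - exercised via simulate_cell
    n_sw = amps.shape[0]
    V_out = np.empty((n_sw, n))
    Lr = rise.shape[0]
    Lf = fall.shape[0]
    L = Lr + Lf
    max_spk = 400
    spk_peak_t = np.full((n_sw, max_spk), -1.0)
    spk_peak_v = np.zeros((n_sw, max_spk))
    spk_thr_t = np.full((n_sw, max_spk), -1.0)
    n_spk = np.zeros(n_sw, np.int64)
    dec_w = np.exp(-dt / tau_w)
    dec_f = np.exp(-dt / tau_f)
    dec_d = np.exp(-dt / tau_d)
    dec_s = np.exp(-dt / tau_s)
    for s in range(n_sw):
        V = V0
        w = 0.0
        cf = 0.0
        cd = 0.0
        cs = 0.0
        h = 1.0 / (1.0 + np.exp((V0 - h_V) / h_k))
        k = 0
        i = 0
        while i < n:
            V_out[s, i] = V
            I = holding + noise[s, i]
            if onset_i <= i < offset_i:
                I += amps[s]
            Ipost = -cf + cd - cs
            dV = dt * (-gL * (V - EL) + I - w + Ipost) / C
            hinf = 1.0 / (1.0 + np.exp((V - h_V) / h_k))
            h += dt * (hinf - h) / h_tau
            w *= dec_w
            cf *= dec_f
            cd *= dec_d
            cs *= dec_s
            V = V + dV
            i += 1
            if spiking and V >= VT and h >= h_min and i + L < n:
                peak = VT + A * h
                thr_i = i
                j = i
                for r in range(Lr):
                    Vp = VT + (peak - VT) * rise[r]
                    V_out[s, j] = Vp
                    hinf = 1.0 / (1.0 + np.exp((Vp - h_V) / h_k))
                    h += dt * (hinf - h) / h_tau
                    w *= dec_w
                    cf *= dec_f
                    cd *= dec_d
                    cs *= dec_s
                    j += 1
                for r in range(Lf):
                    Vp = Vr + (peak - Vr) * fall[r]
                    V_out[s, j] = Vp
                    hinf = 1.0 / (1.0 + np.exp((Vp - h_V) / h_k))
                    h += dt * (hinf - h) / h_tau
                    w *= dec_w
                    cf *= dec_f
                    cd *= dec_d
                    cs *= dec_s
                    j += 1
                w += w_b
                cf += a_f
                cd += a_d
                cs += a_s
                if k < max_spk:
                    spk_peak_t[s, k] = (thr_i + Lr - 1) * dt
                    spk_peak_v[s, k] = peak
                    spk_thr_t[s, k] = thr_i * dt
                    k += 1
                V = Vr
                i = j
        n_spk[s] = k
    return V_out, n_spk, spk_peak_t, spk_peak_v, spk_thr_t


@dataclass
class SimTruthCell:
    """Emitted-spike ground truth for one simulated SweepSet."""

    peak_times_ms: list  # per sweep
    peak_mV: list
    thr_times_ms: list


def _noise_array(rng, n_sweeps: int, n: int, dt: float, sd: float) -> np.ndarray:
    """Step-current noise, constant over 1-ms blocks, SD ``sd`` pA."""
    if sd == 0:
        return np.zeros((n_sweeps, n))
    rep = max(1, int(round(1.0 / dt)))
    blocks = n // rep + 1
    vals = rng.normal(0.0, sd, size=(n_sweeps, blocks))
    return np.repeat(vals, rep, axis=1)[:, :n]


def simulate_cell(
    params: SimCellParams,
    protocol: StepProtocol,
    seed: int = 0,
    dt_ms: float = DEFAULT_DT_MS,
    meta: Optional[CellMeta] = None,
    return_truth: bool = False,
):
    """Simulate one cell's responses to a step protocol.

    Returns a SweepSet (and, with ``return_truth``, the emitted-spike
    ground truth).  ``VT_mV = inf`` disables spiking (passive mode).
    """
    bad = params.violations()
    if bad:
        raise ConfigurationError(f"invalid SimCellParams: {bad}")
    spiking = np.isfinite(params.VT_mV)
    if spiking and dt_ms > 0.1:
        raise ConfigurationError("integration step must be <= 0.1 ms when spiking")
    total_ms = protocol.onset_ms + protocol.duration_ms + protocol.tail_ms
    n = int(round(total_ms / dt_ms))
    onset_i = int(round(protocol.onset_ms / dt_ms))
    offset_i = int(round(protocol.offset_ms / dt_ms))
    amps = np.asarray(protocol.amplitudes_pA, dtype=float)
    rng = np.random.default_rng(seed)
    noise = _noise_array(rng, amps.size, n, dt_ms, params.noise_sd_pA)
    rise, fall = _template_shapes(dt_ms)
    V0 = params.EL_mV + params.holding_pA / params.gL_nS
    vt = params.VT_mV if spiking else 1e9
    V, n_spk, pt, pv, tt = _integrate(
        amps, onset_i, offset_i, n, dt_ms, noise,
        params.C_pF, params.gL_nS, params.EL_mV, vt, params.Vr_mV, params.A_mV,
        params.w_b_pA, params.tau_w_ms,
        params.h_tau_ms, params.h_V_mV, params.h_k_mV, params.h_min,
        params.a_f_pA, params.tau_f_ms, params.a_d_pA, params.tau_d_ms,
        params.a_s_pA, params.tau_s_ms,
        rise, fall, V0, params.holding_pA, spiking,
    )
    if meta is None:
        meta = CellMeta(cell_id="sim", animal_id="sim", group="WT",
                        holding_current_pA=params.holding_pA)
    sweeps = [Sweep(V[i], dt_ms, amps[i]) for i in range(amps.size)]
    ss = SweepSet(meta=meta, protocol=protocol, sweeps=sweeps)
    if not return_truth:
        return ss
    truth = SimTruthCell(
        peak_times_ms=[pt[i, : n_spk[i]].copy() for i in range(amps.size)],
        peak_mV=[pv[i, : n_spk[i]].copy() for i in range(amps.size)],
        thr_times_ms=[tt[i, : n_spk[i]].copy() for i in range(amps.size)],
    )
    return ss, truth


def find_ahp_sweep(
    params: SimCellParams,
    seed: int = 0,
    dt_ms: float = DEFAULT_DT_MS,
    meta: Optional[CellMeta] = None,
    max_pA: float = 220.0,
    isolation_ms: float = 120.0,
) -> SweepSet:
    """Rheobase-style search for a single isolated spike.

    Simulates the 10-pA step family and returns, as a one-sweep "ahp"
    SweepSet, the lowest amplitude whose first overshooting spike is
    followed by no other emission within ``isolation_ms`` and whose AHP
    window lies fully inside the current step.
    """
    grid = StepProtocol(
        name="ahp_search",
        onset_ms=100.0,
        duration_ms=500.0,
        amplitudes_pA=np.arange(10.0, max_pA + 1, 10.0),
        tail_ms=200.0,
    )
    ss, truth = simulate_cell(params, grid, seed=seed, dt_ms=dt_ms, meta=meta,
                              return_truth=True)
    for i, amp in enumerate(grid.amplitudes_pA):
        peaks = truth.peak_times_ms[i]
        heights = truth.peak_mV[i]
        over = peaks[heights > 0]
        if over.size == 0:
            continue
        t0 = over[0]
        others = peaks[(peaks > t0) & (peaks <= t0 + isolation_ms)]
        if others.size:
            continue
        if t0 + isolation_ms > grid.offset_ms:
            continue
        prot = StepProtocol(
            name="ahp", onset_ms=grid.onset_ms, duration_ms=grid.duration_ms,
            amplitudes_pA=np.array([amp]), tail_ms=grid.tail_ms,
        )
        return SweepSet(meta=ss.meta, protocol=prot, sweeps=[ss.sweeps[i]])
    raise SimulationError("no amplitude produced an isolated spike")


# ---------------------------------------------------------------------------
# group presets
# ---------------------------------------------------------------------------

@dataclass
class GroupPreset:
    """Distribution (mean, CV) over SimCellParams fields for one
    group x cell-type combination."""

    group: str
    cell_type: str
    means: dict
    cvs: dict = field(default_factory=dict)

    def draw(self, rng: np.random.Generator) -> SimCellParams:
        """One parameter draw; normal per field, truncated at +/-2.5 SD."""
        values = {}
        for name, mu in self.means.items():
            cv = self.cvs.get(name, 0.0)
            if cv < 0:
                raise ConfigurationError(f"negative CV for {name}")
            sd = cv * abs(mu)
            if sd == 0:
                values[name] = mu
            else:
                z = np.clip(rng.standard_normal(), -2.5, 2.5)
                values[name] = mu + sd * z
        return SimCellParams(**values)


# CVs shared by all presets: moderate biophysical heterogeneity, kept below
# the between-cell spread of real cohorts so the two firing phenotypes stay
# separable (see docs/methods.md).
_DEFAULT_CVS = {
    "C_pF": 0.10, "gL_nS": 0.10, "EL_mV": 0.025, "VT_mV": 0.02, "Vr_mV": 0.02,
    "A_mV": 0.04, "w_b_pA": 0.12, "tau_w_ms": 0.08,
    "h_tau_ms": 0.05, "h_V_mV": 0.01, "h_min": 0.0,
    "a_f_pA": 0.12, "a_d_pA": 0.15, "a_s_pA": 0.12,
}

# Wild-type type I: high R_in, low rheobase, depolarization-block prone.
# The availability variable is anchored above threshold (h_V = -40 mV) so
# that h depletes almost exclusively during the pasted spike waveform and
# recovers between spikes: short early-train ISIs at strong steps drive h
# below h_min, triggering the self-sustaining block.
_WT_TYPE_I = {
    "C_pF": 59.0, "gL_nS": 2.256, "EL_mV": -59.6, "VT_mV": -48.4, "Vr_mV": -55.4,
    "A_mV": 90.0, "w_b_pA": 6.0, "tau_w_ms": 120.0,
    "h_tau_ms": 40.0, "h_V_mV": -40.0, "h_k_mV": 2.5, "h_min": 0.95,
    "a_f_pA": 180.0, "tau_f_ms": 2.5, "a_d_pA": 30.0, "tau_d_ms": 25.0,
    "a_s_pA": 33.0, "tau_s_ms": 100.0, "noise_sd_pA": 5.0,
}

# Wild-type type II: lower R_in, higher rheobase, sustained firing
# (inactivation disabled: h_inf ~ 1 at all physiological voltages).
_WT_TYPE_II = {
    "C_pF": 107.4, "gL_nS": 3.366, "EL_mV": -69.2, "VT_mV": -56.9, "Vr_mV": -62.9,
    "A_mV": 98.0, "w_b_pA": 20.0, "tau_w_ms": 120.0,
    "h_tau_ms": 40.0, "h_V_mV": 100.0, "h_k_mV": 6.0, "h_min": 0.0,
    "a_f_pA": 450.0, "tau_f_ms": 2.0, "a_d_pA": 25.0, "tau_d_ms": 25.0,
    "a_s_pA": 38.0, "tau_s_ms": 100.0, "noise_sd_pA": 5.0,
}

# Tg2576 shifts (documented effect directions): type I fires less (larger
# adaptation increment), more negative resting potential, larger C, smaller
# ADP current; type II fires more (smaller adaptation), larger ADP current.
_TG_TYPE_I = dict(
    _WT_TYPE_I,
    C_pF=77.8, gL_nS=2.387, EL_mV=-66.6, VT_mV=-53.8, Vr_mV=-60.8,
    w_b_pA=9.0, a_d_pA=8.0, a_s_pA=38.0, h_min=0.98,
)
_TG_TYPE_II = dict(
    _WT_TYPE_II,
    C_pF=91.1, gL_nS=2.893, EL_mV=-72.9, VT_mV=-60.1, Vr_mV=-66.1,
    w_b_pA=14.0, a_f_pA=550.0, a_d_pA=50.0,
)

#: Default type-I fraction per group (rescue groups share the wild-type mix).
DEFAULT_TYPE_MIX = {"WT": 0.70, "TG": 0.58, "TG_RSG": 0.70, "WT_RSG": 0.70}


def group_presets() -> dict:
    """The 8 default presets keyed by (group, cell_type).

    Wild-type and both rosiglitazone-treated groups share distributions
    (rescue by construction); Tg2576 presets shift only the documented
    parameters.
    """
    out = {}
    for group in GROUPS:
        t1 = _TG_TYPE_I if group == "TG" else _WT_TYPE_I
        t2 = _TG_TYPE_II if group == "TG" else _WT_TYPE_II
        out[(group, "typeI")] = GroupPreset(group, "typeI", dict(t1), dict(_DEFAULT_CVS))
        out[(group, "typeII")] = GroupPreset(group, "typeII", dict(t2), dict(_DEFAULT_CVS))
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort."""

    seed: int
    n_animals_per_group: int = 15
    cells_per_animal_range: tuple = (1, 4)
    groups: tuple = GROUPS
    type_mix: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    noise_sd_pA: Optional[float] = None  # override preset noise when set
    max_step_pA: float = 220.0
    presets: Optional[dict] = None


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def make_cohort(config: CohortConfig, out_dir=None):
    """Generate a labeled synthetic cohort.

    Cells are assigned to animals with per-animal counts drawn uniformly
    from ``cells_per_animal_range``; each cell gets all four protocols
    (mrp, passive, firing, ahp).  Returns ``(cells, manifest, truth)``
    where ``cells`` maps cell_id to its protocol dictionary.  With
    ``out_dir`` the native containers, manifest CSV and truth CSV are also
    written.

    Fully reproducible from ``config.seed``.
    """
    if config.n_animals_per_group < 1:
        raise ConfigurationError("n_animals_per_group must be >= 1")
    if not config.type_mix:
        raise ConfigurationError("empty type_mix")
    presets = config.presets if config.presets is not None else group_presets()
    root = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    cells = {}
    manifest_rows = []
    truth_rows = []
    lo, hi = config.cells_per_animal_range
    firing = firing_protocol(config.max_step_pA)
    passive = passive_protocol()
    mrp = mrp_protocol()
    cell_idx = 0
    for group in config.groups:
        frac_t1 = config.type_mix.get(group, config.type_mix.get("WT", 0.5))
        for a in range(config.n_animals_per_group):
            animal_id = f"{group}_a{a + 1:02d}"
            n_cells = int(assign_rng.integers(lo, hi + 1))
            for c in range(n_cells):
                cell_idx += 1
                cell_id = f"{group}_c{cell_idx:04d}"
                cell_type = "typeI" if assign_rng.random() < frac_t1 else "typeII"
                preset = presets[(group, cell_type)]
                params = preset.draw(assign_rng)
                if config.noise_sd_pA is not None:
                    params = replace(params, noise_sd_pA=config.noise_sd_pA)
                meta = CellMeta(cell_id=cell_id, animal_id=animal_id, group=group,
                                holding_current_pA=params.holding_pA)
                child = root.spawn(1)[0]
                s_m, s_p, s_f, s_a = (_derive_seed(x) for x in child.spawn(4))
                protos = {
                    "mrp": simulate_cell(params, mrp, seed=s_m, meta=meta),
                    "passive": simulate_cell(params, passive, seed=s_p, meta=meta),
                    "firing": simulate_cell(params, firing, seed=s_f, meta=meta),
                }
                try:
                    protos["ahp"] = find_ahp_sweep(params, seed=s_a, meta=meta,
                                                   max_pA=config.max_step_pA)
                except SimulationError:
                    pass
                cells[cell_id] = protos
                manifest_rows.append(
                    {"cell_id": cell_id, "animal_id": animal_id, "group": group,
                     "path": f"{cell_id}.h5"}
                )
                truth_rows.append(
                    {
                        "cell_id": cell_id, "animal_id": animal_id, "group": group,
                        "label": cell_type,
                        "R_MOhm": params.R_MOhm, "tau_ms": params.tau_m_ms,
                        "C_pF": params.C_pF, "VT_mV": params.VT_mV,
                        "EL_mV": params.EL_mV,
                        **{f"p_{k}": v for k, v in dataclasses.asdict(params).items()},
                    }
                )
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cid, protos in cells.items():
            for ss in protos.values():
                write_sweepset(ss, out_dir / f"{cid}.h5")
        manifest_disk = manifest.copy()
        write_manifest(manifest_disk, out_dir / "manifest.csv")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return cells, manifest, truth
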