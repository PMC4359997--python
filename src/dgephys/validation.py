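"""Recovery and calibration benchmarks for the whole pipeline.

Each function builds its own inputs from a seed — synthetic cohorts with
known ground truth, or simulated null data for the statistical tests —
runs the relevant pipeline stage, and returns the measured quantity:
parameter-recovery errors, classification agreement, simulated type-I
error rates, and end-to-end effect-direction recovery.  They back both
the acceptance tests and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import features as ft
from . import synthetic as syn
from .classify import classify_cohort
from .pipeline import PipelineConfig, extract_cohort_features, run_pipeline
from .stats import dunnett_critical_value


def _draw_mixed_params(n_cells: int, seed: int, noise_sd: float):
    """Cells drawn from the WT presets (70/30 type mix), fixed noise."""
    presets = syn.group_presets()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_cells):
        ct = "typeI" if rng.random() < 0.7 else "typeII"
        params = presets[("WT", ct)].draw(rng)
        out.append((ct, syn.SimCellParams(**{**params.__dict__, "noise_sd_pA": noise_sd})))
    return out


def passive_recovery(n_cells: int = 50, seed: int = 0, noise_sd: float = 0.0) -> dict:
    """Relative errors of R_in, tau and C_m against generator truth.

    Returns the mean and max relative error (percent) over a passive
    cohort; with ``noise_sd = 0`` the only error sources are the Euler
    discretization and the estimators themselves.
    """
    cells = _draw_mixed_params(n_cells, seed, noise_sd)
    prot = syn.passive_protocol()
    errs = {"R_in": [], "tau": [], "C_m": []}
    for i, (_, params) in enumerate(cells):
        ss = syn.simulate_cell(params, prot, seed=seed + 1000 + i)
        rin, _, _ = ft.estimate_rin(ss)
        tau, _ = ft.estimate_tau(ss.sweep_at(-40.0), prot.onset_ms)
        cm = ft.estimate_cm(tau, rin)
        errs["R_in"].append(abs(rin - params.R_MOhm) / params.R_MOhm)
        errs["tau"].append(abs(tau - params.tau_m_ms) / params.tau_m_ms)
        errs["C_m"].append(abs(cm - params.C_pF) / params.C_pF)
    return {
        k: {"mean_pct": 100 * float(np.mean(v)), "max_pct": 100 * float(np.max(v))}
        for k, v in errs.items()
    }


def threshold_recovery(n_cells: int = 50, seed: int = 0, noise_sd: float = 0.0) -> float:
    """Mean |estimated V_trh - true VT| (mV) over a spiking cohort."""
    cells = _draw_mixed_params(n_cells, seed, noise_sd)
    prot = syn.firing_protocol()
    errs = []
    for i, (_, params) in enumerate(cells):
        ss = syn.simulate_cell(params, prot, seed=seed + 2000 + i)
        io = ft.io_curve(ss)
        _, _, vtrh = ft.current_threshold_and_latency(io, ss)
        errs.append(abs(vtrh - params.VT_mV))
    return float(np.mean(errs))


def classification_agreement(seed: int = 0, noise_sd=None,
                             n_animals_per_group: int = 13) -> dict:
    """Fraction of cells whose label matches the generator truth."""
    cfg = syn.CohortConfig(seed=seed, n_animals_per_group=n_animals_per_group,
                           cells_per_animal_range=(1, 3), noise_sd_pA=noise_sd)
    cells, manifest, truth = syn.make_cohort(cfg)
    _, _, ios = extract_cohort_features(cells, manifest)
    groups = dict(zip(manifest["cell_id"], manifest["group"]))
    labels, _ = classify_cohort(ios, groups)
    merged = labels.merge(truth[["cell_id", "label"]], on="cell_id",
                          suffixes=("_pred", "_true"))
    return {
        "n": len(merged),
        "agreement": float((merged["label_pred"] == merged["label_true"]).mean()),
        "unclassified": float((merged["label_pred"] == "unclassified").mean()),
    }


# ---------------------------------------------------------------------------
# simulated-null calibration of the statistical battery
# ---------------------------------------------------------------------------

def type1_error_t(n_rep: int = 10_000, n: int = 10, alpha: float = 0.05,
                  seed: int = 0) -> float:
    """Rejection rate of the pooled t-test on simulated null data."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_rep, n))
    b = rng.standard_normal((n_rep, n))
    df = 2 * n - 2
    sp2 = ((n - 1) * a.var(axis=1, ddof=1) + (n - 1) * b.var(axis=1, ddof=1)) / df
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (2 / n))
    crit = sps.t.ppf(1 - alpha / 2, df)
    return float((np.abs(t) > crit).mean())


def _anova_f(data: np.ndarray, k: int, n: int):
    """Vectorized one-way F for (n_rep, k, n) null arrays."""
    gmeans = data.mean(axis=2)
    grand = data.mean(axis=(1, 2))
    ssb = n * ((gmeans - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((data - gmeans[:, :, None]) ** 2).sum(axis=(1, 2))
    return (ssb / (k - 1)) / (ssw / (k * n - k))


def type1_error_anova(n_rep: int = 10_000, k: int = 3, n: int = 8,
                      alpha: float = 0.05, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_rep, k, n))
    f = _anova_f(data, k, n)
    crit = sps.f.ppf(1 - alpha, k - 1, k * n - k)
    return float((f > crit).mean())


def type1_error_kruskal(n_rep: int = 10_000, k: int = 3, n: int = 8,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of Kruskal-Wallis (chi-square approximation) under the
    null; continuous data, so no tie correction is exercised."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_rep, k * n))
    order = np.argsort(data, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n_rep)[:, None]
    ranks[rows, order] = np.arange(1, k * n + 1)
    N = k * n
    rbars = ranks.reshape(n_rep, k, n).mean(axis=2)
    h = 12 / (N * (N + 1)) * (n * (rbars - (N + 1) / 2) ** 2).sum(axis=1)
    crit = sps.chi2.ppf(1 - alpha, k - 1)
    return float((h > crit).mean())


def dunnett_familywise_error(n_rep: int = 10_000, k: int = 3, n: int = 8,
                             alpha: float = 0.05, seed: int = 0,
                             n_mc: int = 1_000_000) -> float:
    """Familywise rejection rate of Dunnett many-to-one comparisons under
    the global null, against the Monte-Carlo critical value."""
    df = k * n - k
    crit = dunnett_critical_value([n] * k, 0, df, alpha=alpha, n_mc=n_mc, seed=seed)
    rng = np.random.default_rng(seed + 1)
    data = rng.standard_normal((n_rep, k, n))
    gmeans = data.mean(axis=2)
    ssw = ((data - gmeans[:, :, None]) ** 2).sum(axis=(1, 2))
    mse = ssw / df
    se = np.sqrt(mse * (2 / n))
    ts = (gmeans[:, 1:] - gmeans[:, [0]]) / se[:, None]
    return float((np.abs(ts).max(axis=1) > crit).mean())


# ---------------------------------------------------------------------------
# end-to-end effect-direction recovery
# ---------------------------------------------------------------------------

#: (variable, cell type, expected sign of mean(TG) - mean(WT))
EFFECT_DIRECTIONS = [
    ("n_spikes_60pA", "typeI", -1),
    ("n_spikes_220pA", "typeII", +1),
    ("ADP_mV", "typeI", -1),
    ("ADP_mV", "typeII", +1),
]


def effect_directions_recovered(seed: int, n_animals_per_group: int = 14) -> dict:
    """One pipeline replicate: check every injected TG-vs-WT effect sign and
    that the rescue group sits closer to wild-type than the disease group.

    Replicates use 14 animals of 2-3 cells per group so that the minority
    type II stratum keeps a workable sample in every arm.
    """
    cfg = PipelineConfig(
        seed=seed,
        simulate=syn.CohortConfig(seed=seed, n_animals_per_group=n_animals_per_group,
                                  cells_per_animal_range=(2, 3)),
    )
    res = run_pipeline(cfg)
    fdf = res.features
    out = {}
    for var, ct, sign in EFFECT_DIRECTIONS:
        sub = fdf[fdf["label"] == ct]
        means = sub.groupby("group")[var].mean()
        diff = means["TG"] - means["WT"]
        rescued = abs(means["TG_RSG"] - means["WT"]) < abs(diff)
        out[f"{var}:{ct}"] = {"sign_ok": bool(np.sign(diff) == sign),
                              "rescued": bool(rescued)}
    return out


def effect_direction_recovery_rate(n_replicates: int = 10, seed: int = 0) -> dict:
    """Fraction of replicates in which every sign and rescue check holds."""
    sign_ok = 0
    rescue_ok = 0
    for r in range(n_replicates):
        checks = effect_directions_recovered(seed * 1000 + r + 1)
        sign_ok += all(c["sign_ok"] for c in checks.values())
        rescue_ok += all(c["rescued"] for c in checks.values())
    return {
        "n_replicates": n_replicates,
        "sign_recovery": sign_ok / n_replicates,
        "rescue_recovery": rescue_ok / n_replicates,
    }
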