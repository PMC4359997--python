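"""End-to-end orchestration: cohort -> QC -> features -> classification ->
group statistics -> tables.

The pipeline either simulates a synthetic cohort or loads a recorded one
from its manifest + HDF5 containers, extracts the full per-cell feature
battery, applies QC, classifies cells into type I / type II, and produces
the group-comparison tables (mean +/- SE per group with omnibus and
post hoc p-values against the control group) plus run bookkeeping.

Per-variable test routing follows the convention that normally
distributed variables go through ANOVA with Dunnett (or the less
stringent Fisher LSD) post hoc comparisons, while skewed variables (the
ADP and slow AHP of type I cells) are routed to Kruskal-Wallis with
Dunn's post hoc test.  The routing map is configuration; the default is
in :data:`DEFAULT_ROUTING`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .classify import ClassifierThresholds, classify_cohort
from .features import extract_cell_features, features_to_frame
from .sweep_io import GROUPS, read_manifest, read_sweepset, list_sweepsets
from .synthetic import CohortConfig, make_cohort


class PipelineError(RuntimeError):
    pass


#: (omnibus, posthoc) per summary variable, keyed "<column>:<cell type>";
#: a bare column name applies to both types; anything absent uses the
#: ANOVA + Dunnett default.
DEFAULT_ROUTING = {
    "ADP_mV:typeI": ("kruskal", "dunn"),
    "ADP_mV:typeII": ("anova", "fisher_lsd"),
    "sAHP_mV:typeI": ("kruskal", "dunn"),
    "V_trh_mV": ("anova", "fisher_lsd"),
    "C_m_pF": ("anova", "fisher_lsd"),
}

SUMMARY_VARIABLES = [
    "MRP_mV", "I_trh_pA", "V_trh_mV", "first_spike_latency_ms",
    "R_in_MOhm", "tau_ms", "C_m_pF", "fAHP_mV", "ADP_mV", "sAHP_mV",
]


@dataclass
class PipelineConfig:
    seed: int
    simulate: Optional[CohortConfig] = None
    input_dir: Optional[str] = None
    out_dir: Optional[str] = None
    rule_mode: str = "or"
    freq_mode: str = "mean_inverse_isi"
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    control_group: str = "WT"
    routing: dict = field(default_factory=dict)
    summary_variables: list = field(default_factory=lambda: list(SUMMARY_VARIABLES))
    count_steps_pA: list = field(default_factory=lambda: [60.0, 90.0, 220.0])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise PipelineError("config must name a master seed")
        sim = raw.pop("simulate", None)
        thr = raw.pop("thresholds", None)
        cfg = cls(seed=int(raw.pop("seed")), **raw)
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            if "cells_per_animal_range" in sim:
                sim["cells_per_animal_range"] = tuple(sim["cells_per_animal_range"])
            cfg.simulate = CohortConfig(**sim)
        if thr is not None:
            cfg.thresholds = ClassifierThresholds(**thr)
        return cfg


@dataclass
class RunReport:
    """Bookkeeping: every input cell lands in exactly one outcome bin."""

    recorded: int
    qc_failed: int
    unclassified: int
    classified: int
    per_group: dict
    seed: int

    def conserved(self) -> bool:
        return self.recorded == self.qc_failed + self.unclassified + self.classified


@dataclass
class RunResult:
    features: pd.DataFrame
    labels: pd.DataFrame
    summaries: dict  # cell_type -> GroupSummaryTable DataFrame
    proportions: dict  # group -> ProportionSummary
    report: RunReport
    manifest: pd.DataFrame
    truth: Optional[pd.DataFrame] = None


def load_cohort(input_dir) -> tuple[dict, pd.DataFrame]:
    """Read a cohort (manifest.csv + per-cell containers) from disk."""
    input_dir = Path(input_dir)
    manifest = read_manifest(input_dir / "manifest.csv")
    cells = {}
    for _, row in manifest.iterrows():
        path = input_dir / row["path"]
        protos = {}
        for cid, pname in list_sweepsets(path):
            if cid == row["cell_id"]:
                protos[pname] = read_sweepset(path, cid, pname)
        cells[row["cell_id"]] = protos
    return cells, manifest


def extract_cohort_features(cells: dict, manifest: pd.DataFrame,
                            rule_mode: str = "or",
                            freq_mode: str = "mean_inverse_isi"):
    """Run the feature battery over every cell; returns (features, metas, ios)."""
    feats, metas, ios = [], [], {}
    for _, row in manifest.iterrows():
        protos = cells[row["cell_id"]]
        f = extract_cell_features(protos, rule_mode=rule_mode, freq_mode=freq_mode)
        feats.append(f)
        metas.append(next(iter(protos.values())).meta)
        if f.io is not None:
            ios[row["cell_id"]] = f.io
    return feats, metas, ios


def animals_table(manifest: pd.DataFrame, labels: Optional[pd.DataFrame] = None):
    """Per-animal cell counts plus (min, max, median) cells/animal per group.

    The median of an even-count list is the mean of the middle two.
    """
    if manifest.empty:
        raise PipelineError("empty manifest")
    df = manifest.copy()
    if labels is not None:
        df = df.merge(labels[["cell_id", "label"]], on="cell_id", how="left")
    per_animal = (
        df.groupby(["group", "animal_id"])["cell_id"].count().rename("n_cells").reset_index()
    )
    summary = {}
    for group, sub in per_animal.groupby("group"):
        counts = sub["n_cells"].to_numpy()
        summary[group] = {
            "min": int(counts.min()),
            "max": int(counts.max()),
            "median": float(np.median(counts)),
        }
    return per_animal, summary


def _route(variable: str, cell_type: str, routing: dict):
    for key in (f"{variable}:{cell_type}", variable):
        if key in routing:
            return routing[key]
    return ("anova", "dunnett")


def summarize_groups(
    features: pd.DataFrame,
    variables: list,
    groups: list,
    control_group: str = "WT",
    cell_type: str = "",
    routing: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +/- SE per group per variable, with omnibus + post hoc p-values.

    ``features`` must already be restricted to the cells entering the
    summary (QC-passed, one cell type).  Groups with data but fewer than
    two usable values are reported without tests.
    """
    routing = {**DEFAULT_ROUTING, **(routing or {})}
    rows = []
    for var in variables:
        if var not in features.columns:
            continue
        row = {"variable": var}
        samples = []
        for g in groups:
            vals = features.loc[features["group"] == g, var].dropna().to_numpy()
            ms = st.mean_se(vals) if vals.size else None
            row[f"{g}_n"] = vals.size
            row[f"{g}_mean"] = ms.mean if ms else np.nan
            row[f"{g}_se"] = ms.se if ms else np.nan
            samples.append(vals)
        omnibus, posthoc = _route(var, cell_type, routing)
        row["omnibus"] = omnibus
        row["posthoc"] = posthoc
        usable = all(s.size >= 2 for s in samples) and len(samples) >= 2
        if usable and control_group in groups:
            ctrl = groups.index(control_group)
            if omnibus == "anova":
                row["omnibus_p"] = st.one_way_anova(samples).p_value
            else:
                row["omnibus_p"] = st.kruskal_wallis(samples).p_value
            if posthoc == "dunnett":
                ph = st.dunnett_posthoc(samples, ctrl, seed=seed)
            elif posthoc == "fisher_lsd":
                ph = st.fisher_lsd(samples, ctrl)
            else:
                ph = st.dunn_posthoc(samples, ctrl)
            for comp in ph.comparisons:
                row[f"p_{groups[comp.index]}_vs_{control_group}"] = comp.p_adjusted
        else:
            row["omnibus_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Simulate or ingest, QC, extract, classify, and summarize a cohort.

    Rerunning with the same config and seed reproduces every output
    bit-for-bit.
    """
    truth = None
    if config.simulate is not None:
        cells, manifest, truth = make_cohort(config.simulate)
    elif config.input_dir is not None:
        cells, manifest = load_cohort(config.input_dir)
    else:
        raise PipelineError("config needs either simulate or input_dir")
    if manifest.empty:
        raise PipelineError("no cells in cohort")

    feats, metas, ios = extract_cohort_features(
        cells, manifest, rule_mode=config.rule_mode, freq_mode=config.freq_mode
    )
    fdf = features_to_frame(feats, metas)

    qc_ok = fdf["qc_passed"].fillna(False).astype(bool) if "qc_passed" in fdf else pd.Series(True, index=fdf.index)
    passed_ids = set(fdf.loc[qc_ok, "cell_id"])
    ios_ok = {cid: io for cid, io in ios.items() if cid in passed_ids}
    group_by_cell = dict(zip(manifest["cell_id"], manifest["group"]))
    labels, proportions = classify_cohort(ios_ok, group_by_cell, config.thresholds)

    fdf = fdf.merge(labels[["cell_id", "label"]], on="cell_id", how="left")
    summaries = {}
    groups = [g for g in GROUPS if g in set(manifest["group"])]
    count_vars = [f"n_spikes_{s:g}pA" for s in config.count_steps_pA]
    for cell_type in ("typeI", "typeII"):
        sub = fdf[(fdf["label"] == cell_type) & qc_ok.reindex(fdf.index, fill_value=False)]
        if sub.empty:
            continue
        summaries[cell_type] = summarize_groups(
            sub,
            config.summary_variables + count_vars,
            groups,
            control_group=config.control_group,
            cell_type=cell_type,
            routing=config.routing,
            seed=config.seed,
        )

    n_rec = len(manifest)
    n_qc_failed = int((~qc_ok).sum())
    n_uncl = int((labels["label"] == "unclassified").sum())
    n_class = int((labels["label"] != "unclassified").sum())
    per_group = {
        g: {
            "recorded": int((manifest["group"] == g).sum()),
            "typeI": proportions[g].n_typeI if g in proportions else 0,
            "typeII": proportions[g].n_typeII if g in proportions else 0,
            "unclassified": proportions[g].n_unclassified if g in proportions else 0,
        }
        for g in groups
    }
    report = RunReport(
        recorded=n_rec, qc_failed=n_qc_failed, unclassified=n_uncl,
        classified=n_class, per_group=per_group, seed=config.seed,
    )
    result = RunResult(
        features=fdf, labels=labels, summaries=summaries,
        proportions=proportions, report=report, manifest=manifest, truth=truth,
    )
    if config.out_dir is not None:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: RunResult, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    result.labels.to_csv(out / "labels.csv", index=False)
    result.manifest.to_csv(out / "manifest.csv", index=False)
    if result.truth is not None:
        result.truth.to_csv(out / "truth.csv", index=False)
    for cell_type, table in result.summaries.items():
        table.to_csv(out / f"summary_{cell_type}.csv", index=False)
    props = {
        g: {
            "n_typeI": p.n_typeI,
            "n_typeII": p.n_typeII,
            "n_unclassified": p.n_unclassified,
            "prop_typeI": p.prop_typeI,
            "Z": p.z_test.statistic if p.z_test else None,
            "p": p.z_test.p_value if p.z_test else None,
        }
        for g, p in result.proportions.items()
    }
    (out / "proportions.json").write_text(json.dumps(props, indent=2, sort_keys=True))
    (out / "report.json").write_text(
        json.dumps(dataclasses.asdict(result.report), indent=2, sort_keys=True)
    )
    return out
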