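"""Deterministic type I / type II granule-cell classification.

Dentate granule neurons stratify by firing phenotype: *type I*
(presumptively less mature) cells reach their maximum spike count at
moderate step currents and fail to sustain firing above ~150 pA
(depolarization block), while *type II* (more mature) cells fire
throughout the step range with counts growing monotonically to the
maximum stimulus.  The qualitative criteria are operationalized here as
explicit numeric thresholds on the input-output curve, with an
``unclassified`` category for cells falling between the two rule regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .features import IOCurve, NoRheobaseError
from .stats import TestResult, one_proportion_z


@dataclass
class ClassifierThresholds:
    """Numeric operationalization of the firing-pattern criteria.

    ``block_I_pA``: the highest step current at which a type I cell may
    peak (block sets in above ~150 pA); ``fail_ratio`` / ``sustain_ratio``:
    bounds on N(max step)/N_max separating collapsing from sustained
    firing; ``rho_min``: minimum Spearman correlation of count vs current
    over suprathreshold steps required of type II.
    """

    block_I_pA: float = 150.0
    fail_ratio: float = 0.6
    sustain_ratio: float = 0.9
    rho_min: float = 0.8


@dataclass
class CellLabel:
    label: str  # typeI | typeII | unclassified
    N_max: int
    I_at_Nmax_pA: float
    N_at_max_step: int
    high_intensity_ratio: float
    monotonicity_rho: float


@dataclass
class ProportionSummary:
    """Per-group type composition with a one-proportion Z-test vs 0.5."""

    group: str
    n_typeI: int
    n_typeII: int
    n_unclassified: int
    prop_typeI: float
    z_test: Optional[TestResult] = None


def classify_cell(
    io: IOCurve, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> CellLabel:
    """Label one cell from its input-output curve.

    type I  iff I(N_max) <= block_I_pA and N(max step)/N_max < fail_ratio;
    type II iff N(max step)/N_max >= sustain_ratio and Spearman
    rho(amplitude, count) >= rho_min over suprathreshold steps;
    otherwise unclassified.  Ties in N_max resolve to the lowest amplitude.
    """
    supra = np.flatnonzero(io.n_spikes >= 1)
    if supra.size == 0:
        raise NoRheobaseError("no suprathreshold steps")
    counts = io.n_spikes
    i_max = int(np.argmax(counts))  # argmax returns the first (lowest-amplitude) tie
    n_max = int(counts[i_max])
    n_last = int(counts[-1])
    ratio = n_last / n_max
    amps_s = io.amplitudes_pA[supra]
    counts_s = counts[supra]
    if supra.size >= 3 and np.ptp(counts_s) > 0:
        rho = float(spearmanr(amps_s, counts_s).statistic)
    else:
        rho = np.nan
    label = "unclassified"
    if io.amplitudes_pA[i_max] <= thresholds.block_I_pA and ratio < thresholds.fail_ratio:
        label = "typeI"
    elif ratio >= thresholds.sustain_ratio and np.isfinite(rho) and rho >= thresholds.rho_min:
        label = "typeII"
    return CellLabel(
        label=label,
        N_max=n_max,
        I_at_Nmax_pA=float(io.amplitudes_pA[i_max]),
        N_at_max_step=n_last,
        high_intensity_ratio=float(ratio),
        monotonicity_rho=rho,
    )


def proportion_summary(group: str, n_typeI: int, n_typeII: int,
                       n_unclassified: int = 0) -> ProportionSummary:
    """Composition summary over classified cells, with Z-test vs 0.5."""
    n_class = n_typeI + n_typeII
    prop = n_typeI / n_class if n_class else np.nan
    z = one_proportion_z(n_typeI, n_class) if n_class else None
    return ProportionSummary(
        group=group, n_typeI=n_typeI, n_typeII=n_typeII,
        n_unclassified=n_unclassified, prop_typeI=prop, z_test=z,
    )


def classify_cohort(
    io_by_cell: dict,
    group_by_cell: dict,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[pd.DataFrame, dict]:
    """Label every cell and summarize per-group type proportions.

    Returns a labels DataFrame (cell_id, group, label, evidence columns)
    and a dict of :class:`ProportionSummary` keyed by group; unclassified
    cells are excluded from the proportions but counted.
    """
    rows = []
    for cell_id, io in io_by_cell.items():
        group = group_by_cell[cell_id]
        try:
            lab = classify_cell(io, thresholds)
        except NoRheobaseError:
            lab = CellLabel("unclassified", 0, np.nan, 0, np.nan, np.nan)
        rows.append(
            {
                "cell_id": cell_id, "group": group, "label": lab.label,
                "N_max": lab.N_max, "I_at_Nmax_pA": lab.I_at_Nmax_pA,
                "N_at_max_step": lab.N_at_max_step,
                "high_intensity_ratio": lab.high_intensity_ratio,
                "monotonicity_rho": lab.monotonicity_rho,
            }
        )
    labels = pd.DataFrame(rows)
    summaries = {}
    for group, sub in labels.groupby("group"):
        if sub.empty:
            raise ValueError(f"empty group {group}")
        summaries[group] = proportion_summary(
            group,
            int((sub["label"] == "typeI").sum()),
            int((sub["label"] == "typeII").sum()),
            int((sub["label"] == "unclassified").sum()),
        )
    return labels, summaries
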