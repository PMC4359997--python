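"""Reference cohort bookkeeping for the Tg2576 / rosiglitazone study design.

The synthetic generator emulates a four-arm cross-sectional design:
wild-type (WT) and Tg2576 amyloidosis-model (TG) mice, each untreated or
fed rosiglitazone (WT_RSG, TG_RSG).  This module carries the reference
per-animal type I / type II composition of such a cohort — used by the
worked examples, the animals-table layout and the exclusion bookkeeping —
as plain data: one list of per-cell labels per animal, plus the total
number of cells recorded per group before classification.
"""

from __future__ import annotations

import pandas as pd

#: Per-animal cell-type labels ("t1" = type I, "t2" = type II), one inner
#: list per animal, classified cells only.
REFERENCE_COHORT = {
    "WT": [
        ["t1"], ["t1"], ["t1"], ["t1", "t1"], ["t1", "t1"], ["t1", "t2"],
        ["t2"], ["t2"], ["t2", "t1", "t1"], ["t2", "t2"], ["t1"], ["t1"],
        ["t1", "t1"], ["t2", "t2", "t1", "t1", "t1"], ["t1", "t1"],
    ],
    "TG": [
        ["t1"], ["t2"], ["t1", "t1", "t2"], ["t1", "t2"], ["t2"],
        ["t1", "t1", "t1"], ["t2", "t2", "t1"], ["t2", "t1"],
        ["t1", "t1", "t1", "t1"], ["t2", "t2"], ["t1"], ["t2"], ["t1"],
        ["t2", "t2"], ["t1", "t1", "t1"], ["t2"],
    ],
    "TG_RSG": [
        ["t1", "t1"], ["t2", "t2"], ["t1"], ["t2"], ["t1", "t1"], ["t1"],
        ["t2"], ["t1", "t2", "t2"], ["t1", "t1"], ["t1", "t1", "t1"],
        ["t1", "t2"], ["t1", "t2"], ["t2"], ["t1"], ["t1", "t1", "t1"],
        ["t1", "t1"], ["t1"], ["t1", "t1"], ["t1", "t2"], ["t2", "t1"],
        ["t1"],
    ],
    "WT_RSG": [
        ["t1"], ["t1"], ["t2", "t2"], ["t1", "t1"], ["t1", "t1"],
        ["t2", "t1"], ["t1", "t1"], ["t1"], ["t1", "t2", "t1"],
        ["t2", "t1", "t2", "t2", "t2", "t1"], ["t1"], ["t1"],
    ],
}

#: Cells recorded per group before QC/classification exclusions.
RECORDED_TOTALS = {"WT": 31, "TG": 33, "TG_RSG": 39, "WT_RSG": 27}


def reference_labels() -> pd.DataFrame:
    """Flat cell table: cell_id, animal_id, group, label (typeI/typeII)."""
    rows = []
    i = 0
    for group, animals in REFERENCE_COHORT.items():
        for a, labels in enumerate(animals, start=1):
            for lab in labels:
                i += 1
                rows.append(
                    {
                        "cell_id": f"{group}_ref{i:03d}",
                        "animal_id": f"{group}_a{a:02d}",
                        "group": group,
                        "label": "typeI" if lab == "t1" else "typeII",
                    }
                )
    return pd.DataFrame(rows)


def classified_counts() -> dict:
    """(n_typeI, n_typeII) per group in the reference cohort."""
    out = {}
    for group, animals in REFERENCE_COHORT.items():
        flat = [lab for cell_labels in animals for lab in cell_labels]
        out[group] = (flat.count("t1"), flat.count("t2"))
    return out


def excluded_cells() -> int:
    """Recorded cells that fell into neither type category."""
    recorded = sum(RECORDED_TOTALS.values())
    classified = sum(t1 + t2 for t1, t2 in classified_counts().values())
    return recorded - classified
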