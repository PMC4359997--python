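"""Data model, HDF5 container and quality-control gating for episodic
current-clamp recordings.

A recording session for one cell is a set of *protocols* (families of
current steps), each yielding one voltage sweep per step amplitude.  The
on-disk container is a single HDF5 file per cell::

    /cells/<cell_id>/meta                 (attrs: animal_id, group, ...)
    /cells/<cell_id>/<protocol>/voltage   (2-D float64, sweeps x samples, mV)
                                          (attrs: dt_ms, onset_ms, duration_ms,
                                           tail_ms, amplitudes_pA)

Units follow electrophysiology convention throughout: millivolts,
milliseconds, picoamperes, megaohms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

GROUPS = ("WT", "TG", "TG_RSG", "WT_RSG")

#: QC rule identifiers, in reporting order.
QC_RULES = (
    "mrp_rule",
    "holding_rule",
    "spontaneous_firing_rule",
    "triphasic_ahp_rule",
    "adaptation_rule",
)


class ValidationError(ValueError):
    """A domain-type invariant is violated."""


class FormatError(ValueError):
    """An on-disk container is missing a required attribute or dataset."""


@dataclass
class StepProtocol:
    """A family of square current steps.

    Parameters
    ----------
    name : str
        Protocol identifier ("firing", "passive", "mrp", "ahp", ...).
    onset_ms, duration_ms, tail_ms : float
        Step onset, step duration and post-step recorded time.
    amplitudes_pA : array
        Step currents, strictly increasing, one per sweep.
    """

    name: str
    onset_ms: float
    duration_ms: float
    amplitudes_pA: np.ndarray
    tail_ms: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=float)

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms

    def violations(self) -> list[str]:
        out = []
        if not self.duration_ms > 0:
            out.append("duration_ms")
        if self.onset_ms < 0:
            out.append("onset_ms")
        amps = self.amplitudes_pA
        if amps.ndim != 1 or amps.size == 0 or np.any(np.diff(amps) <= 0):
            out.append("amplitudes")
        return out


@dataclass
class Sweep:
    """One voltage trace (mV) for one injected step current."""

    voltage_mV: np.ndarray
    dt_ms: float
    amplitude_pA: float

    def __post_init__(self) -> None:
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.voltage_mV.size

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms


@dataclass
class CellMeta:
    """Per-cell bookkeeping: identity, experimental group, recording state."""

    cell_id: str
    animal_id: str
    group: str
    holding_current_pA: float = 0.0
    series_resistance_MOhm: Optional[float] = None
    mrp_mV: Optional[float] = None

    def violations(self) -> list[str]:
        out = []
        if self.group not in GROUPS:
            out.append("group")
        if (
            self.series_resistance_MOhm is not None
            and not self.series_resistance_MOhm > 0
        ):
            out.append("series_resistance_MOhm")
        return out


@dataclass
class SweepSet:
    """A cell's sweeps for one protocol, one sweep per step amplitude."""

    meta: CellMeta
    protocol: StepProtocol
    sweeps: list[Sweep]

    @property
    def dt_ms(self) -> float:
        return self.sweeps[0].dt_ms

    def voltage_matrix(self) -> np.ndarray:
        return np.stack([s.voltage_mV for s in self.sweeps])

    def sweep_at(self, amplitude_pA: float) -> Sweep:
        """The sweep for a given step amplitude (exact match)."""
        for s in self.sweeps:
            if s.amplitude_pA == amplitude_pA:
                return s
        raise KeyError(f"no sweep at {amplitude_pA} pA")


@dataclass
class QCResult:
    """Outcome of cell-level quality control.

    ``passed`` is equivalent to ``reasons`` being empty; when a cell fails,
    ``reasons`` lists every violated rule identifier (see :data:`QC_RULES`).
    """

    passed: bool
    reasons: list[str] = field(default_factory=list)


def validate_sweepset(sweepset: SweepSet) -> list[str]:
    """Report all invariant violations of a SweepSet (never raises)."""
    out = list(sweepset.protocol.violations())
    out.extend(sweepset.meta.violations())
    n_amp = sweepset.protocol.amplitudes_pA.size
    if len(sweepset.sweeps) != n_amp:
        out.append("sweep_count")
    dts = {s.dt_ms for s in sweepset.sweeps}
    if len(dts) > 1:
        out.append("dt_ms_mismatch")
    for s in sweepset.sweeps:
        if not s.dt_ms > 0:
            out.append("dt_ms")
            break
    p = sweepset.protocol
    needed = p.onset_ms + p.duration_ms + p.tail_ms
    for s in sweepset.sweeps:
        if s.dt_ms > 0 and s.n_samples * s.dt_ms < needed:
            out.append("trace_length")
            break
    # amplitudes recorded on the sweeps must match the protocol
    if len(sweepset.sweeps) == n_amp and not np.allclose(
        [s.amplitude_pA for s in sweepset.sweeps], p.amplitudes_pA
    ):
        out.append("sweep_amplitudes")
    return out


def _require(ok: bool, what: str) -> None:
    if not ok:
        raise ValidationError(what)


def write_sweepset(sweepset: SweepSet, path) -> Path:
    """Write a SweepSet into the per-cell HDF5 container at ``path``.

    The file is opened in append mode so that several protocols of the same
    cell accumulate in one file.  ``read_sweepset(write_sweepset(x))``
    reproduces voltages bit-exactly and metadata field-for-field.
    """
    bad = validate_sweepset(sweepset)
    if bad:
        raise ValidationError(f"invalid SweepSet: {bad}")
    path = Path(path)
    meta, prot = sweepset.meta, sweepset.protocol
    with h5py.File(path, "a") as f:
        cell = f.require_group(f"cells/{meta.cell_id}")
        mgrp = cell.require_group("meta")
        mgrp.attrs["animal_id"] = meta.animal_id
        mgrp.attrs["group"] = meta.group
        mgrp.attrs["holding_current_pA"] = float(meta.holding_current_pA)
        if meta.series_resistance_MOhm is not None:
            mgrp.attrs["series_resistance_MOhm"] = float(meta.series_resistance_MOhm)
        if meta.mrp_mV is not None:
            mgrp.attrs["mrp_mV"] = float(meta.mrp_mV)
        if prot.name in cell:
            del cell[prot.name]
        pg = cell.create_group(prot.name)
        pg.create_dataset("voltage", data=sweepset.voltage_matrix())
        pg.attrs["dt_ms"] = float(sweepset.dt_ms)
        pg.attrs["onset_ms"] = float(prot.onset_ms)
        pg.attrs["duration_ms"] = float(prot.duration_ms)
        pg.attrs["tail_ms"] = float(prot.tail_ms)
        pg.attrs["amplitudes_pA"] = prot.amplitudes_pA
    return path


def list_sweepsets(path) -> list[tuple[str, str]]:
    """(cell_id, protocol_name) pairs stored in a container file."""
    out = []
    with h5py.File(path, "r") as f:
        if "cells" not in f:
            return out
        for cid, cell in f["cells"].items():
            for name in cell:
                if name != "meta":
                    out.append((cid, name))
    return out


def read_sweepset(path, cell_id: Optional[str] = None, protocol: Optional[str] = None) -> SweepSet:
    """Read one SweepSet back from a container file.

    When the file holds a single cell (or a single protocol) the
    corresponding argument may be omitted.  Unknown extra attributes are
    ignored; a missing required attribute raises :class:`FormatError`
    naming it.
    """
    with h5py.File(path, "r") as f:
        if "cells" not in f:
            raise FormatError("cells")
        cells = list(f["cells"])
        if cell_id is None:
            if len(cells) != 1:
                raise FormatError(f"cell_id required, file holds {len(cells)} cells")
            cell_id = cells[0]
        if cell_id not in f["cells"]:
            raise FormatError(f"cell {cell_id!r} not in file")
        cell = f["cells"][cell_id]
        prots = [k for k in cell if k != "meta"]
        if protocol is None:
            if len(prots) != 1:
                raise FormatError(f"protocol required, cell holds {prots}")
            protocol = prots[0]
        if protocol not in cell:
            raise FormatError(f"protocol {protocol!r} not in cell {cell_id!r}")
        pg = cell[protocol]
        for attr in ("dt_ms", "onset_ms", "duration_ms", "tail_ms", "amplitudes_pA"):
            if attr not in pg.attrs:
                raise FormatError(attr)
        if "voltage" not in pg:
            raise FormatError("voltage")
        volt = pg["voltage"][()]
        amps = np.asarray(pg.attrs["amplitudes_pA"], dtype=float)
        mattrs = cell["meta"].attrs if "meta" in cell else {}
        for attr in ("animal_id", "group"):
            if attr not in mattrs:
                raise FormatError(attr)
        meta = CellMeta(
            cell_id=cell_id,
            animal_id=str(mattrs["animal_id"]),
            group=str(mattrs["group"]),
            holding_current_pA=float(mattrs.get("holding_current_pA", 0.0)),
            series_resistance_MOhm=(
                float(mattrs["series_resistance_MOhm"])
                if "series_resistance_MOhm" in mattrs
                else None
            ),
            mrp_mV=float(mattrs["mrp_mV"]) if "mrp_mV" in mattrs else None,
        )
        prot = StepProtocol(
            name=protocol,
            onset_ms=float(pg.attrs["onset_ms"]),
            duration_ms=float(pg.attrs["duration_ms"]),
            amplitudes_pA=amps,
            tail_ms=float(pg.attrs["tail_ms"]),
        )
        dt = float(pg.attrs["dt_ms"])
        sweeps = [Sweep(volt[i], dt, amps[i]) for i in range(volt.shape[0])]
    ss = SweepSet(meta=meta, protocol=prot, sweeps=sweeps)
    bad = validate_sweepset(ss)
    if bad:
        raise ValidationError(f"invalid SweepSet in file: {bad}")
    return ss


def sweepsets_equal(a: SweepSet, b: SweepSet) -> bool:
    """Field-for-field, bit-exact equality of two SweepSets."""
    if dataclasses.asdict(a.meta) != dataclasses.asdict(b.meta):
        return False
    pa, pb = a.protocol, b.protocol
    if (pa.name, pa.onset_ms, pa.duration_ms, pa.tail_ms) != (
        pb.name,
        pb.onset_ms,
        pb.duration_ms,
        pb.tail_ms,
    ):
        return False
    if not np.array_equal(pa.amplitudes_pA, pb.amplitudes_pA):
        return False
    if len(a.sweeps) != len(b.sweeps):
        return False
    return all(
        sa.dt_ms == sb.dt_ms
        and sa.amplitude_pA == sb.amplitude_pA
        and np.array_equal(sa.voltage_mV, sb.voltage_mV)
        for sa, sb in zip(a.sweeps, b.sweeps)
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_evaluate(
    meta: CellMeta,
    mrp_mV: float,
    rule_mode: str = "or",
    spontaneous_spikes: Optional[int] = None,
    has_triphasic_ahp: Optional[bool] = None,
    has_adaptation: Optional[bool] = None,
) -> QCResult:
    """Apply the cell-inclusion rules.

    The two core rules are a resting potential *strictly* more negative than
    -50 mV (``mrp_rule``; -50.0 exactly fails) and a holding current between
    -25 and +25 pA inclusive (``holding_rule``).  ``rule_mode`` selects how
    they combine: ``"or"`` (either suffices — the literal reading of the
    recording criteria, the default) or ``"and"`` (both required, the
    physiologically conservative variant).

    The remaining three rules are evaluated only when their evidence is
    supplied: any overshooting spike at rest fails
    ``spontaneous_firing_rule``; a missing triphasic AHP fails
    ``triphasic_ahp_rule``; absent firing adaptation fails
    ``adaptation_rule``.
    """
    if rule_mode not in ("or", "and"):
        raise ValueError(f"unknown rule_mode {rule_mode!r}")
    mrp_ok = mrp_mV < -50.0
    holding_ok = -25.0 <= meta.holding_current_pA <= 25.0
    core_ok = (mrp_ok or holding_ok) if rule_mode == "or" else (mrp_ok and holding_ok)
    violated = []
    if not core_ok:
        if not mrp_ok:
            violated.append("mrp_rule")
        if not holding_ok:
            violated.append("holding_rule")
    if spontaneous_spikes is not None and spontaneous_spikes > 0:
        violated.append("spontaneous_firing_rule")
    if has_triphasic_ahp is not None and not has_triphasic_ahp:
        violated.append("triphasic_ahp_rule")
    if has_adaptation is not None and not has_adaptation:
        violated.append("adaptation_rule")
    return QCResult(passed=not violated, reasons=violated)


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["cell_id", "animal_id", "group", "path"]


def validate_manifest(manifest: pd.DataFrame) -> list[str]:
    """Invariant check for a cohort manifest DataFrame."""
    out = []
    for col in MANIFEST_COLUMNS:
        if col not in manifest.columns:
            out.append(f"missing:{col}")
    if out:
        return out
    if manifest["cell_id"].duplicated().any():
        out.append("cell_id_unique")
    groups_per_animal = manifest.groupby("animal_id")["group"].nunique()
    if (groups_per_animal > 1).any():
        out.append("animal_single_group")
    if not manifest["group"].isin(GROUPS).all():
        out.append("group")
    return out


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    bad = validate_manifest(manifest)
    if bad:
        raise ValidationError(f"invalid manifest: {bad}")
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"cell_id": str, "animal_id": str, "group": str})
    bad = validate_manifest(manifest)
    if bad:
        raise ValidationError(f"invalid manifest: {bad}")
    return manifest


def group_counts(manifest: pd.DataFrame) -> pd.Series:
    """Cells per group; equals the sum of per-animal counts by construction."""
    return manifest.groupby("group")["cell_id"].count()
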