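"""Longitudinal cohort data model and block-grid construction.

A cohort is a set of patients, each with an ordered list of dated tumor
samples and a list of dated clinical events (treatments, status changes).
The block view arranges the cohort into alternating *timepoint blocks*
(one aligned sample per patient) and *event blocks* (events falling
between the flanking samples).  Timepoints are ordinal by default: a
patient's i-th sample sits in timepoint block i.  Patients can be shifted
to realign the cohort, e.g. relative to the start of a treatment.

Dates are integer days relative to a per-patient reference point (the
cBioPortal timeline convention); no calendar parsing happens here.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

__all__ = [
    "GAP",
    "Gap",
    "EventRecord",
    "PatientRecord",
    "Feature",
    "TransformRecord",
    "Cohort",
    "Block",
    "BlockGrid",
    "build_cohort",
    "derive_blocks",
    "shift_patients",
    "align_to_event",
    "event_attribute_feature",
    "timeline_series",
    "PatientTrack",
]

DATATYPES = ("binary", "categorical", "ordinal", "continuous")
SOURCES = ("clinical_patient", "clinical_sample", "mutation", "cna", "expression", "derived")
LEVELS = ("sample", "patient", "event")


class Gap:
    """Sentinel for 'patient has no sample/event at this block'.

    Distinct from a missing measurement (``None``): a gap means the
    patient was not sampled at that timepoint at all.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "GAP"


GAP = Gap()


@dataclass
class EventRecord:
    """A dated clinical event (e.g. a TREATMENT with AGENT=TMZ)."""

    event_type: str
    attributes: dict[str, str]
    start_date: int
    stop_date: int | None = None

    def __post_init__(self) -> None:
        if self.stop_date is not None and self.stop_date < self.start_date:
            raise ValueError(
                f"event {self.event_type}: stop_date {self.stop_date} precedes "
                f"start_date {self.start_date}"
            )

    @property
    def duration(self) -> int:
        """Days between start and stop; 0 for point events."""
        return 0 if self.stop_date is None else self.stop_date - self.start_date

    def matches(self, event_type: str, attribute_filter: Mapping[str, str] | None = None) -> bool:
        if self.event_type != event_type:
            return False
        if attribute_filter:
            return all(self.attributes.get(k) == v for k, v in attribute_filter.items())
        return True


@dataclass
class PatientRecord:
    """One patient: ordered dated samples plus dated events."""

    patient_id: str
    samples: list[tuple[str, int]]  # (sample_id, date in days)
    events: list[EventRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"patient {self.patient_id} has no samples")
        dates = [d for _, d in self.samples]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"patient {self.patient_id}: sample dates not non-decreasing")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def sample_dates(self) -> list[int]:
        return [d for _, d in self.samples]


@dataclass
class TransformRecord:
    """One entry of the operation log; replaying the log is deterministic."""

    op_name: str
    params: dict[str, Any]
    timestamp: int  # monotone counter, not wall-clock


@dataclass
class Feature:
    """A typed variable measured per sample, patient or event.

    ``values`` maps a sample id (level=sample), patient id (level=patient)
    or ``(patient_id, event_index)`` key (level=event) to a value; keys
    that are absent or map to ``None`` are missing.
    """

    feature_id: str
    display_name: str
    datatype: str
    source: str
    level: str
    domain: list | tuple | None = None  # category list, or (lo, hi) for continuous
    color_scale: str | dict | None = None
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.datatype not in DATATYPES:
            raise ValueError(f"unknown datatype {self.datatype!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.datatype in ("categorical", "ordinal"):
            dom = list(self.domain or [])
            if len(dom) != len(set(dom)):
                raise ValueError(f"feature {self.feature_id}: duplicate domain categories")
            bad = {v for v in self.values.values() if v is not None and v not in dom}
            if bad:
                raise ValueError(
                    f"feature {self.feature_id}: values {sorted(map(str, bad))} outside domain"
                )
        if self.datatype == "binary":
            bad = {v for v in self.values.values() if v not in (0, 1, None)}
            if bad:
                raise ValueError(f"feature {self.feature_id}: non-binary values {bad}")

    def get(self, key) -> Any:
        return self.values.get(key)

    def non_missing(self) -> list:
        return [v for v in self.values.values() if v is not None]

    def observed_range(self) -> tuple[float, float] | None:
        """Cohort-wide (min, max) of non-missing values; continuous only."""
        vals = self.non_missing()
        if self.datatype != "continuous" or not vals:
            return None
        return (float(min(vals)), float(max(vals)))

    def replace(self, **changes) -> "Feature":
        data = {
            "feature_id": self.feature_id,
            "display_name": self.display_name,
            "datatype": self.datatype,
            "source": self.source,
            "level": self.level,
            "domain": copy.copy(self.domain),
            "color_scale": copy.copy(self.color_scale),
            "values": dict(self.values),
        }
        data.update(changes)
        return Feature(**data)


@dataclass
class Cohort:
    """Patients + feature registry + operation log."""

    patients: list[PatientRecord]
    features: dict[str, Feature] = field(default_factory=dict)
    op_log: list[TransformRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        pids = [p.patient_id for p in self.patients]
        if len(pids) != len(set(pids)):
            raise ValueError("duplicate patient ids")
        seen: dict[str, str] = {}
        for p in self.patients:
            for sid in p.sample_ids:
                if sid in seen:
                    raise ValueError(
                        f"sample id {sid!r} appears under patients {seen[sid]!r} and {p.patient_id!r}"
                    )
                seen[sid] = p.patient_id
        self._sample_to_patient = seen

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def sample_ids(self) -> list[str]:
        return list(self._sample_to_patient)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def add_feature(self, feature: Feature) -> None:
        if feature.feature_id in self.features:
            raise ValueError(f"feature id {feature.feature_id!r} already registered")
        if feature.level == "sample":
            unknown = set(feature.values) - set(self._sample_to_patient)
            if unknown:
                raise ValueError(
                    f"feature {feature.feature_id}: values reference unknown samples "
                    f"{sorted(unknown)[:5]}"
                )
        elif feature.level == "patient":
            unknown = set(feature.values) - set(self.patient_ids)
            if unknown:
                raise ValueError(
                    f"feature {feature.feature_id}: values reference unknown patients "
                    f"{sorted(unknown)[:5]}"
                )
        self.features[feature.feature_id] = feature

    def log(self, op_name: str, params: Mapping[str, Any]) -> TransformRecord:
        rec = TransformRecord(op_name=op_name, params=dict(params), timestamp=len(self.op_log))
        self.op_log.append(rec)
        return rec


def build_cohort(
    clinical_tables: Sequence,
    timeline_events: Iterable[tuple[str, EventRecord]] = (),
    feature_defs: Sequence[Feature] = (),
) -> Cohort:
    """Assemble a :class:`Cohort` from parsed clinical tables and events.

    ``clinical_tables`` are objects with attributes ``level`` (``"sample"``
    or ``"patient"``), ``sample_map`` (ordered ``(patient_id, sample_id)``
    pairs; sample-level tables only), ``patient_ids`` and ``features``
    (see :class:`cohortflow.io_formats.ClinicalTable`).  Sample dates are
    taken from SPECIMEN timeline events carrying a SAMPLE_ID attribute;
    samples without one get ordinal fallback dates preserving input order.

    ``timeline_events`` are ``(patient_id, EventRecord)`` pairs; SPECIMEN
    events are consumed for dating, all others are attached to patients.
    """
    order: list[str] = []
    samples_by_patient: dict[str, list[str]] = {}
    for tab in clinical_tables:
        if tab.level == "sample":
            for pid, sid in tab.sample_map:
                if pid not in samples_by_patient:
                    samples_by_patient[pid] = []
                    order.append(pid)
                samples_by_patient[pid].append(sid)
        else:
            for pid in tab.patient_ids:
                if pid not in samples_by_patient:
                    samples_by_patient[pid] = []
                    order.append(pid)

    events = list(timeline_events)
    specimen_dates: dict[str, int] = {}
    other_events: dict[str, list[EventRecord]] = {}
    for pid, ev in events:
        if ev.event_type == "SPECIMEN" and "SAMPLE_ID" in ev.attributes:
            specimen_dates[ev.attributes["SAMPLE_ID"]] = ev.start_date
        else:
            other_events.setdefault(pid, []).append(ev)

    unknown_event_pids = set(other_events) - set(order)
    if unknown_event_pids:
        raise ValueError(f"timeline events reference unknown patients {sorted(unknown_event_pids)}")

    patients = []
    for pid in order:
        sids = samples_by_patient[pid]
        if not sids:
            # patient-level-only patient still needs one anchor sample slot
            raise ValueError(f"patient {pid} has no samples in any sample-level table")
        dated = [(sid, specimen_dates.get(sid)) for sid in sids]
        if any(d is None for _, d in dated):
            dated = [(sid, i if d is None else d) for i, (sid, d) in enumerate(dated)]
        dated.sort(key=lambda t: t[1])
        patients.append(
            PatientRecord(
                patient_id=pid,
                samples=[(s, int(d)) for s, d in dated],
                events=sorted(other_events.get(pid, []), key=lambda e: e.start_date),
            )
        )

    cohort = Cohort(patients=patients)
    for tab in clinical_tables:
        for feat in tab.features:
            cohort.add_feature(feat)
    for feat in feature_defs:
        cohort.add_feature(feat)
    return cohort


# ---------------------------------------------------------------------------
# Block grid


@dataclass
class Block:
    """One layer of the block view.

    ``cells[(feature_id, patient_id)]`` holds the value at this block, or
    :data:`GAP` when the patient has no sample/event here.  ``order`` is
    the left-to-right patient permutation; ``slot`` locates the block in
    the grid (timepoint index, or the timepoint index it follows for
    event blocks, with -1 for the leading event block).
    """

    index: int
    kind: str  # "timepoint" | "event"
    slot: int
    rows: list[str]
    columns: list[str]
    cells: dict[tuple[str, str], Any]
    primary_feature: str | None = None
    order: list[str] = field(default_factory=list)
    grouped: bool = False

    def __post_init__(self) -> None:
        if not self.order:
            self.order = list(self.columns)
        if sorted(self.order) != sorted(self.columns):
            raise ValueError(f"block {self.index}: order is not a permutation of columns")

    def value(self, feature_id: str, patient_id: str) -> Any:
        return self.cells.get((feature_id, patient_id), GAP)

    def present_patients(self) -> list[str]:
        """Patients with a non-gap cell in this block, in column order."""
        if not self.rows:
            return []
        r0 = self.rows[0]
        return [p for p in self.order if self.value(r0, p) is not GAP]

    def replace(self, **changes) -> "Block":
        data = {
            "index": self.index,
            "kind": self.kind,
            "slot": self.slot,
            "rows": list(self.rows),
            "columns": list(self.columns),
            "cells": dict(self.cells),
            "primary_feature": self.primary_feature,
            "order": list(self.order),
            "grouped": self.grouped,
        }
        data.update(changes)
        return Block(**data)


class BlockGrid:
    """The alternating timepoint/event block grid for a cohort.

    Holds per-patient shift offsets so that realignment (e.g. to a
    treatment event) is expressed as whole-sequence shifts; blocks are
    rebuilt from the offsets, so a shift and its reverse restore the grid
    exactly.
    """

    def __init__(
        self,
        cohort: Cohort,
        displayed_features: Sequence[str],
        include_events: bool = False,
        event_features: Sequence[str] = (),
        offsets: Mapping[str, int] | None = None,
    ):
        for fid in list(displayed_features) + list(event_features):
            if fid not in cohort.features:
                raise KeyError(f"feature {fid!r} not registered in cohort")
        for fid in displayed_features:
            if cohort.features[fid].level == "event" and not include_events:
                raise ValueError(
                    f"event-level feature {fid!r} requested but include_events is False"
                )
        self.cohort = cohort
        self.displayed_features = [
            f for f in displayed_features if cohort.features[f].level != "event"
        ]
        self.event_features = list(event_features) + [
            f for f in displayed_features if cohort.features[f].level == "event"
        ]
        self.include_events = include_events
        self.offsets = {p.patient_id: 0 for p in cohort.patients}
        if offsets:
            for pid, off in offsets.items():
                if off < 0:
                    raise ValueError(f"patient {pid}: negative block offset {off}")
                self.offsets[pid] = int(off)
        self.blocks: list[Block] = []
        self._rebuild()

    # -- construction ------------------------------------------------------

    @property
    def n_timepoints(self) -> int:
        return max(self.offsets[p.patient_id] + len(p.samples) for p in self.cohort.patients)

    def _sample_at(self, patient: PatientRecord, tp: int) -> tuple[str, int] | None:
        j = tp - self.offsets[patient.patient_id]
        if 0 <= j < len(patient.samples):
            return patient.samples[j]
        return None

    def _cell_value(self, feat: Feature, patient: PatientRecord, tp: int) -> Any:
        sample = self._sample_at(patient, tp)
        if feat.level == "patient":
            return GAP if sample is None else feat.get(patient.patient_id)
        if sample is None:
            return GAP
        return feat.get(sample[0])

    def _event_slot(self, patient: PatientRecord, ev: EventRecord) -> int:
        """Timepoint index after which the event block holding ``ev`` sits.

        Membership interval is left-open right-closed ``(d_j, d_{j+1}]``;
        events on/before the first sample go to the slot before it, events
        after the last sample to the slot after it.
        """
        off = self.offsets[patient.patient_id]
        dates = patient.sample_dates
        if ev.start_date <= dates[0]:
            return off - 1
        for j in range(len(dates) - 1):
            if dates[j] < ev.start_date <= dates[j + 1]:
                return off + j
        return off + len(dates) - 1

    def events_at_slot(self, patient_id: str, slot: int) -> list[EventRecord]:
        patient = self.cohort.patient(patient_id)
        return [ev for ev in patient.events if self._event_slot(patient, ev) == slot]

    def _rebuild(self) -> None:
        cohort = self.cohort
        columns = cohort.patient_ids
        old_orders = {(b.kind, b.slot): b for b in self.blocks}
        n_tp = self.n_timepoints

        tp_blocks: dict[int, Block] = {}
        for tp in range(n_tp):
            cells = {}
            for fid in self.displayed_features:
                feat = cohort.features[fid]
                for patient in cohort.patients:
                    cells[(fid, patient.patient_id)] = self._cell_value(feat, patient, tp)
            tp_blocks[tp] = Block(
                index=0, kind="timepoint", slot=tp,
                rows=list(self.displayed_features), columns=list(columns), cells=cells,
            )

        ev_blocks: dict[int, Block] = {}
        if self.include_events:
            slots = list(range(-1, n_tp))
            for slot in slots:
                cells = {}
                any_event = False
                for patient in cohort.patients:
                    matching = [
                        i for i, ev in enumerate(patient.events)
                        if self._event_slot(patient, ev) == slot
                    ]
                    if matching:
                        any_event = True
                    for fid in self.event_features:
                        feat = cohort.features[fid]
                        vals = sorted(
                            {feat.values.get((patient.patient_id, i)) for i in matching} - {None}
                        )
                        cells[(fid, patient.patient_id)] = "+".join(map(str, vals)) if vals else GAP
                # interior slots always materialize (blocks alternate);
                # leading/trailing only when they actually hold events
                if 0 <= slot < n_tp - 1 or any_event:
                    ev_blocks[slot] = Block(
                        index=0, kind="event", slot=slot,
                        rows=list(self.event_features), columns=list(columns), cells=cells,
                    )

        ordered: list[Block] = []
        if -1 in ev_blocks:
            ordered.append(ev_blocks[-1])
        for tp in range(n_tp):
            ordered.append(tp_blocks[tp])
            if tp in ev_blocks:
                ordered.append(ev_blocks[tp])
        for i, b in enumerate(ordered):
            b.index = i
            prev = old_orders.get((b.kind, b.slot))
            if prev is not None and sorted(prev.order) == sorted(b.columns):
                b.order = list(prev.order)
                b.primary_feature = prev.primary_feature
        self.blocks = ordered

    # -- queries -----------------------------------------------------------

    def timepoint_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.kind == "timepoint"]

    def block_of_sample(self, sample_id: str) -> int:
        pid = self.cohort._sample_to_patient[sample_id]
        patient = self.cohort.patient(pid)
        j = patient.sample_ids.index(sample_id)
        return self.offsets[pid] + j

    def patient_series(self, feature_id: str, patient_id: str) -> list:
        """Per-timepoint values for one patient (None at gaps/missing).

        Computed from the grid's alignment directly, so any registered
        sample/patient-level feature can be scored, displayed or not.
        """
        feat = self.cohort.features[feature_id]
        patient = self.cohort.patient(patient_id)
        out = []
        for tp in range(self.n_timepoints):
            v = self._cell_value(feat, patient, tp)
            out.append(None if v is GAP else v)
        return out

    def values_at_timepoint(self, feature_id: str, tp: int) -> list:
        """Non-gap values of a feature across patients at one timepoint
        (missing measurements included as None)."""
        feat = self.cohort.features[feature_id]
        out = []
        for patient in self.cohort.patients:
            v = self._cell_value(feat, patient, tp)
            if v is not GAP:
                out.append(v)
        return out

    def copy(self) -> "BlockGrid":
        grid = BlockGrid(
            self.cohort, self.displayed_features, self.include_events,
            self.event_features, offsets=dict(self.offsets),
        )
        for new, old in zip(grid.blocks, self.blocks):
            new.order = list(old.order)
            new.primary_feature = old.primary_feature
            new.grouped = old.grouped
        return grid


def derive_blocks(
    cohort: Cohort,
    displayed_features: Sequence[str],
    include_events: bool = False,
    event_features: Sequence[str] = (),
) -> BlockGrid:
    """Build the block grid: one timepoint block per ordinal sample index,
    with event blocks interleaved when ``include_events`` is set."""
    return BlockGrid(cohort, displayed_features, include_events, event_features)


def shift_patients(grid: BlockGrid, patient_ids: Sequence[str], offset: int) -> BlockGrid:
    """Shift the whole sample sequences of ``patient_ids`` by ``offset``
    block positions (positive = later).  Returns a new grid; vacated
    positions become gaps and the grid grows if needed."""
    for b in grid.blocks:
        if b.grouped:
            raise ValueError("cannot shift patients while blocks are grouped")
    new_offsets = dict(grid.offsets)
    for pid in patient_ids:
        if pid not in new_offsets:
            raise KeyError(f"unknown patient {pid!r}")
        shifted = new_offsets[pid] + offset
        if shifted < 0:
            raise ValueError(
                f"shift of {offset} would move patient {pid!r} to negative block index"
            )
        new_offsets[pid] = shifted
    out = grid.copy()
    out.offsets = new_offsets
    out._rebuild()
    return out


def align_to_event(
    cohort: Cohort,
    grid: BlockGrid,
    event_type: str,
    attribute_filter: Mapping[str, str] | None = None,
) -> BlockGrid:
    """Realign the cohort so that every matching patient's first sample on
    or after the event start shares one reference timepoint block.

    Patients without a matching event keep their default alignment.
    Implemented as per-patient shifts, so it composes with manual shifts.
    """
    anchors: dict[str, int] = {}
    for patient in cohort.patients:
        hits = [ev for ev in patient.events if ev.matches(event_type, attribute_filter)]
        if not hits:
            continue
        first = min(hits, key=lambda e: e.start_date)
        dates = patient.sample_dates
        post = [j for j, d in enumerate(dates) if d >= first.start_date]
        if post:
            anchors[patient.patient_id] = post[0]
    if not anchors:
        filt = dict(attribute_filter or {})
        raise ValueError(f"no patient has an event matching type={event_type!r} {filt}")

    ref = max(grid.offsets[pid] + j for pid, j in anchors.items())
    out = grid
    for pid, j in anchors.items():
        delta = ref - (grid.offsets[pid] + j)
        if delta:
            out = shift_patients(out, [pid], delta)
    return out


def event_attribute_feature(
    cohort: Cohort,
    event_type: str,
    attribute: str,
    feature_id: str | None = None,
    register: bool = True,
) -> Feature:
    """Derive an event-level categorical feature from one event attribute
    (e.g. TREATMENT/AGENT -> the drug given), keyed by (patient, event index)."""
    values = {}
    cats: list[str] = []
    for patient in cohort.patients:
        for i, ev in enumerate(patient.events):
            if ev.event_type == event_type and attribute in ev.attributes:
                v = ev.attributes[attribute]
                values[(patient.patient_id, i)] = v
                if v not in cats:
                    cats.append(v)
    feat = Feature(
        feature_id=feature_id or f"{event_type}_{attribute}",
        display_name=f"{event_type} {attribute}",
        datatype="categorical",
        source="derived",
        level="event",
        domain=sorted(cats),
        values=values,
    )
    if register:
        cohort.add_feature(feat)
    return feat


# ---------------------------------------------------------------------------
# Timeline view series


@dataclass
class PatientTrack:
    """Date-proportional per-patient series for the timeline view."""

    patient_id: str
    markers: list[tuple[int, str, Any]]  # (date, sample_id, feature value or None)
    bars: list[tuple[int, int, str, dict]]  # (start, stop, event_type, attributes)


def timeline_series(cohort: Cohort, display_feature: str) -> list[PatientTrack]:
    """Per-patient dated markers (samples, colored by ``display_feature``)
    and event bars; open-ended events become zero-length point bars."""
    feat = cohort.features[display_feature]
    if feat.level != "sample":
        raise ValueError("timeline display feature must be sample-level")
    tracks = []
    for patient in cohort.patients:
        markers = [(d, sid, feat.get(sid)) for sid, d in patient.samples]
        bars = [
            (ev.start_date, ev.stop_date if ev.stop_date is not None else ev.start_date,
             ev.event_type, dict(ev.attributes))
            for ev in patient.events
        ]
        tracks.append(PatientTrack(patient.patient_id, markers, bars))
    return tracks
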