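"""Block-view arrangement: per-block stable sorting, multidimensional
sorting, cohort-wide realignment, grouping into proportion blocks, and
patient-line / Sankey-flow computation between adjacent blocks.

All operations are pure: they take blocks (or the grid) and return new
objects, so grouping then discarding the grouped object trivially
restores the pre-grouping patient order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .model import GAP, Block, Feature

__all__ = [
    "sort_block",
    "sort_block_multi",
    "realign_all",
    "group_block",
    "GroupedBlock",
    "FlowSet",
    "compute_flows",
    "build_flowsets",
    "highlight_selection",
    "layout_state_to_dict",
]

MISSING_GROUP = "(missing)"


def _sort_key(feature: Feature, value, direction: str):
    """(missing-last flag, orderable key); categorical order = domain order."""
    if value is GAP or value is None:
        return (1, 0.0)
    if feature.datatype in ("categorical", "ordinal"):
        key = float((feature.domain or []).index(value))
    else:
        key = float(value)
    return (0, -key if direction == "desc" else key)


def sort_block(block: Block, feature: Feature, direction: str = "asc") -> Block:
    """Stable sort of the block's patient order by one feature.

    Ties keep their prior relative order; missing values and gaps go
    last regardless of direction.  Sets the block's primary feature.
    """
    if block.grouped:
        raise ValueError("cannot sort a grouped block; ungroup first")
    if feature.feature_id not in block.rows:
        raise KeyError(f"feature {feature.feature_id!r} is not displayed in this block")
    if direction not in ("asc", "desc"):
        raise ValueError("direction must be 'asc' or 'desc'")
    order = sorted(
        block.order,
        key=lambda pid: _sort_key(feature, block.value(feature.feature_id, pid), direction),
    )
    return block.replace(order=order, primary_feature=feature.feature_id)


def sort_block_multi(
    block: Block, features: Sequence[Feature], directions: Sequence[str]
) -> Block:
    """Lexicographic sort by several features, most-significant first.

    Implemented as repeated stable single-feature sorts from least- to
    most-significant key, so the prior patient order breaks remaining
    ties.  The most significant feature becomes the block's primary.
    """
    if len(features) != len(directions):
        raise ValueError(
            f"{len(features)} features but {len(directions)} directions"
        )
    out = block
    for feat, direction in zip(reversed(list(features)), reversed(list(directions))):
        out = sort_block(out, feat, direction)
    return out


def realign_all(blocks: Sequence[Block], reference_block_index: int) -> list[Block]:
    """Propagate one block's patient order to every ungrouped block.

    Patients absent from the reference order are appended in their prior
    relative order.  Idempotent.
    """
    ref = next((b for b in blocks if b.index == reference_block_index), None)
    if ref is None:
        raise KeyError(f"no block with index {reference_block_index}")
    if ref.grouped:
        raise ValueError("cannot realign to a grouped block")
    out = []
    for b in blocks:
        if b.grouped or b.index == reference_block_index:
            out.append(b)
            continue
        in_ref = [p for p in ref.order if p in set(b.columns)]
        extra = [p for p in b.order if p not in set(ref.order)]
        out.append(b.replace(order=in_ref + extra))
    return out


@dataclass
class GroupedBlock:
    """A block aggregated into proportions of its primary feature.

    ``groups`` partition the block's non-gap patients (those missing the
    primary value form an explicit trailing "(missing)" group); group
    order follows the primary feature's domain order.  Nested summaries
    describe every other displayed feature within each group —
    categorical: value->count; continuous: five-number summary (linear
    interpolation quartiles) plus the raw values for gradient rendering.
    """

    index: int
    kind: str
    slot: int
    primary_feature: str
    groups: list[tuple[Any, list[str]]]
    nested_summaries: dict[Any, dict[str, Any]]
    selected_counts: dict[Any, int] = field(default_factory=dict)
    grouped: bool = True

    def group_sizes(self) -> dict[Any, int]:
        return {g: len(pids) for g, pids in self.groups}

    def patients(self) -> list[str]:
        return [p for _, pids in self.groups for p in pids]

    def group_of(self, patient_id: str) -> Any | None:
        for g, pids in self.groups:
            if patient_id in pids:
                return g
        return None


def _five_number(vals: list[float]) -> tuple[float, float, float, float, float]:
    q = np.percentile(np.asarray(vals, dtype=float), [0, 25, 50, 75, 100], method="linear")
    return tuple(float(x) for x in q)


def group_block(
    block: Block, primary_feature: Feature, features: Mapping[str, Feature]
) -> GroupedBlock:
    """Partition a block's patients by the primary feature's value.

    Continuous primaries are rejected: with near-unique values every
    patient would be its own group, so a continuous feature has to be
    binned into an ordinal one before grouping.
    """
    if primary_feature.feature_id not in block.rows:
        raise KeyError(f"feature {primary_feature.feature_id!r} is not displayed in this block")
    if primary_feature.datatype == "continuous":
        raise ValueError(
            f"cannot group by continuous feature {primary_feature.feature_id!r}: "
            "bin it into an ordinal feature first"
        )
    fid = primary_feature.feature_id
    domain = list(primary_feature.domain or [])
    if primary_feature.datatype == "binary":
        domain = [0, 1]

    members: dict[Any, list[str]] = {}
    for pid in block.order:
        v = block.value(fid, pid)
        if v is GAP:
            continue
        key = MISSING_GROUP if v is None else v
        members.setdefault(key, []).append(pid)

    ordered_keys = [g for g in domain if g in members]
    if MISSING_GROUP in members:
        ordered_keys.append(MISSING_GROUP)
    groups = [(g, members[g]) for g in ordered_keys]

    summaries: dict[Any, dict[str, Any]] = {}
    for g, pids in groups:
        per_feature: dict[str, Any] = {}
        for other in block.rows:
            if other == fid:
                continue
            feat = features[other]
            vals = [block.value(other, p) for p in pids]
            vals = [v for v in vals if v is not GAP and v is not None]
            if feat.datatype == "continuous":
                per_feature[other] = {
                    "five_number": _five_number(vals) if vals else None,
                    "values": vals,
                }
            else:
                per_feature[other] = dict(Counter(vals))
        summaries[g] = per_feature

    return GroupedBlock(
        index=block.index,
        kind=block.kind,
        slot=block.slot,
        primary_feature=fid,
        groups=groups,
        nested_summaries=summaries,
    )


@dataclass
class FlowSet:
    """Connections between two adjacent visible blocks.

    ``lines`` (ungrouped/mixed sides): one entry per patient present on
    both sides, carrying a position anchor per side — ``("pos", i)`` for
    an ungrouped block order index or ``("group", value)`` for a grouped
    side.  ``flows`` (both sides grouped): (source group, target group)
    -> patient id list.  Patients present on only one side are reported
    as exits (source only) / entries (target only).  The primary feature
    ids of both ends are carried so rendering can repeat their colors as
    proxies at the band ends.
    """

    between: tuple[int, int]
    mode: str  # "lines" | "flows" | "mixed"
    lines: list[tuple[str, tuple, tuple]] = field(default_factory=list)
    flows: dict[tuple[Any, Any], list[str]] = field(default_factory=dict)
    entries: list[str] = field(default_factory=list)
    exits: list[str] = field(default_factory=list)
    highlight: set[str] = field(default_factory=set)
    source_primary: str | None = None
    target_primary: str | None = None

    def flow_counts(self) -> dict[tuple[Any, Any], int]:
        return {k: len(v) for k, v in self.flows.items()}


def _present(state: Block | GroupedBlock) -> list[str]:
    if isinstance(state, GroupedBlock):
        return state.patients()
    return state.present_patients()


def _anchor(state: Block | GroupedBlock, pid: str) -> tuple:
    if isinstance(state, GroupedBlock):
        return ("group", state.group_of(pid))
    return ("pos", state.order.index(pid))


def compute_flows(
    state_a: Block | GroupedBlock,
    state_b: Block | GroupedBlock,
    *,
    max_index_gap: int = 1,
) -> FlowSet:
    """Connections between two adjacent block states.

    Both ungrouped -> per-patient lines; both grouped -> counted
    group-to-group Sankey flows; mixed -> per-patient lines fanning
    between order positions and group segments.  ``max_index_gap`` > 1
    is used internally when an ungrouped event block is bridged.
    """
    if not 1 <= abs(state_a.index - state_b.index) <= max_index_gap:
        raise ValueError(
            f"blocks {state_a.index} and {state_b.index} are not adjacent"
        )
    pres_a, pres_b = _present(state_a), _present(state_b)
    shared = [p for p in pres_a if p in set(pres_b)]
    exits = [p for p in pres_a if p not in set(pres_b)]
    entries = [p for p in pres_b if p not in set(pres_a)]

    grouped_a = isinstance(state_a, GroupedBlock)
    grouped_b = isinstance(state_b, GroupedBlock)
    fs = FlowSet(
        between=(state_a.index, state_b.index),
        mode="flows" if grouped_a and grouped_b else
             "lines" if not grouped_a and not grouped_b else "mixed",
        entries=entries,
        exits=exits,
        source_primary=state_a.primary_feature,
        target_primary=state_b.primary_feature,
    )
    if fs.mode == "flows":
        order_a = {g: i for i, (g, _) in enumerate(state_a.groups)}
        order_b = {g: i for i, (g, _) in enumerate(state_b.groups)}
        shared_set = set(shared)
        for g, pids in state_a.groups:
            for pid in pids:
                if pid in shared_set:
                    gb = state_b.group_of(pid)
                    fs.flows.setdefault((g, gb), []).append(pid)
        # band order at each end follows the opposite end's group order
        fs.flows = dict(
            sorted(
                fs.flows.items(),
                key=lambda kv: (order_a.get(kv[0][0], 0), order_b.get(kv[0][1], 0)),
            )
        )
    else:
        for pid in shared:
            fs.lines.append((pid, _anchor(state_a, pid), _anchor(state_b, pid)))
    return fs


def build_flowsets(states: Sequence[Block | GroupedBlock]) -> list[FlowSet]:
    """Flowsets between consecutive visible blocks.

    A grouped event block participates in the chain (flows pass through
    its groupings); an ungrouped event block is bridged, connecting the
    flanking timepoint blocks directly.
    """
    chain = [
        s for s in states
        if s.kind != "event" or isinstance(s, GroupedBlock)
    ]
    return [
        compute_flows(a, b, max_index_gap=2)
        for a, b in zip(chain, chain[1:])
    ]


def highlight_selection(
    flowsets: Sequence[FlowSet],
    grouped_blocks: Sequence[GroupedBlock],
    patient_ids: Sequence[str],
    known_patients: Sequence[str],
) -> tuple[list[FlowSet], list[GroupedBlock]]:
    """Annotate flowsets and grouped blocks with a patient selection.

    Returns copies: each flowset's ``highlight`` set is filled and each
    grouped block's per-group selected counts are recomputed, enabling
    partial-band and partial-bar highlighting downstream.
    """
    unknown = set(patient_ids) - set(known_patients)
    if unknown:
        raise KeyError(f"unknown patient ids {sorted(unknown)}")
    sel = set(patient_ids)
    out_fs = []
    for fs in flowsets:
        new = FlowSet(
            between=fs.between, mode=fs.mode, lines=list(fs.lines),
            flows={k: list(v) for k, v in fs.flows.items()},
            entries=list(fs.entries), exits=list(fs.exits),
            highlight=sel & ({p for p, _, _ in fs.lines}
                             | {p for v in fs.flows.values() for p in v}),
            source_primary=fs.source_primary, target_primary=fs.target_primary,
        )
        out_fs.append(new)
    out_gb = []
    for gb in grouped_blocks:
        new = GroupedBlock(
            index=gb.index, kind=gb.kind, slot=gb.slot,
            primary_feature=gb.primary_feature,
            groups=[(g, list(p)) for g, p in gb.groups],
            nested_summaries=gb.nested_summaries,
            selected_counts={g: len(sel & set(p)) for g, p in gb.groups},
        )
        out_gb.append(new)
    return out_fs, out_gb


def layout_state_to_dict(
    blocks: Sequence[Block],
    grouped_blocks: Sequence[GroupedBlock] = (),
    flowsets: Sequence[FlowSet] = (),
) -> dict:
    """JSON-serializable snapshot of the layout (orders, groups, flows)."""
    grouped_idx = {g.index for g in grouped_blocks}
    return {
        "blocks": [
            {
                "index": b.index,
                "kind": b.kind,
                "slot": b.slot,
                "rows": list(b.rows),
                "order": list(b.order),
                "primary_feature": b.primary_feature,
                "grouped": b.index in grouped_idx,
            }
            for b in blocks
        ],
        "grouped_blocks": [
            {
                "index": g.index,
                "primary_feature": g.primary_feature,
                "groups": [[str(val), list(pids)] for val, pids in g.groups],
            }
            for g in grouped_blocks
        ],
        "flows": [
            {
                "between": list(fs.between),
                "mode": fs.mode,
                "lines": [[p, list(a), list(b)] for p, a, b in fs.lines],
                "flows": [[str(k[0]), str(k[1]), sorted(v)] for k, v in fs.flows.items()],
                "entries": sorted(fs.entries),
                "exits": sorted(fs.exits),
            }
            for fs in flowsets
        ],
    }
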