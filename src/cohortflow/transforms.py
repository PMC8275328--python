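"""Feature transforms: binning, log scaling, type conversion, Boolean and
gene-set combination, inversion, renaming and row ordering.

Two surfaces are provided.  The pure functions (``bin_continuous``,
``log_transform``, ...) map :class:`~cohortflow.model.Feature` objects to
new Features and never touch a cohort.  The cohort-level
:func:`apply_transform` wrapper resolves feature ids, registers the
result and appends a :class:`~cohortflow.model.TransformRecord` to the
operation log; :func:`replay` re-applies a log deterministically.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

from .model import Cohort, Feature, TransformRecord

__all__ = [
    "BinSpec",
    "CombineSpec",
    "bin_continuous",
    "log_transform",
    "combine_binary",
    "combine_continuous_mean",
    "invert_binary",
    "to_ordinal",
    "to_categorical",
    "rename_feature",
    "set_color_scale",
    "reorder_features",
    "apply_transform",
    "replay",
    "TRANSFORMS",
]

SOURCE_ORDER = {s: i for i, s in enumerate(
    ("clinical_patient", "clinical_sample", "mutation", "cna", "expression", "derived")
)}
DATATYPE_ORDER = {d: i for i, d in enumerate(("binary", "categorical", "ordinal", "continuous"))}


@dataclass(frozen=True)
class BinSpec:
    """Thresholds and labels for binning a continuous feature.

    ``len(labels) == len(edges) + 1``; a value lands in the upper bin of
    an edge when it is >= the edge (so edge 150 puts 150 in "high",
    matching the low <150 / high >=150 reading).
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __init__(self, edges: Sequence[float], labels: Sequence[str]):
        edges = tuple(float(e) for e in edges)
        labels = tuple(labels)
        if not edges:
            raise ValueError("BinSpec needs at least one edge")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if len(labels) != len(edges) + 1:
            raise ValueError(f"need {len(edges) + 1} labels for {len(edges)} edges")
        if len(set(labels)) != len(labels):
            raise ValueError("bin labels must be unique")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "labels", labels)

    def assign(self, value: float) -> str:
        return self.labels[bisect_right(self.edges, value)]


@dataclass(frozen=True)
class CombineSpec:
    input_feature_ids: tuple[str, ...]
    operator: str  # AND | OR | MEAN
    output_name: str

    def __post_init__(self) -> None:
        if self.operator not in ("AND", "OR", "MEAN"):
            raise ValueError(f"unknown combine operator {self.operator!r}")
        if len(self.input_feature_ids) < 2:
            raise ValueError("combining requires at least two input features")


def _derived(feature: Feature, feature_id: str | None, suffix: str) -> str:
    return feature_id or f"{feature.feature_id}_{suffix}"


def bin_continuous(feature: Feature, bin_spec: BinSpec, feature_id: str | None = None) -> Feature:
    """Bin a continuous feature into an ordinal one (bins in edge order)."""
    if feature.datatype != "continuous":
        raise ValueError(f"bin_continuous requires a continuous feature, got {feature.datatype}")
    values = {}
    for key, v in feature.values.items():
        if v is None:
            values[key] = None
            continue
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ValueError(f"non-numeric value {v!r} at {key!r}")
        values[key] = bin_spec.assign(float(v))
    return feature.replace(
        feature_id=_derived(feature, feature_id, "binned"),
        display_name=f"{feature.display_name} (binned)",
        datatype="ordinal",
        source="derived",
        domain=list(bin_spec.labels),
        color_scale=None,
        values=values,
    )


def log_transform(
    feature: Feature, base: float = 10.0, pseudocount: float = 0.0,
    feature_id: str | None = None,
) -> Feature:
    if feature.datatype != "continuous":
        raise ValueError("log_transform requires a continuous feature")
    bad = sorted(
        str(k) for k, v in feature.values.items() if v is not None and v + pseudocount <= 0
    )
    if bad:
        raise ValueError(
            f"log transform undefined for nonpositive values at: {', '.join(bad[:10])}"
        )
    values = {
        k: None if v is None else math.log(v + pseudocount, base)
        for k, v in feature.values.items()
    }
    nm = [v for v in values.values() if v is not None]
    return feature.replace(
        feature_id=_derived(feature, feature_id, "log"),
        display_name=f"log{base:g}({feature.display_name})",
        source="derived",
        domain=(min(nm), max(nm)) if nm else None,
        values=values,
    )


def _check_same_level(features: Sequence[Feature]) -> str:
    levels = {f.level for f in features}
    if len(levels) != 1:
        raise ValueError(f"cannot combine features of mixed levels {sorted(levels)}")
    return levels.pop()


def combine_binary(
    features: Sequence[Feature], operator: str, output_name: str,
    feature_id: str | None = None,
) -> Feature:
    """Boolean fold of binary features (e.g. pathway mutation status).

    The fold runs over non-missing inputs; a short-circuit value (1 for
    OR, 0 for AND) decides the output even when other inputs are missing,
    and the output is missing only when every input is missing.
    """
    if operator not in ("AND", "OR"):
        raise ValueError(f"operator must be AND or OR, got {operator!r}")
    if len(features) < 2:
        raise ValueError("combine_binary needs at least two features")
    for f in features:
        if f.datatype != "binary":
            raise ValueError(f"combine_binary input {f.feature_id} is {f.datatype}, not binary")
    level = _check_same_level(features)
    keys = sorted({k for f in features for k in f.values}, key=str)
    short = 1 if operator == "OR" else 0
    values: dict = {}
    for k in keys:
        vals = [f.values.get(k) for f in features]
        present = [v for v in vals if v is not None]
        if not present:
            values[k] = None
        elif short in present:
            values[k] = short
        elif None in vals:
            values[k] = None  # undecided: the missing input could flip the fold
        else:
            values[k] = 1 - short
    return Feature(
        feature_id=feature_id or output_name,
        display_name=output_name,
        datatype="binary",
        source="derived",
        level=level,
        values=values,
    )


def combine_continuous_mean(
    features: Sequence[Feature], output_name: str, feature_id: str | None = None
) -> Feature:
    """Per-key arithmetic mean of continuous features (gene-set style
    aggregation); missing inputs are dropped from the mean."""
    if len(features) < 2:
        raise ValueError("combine_continuous_mean needs at least two features")
    for f in features:
        if f.datatype != "continuous":
            raise ValueError(f"input {f.feature_id} is {f.datatype}, not continuous")
    level = _check_same_level(features)
    keys = sorted({k for f in features for k in f.values}, key=str)
    values = {}
    for k in keys:
        present = [f.values[k] for f in features if f.values.get(k) is not None]
        values[k] = sum(present) / len(present) if present else None
    nm = [v for v in values.values() if v is not None]
    return Feature(
        feature_id=feature_id or output_name,
        display_name=output_name,
        datatype="continuous",
        source="derived",
        level=level,
        domain=(min(nm), max(nm)) if nm else None,
        values=values,
    )


def invert_binary(feature: Feature, feature_id: str | None = None) -> Feature:
    if feature.datatype != "binary":
        raise ValueError("invert_binary requires a binary feature")
    values = {k: None if v is None else 1 - v for k, v in feature.values.items()}
    return feature.replace(
        feature_id=_derived(feature, feature_id, "inv"),
        display_name=f"NOT {feature.display_name}",
        values=values,
    )


def to_ordinal(feature: Feature, category_order: Sequence, feature_id: str | None = None) -> Feature:
    """Impose a total order on a categorical domain."""
    if feature.datatype not in ("categorical", "ordinal"):
        raise ValueError("to_ordinal requires a categorical feature")
    order = list(category_order)
    if sorted(map(str, order)) != sorted(map(str, feature.domain or [])):
        raise ValueError(
            f"category_order {order} is not a permutation of domain {list(feature.domain or [])}"
        )
    return feature.replace(
        feature_id=_derived(feature, feature_id, "ordinal"),
        datatype="ordinal",
        domain=order,
    )


def to_categorical(feature: Feature, feature_id: str | None = None) -> Feature:
    """Drop the order of an ordinal domain."""
    if feature.datatype != "ordinal":
        raise ValueError("to_categorical requires an ordinal feature")
    return feature.replace(
        feature_id=_derived(feature, feature_id, "categorical"),
        datatype="categorical",
    )


def rename_feature(feature: Feature, display_name: str) -> Feature:
    return feature.replace(display_name=display_name)


def set_color_scale(feature: Feature, color_scale) -> Feature:
    return feature.replace(color_scale=color_scale)


def reorder_features(
    rows: Sequence[str],
    features: Mapping[str, Feature],
    sort_key: str | Sequence[str],
) -> list[str]:
    """Reorder displayed rows by datatype/source/name or an explicit list.

    Sorting is stable: rows tying on the key keep their prior relative
    order.  The explicit list must be a permutation of ``rows``.
    """
    rows = list(rows)
    if not isinstance(sort_key, str):
        explicit = list(sort_key)
        if sorted(explicit) != sorted(rows):
            raise ValueError("explicit order is not a permutation of the current rows")
        return explicit
    if sort_key == "name":
        return sorted(rows, key=lambda r: features[r].display_name)
    if sort_key == "datatype":
        return sorted(rows, key=lambda r: DATATYPE_ORDER[features[r].datatype])
    if sort_key == "source":
        return sorted(rows, key=lambda r: SOURCE_ORDER[features[r].source])
    raise ValueError(f"unknown sort key {sort_key!r}")


# ---------------------------------------------------------------------------
# Cohort-level application + replay


def _op_bin(cohort: Cohort, *, feature: str, edges, labels, output_id=None) -> Feature:
    return bin_continuous(cohort.features[feature], BinSpec(edges, labels), output_id)


def _op_log(cohort: Cohort, *, feature: str, base=10.0, pseudocount=0.0, output_id=None) -> Feature:
    return log_transform(cohort.features[feature], base, pseudocount, output_id)


def _op_combine_binary(cohort: Cohort, *, features, operator, output_name, output_id=None) -> Feature:
    return combine_binary([cohort.features[f] for f in features], operator, output_name, output_id)


def _op_combine_mean(cohort: Cohort, *, features, output_name, output_id=None) -> Feature:
    return combine_continuous_mean([cohort.features[f] for f in features], output_name, output_id)


def _op_invert(cohort: Cohort, *, feature, output_id=None) -> Feature:
    return invert_binary(cohort.features[feature], output_id)


def _op_to_ordinal(cohort: Cohort, *, feature, category_order, output_id=None) -> Feature:
    return to_ordinal(cohort.features[feature], category_order, output_id)


def _op_to_categorical(cohort: Cohort, *, feature, output_id=None) -> Feature:
    return to_categorical(cohort.features[feature], output_id)


TRANSFORMS = {
    "bin": _op_bin,
    "log": _op_log,
    "combine_binary": _op_combine_binary,
    "combine_mean": _op_combine_mean,
    "invert": _op_invert,
    "to_ordinal": _op_to_ordinal,
    "to_categorical": _op_to_categorical,
}


def apply_transform(cohort: Cohort, op_name: str, params: Mapping[str, Any]) -> Feature:
    """Run a named transform against the cohort's feature registry,
    register the derived feature and log the operation."""
    if op_name in TRANSFORMS:
        feat = TRANSFORMS[op_name](cohort, **params)
        cohort.add_feature(feat)
    elif op_name == "rename":
        feat = rename_feature(cohort.features[params["feature"]], params["display_name"])
        cohort.features[feat.feature_id] = feat
    elif op_name == "set_color_scale":
        feat = set_color_scale(cohort.features[params["feature"]], params["color_scale"])
        cohort.features[feat.feature_id] = feat
    else:
        raise KeyError(f"unknown transform {op_name!r}")
    cohort.log(op_name, params)
    return feat


def replay(cohort: Cohort, op_log: Sequence[TransformRecord]) -> Cohort:
    """Re-apply a recorded operation log to a freshly built cohort.

    All logged operations are deterministic, so replay reproduces the
    derived-feature registry (and hence any block state built from it)
    exactly.
    """
    for rec in op_log:
        apply_transform(cohort, rec.op_name, rec.params)
    return cohort
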