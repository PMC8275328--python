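"""Variability scoring and feature ranking.

Features can vary in two directions on the block grid: *within* a
timepoint (row scores — how heterogeneous is the cohort at one aligned
timepoint) and *across* timepoints (column scores — how much does a
single patient's value change over time).  For nominal data we use two
standard dispersion measures:

* ModVR (Freeman's mode-based variation ratio), ``K(n - f_m) / (n(K-1))``
  with ``n`` observations, modal frequency ``f_m`` and ``K`` observed
  categories; 0 for a constant multiset, 1 exactly when the values are
  uniform over K >= 2 categories.
* the coefficient of unalikeability, ``1 - sum_k p_k^2`` — the fraction
  of ordered observation pairs (self-pairs included) that differ.

For numeric data the coefficient of variation (sd/mean, sample sd) and
the sample variance are provided.  Across timepoints, the rate of change
is the fraction of adjacent-timepoint transitions whose value changed
(categorical) or the mean absolute step relative to the cohort-wide
observed range (continuous).

Per-timepoint / per-patient scores are aggregated (min, max or mean) to
one scalar per feature, and features are ranked descending (rank 1 =
most variable); missing scores rank last.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .model import BlockGrid, Cohort

__all__ = [
    "modvr",
    "unalikeability",
    "coefficient_of_variation",
    "variance_score",
    "rate_of_change_categorical",
    "rate_of_change_continuous",
    "score_feature",
    "rank_features",
    "ScoreTable",
    "SCORE_DEFINITIONS",
    "ScoreDefinition",
]

CATEGORICAL_TYPES = frozenset({"binary", "categorical", "ordinal"})


@dataclass(frozen=True)
class ScoreDefinition:
    name: str
    applicable_datatypes: frozenset
    orientation: str  # "row" (within timepoint) | "column" (across timepoints)
    bounded: tuple[float, float] | None


def _clean(values) -> list:
    return [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]


def modvr(values: Sequence) -> float | None:
    """Mode-based variation ratio, standardized to [0, 1].

    With n non-missing observations over K observed categories and modal
    frequency f_m: K(n - f_m) / (n(K - 1)); 0 when K == 1.  Needs at
    least 2 observations, else the score is missing (None).
    """
    vals = _clean(values)
    n = len(vals)
    if n < 2:
        return None
    counts = Counter(vals)
    k = len(counts)
    if k == 1:
        return 0.0
    f_m = max(counts.values())
    return k * (n - f_m) / (n * (k - 1))


def unalikeability(values: Sequence) -> float | None:
    """Coefficient of unalikeability: 1 - sum of squared category
    proportions, i.e. the fraction of ordered observation pairs
    (including self-pairs) whose members differ."""
    vals = _clean(values)
    n = len(vals)
    if n < 2:
        return None
    counts = Counter(vals)
    return 1.0 - sum((c / n) ** 2 for c in counts.values())


def _sample_sd(vals: list[float]) -> float:
    mean = sum(vals) / len(vals)
    return math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))


def coefficient_of_variation(values: Sequence) -> float | None:
    """|sd / mean| with the n-1 sample standard deviation.

    Missing when fewer than 2 observations or the mean is 0 (ratio
    undefined); a negative mean yields the absolute ratio so the
    CV<1 / CV>1 reading stays meaningful.
    """
    vals = [float(v) for v in _clean(values)]
    if len(vals) < 2:
        return None
    mean = sum(vals) / len(vals)
    if mean == 0:
        return None
    return abs(_sample_sd(vals) / mean)


def variance_score(values: Sequence) -> float | None:
    """Sample variance (n-1 denominator)."""
    vals = [float(v) for v in _clean(values)]
    if len(vals) < 2:
        return None
    mean = sum(vals) / len(vals)
    return sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)


def _valid_pairs(series: Sequence) -> list[tuple]:
    """Adjacent pairs with both members observed; pairs spanning a gap or
    missing value are dropped, never bridged."""
    pairs = []
    for a, b in zip(series, series[1:]):
        if a is not None and b is not None:
            pairs.append((a, b))
    return pairs


def rate_of_change_categorical(series: Sequence) -> float | None:
    """Changed transitions / total valid transitions, in [0, 1]."""
    pairs = _valid_pairs(series)
    if not pairs:
        return None
    return sum(1 for a, b in pairs if a != b) / len(pairs)


def rate_of_change_continuous(series: Sequence, feature_range: float) -> float | None:
    """Mean absolute adjacent step divided by the observed cohort-wide
    range; a zero-range (constant) feature scores 0 by convention."""
    pairs = _valid_pairs(series)
    if not pairs:
        return None
    if feature_range == 0:
        return 0.0
    if feature_range < 0:
        raise ValueError("feature_range must be non-negative")
    return (sum(abs(b - a) for a, b in pairs) / len(pairs)) / feature_range


SCORE_DEFINITIONS = {
    "modvr": ScoreDefinition("modvr", CATEGORICAL_TYPES, "row", (0.0, 1.0)),
    "unalikeability": ScoreDefinition("unalikeability", CATEGORICAL_TYPES, "row", (0.0, 1.0)),
    "cv": ScoreDefinition("cv", frozenset({"continuous"}), "row", None),
    "variance": ScoreDefinition("variance", frozenset({"continuous"}), "row", None),
    "rate_of_change": ScoreDefinition(
        "rate_of_change", CATEGORICAL_TYPES | {"continuous"}, "column", (0.0, 1.0)
    ),
}

_ROW_FUNCS = {
    "modvr": modvr,
    "unalikeability": unalikeability,
    "cv": coefficient_of_variation,
    "variance": variance_score,
}

AGGREGATIONS = {
    "min": min,
    "max": max,
    "mean": lambda xs: sum(xs) / len(xs),
}


def _check_applicable(score_name: str, datatype: str) -> ScoreDefinition:
    try:
        sdef = SCORE_DEFINITIONS[score_name]
    except KeyError:
        raise KeyError(f"unknown score {score_name!r}") from None
    if datatype not in sdef.applicable_datatypes:
        raise ValueError(
            f"score {score_name!r} is not defined for {datatype} features "
            f"(applies to: {', '.join(sorted(sdef.applicable_datatypes))})"
        )
    return sdef


def per_block_scores(grid: BlockGrid, feature_id: str, score_name: str) -> list[float | None]:
    """Row score per timepoint block, over the patients present there."""
    feat = grid.cohort.features[feature_id]
    _check_applicable(score_name, feat.datatype)
    fn = _ROW_FUNCS[score_name]
    out = []
    for tp in range(grid.n_timepoints):
        vals = grid.values_at_timepoint(feature_id, tp)
        out.append(fn([v for v in vals if v is not None]))
    return out


def per_patient_scores(grid: BlockGrid, feature_id: str) -> list[float | None]:
    """Column (rate-of-change) score per patient over their timepoint series."""
    feat = grid.cohort.features[feature_id]
    _check_applicable("rate_of_change", feat.datatype)
    if feat.datatype == "continuous":
        rng = feat.observed_range()
        span = 0.0 if rng is None else rng[1] - rng[0]
    out = []
    for pid in grid.cohort.patient_ids:
        series = grid.patient_series(feature_id, pid)
        if feat.datatype == "continuous":
            out.append(rate_of_change_continuous(series, span))
        else:
            out.append(rate_of_change_categorical(series))
    return out


def score_feature(
    cohort: Cohort,
    grid: BlockGrid,
    feature_id: str,
    score_name: str,
    aggregation: str = "mean",
) -> float | None:
    """One aggregated variability score for a feature.

    Row scores are computed once per timepoint block (across patients),
    column scores once per patient (across that patient's timepoints);
    the chosen aggregation then folds the list, ignoring missing
    entries.  All-missing -> missing (None).
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {sorted(AGGREGATIONS)}")
    sdef = _check_applicable(score_name, cohort.features[feature_id].datatype)
    if sdef.orientation == "row":
        scores = per_block_scores(grid, feature_id, score_name)
    else:
        scores = per_patient_scores(grid, feature_id)
    present = [s for s in scores if s is not None]
    if not present:
        return None
    return AGGREGATIONS[aggregation](present)


@dataclass
class ScoreTable:
    """Per-feature variability scores with rank columns.

    ``table`` holds one row per feature: metadata columns (display name,
    datatype, source, observed range/categories), one score column per
    ``(score, aggregation)`` request and a matching ``rank:`` column
    (descending, ties share the min rank, missing scores last).
    """

    table: pd.DataFrame
    requests: list[tuple[str, str]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    def rank_of(self, feature_id: str, column: str) -> int:
        row = self.table[self.table["feature_id"] == feature_id]
        return int(row[f"rank:{column}"].iloc[0])


def _domain_summary(feat) -> str:
    if feat.datatype == "continuous":
        rng = feat.observed_range()
        return "" if rng is None else f"[{rng[0]:g}, {rng[1]:g}]"
    return ", ".join(map(str, feat.domain or []))


def rank_features(
    cohort: Cohort,
    grid: BlockGrid,
    score_requests: Sequence[tuple[str, str]],
    feature_ids: Sequence[str] | None = None,
) -> ScoreTable:
    """Score and rank features for the exploration table.

    ``score_requests`` are ``(score_name, aggregation)`` pairs.  Scores
    that do not apply to a feature's datatype are recorded as missing so
    heterogeneous features can share one table; higher variability ranks
    first and missing scores rank after all scored features.
    """
    if not score_requests:
        raise ValueError("at least one (score, aggregation) request is required")
    fids = list(feature_ids) if feature_ids is not None else [
        f for f in cohort.features if cohort.features[f].level != "event"
    ]
    if not fids:
        raise ValueError("no features to rank")

    rows = []
    for fid in fids:
        feat = cohort.features[fid]
        row = {
            "feature_id": fid,
            "name": feat.display_name,
            "datatype": feat.datatype,
            "source": feat.source,
            "domain": _domain_summary(feat),
        }
        for score_name, agg in score_requests:
            col = f"{score_name}_{agg}"
            try:
                row[col] = score_feature(cohort, grid, fid, score_name, agg)
            except ValueError:
                row[col] = None  # score not applicable to this datatype
        rows.append(row)

    table = pd.DataFrame(rows)
    for score_name, agg in score_requests:
        col = f"{score_name}_{agg}"
        ranks = table[col].rank(method="min", ascending=False, na_option="bottom")
        table[f"rank:{col}"] = ranks.astype(int)
    return ScoreTable(table=table, requests=[tuple(r) for r in score_requests])
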