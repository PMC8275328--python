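"""Seeded synthetic longitudinal cohorts.

The generator emulates the shape of a small glioma-style cohort: tens of
patients, each sampled at 2-4 ordered timepoints, with

* categorical sample features evolving per patient as first-order Markov
  chains — at each step the value switches with probability ``p`` and,
  when it switches, moves uniformly to one of the *other* categories, so
  the probability that an adjacent pair differs is exactly ``p``;
* continuous sample features following a drifting random walk;
* an optional treatment event placed between two consecutive samples,
  which with probability ``q`` raises a designated continuous feature
  (mutation burden) above a high threshold at every later sample,
  emulating treatment-induced hypermutation;
* binary per-gene mutation features enriched in effect-bearing samples.

Unaffected values of the designated feature are reflected below the high
threshold so the planted effect is the only source of high-bin
membership — the generated ground truth is then exactly recoverable.
All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .io_formats import ClinicalTable, write_clinical_tsv, write_maf, write_timeline_tsv
from .model import Cohort, EventRecord, Feature, PatientRecord

__all__ = [
    "CategoricalFeatureSpec",
    "ContinuousFeatureSpec",
    "EventSpec",
    "EffectSpec",
    "GeneSpec",
    "SyntheticCohortConfig",
    "GroundTruth",
    "generate_synthetic_cohort",
    "write_synthetic_cohort",
    "cohort_to_clinical_table",
]


def _check_prob(name: str, p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")
    return float(p)


@dataclass
class CategoricalFeatureSpec:
    """A categorical sample feature with independently controllable
    within-timepoint spread (initial distribution) and across-timepoint
    variability (Markov switch probability)."""

    name: str
    categories: tuple[str, ...]
    distribution: tuple[float, ...]  # within-timepoint (initial) weights
    switch_probability: float  # per-transition P(value changes)

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"{self.name}: need >= 2 categories")
        if len(self.distribution) != len(self.categories):
            raise ValueError(f"{self.name}: distribution length mismatch")
        if abs(sum(self.distribution) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: distribution weights must sum to 1")
        _check_prob(f"{self.name}.switch_probability", self.switch_probability)


@dataclass
class ContinuousFeatureSpec:
    """A continuous sample feature as a drifting random walk."""

    name: str
    baseline_mean: float = 45.0
    baseline_sd: float = 15.0
    drift: float = 8.0  # per-step mean increment
    noise_sd: float = 12.0


@dataclass
class EventSpec:
    """Inter-timepoint treatment events (e.g. TMZ chemotherapy)."""

    event_type: str = "TREATMENT"
    attributes: dict = field(default_factory=lambda: {"AGENT": "TMZ"})
    occurrence_probability: float = 0.5

    def __post_init__(self) -> None:
        _check_prob("occurrence_probability", self.occurrence_probability)


@dataclass
class EffectSpec:
    """Probabilistic post-event shift of a designated continuous feature
    above a high threshold (treatment-induced hypermutation)."""

    feature: str = "MUTATION_COUNT"
    probability: float = 0.8
    high_threshold: float = 150.0
    high_range: tuple[float, float] = (300.0, 1200.0)

    def __post_init__(self) -> None:
        _check_prob("effect probability", self.probability)
        if self.high_range[0] < self.high_threshold:
            raise ValueError("high_range must lie at or above high_threshold")


@dataclass
class GeneSpec:
    """Binary mutation-presence gene tracks, enriched in affected samples
    (DNA mismatch-repair genes by default)."""

    genes: tuple[str, ...] = ("MLH1", "MSH6", "MSH3")
    background_rate: float = 0.05
    effect_rate: float = 0.9

    def __post_init__(self) -> None:
        _check_prob("background_rate", self.background_rate)
        _check_prob("effect_rate", self.effect_rate)


def _default_categoricals() -> list[CategoricalFeatureSpec]:
    return [
        CategoricalFeatureSpec(
            name="TUMOR_GRADE",
            categories=("II", "III", "IV"),
            distribution=(0.6, 0.25, 0.15),
            switch_probability=0.35,
        ),
        CategoricalFeatureSpec(
            name="MGMT_STATUS",
            categories=("METHYLATED", "UNMETHYLATED"),
            distribution=(0.5, 0.5),
            switch_probability=0.05,
        ),
    ]


@dataclass
class SyntheticCohortConfig:
    """Cohort-shape and noise parameters; defaults mirror a 23-patient
    cohort sampled at 2-4 timepoints with TMZ-style treatment effects."""

    n_patients: int = 23
    timepoint_weights: dict = field(default_factory=lambda: {2: 0.5, 3: 0.3, 4: 0.2})
    categorical_features: list = field(default_factory=_default_categoricals)
    continuous_features: list = field(
        default_factory=lambda: [ContinuousFeatureSpec(name="MUTATION_COUNT")]
    )
    event: EventSpec = field(default_factory=EventSpec)
    effect: EffectSpec = field(default_factory=EffectSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    days_between_samples: tuple[int, int] = (180, 720)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(t < 2 for t in self.timepoint_weights):
            raise ValueError("timepoint counts must be >= 2")
        if abs(sum(self.timepoint_weights.values()) - 1.0) > 1e-9:
            raise ValueError("timepoint weights must sum to 1")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    switch_probabilities: dict[str, float]
    effect_probability: float
    high_threshold: float
    events: dict[str, int]  # patient -> slot s (event between samples s and s+1)
    affected_samples: list[str]
    mutated: list[tuple[str, str]]  # (gene, sample) positives


def generate_synthetic_cohort(
    config: SyntheticCohortConfig,
) -> tuple[Cohort, GroundTruth]:
    """Deterministically generate a cohort plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    tp_counts = sorted(config.timepoint_weights)
    tp_weights = [config.timepoint_weights[t] for t in tp_counts]

    patients: list[PatientRecord] = []
    cat_values: dict[str, dict[str, str]] = {s.name: {} for s in config.categorical_features}
    cont_values: dict[str, dict[str, float]] = {s.name: {} for s in config.continuous_features}
    truth_events: dict[str, int] = {}
    affected: list[str] = []
    mutated: list[tuple[str, str]] = []

    lo, hi = config.effect.high_threshold, config.effect.high_range
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        n_tp = int(rng.choice(tp_counts, p=tp_weights))
        gaps = rng.integers(config.days_between_samples[0], config.days_between_samples[1] + 1,
                            size=n_tp - 1)
        dates = [0] + list(np.cumsum(gaps))
        sids = [f"{pid}_S{j}" for j in range(n_tp)]

        # categorical Markov chains
        for spec in config.categorical_features:
            cats = list(spec.categories)
            v = str(rng.choice(cats, p=list(spec.distribution)))
            cat_values[spec.name][sids[0]] = v
            for j in range(1, n_tp):
                if rng.random() < spec.switch_probability:
                    others = [c for c in cats if c != v]
                    v = str(others[rng.integers(len(others))])
                cat_values[spec.name][sids[j]] = v

        # event placement
        events: list[EventRecord] = []
        slot = None
        has_effect = False
        if rng.random() < config.event.occurrence_probability:
            slot = int(rng.integers(0, n_tp - 1))
            start = int(rng.integers(dates[slot] + 1, dates[slot + 1] + 1))
            stop = min(start + int(rng.integers(20, 120)), int(dates[slot + 1]))
            events.append(EventRecord(
                event_type=config.event.event_type,
                attributes=dict(config.event.attributes),
                start_date=start,
                stop_date=max(stop, start),
            ))
            truth_events[pid] = slot
            has_effect = rng.random() < config.effect.probability

        # continuous random walks; designated feature reflected below the
        # high threshold unless the planted effect applies
        for spec in config.continuous_features:
            designated = spec.name == config.effect.feature
            v = float(rng.normal(spec.baseline_mean, spec.baseline_sd))
            for j in range(n_tp):
                if j > 0:
                    v = v + spec.drift + float(rng.normal(0.0, spec.noise_sd))
                if designated and has_effect and slot is not None and j > slot:
                    val = float(rng.uniform(hi[0], hi[1]))
                    affected.append(sids[j])
                else:
                    val = v
                    if designated:
                        # reflect into (1, threshold-1): keep unaffected
                        # samples identifiably below the high bin
                        span = lo - 2.0
                        val = 1.0 + abs((val - 1.0) % (2 * span) - span) if span > 0 else min(val, lo - 1)
                    else:
                        val = max(val, 0.0)
                cont_values[spec.name][sids[j]] = round(float(val), 2)

        # gene mutation indicators
        for gene in config.genes.genes:
            for j, sid in enumerate(sids):
                rate = (config.genes.effect_rate if sid in set(affected)
                        else config.genes.background_rate)
                if rng.random() < rate:
                    mutated.append((gene, sid))

        patients.append(PatientRecord(
            patient_id=pid,
            samples=list(zip(sids, [int(d) for d in dates])),
            events=events,
        ))

    cohort = Cohort(patients=patients)
    for spec in config.categorical_features:
        cohort.add_feature(Feature(
            feature_id=spec.name, display_name=spec.name.replace("_", " ").title(),
            datatype="categorical", source="clinical_sample", level="sample",
            domain=list(spec.categories), values=dict(cat_values[spec.name]),
        ))
    for spec in config.continuous_features:
        vals = cont_values[spec.name]
        nm = list(vals.values())
        cohort.add_feature(Feature(
            feature_id=spec.name, display_name=spec.name.replace("_", " ").title(),
            datatype="continuous", source="clinical_sample", level="sample",
            domain=(min(nm), max(nm)) if nm else None, values=dict(vals),
        ))
    mut_set = set(mutated)
    for gene in config.genes.genes:
        cohort.add_feature(Feature(
            feature_id=f"mut_{gene}", display_name=gene,
            datatype="binary", source="mutation", level="sample",
            values={sid: (1 if (gene, sid) in mut_set else 0) for sid in cohort.sample_ids},
        ))

    truth = GroundTruth(
        switch_probabilities={s.name: s.switch_probability for s in config.categorical_features},
        effect_probability=config.effect.probability,
        high_threshold=config.effect.high_threshold,
        events=truth_events,
        affected_samples=affected,
        mutated=mutated,
    )
    return cohort, truth


def cohort_to_clinical_table(cohort: Cohort, level: str = "sample") -> ClinicalTable:
    """Project a cohort's clinical features back into a writable table."""
    table = ClinicalTable(level=level, patient_ids=cohort.patient_ids)
    if level == "sample":
        table.sample_map = [
            (p.patient_id, sid) for p in cohort.patients for sid in p.sample_ids
        ]
    table.features = [
        f for f in cohort.features.values()
        if f.level == level and f.source in (f"clinical_{level}",)
    ]
    return table


def write_synthetic_cohort(cohort: Cohort, truth: GroundTruth, out_dir) -> dict[str, Path]:
    """Write a generated cohort as cBioPortal-style flat files plus the
    ground-truth JSON; the files round-trip through the readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical_sample": out / "data_clinical_sample.txt",
        "timeline": out / "data_timeline.txt",
        "maf": out / "data_mutations.maf",
        "ground_truth": out / "ground_truth.json",
    }
    write_clinical_tsv(cohort_to_clinical_table(cohort, "sample"), paths["clinical_sample"])
    events: list[tuple[str, EventRecord]] = []
    for p in cohort.patients:
        for sid, date in p.samples:
            events.append((p.patient_id, EventRecord(
                event_type="SPECIMEN", attributes={"SAMPLE_ID": sid},
                start_date=date,
            )))
        for ev in p.events:
            events.append((p.patient_id, ev))
    write_timeline_tsv(events, paths["timeline"])
    write_maf(truth.mutated, paths["maf"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "switch_probabilities": truth.switch_probabilities,
                "effect_probability": truth.effect_probability,
                "high_threshold": truth.high_threshold,
                "events": truth.events,
                "affected_samples": truth.affected_samples,
                "mutated": [list(t) for t in truth.mutated],
            },
            fh, indent=2, sort_keys=True,
        )
    return paths
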