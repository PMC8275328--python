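"""Readers and writers for cBioPortal-style flat files.

Supported dialects:

* clinical sample/patient TSV with the four ``#``-prefixed metadata
  header rows (display names, descriptions, datatypes, priorities)
  followed by a column-name row; files without metadata headers are
  accepted with datatype inference and a warning;
* timeline-event TSV (PATIENT_ID, START_DATE, STOP_DATE, EVENT_TYPE plus
  free attribute columns), integer day dates;
* minimal MAF (Hugo_Symbol, Tumor_Sample_Barcode) turned into binary
  per-gene mutation-presence features;
* a JSON view-metadata sidecar describing displayed features, their
  transform history and the layout state, which round-trips.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .model import Cohort, EventRecord, Feature

__all__ = [
    "ClinicalTable",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_timeline_tsv",
    "write_timeline_tsv",
    "read_maf",
    "write_maf",
    "write_view_metadata",
    "read_view_metadata",
]

NA_STRINGS = {"", "NA", "N/A", "NaN", "nan", "[Not Available]"}


@dataclass
class ClinicalTable:
    """Parsed clinical file: id framing plus one Feature per data column."""

    level: str  # "sample" | "patient"
    sample_map: list[tuple[str, str]] = field(default_factory=list)  # (patient, sample)
    patient_ids: list[str] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_clinical_tsv(path, level: str) -> ClinicalTable:
    """Parse a cBioPortal clinical file at patient or sample level.

    The datatype metadata row maps NUMBER -> continuous and STRING ->
    categorical.  Missing values are NA/empty.  Duplicate SAMPLE_ID (or
    PATIENT_ID for patient level) rows are an error.
    """
    if level not in ("sample", "patient"):
        raise ValueError("level must be 'sample' or 'patient'")
    lines = Path(path).read_text().splitlines()
    meta = [ln[1:] for ln in lines if ln.startswith("#")]
    body = [ln for ln in lines if not ln.startswith("#") and ln.strip()]
    if not body:
        raise ValueError(f"{path}: no data rows")

    display_names = descriptions = datatypes = None
    if meta:
        if len(meta) < 3:
            raise ValueError(f"{path}: expected 4 '#' metadata header rows, found {len(meta)}")
        display_names = meta[0].split("\t")
        descriptions = meta[1].split("\t")
        datatypes = meta[2].split("\t")
    else:
        warnings.warn(
            f"{path}: no '#' metadata headers; inferring datatypes from values", stacklevel=2
        )

    reader = csv.reader(body, delimiter="\t")
    header = next(reader)
    records = [row for row in reader]
    cols = {name: i for i, name in enumerate(header)}
    if "PATIENT_ID" not in cols:
        raise ValueError(f"{path}: missing required PATIENT_ID column")
    if level == "sample" and "SAMPLE_ID" not in cols:
        raise ValueError(f"{path}: missing required SAMPLE_ID column for sample-level file")

    id_col = "SAMPLE_ID" if level == "sample" else "PATIENT_ID"
    ids = [row[cols[id_col]] for row in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"{path}: duplicate {id_col} rows: {sorted(dup)[:5]}")

    table = ClinicalTable(level=level)
    if level == "sample":
        table.sample_map = [(row[cols["PATIENT_ID"]], row[cols["SAMPLE_ID"]]) for row in records]
        table.patient_ids = list(dict.fromkeys(p for p, _ in table.sample_map))
    else:
        table.patient_ids = ids

    for name, idx in cols.items():
        if name in ("PATIENT_ID", "SAMPLE_ID"):
            continue
        raw = [row[idx] if idx < len(row) else "" for row in records]
        if datatypes is not None and idx < len(datatypes):
            dtype = "continuous" if datatypes[idx].upper() == "NUMBER" else "categorical"
        else:
            non_na = [v for v in raw if v not in NA_STRINGS]
            dtype = "continuous" if non_na and all(_is_number(v) for v in non_na) else "categorical"
        values = {}
        cats: list[str] = []
        for key, v in zip(ids, raw):
            if v in NA_STRINGS:
                values[key] = None
            elif dtype == "continuous":
                values[key] = float(v)
            else:
                values[key] = v
                if v not in cats:
                    cats.append(v)
        nm = [v for v in values.values() if v is not None]
        table.features.append(
            Feature(
                feature_id=name,
                display_name=(display_names[idx] if display_names and idx < len(display_names)
                              else name),
                datatype=dtype,
                source=f"clinical_{level}",
                level=level,
                domain=(min(nm), max(nm)) if dtype == "continuous" and nm else
                       (cats if dtype == "categorical" else None),
                values=values,
            )
        )
    return table


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def write_clinical_tsv(table: ClinicalTable, path) -> None:
    """Write a clinical table back to the 4-metadata-row dialect."""
    id_cols = ["PATIENT_ID", "SAMPLE_ID"] if table.level == "sample" else ["PATIENT_ID"]
    feat_cols = [f.feature_id for f in table.features]
    names = id_cols + [f.display_name for f in table.features]
    descs = id_cols + [f.display_name for f in table.features]
    dtypes = ["STRING"] * len(id_cols) + [
        "NUMBER" if f.datatype == "continuous" else "STRING" for f in table.features
    ]
    prios = ["1"] * (len(id_cols) + len(feat_cols))
    keys = ([s for _, s in table.sample_map] if table.level == "sample" else table.patient_ids)
    with open(path, "w", newline="") as fh:
        for row in (names, descs, dtypes, prios):
            fh.write("#" + "\t".join(row) + "\n")
        fh.write("\t".join(id_cols + feat_cols) + "\n")
        for i, key in enumerate(keys):
            idrow = ([table.sample_map[i][0], key] if table.level == "sample" else [key])
            fh.write("\t".join(idrow + [_fmt(f.values.get(key)) for f in table.features]) + "\n")


def read_timeline_tsv(path) -> list[tuple[str, EventRecord]]:
    """Parse a cBioPortal timeline file into (patient_id, EventRecord)
    pairs; extra columns become event attributes.  Dates are integer
    days (negative allowed); an empty STOP_DATE makes a point event."""
    lines = Path(path).read_text().splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    reader = csv.reader(body, delimiter="\t")
    header = next(reader)
    required = {"PATIENT_ID", "START_DATE", "EVENT_TYPE"}
    if not required <= set(header):
        raise ValueError(f"{path}: timeline file requires columns {sorted(required)}")
    cols = {name: i for i, name in enumerate(header)}
    attr_cols = [c for c in header if c not in ("PATIENT_ID", "START_DATE", "STOP_DATE", "EVENT_TYPE")]
    out = []
    for lineno, row in enumerate(reader, start=2):
        pid = row[cols["PATIENT_ID"]]
        raw_start = row[cols["START_DATE"]]
        try:
            start = int(raw_start)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: START_DATE {raw_start!r} is not an integer"
            ) from None
        stop = None
        if "STOP_DATE" in cols and cols["STOP_DATE"] < len(row):
            raw_stop = row[cols["STOP_DATE"]]
            if raw_stop not in NA_STRINGS:
                try:
                    stop = int(raw_stop)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: STOP_DATE {raw_stop!r} is not an integer"
                    ) from None
        attributes = {
            c: row[cols[c]] for c in attr_cols
            if cols[c] < len(row) and row[cols[c]] not in NA_STRINGS
        }
        out.append(
            (pid, EventRecord(
                event_type=row[cols["EVENT_TYPE"]], attributes=attributes,
                start_date=start, stop_date=stop,
            ))
        )
    return out


def write_timeline_tsv(events: Iterable[tuple[str, EventRecord]], path) -> None:
    events = list(events)
    attr_cols = sorted({k for _, ev in events for k in ev.attributes})
    header = ["PATIENT_ID", "START_DATE", "STOP_DATE", "EVENT_TYPE"] + attr_cols
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for pid, ev in events:
            row = [
                pid, str(ev.start_date),
                "" if ev.stop_date is None else str(ev.stop_date),
                ev.event_type,
            ] + [ev.attributes.get(c, "") for c in attr_cols]
            fh.write("\t".join(row) + "\n")


def read_maf(path, genes: Sequence[str], sample_ids: Sequence[str]) -> tuple[list[Feature], int]:
    """Binary mutation-presence features from a MAF file.

    For each requested HUGO symbol: 1 if the file holds >= 1 record for
    (gene, sample), else 0 for every cohort sample — MAF is a
    positive-report format, so absence means observed-not-mutated, not
    missing.  Returns the features and the count of MAF rows whose
    sample is not in the cohort (ignored).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("at least one gene symbol is required")
    lines = Path(path).read_text().splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    reader = csv.reader(body, delimiter="\t")
    header = next(reader)
    if "Hugo_Symbol" not in header or "Tumor_Sample_Barcode" not in header:
        raise ValueError(f"{path}: MAF requires Hugo_Symbol and Tumor_Sample_Barcode columns")
    gi, si = header.index("Hugo_Symbol"), header.index("Tumor_Sample_Barcode")
    known = set(sample_ids)
    hits: dict[str, set[str]] = {g: set() for g in genes}
    ignored = 0
    for row in reader:
        gene, sample = row[gi], row[si]
        if sample not in known:
            ignored += 1
            continue
        if gene in hits:
            hits[gene].add(sample)
    features = [
        Feature(
            feature_id=f"mut_{gene}",
            display_name=gene,
            datatype="binary",
            source="mutation",
            level="sample",
            values={sid: (1 if sid in hits[gene] else 0) for sid in sample_ids},
        )
        for gene in genes
    ]
    return features, ignored


def write_maf(records: Iterable[tuple[str, str]], path) -> None:
    """Write minimal (gene, sample) presence records as a MAF."""
    with open(path, "w", newline="") as fh:
        fh.write("#version 2.4\n")
        fh.write("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n")
        for gene, sample in records:
            fh.write(f"{gene}\t{sample}\tMissense_Mutation\n")


# ---------------------------------------------------------------------------
# View metadata sidecar


def write_view_metadata(
    layout_state: dict,
    displayed_features: Sequence[str],
    cohort: Cohort,
    path,
    score_settings: dict | None = None,
) -> dict:
    """Export the current view description: displayed features with
    datatype/source/domain and their transform history (from the op
    log), the serialized layout state and any score settings."""
    doc = {
        "features": [
            {
                "feature_id": fid,
                "display_name": cohort.features[fid].display_name,
                "datatype": cohort.features[fid].datatype,
                "source": cohort.features[fid].source,
                "level": cohort.features[fid].level,
                "domain": (list(cohort.features[fid].domain)
                           if cohort.features[fid].domain is not None else None),
            }
            for fid in displayed_features
        ],
        "transform_log": [
            {"op": rec.op_name, "params": rec.params, "step": rec.timestamp}
            for rec in cohort.op_log
        ],
        "layout": layout_state,
        "scores": score_settings or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
    return doc


def read_view_metadata(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
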