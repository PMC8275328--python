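"""cBioPortal REST API client with an on-disk response cache.

Clinical patient/sample data, timeline events and per-gene mutation
calls for a public study are assembled into a
:class:`~cohortflow.model.Cohort`.  Every response is cached verbatim
under a content-addressed filename (hash of the request), so a study
fetched once can be re-assembled later with the network disabled —
``fetch_cbioportal`` never goes online when the cache already answers.

HTTP is done with the standard library (urllib); no third-party client
is needed for the handful of JSON endpoints used here.
"""

from __future__ import annotations

import hashlib
import json
import urllib.parse
import urllib.request
import warnings
from pathlib import Path
from typing import Sequence

from .io_formats import ClinicalTable
from .model import Cohort, EventRecord, Feature, build_cohort

__all__ = ["CBioPortalClient", "fetch_cbioportal"]

DEFAULT_BASE_URL = "https://www.cbioportal.org/api"


class CBioPortalClient:
    """Thin JSON client: GET/POST against the portal API, cache first."""

    def __init__(self, base_url: str = DEFAULT_BASE_URL, cache_dir=None, timeout: float = 30.0):
        self.base_url = base_url.rstrip("/")
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self.timeout = timeout
        if self.cache_dir:
            self.cache_dir.mkdir(parents=True, exist_ok=True)

    def _cache_path(self, url: str, body: bytes | None) -> Path | None:
        if not self.cache_dir:
            return None
        digest = hashlib.sha256(url.encode() + (body or b"")).hexdigest()[:32]
        return self.cache_dir / f"{digest}.json"

    def get_json(self, path: str, params: dict | None = None, payload=None):
        url = f"{self.base_url}/{path.lstrip('/')}"
        if params:
            url += "?" + urllib.parse.urlencode(sorted(params.items()))
        body = json.dumps(payload).encode() if payload is not None else None
        cache = self._cache_path(url, body)
        if cache is not None and cache.exists():
            return json.loads(cache.read_text())
        req = urllib.request.Request(
            url, data=body,
            headers={"Accept": "application/json", "Content-Type": "application/json"},
            method="POST" if body is not None else "GET",
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                data = json.loads(resp.read().decode())
        except urllib.error.HTTPError as err:  # pragma: no cover - network
            raise RuntimeError(f"cBioPortal request failed ({err.code}) for {url}: {err.reason}")
        if cache is not None:
            cache.write_text(json.dumps(data, sort_keys=True))
        return data

    # -- study pieces ------------------------------------------------------

    def samples(self, study_id: str) -> list[dict]:
        return self.get_json(
            f"studies/{study_id}/samples", {"pageSize": 10000000, "projection": "SUMMARY"}
        )

    def clinical_data(self, study_id: str, level: str) -> list[dict]:
        return self.get_json(
            f"studies/{study_id}/clinical-data",
            {"clinicalDataType": level.upper(), "pageSize": 10000000},
        )

    def clinical_attributes(self, study_id: str) -> dict[str, str]:
        rows = self.get_json(f"studies/{study_id}/clinical-attributes", {"pageSize": 10000000})
        return {r["clinicalAttributeId"]: r.get("datatype", "STRING") for r in rows}

    def timeline(self, study_id: str, patient_ids: Sequence[str]) -> list[dict]:
        out = []
        for pid in patient_ids:
            out.extend(self.get_json(
                f"studies/{study_id}/patients/{pid}/clinical-events", {"pageSize": 10000000}
            ))
        return out

    def gene(self, symbol: str) -> dict:
        return self.get_json(f"genes/{symbol}")

    def mutations(self, study_id: str, entrez_gene_id: int) -> list[dict]:
        return self.get_json(
            f"molecular-profiles/{study_id}_mutations/mutations",
            {"sampleListId": f"{study_id}_all", "pageSize": 10000000,
             "entrezGeneId": entrez_gene_id},
        )


def _clinical_table(
    rows: list[dict], attr_types: dict[str, str], level: str,
    sample_map: list[tuple[str, str]], patient_ids: list[str],
) -> ClinicalTable:
    key_field = "sampleId" if level == "sample" else "patientId"
    keys = [s for _, s in sample_map] if level == "sample" else patient_ids
    by_attr: dict[str, dict] = {}
    for r in rows:
        by_attr.setdefault(r["clinicalAttributeId"], {})[r[key_field]] = r.get("value")
    table = ClinicalTable(level=level, sample_map=sample_map, patient_ids=patient_ids)
    for attr_id, vals in sorted(by_attr.items()):
        numeric = attr_types.get(attr_id) == "NUMBER"
        values: dict = {}
        cats: list[str] = []
        for k in keys:
            raw = vals.get(k)
            if raw in (None, "", "NA"):
                values[k] = None
            elif numeric:
                try:
                    values[k] = float(raw)
                except ValueError:
                    values[k] = None
            else:
                values[k] = raw
                if raw not in cats:
                    cats.append(raw)
        nm = [v for v in values.values() if v is not None]
        table.features.append(Feature(
            feature_id=attr_id, display_name=attr_id,
            datatype="continuous" if numeric else "categorical",
            source=f"clinical_{level}", level=level,
            domain=((min(nm), max(nm)) if nm else None) if numeric else cats,
            values=values,
        ))
    return table


def fetch_cbioportal(
    study_id: str,
    base_url: str = DEFAULT_BASE_URL,
    gene_requests: Sequence[str] = (),
    cache_dir=None,
) -> Cohort:
    """Assemble a cohort from a cBioPortal study.

    Downloads (or replays from cache) the study's samples, clinical
    sample+patient data, per-patient timeline events and, for each
    requested HUGO symbol, mutation calls turned into binary
    mutation-presence features.  Unknown gene symbols are skipped with a
    warning.
    """
    client = CBioPortalClient(base_url, cache_dir)
    samples = client.samples(study_id)
    if not samples:
        raise RuntimeError(f"study {study_id!r} returned no samples")
    sample_map = [(s["patientId"], s["sampleId"]) for s in samples]
    patient_ids = list(dict.fromkeys(p for p, _ in sample_map))
    attr_types = client.clinical_attributes(study_id)

    sample_table = _clinical_table(
        client.clinical_data(study_id, "sample"), attr_types, "sample", sample_map, patient_ids
    )
    patient_table = _clinical_table(
        client.clinical_data(study_id, "patient"), attr_types, "patient", [], patient_ids
    )

    events = []
    for ev in client.timeline(study_id, patient_ids):
        attrs = {a["key"]: a["value"] for a in ev.get("attributes", [])}
        try:
            start = int(ev["startNumberOfDaysSinceDiagnosis"])
        except (KeyError, TypeError, ValueError):
            continue
        stop = ev.get("endNumberOfDaysSinceDiagnosis")
        events.append((ev["patientId"], EventRecord(
            event_type=ev.get("eventType", "OTHER"), attributes=attrs,
            start_date=start, stop_date=int(stop) if stop is not None else None,
        )))

    gene_features = []
    all_sids = [s for _, s in sample_map]
    for symbol in gene_requests:
        try:
            gene = client.gene(symbol)
            calls = client.mutations(study_id, gene["entrezGeneId"])
        except (RuntimeError, KeyError) as err:
            warnings.warn(f"skipping gene {symbol!r}: {err}", stacklevel=2)
            continue
        hit = {c["sampleId"] for c in calls}
        gene_features.append(Feature(
            feature_id=f"mut_{symbol}", display_name=symbol,
            datatype="binary", source="mutation", level="sample",
            values={sid: (1 if sid in hit else 0) for sid in all_sids},
        ))

    return build_cohort([sample_table, patient_table], events, gene_features)
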