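import pytest

from cohortflow.model import Cohort, EventRecord, Feature, PatientRecord


def make_feature(fid, datatype, values, level="sample", domain=None, source="clinical_sample"):
    if domain is None and datatype in ("categorical", "ordinal"):
        seen = []
        for v in values.values():
            if v is not None and v not in seen:
                seen.append(v)
        domain = seen
    return Feature(
        feature_id=fid, display_name=fid, datatype=datatype, source=source,
        level=level, domain=domain, values=dict(values),
    )


@pytest.fixture
def small_cohort():
    """Four patients, two samples each, one TMZ treatment for P1/P2.

    MGMT status: timepoint 0 = [meth, unmeth, meth, meth]; at timepoint 1
    patient P2 switches meth -> unmeth, giving the canonical
    {meth:3, unmeth:1} -> {meth:2, unmeth:2} grouped transition.
    """
    patients = [
        PatientRecord("P1", [("P1_S0", 0), ("P1_S1", 400)],
                      [EventRecord("TREATMENT", {"AGENT": "TMZ"}, 100, 250)]),
        PatientRecord("P2", [("P2_S0", 0), ("P2_S1", 500)],
                      [EventRecord("TREATMENT", {"AGENT": "TMZ"}, 450, None)]),
        PatientRecord("P3", [("P3_S0", 0), ("P3_S1", 300)]),
        PatientRecord("P4", [("P4_S0", 0), ("P4_S1", 600)]),
    ]
    cohort = Cohort(patients=patients)
    cohort.add_feature(make_feature(
        "MGMT", "categorical",
        {"P1_S0": "meth", "P2_S0": "unmeth", "P3_S0": "meth", "P4_S0": "meth",
         "P1_S1": "meth", "P2_S1": "unmeth", "P3_S1": "meth", "P4_S1": "unmeth"},
        domain=["meth", "unmeth"],
    ))
    cohort.add_feature(make_feature(
        "grade", "ordinal",
        {"P1_S0": "II", "P2_S0": "II", "P3_S0": "III", "P4_S0": "II",
         "P1_S1": "III", "P2_S1": "IV", "P3_S1": "III", "P4_S1": "II"},
        domain=["II", "III", "IV"],
    ))
    cohort.add_feature(make_feature(
        "mut_count", "continuous",
        {"P1_S0": 40.0, "P2_S0": 55.0, "P3_S0": 30.0, "P4_S0": 80.0,
         "P1_S1": 300.0, "P2_S1": 120.0, "P3_S1": 45.0, "P4_S1": 149.0},
    ))
    return cohort


@pytest.fixture
def ragged_cohort():
    """Patients with 2, 3 and 4 samples (ragged timepoint structure)."""
    patients = [
        PatientRecord("A", [("A_S0", 0), ("A_S1", 200)]),
        PatientRecord("B", [("B_S0", 0), ("B_S1", 180), ("B_S2", 400)]),
        PatientRecord("C", [("C_S0", 0), ("C_S1", 150), ("C_S2", 350), ("C_S3", 500)]),
    ]
    cohort = Cohort(patients=patients)
    values = {sid: float(i) for i, sid in enumerate(cohort.sample_ids)}
    cohort.add_feature(make_feature("score", "continuous", values))
    return cohort
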