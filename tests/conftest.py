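import pytest

from echointerchange import (
    Analyst,
    CohortTable,
    Device,
    MeasurementRecord,
    MethodId,
)

HH_AI = MethodId(Device.HANDHELD, Analyst.AI)
HH_CL1 = MethodId(Device.HANDHELD, Analyst.HUMAN_CORELAB_1)
HH_CL2 = MethodId(Device.HANDHELD, Analyst.HUMAN_CORELAB_2)
CART_AI = MethodId(Device.CART, Analyst.AI)
CART_CLIN = MethodId(Device.CART, Analyst.HUMAN_CLINICAL)
CART_CL1 = MethodId(Device.CART, Analyst.HUMAN_CORELAB_1)


def make_cohort(rows):
    """rows: (patient_id, method, parameter, value[, quality]) tuples."""
    records = []
    for row in rows:
        pid, method, parameter, value = row[:4]
        quality = row[4] if len(row) > 4 else None
        records.append(MeasurementRecord(pid, method, parameter, value, quality))
    return CohortTable(records)


@pytest.fixture
def triad_cohort():
    """Five patients with complete LVEF triads for (handheld AI; two cart humans)."""
    rows = []
    for i, (t, r1, r2) in enumerate(
        [(50, 52, 48), (60, 58, 62), (45, 44, 47), (66, 65, 63), (38, 36, 40)]
    ):
        pid = f"P{i + 1}"
        rows += [
            (pid, HH_AI, "lvef", float(t), "good"),
            (pid, CART_CLIN, "lvef", float(r1), "excellent"),
            (pid, CART_CL1, "lvef", float(r2), "excellent"),
        ]
    return make_cohort(rows)
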