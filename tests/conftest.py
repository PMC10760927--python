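import datetime as dt

import pytest

from rdstage.model import EvidenceRecord, RegistryCase, SourceTier
from rdstage.vocab import load_default_vocabulary

DIAG = dt.date(2019, 3, 1)


@pytest.fixture(scope="session")
def vocab():
    return load_default_vocabulary()


def make_case(case_id="P1", diagnosis_date=DIAG, histology="8140/3",
              topography="C250", **kwargs):
    return RegistryCase(
        case_id=case_id,
        diagnosis_date=diagnosis_date,
        histology=histology,
        topography=topography,
        **kwargs,
    )


def make_evidence(case_id="P1", tier=SourceTier.PATHOLOGY, days_after=10,
                  diagnosis_date=DIAG, **kwargs):
    return EvidenceRecord(
        case_id=case_id,
        tier=tier,
        record_date=diagnosis_date + dt.timedelta(days=days_after),
        **kwargs,
    )
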