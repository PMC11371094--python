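import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from mmstage.models import ClinicalNote, NoteType

# deterministic hypothesis runs: same examples in every environment
settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def sample_notes():
    return [
        ClinicalNote(
            "n1", "p1", dt.date(2015, 3, 2), NoteType.HEM_ONC,
            "Multiple myeloma, ISS stage III at diagnosis.\nPlan discussed.",
        ),
        ClinicalNote(
            "n2", "p1", dt.date(2015, 6, 20), NoteType.OTHER,
            "CKD stage 3. Continues Bactrim DS for prophylaxis.",
        ),
        ClinicalNote("n3", "p2", dt.date(2016, 1, 1), NoteType.PATHOLOGY, ""),
    ]
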