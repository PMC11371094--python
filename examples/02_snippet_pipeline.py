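"""Cut snippets from a clinical note and run the extractor on each.

A snippet is a 100-before / 200-after character window around each trigger
("stage", ISS, R-ISS, Durie/DS...).  The printout shows the trigger, the
window offsets, and the labels extracted from the windowed text.
"""

import datetime

from mmstage import ClinicalNote, NoteType, extract_snippet_stage, snippets_from_corpus

note = ClinicalNote(
    note_id="n1",
    patient_id="p1",
    note_date=datetime.date(2016, 4, 12),
    note_type=NoteType.HEM_ONC,
    text=(
        "Seen in hematology clinic for multiple myeloma. Bone marrow with 40% "
        "plasma cells. ISS stage III at diagnosis, beta-2 microglobulin 6.1. "
        "Also followed for CKD stage 3 by nephrology. Continues Bactrim DS for "
        "PJP prophylaxis while on therapy."
    ),
)

for snippet in snippets_from_corpus([note]):
    prediction = extract_snippet_stage(snippet)
    labels = sorted((l.system.value, l.value) for l in prediction.labels)
    print(
        f"trigger {snippet.trigger.matched_text!r:12s} "
        f"window [{snippet.window_start:3d},{snippet.window_end:3d}) -> {labels}"
    )
# The CKD stage value itself is suppressed (other-disease context), but its
# window still overlaps the true ISS mention and reports it; the antibiotic
# DS window comes out empty ("not stage").
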