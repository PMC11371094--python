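"""Roll snippet-level labels up to one per-system stage at treatment start.

Three stage-bearing snippets at different distances from the index date:
for each staging system, the value from the closest eligible note wins.
"""

import datetime

from mmstage import StageLabel, StagingSystem, rollup_patient_stage
from mmstage.models import SnippetPrediction
from mmstage.snippet_finder import CandidateMatch, Snippet

INDEX_DATE = datetime.date(2015, 6, 1)


def snippet_with_labels(note_id, days_from_index, labels):
    date = INDEX_DATE + datetime.timedelta(days=days_from_index)
    snippet = Snippet(f"{note_id}:0", note_id, "p1", date, 0, 50, "",
                      CandidateMatch(note_id, 0, 1, ""))
    labels = frozenset(labels)
    return snippet, SnippetPrediction(snippet.snippet_id, labels,
                                      {l: (0, 3) for l in labels})


pairs = [
    snippet_with_labels("n1", -200, [StageLabel(StagingSystem.ISS, 2)]),
    snippet_with_labels("n2", -15, [StageLabel(StagingSystem.ISS, 3)]),
    snippet_with_labels("n3", +90, [StageLabel(StagingSystem.RISS, 2)]),
]

record = rollup_patient_stage(pairs, INDEX_DATE, patient_id="p1")
for system, a in sorted(record.assignments.items()):
    print(f"{system.value:8s} stage {a.value}  (from {a.source_note_id}, "
          f"{a.day_distance} days from index)")
# ISS resolves to 3 - the mention 15 days before treatment beats the one 200
# days out; R-ISS comes from its only mention, independently of ISS.
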