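"""Extract myeloma stage labels from single sentences.

Each line prints the (staging system, stage value) pairs the rule pipeline
reads out of the text; an empty set means the text carries no myeloma stage
(distractors like CKD stage or the Bactrim DS antibiotic are suppressed).
"""

from mmstage import extract_text_stage

SENTENCES = [
    "Multiple myeloma, ISS stage III at diagnosis.",
    "Staging notable for R-ISS 2 and ISS 3.",
    "Durie-Salmon IIIA at presentation.",
    "Newly diagnosed with stage II disease.",       # no named system -> UNCLEAR
    "CKD stage 3, followed by nephrology.",          # other disease -> no label
    "Bactrim DS 800-160 bid for prophylaxis.",       # antibiotic DS -> no label
]

for sentence in SENTENCES:
    labels = sorted((l.system.value, l.value) for l in extract_text_stage(sentence))
    print(f"{sentence!r:60s} -> {labels}")
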