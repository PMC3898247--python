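"""Classify the packaged tobacco mitogenome transcript catalogue.

The package ships two curated tables for the tobacco mitochondrial genome
(NC_006581): the predicted transcript catalogue (member coding segments per
transcribed area) and the ORF follow-up survey (peak DOC, polysome calls).
Running the cistronic classifier over the catalogue and counting the survey
rows reproduces the headline numbers without any sequencing input.
"""

import mtscope as m
from mtscope.fixtures import table1_transcript_units

units = table1_transcript_units()
for u in units[:4]:
    print(f"{'::'.join(u.members):<40} -> {u.cistronic_class}")
print("...")

counts = m.fixture_counts()
print(f"\nmonocistronic transcripts: {counts['mono']}")
print(f"polycistronic transcripts: {counts['poly']}")
print(f"candidate ORFs surveyed:   {counts['candidate_orfs']}")
print(f"polysome associated:       {counts['pellet_associated']}")
print(f"detected in supernatant:   {counts['supernatant_detected']}")
# a transcript with one coding segment (a complete coding region or a
# single exon) is monocistronic; two or more segments -- even two exons of
# the same gene -- make it polycistronic
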