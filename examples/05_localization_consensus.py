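"""Majority-consensus subcellular localization.

Combines per-tool predictions (SignalP, ChloroP, TargetP) into a consensus
compartment per protein: the compartment named by a strict plurality wins,
ties are reported as ambiguous, and a curated override always takes
precedence.
"""

from omicshape import AnnotationRecord, annotate_consensus, majority_consensus

print("direct calls:")
for calls in (
    {"SignalP": "other", "ChloroP": "chloroplast", "TargetP": "chloroplast"},
    {"SignalP": "secretory", "ChloroP": "chloroplast", "TargetP": "mitochondrion"},
    {"TargetP": "mitochondrion"},
):
    print(f"  {sorted(calls.values())} -> {majority_consensus(calls)}")

records = [
    AnnotationRecord("IMET_A", localization_calls={
        "SignalP": "other", "ChloroP": "chloroplast", "TargetP": "chloroplast",
    }),
    AnnotationRecord("IMET_B", localization_calls={
        "SignalP": "secretory", "ChloroP": "chloroplast", "TargetP": "mitochondrion",
    }),
    AnnotationRecord("IMET_C", localization_calls={
        "TargetP": "mitochondrion", "override": "chloroplast",
    }),
]
annotate_consensus(records)
print("annotated records (override beats the tool vote):")
for rec in records:
    print(f"  {rec.entity_id}: {rec.consensus_localization}")
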