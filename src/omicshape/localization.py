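"""Majority-consensus subcellular localization from per-tool predictions.

The study ran SignalP (secretory signal peptides), ChloroP (chloroplast
transit peptides) and TargetP (mitochondrial / chloroplast / secretory /
other) and kept the compartment named by a majority of tools. Only the
combination step lives here; the predictors themselves are upstream.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

from .model import AnnotationRecord

__all__ = ["AMBIGUOUS", "majority_consensus", "annotate_consensus"]

AMBIGUOUS = "ambiguous"


def majority_consensus(calls: Mapping[str, str] | Iterable[str]) -> str:
    """Compartment named by a strict plurality of tool calls.

    A tie for the top count (including a three-way split) yields AMBIGUOUS;
    a single call wins outright. Tool order never matters.
    """
    values = list(calls.values()) if isinstance(calls, Mapping) else list(calls)
    if not values:
        raise ValueError("at least one localization call is required")
    counts = Counter(values).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return AMBIGUOUS
    return counts[0][0]


def annotate_consensus(
    records: list[AnnotationRecord], override_key: str = "override"
) -> list[AnnotationRecord]:
    """Fill ``consensus_localization`` for records that carry tool calls.

    A call under ``override_key`` (manual curation / prior literature) wins
    unconditionally; other records get the majority consensus of their tool
    calls, or keep ``None`` if no calls are present.
    """
    for rec in records:
        calls = dict(rec.localization_calls)
        override = calls.pop(override_key, None)
        if override is not None:
            rec.consensus_localization = override
        elif calls:
            rec.consensus_localization = majority_consensus(calls)
    return records
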