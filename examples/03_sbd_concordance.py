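"""Transcript-protein concordance by shape-based distance.

Generates 400 paired transcript/protein trajectories (half of them delayed,
rescaled copies; half independent), computes SBD = 1 - max normalized
cross-correlation for each pair, and classifies pairs against the quartiles
of the SBD pool: below Q1 -> highly similar, above Q3 -> highly unsimilar.
A small SBD means the protein follows the transcript's shape, possibly with
a lag — the delayed-response signature the method is built to detect.
"""

import numpy as np

from omicshape import (
    SBDRecord,
    classify_similarity,
    generate_paired_series,
    pair_profiles,
    sbd,
)

fc_t, fc_p, truths = generate_paired_series(400, frac_delayed=0.5, noise_sd=0.2, seed=1)
pairs, _ = pair_profiles(fc_t, fc_p)

records = []
for t_prof, p_prof in pairs:
    distance, shift, ncc = sbd(t_prof.values, p_prof.values)
    records.append(SBDRecord(t_prof.entity_id, distance, shift, ncc))

classified, thresholds = classify_similarity(records)
print(f"{len(classified)} gene pairs; SBD quartiles: "
      f"Q1 = {thresholds.q1:.3f}, Q3 = {thresholds.q3:.3f}")

counts = {}
for rec in classified:
    counts[rec.similarity_class.value] = counts.get(rec.similarity_class.value, 0) + 1
for name, n in sorted(counts.items()):
    print(f"  {name:>16s}: {n} pairs ({100 * n / len(classified):.0f}%)")

sbds = np.array([r.sbd for r in records])
delayed = np.array([t.is_delayed_copy for t in truths])
print(f"median SBD: delayed copies {np.median(sbds[delayed]):.3f} vs "
      f"independent pairs {np.median(sbds[~delayed]):.3f} "
      "(shape matching sees through the built-in delay)")
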