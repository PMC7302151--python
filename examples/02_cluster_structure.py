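"""Phase and cluster structure of fold-change profiles.

Builds fold changes from a synthetic LFQ matrix, clusters protein profiles
on Spearman correlation distance (cut at k = 8, the study's cluster count),
groups the timepoint columns into 3 temporal phases on Euclidean distance,
and runs a sample-level PCA on the imputed log2 intensities.
"""

from omicshape import (
    ImputationParams,
    OmicsLayer,
    cluster_means,
    column_phase_grouping,
    filter_min_quantified,
    fold_change,
    generate_lfq_matrix,
    hierarchical_cut,
    impute_downshifted_normal,
    log2_transform,
    pca_samples,
    spearman_distance_matrix,
)

matrix, _ = generate_lfq_matrix(400, seed=11)
imputed = impute_downshifted_normal(
    filter_min_quantified(log2_transform(matrix))[0], ImputationParams(seed=3)
)
fc = fold_change(imputed, OmicsLayer.PROTEIN)

dist = spearman_distance_matrix(fc)
assignments = hierarchical_cut(dist, k=8)
summaries = cluster_means(fc, assignments)
print("eight fold-change clusters (size, mean profile over timepoints):")
for s in summaries:
    profile = "  ".join(f"{v:+.2f}" for v in s.mean_profile)
    print(f"  K{s.cluster_index}: n={s.size:<4d} [{profile}]")

phases = column_phase_grouping(fc, n_phases=3)
print("temporal phase of each timepoint (Euclidean column clustering):")
for tp, phase in sorted(phases.items()):
    print(f"  {tp:>5g} h -> phase {phase}")

pca = pca_samples(imputed)
pc1, pc2 = pca.variance_fractions[:2]
print(f"sample PCA: PC1 explains {100 * pc1:.1f}%, PC2 {100 * pc2:.1f}% "
      "of intensity variance (samples of the same phase co-locate)")
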