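"""End-to-end orchestration of the integration workflow.

``run_all`` executes the stages in study order — LFQ preprocessing ->
fold changes (both layers) -> differential testing -> hierarchical
clustering / phases / PCA -> SBD pairing and concordance classes ->
category summaries — writing every intermediate table under an output
directory together with a JSON manifest (versions, seeds, parameters, and
row counts per stage) sufficient to re-execute the run bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    cluster_means,
    column_phase_grouping,
    hierarchical_cut,
    pca_samples,
    spearman_distance_matrix,
)
from .enrichment import category_delta, frequencies_to_frame, top_categories
from .io import (
    read_annotations,
    read_fpkm_matrix,
    read_protein_groups,
    write_fold_changes,
    write_matrix,
    write_table,
)
from .localization import annotate_consensus
from .model import Condition, ConfigurationError, OmicsLayer, SampleKey
from .preprocess import (
    FilterMode,
    ImputationParams,
    differential_test,
    filter_min_quantified,
    fold_change,
    impute_downshifted_normal,
    log2_transform,
)
from .sbd import classify_similarity, pair_profiles, sbd

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "DEFAULT_CATEGORIES"]

#: default twelve-category functional vocabulary (config-overridable)
DEFAULT_CATEGORIES = (
    "photosynthesis",
    "carbon metabolism",
    "lipid metabolism",
    "nitrogen metabolism",
    "protein synthesis",
    "protein degradation",
    "gene expression",
    "chromatin",
    "energy",
    "transport",
    "cell structure",
    "other metabolism",
)


@dataclass
class PipelineConfig:
    proteome: str
    transcriptome: str
    output_dir: str
    proteome_sample_map: dict[str, SampleKey]
    transcriptome_sample_map: dict[str, SampleKey]
    annotations: str | None = None
    category_vocabulary: tuple[str, ...] = DEFAULT_CATEGORIES
    min_fraction: float = 0.5
    filter_mode: FilterMode = FilterMode.SAMPLE_LEVEL
    imputation_width: float = 0.3
    imputation_down_shift: float = 1.8
    imputation_seed: int = 0
    fdr_level: float = 0.05
    k_rows: int = 8
    n_phases: int = 3
    linkage: str = "average"
    quantile_method: str = "linear"
    n_top_categories: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                proteome=raw["proteome"],
                transcriptome=raw["transcriptome"],
                output_dir=raw["output_dir"],
                proteome_sample_map=_parse_sample_map(raw["proteome_sample_map"]),
                transcriptome_sample_map=_parse_sample_map(raw["transcriptome_sample_map"]),
                annotations=raw.get("annotations"),
                category_vocabulary=tuple(
                    raw.get("category_vocabulary", DEFAULT_CATEGORIES)
                ),
                **{
                    k: v
                    for k, v in raw.items()
                    if k
                    in {
                        "min_fraction",
                        "imputation_width",
                        "imputation_down_shift",
                        "imputation_seed",
                        "fdr_level",
                        "k_rows",
                        "n_phases",
                        "linkage",
                        "quantile_method",
                        "n_top_categories",
                    }
                },
            )
        except KeyError as exc:
            raise ConfigurationError(f"config key missing: {exc}") from exc


def _parse_sample_map(raw: dict) -> dict[str, SampleKey]:
    out = {}
    for column, spec in raw.items():
        out[column] = SampleKey(
            Condition(spec["condition"]),
            float(spec["timepoint"]),
            int(spec["replicate"]),
        )
    return out


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "omicshape_version": __version__,
        "parameters": {
            "min_fraction": config.min_fraction,
            "filter_mode": config.filter_mode.value,
            "imputation_width": config.imputation_width,
            "imputation_down_shift": config.imputation_down_shift,
            "imputation_seed": config.imputation_seed,
            "fdr_level": config.fdr_level,
            "k_rows": config.k_rows,
            "n_phases": config.n_phases,
            "linkage": config.linkage,
            "quantile_method": config.quantile_method,
        },
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    # --- preprocessing (proteome) ------------------------------------------
    proteome = read_protein_groups(config.proteome, config.proteome_sample_map)
    record("read_proteome", entities=proteome.n_entities, samples=len(proteome.samples))

    log2_prot = log2_transform(proteome)
    filtered, report = filter_min_quantified(
        log2_prot, config.min_fraction, config.filter_mode
    )
    record("filter", kept=len(report.kept_ids), removed=len(report.removed_ids))

    imputed = impute_downshifted_normal(
        filtered,
        ImputationParams(
            config.imputation_width, config.imputation_down_shift, config.imputation_seed
        ),
    )
    write_matrix(imputed, out_dir / "proteome_log2_imputed.tsv")

    fc_p = fold_change(imputed, OmicsLayer.PROTEIN)
    write_fold_changes(fc_p, out_dir / "fold_changes_protein.tsv")
    record("fold_change_protein", entities=len(fc_p.entity_ids), timepoints=len(fc_p.timepoints))

    diff = differential_test(imputed, config.fdr_level)
    diff_frame = pd.DataFrame(
        [
            (d.entity_id, d.timepoint_hours, d.t_statistic, d.p_value, d.q_value, d.significant)
            for d in diff
        ],
        columns=["entity_id", "timepoint_hours", "t", "p", "q", "significant"],
    )
    write_table(diff_frame, out_dir / "differential_test.tsv", index=False)
    record("differential_test", tests=len(diff), significant=int(diff_frame["significant"].sum()))

    # --- transcriptome ------------------------------------------------------
    transcriptome = read_fpkm_matrix(config.transcriptome, config.transcriptome_sample_map)
    record("read_transcriptome", entities=transcriptome.n_entities)
    fc_t = fold_change(log2_transform(transcriptome), OmicsLayer.TRANSCRIPT)
    write_fold_changes(fc_t, out_dir / "fold_changes_transcript.tsv")

    # --- clustering / phases / PCA -----------------------------------------
    dist = spearman_distance_matrix(fc_p)
    assignments = hierarchical_cut(dist, config.k_rows, config.linkage)
    summaries = cluster_means(fc_p, assignments)
    assign_frame = pd.DataFrame(
        sorted(assignments.items()), columns=["entity_id", "cluster"]
    )
    write_table(assign_frame, out_dir / "cluster_assignments.tsv", index=False)
    write_table(
        pd.DataFrame(
            {s.cluster_index: s.mean_profile for s in summaries}
        ).T.rename_axis("cluster"),
        out_dir / "cluster_means.tsv",
    )
    phases = column_phase_grouping(fc_p, config.n_phases, config.linkage)
    write_table(
        pd.DataFrame(sorted(phases.items()), columns=["timepoint_hours", "phase"]),
        out_dir / "timepoint_phases.tsv",
        index=False,
    )
    pca = pca_samples(imputed)
    write_table(pca.scores, out_dir / "pca_sample_scores.tsv")
    record(
        "clustering",
        clusters=len(summaries),
        phases=len(set(phases.values())),
        pc1_variance=float(pca.variance_fractions[0]),
    )

    # long-format heatmap-ready export
    long = fc_p.data.copy()
    long["cluster"] = [assignments[e] for e in fc_p.entity_ids]
    long = long.melt(
        id_vars="cluster", var_name="timepoint_hours", value_name="log2_ratio",
        ignore_index=False,
    ).rename_axis("entity_id")
    write_table(long.reset_index(), out_dir / "heatmap_long.tsv", index=False)

    # --- SBD concordance ----------------------------------------------------
    pairs, unpaired = pair_profiles(fc_t, fc_p)
    from .sbd import SBDRecord

    records = []
    for t_prof, p_prof in pairs:
        d, shift, ncc = sbd(t_prof.values, p_prof.values)
        records.append(SBDRecord(t_prof.entity_id, d, shift, ncc))
    classified, thresholds = classify_similarity(records, method=config.quantile_method)
    sbd_frame = pd.DataFrame(
        [
            (r.entity_id, r.sbd, r.best_shift, r.ncc_max, r.similarity_class.value,
             thresholds.q1, thresholds.q3)
            for r in classified
        ],
        columns=["entity_id", "sbd", "best_shift", "ncc_max", "class", "q1", "q3"],
    )
    write_table(sbd_frame, out_dir / "sbd_records.tsv", index=False)
    record(
        "sbd",
        paired=len(pairs),
        unpaired=len(unpaired),
        shared_timepoints=len(pairs[0][0].values) if pairs else 0,
        q1=thresholds.q1,
        q3=thresholds.q3,
    )

    # --- functional categories ---------------------------------------------
    if config.annotations:
        annotations = read_annotations(config.annotations, config.category_vocabulary)
        annotate_consensus(annotations)
        freqs = top_categories(assignments, annotations, config.n_top_categories)
        write_table(frequencies_to_frame(freqs), out_dir / "category_frequencies.tsv", index=False)
        deltas = category_delta(fc_t, fc_p, annotations)
        for name, frame in (
            ("category_mean_transcript", deltas.mean_transcript),
            ("category_mean_protein", deltas.mean_protein),
            ("category_delta", deltas.delta),
        ):
            long_frame = frame.rename_axis("category").reset_index().melt(
                id_vars="category", var_name="timepoint_hours", value_name="log2_ratio"
            )
            write_table(long_frame, out_dir / f"{name}.tsv", index=False)
        consensus_frame = pd.DataFrame(
            [
                (a.entity_id, a.consensus_localization)
                for a in annotations
                if a.consensus_localization is not None
            ],
            columns=["entity_id", "consensus_localization"],
        )
        if len(consensus_frame):
            write_table(consensus_frame, out_dir / "localization_consensus.tsv", index=False)
        record("enrichment", annotated=len(annotations), categories=len({
            a.functional_category for a in annotations
        }))

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
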