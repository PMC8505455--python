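"""End-to-end pipeline: simulate -> preprocess -> decoding -> factors ->
forward model -> group comparison, with a JSON report and TSV artifacts.

The stage ordering mirrors the study's analysis flow: within-participant
decoding accuracy ranks the participants; the factor analyses are run on
the most accurately classified participants; the forward model is fitted
on the remaining participants' data using the factor-derived clusters; the
group comparison uses only the concept subset shared by both cohorts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import decoding, factors, forward_model, group_compare, io, preprocess, synth
from .concepts import default_concept_table
from .config import RunConfig
from .geometry import make_geometry

logger = logging.getLogger(__name__)


def _simulate(config: RunConfig):
    geom = make_geometry(config.grid_shape, config.voxel_size_mm)
    table = default_concept_table()
    if config.n_concepts != len(table):
        table = table.iloc[: config.n_concepts].reset_index(drop=True)
    gt = synth.sample_ground_truth(
        geometry=geom,
        concept_labels=table["label"].tolist(),
        category_labels=table["category"].tolist(),
        clusters_per_dimension=config.clusters_per_dimension,
        cluster_size_range=config.cluster_size_range,
        noise_sd=config.noise_sd,
        participant_sd=config.participant_sd,
        group_effect=config.group_effect,
        seed=config.seed,
    )
    cohort = synth.simulate_cohort(
        gt, config.n_faculty, config.n_students, config.n_presentations
    )
    ratings = synth.simulate_ratings(
        gt, n_raters=config.n_raters, rater_noise_sd=config.rater_noise_sd
    )
    return io.StudyBundle(
        geometry=geom, datasets=cohort, concept_table=table,
        ratings=ratings, ground_truth=gt,
    )


def _factor_stage(config: RunConfig, bundle, stability_by_id, fa_ids):
    """Two-level FA on the selected participants; returns factor scores,
    cluster map, and validation metrics."""
    by_id = {d.participant_id: d for d in bundle.datasets}
    fa_sets = [by_id[pid] for pid in fa_ids]
    individual = {
        pid: factors.individual_level_fa(
            by_id[pid], stability_by_id[pid],
            n_per_lobe=config.n_per_lobe, n_factors=config.n_factors,
        )
        for pid in fa_ids
    }
    group_sol = factors.group_level_fa(
        individual, variance_threshold=config.variance_threshold
    )
    # secondary FA on the columns not absorbed by any retained primary factor
    resid_idx = factors.residual_columns(group_sol, config.loading_threshold)
    all_cols = np.column_stack(
        [individual[pid][lobe].scores[:, f]
         for pid, lobe, f in group_sol.column_info]
    ) if group_sol.column_info else np.zeros((len(bundle.concept_table), 0))
    secondary = factors.secondary_fa(
        all_cols[:, resid_idx],
        [group_sol.column_info[i] for i in resid_idx],
        variance_threshold=config.variance_threshold,
    )
    combined_scores = np.column_stack(
        [s for s in (group_sol.scores, secondary.scores) if s.shape[1]]
    ) if (group_sol.n_factors + secondary.n_factors) else np.zeros(
        (len(bundle.concept_table), 0)
    )
    # voxel assignment: profiles averaged over the FA participants, restricted
    # to the voxels stable in all of them
    mean_profiles = np.mean([d.mean_profiles() for d in fa_sets], axis=0)
    stable_sets = [
        set(np.concatenate(list(
            preprocess.select_per_lobe(
                stability_by_id[pid], bundle.geometry, config.n_per_lobe
            ).values()
        )))
        for pid in fa_ids
    ]
    common_stable = np.array(sorted(set.intersection(*stable_sets)), dtype=int)
    loadings = factors.voxel_factor_loadings(mean_profiles, combined_scores)
    assignment = np.full(bundle.geometry.n_voxels, -1, dtype=int)
    if combined_scores.shape[1]:
        assignment[common_stable] = factors.assign_voxels_to_factors(
            loadings[common_stable], config.loading_threshold
        )
    cluster_map = factors.extract_clusters(
        assignment, bundle.geometry,
        min_size=config.min_cluster_size, connectivity=config.connectivity,
    )
    # behavioural validation of the factor interpretations
    rating_corrs = factors.correlate_scores_with_ratings(
        combined_scores, bundle.ratings
    ) if bundle.ratings is not None and combined_scores.shape[1] else []
    extreme_corrs = factors.correlate_scores_with_ratings(
        combined_scores, bundle.ratings, subset=("extremes", config.extremes_k)
    ) if bundle.ratings is not None and combined_scores.shape[1] else []
    # word-length validity check
    word_length = None
    if combined_scores.shape[1]:
        lengths = bundle.concept_table["label"].str.len().to_numpy(float)
        rs = [
            float(np.corrcoef(combined_scores[:, f], lengths)[0, 1])
            for f in range(combined_scores.shape[1])
        ]
        f_best = int(np.argmax(np.abs(rs)))
        wl_clusters = cluster_map.for_factor(f_best)
        wl_voxels = [v for c in wl_clusters for v in c.voxels]
        occ = bundle.geometry.lobe_mask("occipital")
        word_length = {
            "factor": f_best,
            "r_with_label_length": rs[f_best],
            "n_clusters": len(wl_clusters),
            "occipital_fraction": (
                float(np.mean([occ[v] for v in wl_voxels])) if wl_voxels else None
            ),
        }
    return {
        "individual": individual,
        "group_solution": group_sol,
        "secondary_solution": secondary,
        "combined_scores": combined_scores,
        "cluster_map": cluster_map,
        "rating_correlations": rating_corrs,
        "extreme_correlations": extreme_corrs,
        "word_length_check": word_length,
    }


def _group_compare_stage(config: RunConfig, bundle, report: dict):
    shared = np.flatnonzero(bundle.concept_table["elementary"].to_numpy())
    by_group: dict[str, list] = {"faculty": [], "student": []}
    for d in bundle.datasets:
        by_group[d.group].append(d)
    maps_by_group: dict[str, list] = {}
    sub_datasets: dict[str, synth.ActivationDataset] = {}
    for grp, members in by_group.items():
        individual = {}
        for d in members:
            sub = synth.ActivationDataset(
                d.participant_id, d.participant_index, d.group,
                d.psc[shared],
                [d.concept_labels[i] for i in shared], d.geometry,
            )
            sub_datasets[d.participant_id] = sub
            stab = preprocess.voxel_stability(sub.psc)
            individual[d.participant_id] = factors.individual_level_fa(
                sub, stab, n_per_lobe=config.n_per_lobe,
                n_factors=min(config.n_factors, len(shared) - 1),
            )
        group_sol = factors.group_level_fa(
            individual, variance_threshold=config.variance_threshold,
            n_factors_max=config.group_fa_factors,
        )
        maps = []
        for d in members:
            sub = sub_datasets[d.participant_id]
            profiles = sub.mean_profiles()
            loadings = factors.voxel_factor_loadings(profiles, group_sol.scores)
            stab = preprocess.voxel_stability(sub.psc)
            stable = np.concatenate(list(
                preprocess.select_per_lobe(
                    stab, bundle.geometry, config.n_per_lobe
                ).values()
            ))
            assignment = np.full(bundle.geometry.n_voxels, -1, dtype=int)
            assignment[stable] = factors.assign_voxels_to_factors(
                loadings[stable], config.loading_threshold
            )
            maps.append(factors.extract_clusters(
                assignment, bundle.geometry,
                min_size=config.min_cluster_size,
                connectivity=config.connectivity,
            ))
        maps_by_group[grp] = maps
    union = group_compare.union_factor_clusters(
        maps_by_group["faculty"], maps_by_group["student"], bundle.geometry,
        min_participants=min(config.group_min_participants,
                             len(by_group["faculty"]), len(by_group["student"])),
    )
    table = group_compare.build_group_features(
        bundle.datasets, union, shared, n_voxels=config.group_n_voxels
    )
    classification = group_compare.classify_group_membership(table)
    stepwise = group_compare.stepwise_concept_selection(
        table, beam_width=config.stepwise_beam_width
    )
    return {
        "n_shared_concepts": int(shared.size),
        "n_union_clusters": len(union),
        "accuracy": classification["accuracy"],
        "predictions": classification["predictions"],
        "stepwise": stepwise,
    }


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> dict:
    """Execute the configured stages and return the JSON-serializable report.

    Artifacts (TSV tables and ``report.json``) are written under
    ``config.outdir`` unless ``write_artifacts`` is False. Deterministic:
    identical config and seed give a byte-identical report.
    """
    outdir = Path(config.outdir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}

    # --- simulate / load ---------------------------------------------------
    if "simulate" in config.stages:
        bundle = _simulate(config)
        if write_artifacts:
            io.write_bundle(bundle, outdir / "bundle.h5")
    elif config.bundle_path:
        bundle = io.read_bundle(config.bundle_path)
    else:
        raise ValueError("no data: enable the simulate stage or set bundle_path")
    report["stages"]["simulate"] = {
        "n_participants": len(bundle.datasets),
        "n_concepts": len(bundle.concept_table),
        "n_voxels": bundle.geometry.n_voxels,
        "seed": config.seed,
    }
    faculty = [d for d in bundle.datasets if d.group == "faculty"]

    # --- preprocess ---------------------------------------------------------
    stability_by_id = {}
    if "preprocess" in config.stages:
        for d in bundle.datasets:
            stability_by_id[d.participant_id] = preprocess.voxel_stability(d.psc)
        if write_artifacts:
            io.write_stability_tsv(
                stability_by_id[bundle.datasets[0].participant_id],
                bundle.geometry, outdir / "stability_first_participant.tsv",
            )
        scores = np.stack([s.scores for s in stability_by_id.values()])
        finite = np.isfinite(scores)
        report["stages"]["preprocess"] = {
            "mean_stability": float(scores[finite].mean()),
            "n_unscoreable": int((~finite).sum()),
        }

    # --- within/cross decoding ----------------------------------------------
    fa_ids: list[str] = []
    if "decoding" in config.stages:
        within = {
            d.participant_id: decoding.within_participant_cv(
                d, n_features=config.n_features,
                n_test=config.n_test_presentations,
            )
            for d in faculty
        }
        within_means = {pid: r.mean for pid, r in within.items()}
        ranked = sorted(within_means, key=lambda p: (-within_means[p], p))
        fa_ids = ranked[: config.n_fa_participants]
        cross = decoding.cross_participant_cv(faculty, n_features=config.n_features)
        best = ranked[0]
        by_id = {d.participant_id: d for d in faculty}
        perm = decoding.permutation_test(
            within_means[best], by_id[best],
            {"kind": "within", "n_features": config.n_features,
             "n_test": config.n_test_presentations},
            n_permutations=config.n_permutations, seed=config.seed,
        )
        category = decoding.classify_category_means(
            faculty, bundle.concept_table["category"].tolist(),
            n_features=config.n_features,
        )
        report["stages"]["decoding"] = {
            "within_participant": {
                "mean": float(np.mean(list(within_means.values()))),
                "per_participant": {k: float(v) for k, v in within_means.items()},
            },
            "cross_participant": {
                "mean": float(np.mean([r.mean for r in cross])),
                "per_participant": {
                    d.participant_id: float(r.mean)
                    for d, r in zip(faculty, cross)
                },
            },
            "permutation_p_best_participant": perm["p"],
            "fa_participants": fa_ids,
            "category_mean_classification": {
                "grand_mean": category["grand_mean"],
                "per_participant": category["per_participant"],
            },
        }
        if write_artifacts:
            io.write_cv_report_tsv(within[best], outdir / "within_cv_best.tsv")

    # --- factor analysis ----------------------------------------------------
    fa_out = None
    if "factors" in config.stages:
        fa_out = _factor_stage(config, bundle, stability_by_id, fa_ids)
        cm = fa_out["cluster_map"]
        report["stages"]["factors"] = {
            "n_primary_factors": fa_out["group_solution"].n_factors,
            "n_secondary_factors": fa_out["secondary_solution"].n_factors,
            "n_clusters": len(cm),
            "cluster_sizes": [c.size for c in cm.clusters],
            "rating_correlations": fa_out["rating_correlations"],
            "extreme_correlations": fa_out["extreme_correlations"],
            "word_length_check": fa_out["word_length_check"],
        }
        if write_artifacts:
            io.write_factor_scores_tsv(
                fa_out["combined_scores"],
                bundle.concept_table["label"].tolist(),
                outdir / "factor_scores.tsv",
            )
            io.write_clusters_tsv(cm, outdir / "clusters.tsv")

    # --- forward model ------------------------------------------------------
    if "forward_model" in config.stages:
        held_out = [d for d in faculty if d.participant_id not in fa_ids] or faculty
        r2s, ras, n_clusters_used = [], [], []
        for d in held_out:
            feats = forward_model.cluster_mean_activation(
                d.mean_profiles(), stability_by_id[d.participant_id],
                fa_out["cluster_map"], bundle.geometry,
                n_voxels=config.forward_n_voxels,
                cuboid_radius=config.cuboid_radius,
            )
            res = forward_model.loo_evaluate(
                bundle.ratings.values, feats.values,
                list(bundle.ratings.dimension_names),
            )
            r2s.append(res.mean_r2)
            ras.append(res.rank.mean)
            n_clusters_used.append(len(feats.cluster_indices))
        report["stages"]["forward_model"] = {
            "mean_r2": float(np.mean(r2s)),
            "rank_accuracy": float(np.mean(ras)),
            "per_participant_r2": [float(x) for x in r2s],
            "n_clusters_used": n_clusters_used,
            "n_test_participants": len(held_out),
        }

    # --- group comparison ---------------------------------------------------
    if "group_compare" in config.stages:
        report["stages"]["group_compare"] = _group_compare_stage(
            config, bundle, report
        )

    if write_artifacts:
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n"
        )
    return report
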