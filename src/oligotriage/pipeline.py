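"""End-to-end reproducible run: simulate -> score -> cluster -> stats -> trees.

The pipeline regenerates every input (cohort fixture, per-case simulated
fields), scores the images blind to the simulation labels, recovers the NL/NR
partition by clustering, cross-tabulates recovered against fixture labels,
runs the association tests, and fits both partition trees. Every seed is
derived from the single run seed and recorded in the summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import imgio, stats, tree
from .config import RunConfig
from .ihc import IntensityBinarizer, score_case
from .simulate import simulate_case_fields

logger = logging.getLogger("oligotriage")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _stage(name: str):
    logger.info("stage: %s", name)


def run_full_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the whole chain; write outputs under ``out_dir``; return the summary."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        _stage("fixture")
        cohort = cohort_mod.build_cohort_fixture()
        cohort = cohort_mod.add_idh1_r132h_column(cohort)
        cohort_mod.write_cohort_csv(cohort.drop(columns=["idh1_r132h"]),
                                    out / "cohort.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fixture", e) from e

    try:
        _stage("simulate+score")
        case_seeds = config.spawn_seeds(len(cohort))
        rows = []
        images_dir = out / "images"
        for (_, case), seed in zip(cohort.iterrows(), case_seeds):
            fields = simulate_case_fields(
                case["h3k27me3"], n_fields=config.n_fields,
                base_params=config.image_params, seed=seed,
            )
            if config.write_images:
                case_dir = images_dir / case["case_id"]
                case_dir.mkdir(parents=True, exist_ok=True)
                for i, (img, truth) in enumerate(fields, start=1):
                    imgio.write_field_png(img, case_dir / f"field_{i}.png")
                    imgio.write_ground_truth_csv(truth, case_dir / f"field_{i}_truth.csv")
            cs = score_case([img for img, _ in fields])
            row = {"case_id": case["case_id"]}
            row.update({f"field_{i + 1}": s for i, s in enumerate(cs.field_scores)})
            row["case_score"] = cs.case_score
            rows.append(row)
        scores = pd.DataFrame(rows)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate+score", e) from e

    try:
        _stage("binarize")
        binarizer = IntensityBinarizer(linkage=config.linkage)
        scores["label"] = binarizer.fit_predict(
            scores["case_score"].to_numpy().reshape(-1, 1)
        )
        scores.round(4).to_csv(out / "scores.csv", index=False)
        Z, _ = stats.hcluster_scores(scores["case_score"], k=2, method=config.linkage)
        (out / "dendrogram.txt").write_text(
            stats.dendrogram_newick(Z, leaf_names=list(scores["case_id"])) + "\n"
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("binarize", e) from e

    try:
        _stage("stats")
        recovered = cohort.copy()
        recovered["h3k27me3"] = scores["label"].to_numpy()
        report_fixture = stats.marker_frequency_report(cohort)
        report_recovered = stats.marker_frequency_report(recovered)
        report_fixture.round(4).to_csv(out / "marker_frequencies_fixture.csv", index=False)
        report_recovered.round(4).to_csv(out / "marker_frequencies_recovered.csv",
                                         index=False)
        tab_h3 = stats.crosstab(cohort, "diagnosis_group", "h3k27me3")
        tab_atrx = stats.crosstab(cohort, "diagnosis_group", "atrx")
        tab_h3.to_csv(out / "crosstab_h3k27me3.csv")
        tab_atrx.to_csv(out / "crosstab_atrx.csv")
        idh_mut = cohort[cohort["diagnosis_group"].isin(["OLIGO_CODEL", "ASTRO_IDH_MUT"])]
        fisher_table = stats.crosstab(idh_mut, "diagnosis_group", "h3k27me3")
        fisher_table = fisher_table.loc[["OLIGO_CODEL", "ASTRO_IDH_MUT"], ["NL", "NR"]]
        p_fisher = stats.fisher_exact_2x2(fisher_table.to_numpy())
        chi2_stat, chi2_df, chi2_p = stats.chi_squared(fisher_table.to_numpy())
        tests = {
            "codeletion_vs_h3k27me3": {
                "table": fisher_table.to_numpy().tolist(),
                "fisher_two_sided_p": p_fisher,
                "chi_squared": {"statistic": chi2_stat, "df": chi2_df, "p": chi2_p},
            }
        }
        (out / "tests.json").write_text(json.dumps(tests, indent=2) + "\n")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", e) from e

    try:
        _stage("trees")
        default_tree = tree.fit_tree(cohort, min_leaf=config.tree_min_leaf)
        alt_tree = tree.fit_tree(
            cohort, min_leaf=config.tree_min_leaf,
            forced_order=("idh1_r132h", "atrx", "h3k27me3"),
        )
        (out / "tree_default.json").write_text(default_tree.to_json() + "\n")
        (out / "tree_idh1_root.json").write_text(alt_tree.to_json() + "\n")
        oligo_class, oligo_prob = default_tree.predict_profile(
            {"h3k27me3": "NL", "atrx": "RETAINED", "idh1_r132h": "POS"}
        )
        stratum = alt_tree.node_at_path({"idh1_r132h": "POS", "atrx": "RETAINED"})
    except Exception as e:  # noqa: BLE001
        raise PipelineError("trees", e) from e

    try:
        _stage("summary")
        n_oligo_nl_fix = stats.marker_frequency(report_fixture, "OLIGO_CODEL",
                                                "h3k27me3", "NL")
        n_oligo_nl_rec = stats.marker_frequency(report_recovered, "OLIGO_CODEL",
                                                "h3k27me3", "NL")
        recovery = float((recovered["h3k27me3"] == cohort["h3k27me3"]).mean())
        summary = {
            "seed": config.seed,
            "n_cases": int(len(cohort)),
            "n_fields": config.n_fields,
            "case_seeds_head": case_seeds[:5],
            "linkage": config.linkage,
            "binarizer_cut_point": binarizer.cut_point_,
            "label_recovery_rate": recovery,
            "oligo_h3k27me3_nl_fixture": f"{n_oligo_nl_fix[0]}/{n_oligo_nl_fix[1]}",
            "oligo_h3k27me3_nl_recovered": f"{n_oligo_nl_rec[0]}/{n_oligo_nl_rec[1]}",
            "fisher_two_sided_p": p_fisher,
            "default_tree_split_order": default_tree.split_variable_sequence(),
            "oligo_leaf_class": str(oligo_class),
            "oligo_leaf_probability": oligo_prob,
            "idh1_root_atrx_retained_stratum": {
                "n": stratum.n,
                "counts": stratum.counts,
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("summary", e) from e

    return summary
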