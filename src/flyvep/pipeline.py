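"""End-to-end orchestration: simulate -> extract -> classify -> MDS.

Writes a report bundle under ``config.output_dir``:

* ``features.csv`` — the per-fly feature table;
* ``pairwise.csv`` — upper-triangular matrix of pairwise mean accuracies (percent,
  significant cells only);
* ``report.json`` — every number (pairwise, pooled, n-way, MDS stress,
  hull containment) as machine-readable quantile summaries;
* ``distances.csv``, ``embedding.csv``, ``hulls.json`` — similarity stage;
* ``run.log`` — parameters, derived seeds, warnings, retry counts and
  covariance-rank notices.

A stage failure writes a ``FAILED`` marker naming the stage and re-raises;
partial outputs are retained.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict

from .config import (
    RunConfig,
    STAGE_CLASSIFY,
    STAGE_MDS,
    STAGE_SIMULATE,
)
from .exceptions import ConfigurationError
from .io import write_features_csv
from .reports import nway_report, pairwise_matrix, pairwise_table, pooled_binary
from .similarity import distance_matrix, genotype_means, hull_separation, mds_embed
from .spectral import feature_matrix
from .synth import default_presets, load_presets, simulate_cohort


def default_class_map(specs: Dict) -> Dict[str, str]:
    """PD vs non-PD pooling from the genotype class labels: early- and
    late-onset PD presets pool to 'PD', controls to 'non_PD'; the
    general-neurodegeneration class is excluded by default (see
    :func:`default_exclusions`)."""
    mapping = {}
    for name, spec in specs.items():
        if spec.class_label in ("early_PD", "late_PD"):
            mapping[name] = "PD"
        else:
            mapping[name] = "non_PD"
    return mapping


def default_exclusions(specs: Dict) -> list:
    return [n for n, s in specs.items() if s.class_label == "neurodegeneration"]


def run_end_to_end(config: RunConfig, log=None) -> Path:
    """Run the full pipeline; returns the output directory.

    Identical config + seed produce byte-identical CSV outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = log or logging.getLogger("flyvep")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    stage = "configure"
    try:
        config.to_yaml(out / "config.yaml")
        presets = (
            load_presets(config.genotype_presets)
            if config.genotype_presets
            else default_presets()
        )
        if config.genotypes:
            unknown = sorted(set(config.genotypes) - set(presets))
            if unknown:
                raise ConfigurationError(f"unknown genotype preset(s): {unknown}")
            presets = {g: presets[g] for g in config.genotypes}
        logger.info("genotypes: %s", list(presets))
        logger.info(
            "seeds: root=%d simulate=%d classify=%d mds=%d",
            config.seed,
            config.stage_seed(STAGE_SIMULATE),
            config.stage_seed(STAGE_CLASSIFY),
            config.stage_seed(STAGE_MDS),
        )

        stage = "simulate"
        cohort = simulate_cohort(
            list(presets.values()),
            n_flies=config.n_flies,
            n_reps=config.n_reps,
            fs_hz=config.fs_hz,
            seed=config.stage_seed(STAGE_SIMULATE),
            trial_s=config.trial_s,
        )
        logger.info("simulated %d trials", cohort.n_trials)

        stage = "extract"
        features = feature_matrix(
            cohort, bin_s=config.bin_s, discard_lead_bins=config.discard_lead_bins
        )
        write_features_csv(features, out / "features.csv")

        stage = "classify"
        report_json: dict = {"seed": config.seed, "genotypes": list(presets)}
        cls_seed = config.stage_seed(STAGE_CLASSIFY)
        opt_kwargs = dict(
            gamma_grid=config.gamma_grid,
            n_delta=config.n_delta,
            opt_k_folds=config.k_folds,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            pw = pairwise_matrix(
                features, regularized=True, n_iter=config.n_iter,
                k_folds=None, seed=cls_seed, **opt_kwargs,
            )
            pairwise_table(pw).to_csv(out / "pairwise.csv", float_format="%.17g")
            report_json["pairwise"] = {
                f"{g1}|{g2}": (rep.to_dict() if rep is not None else None)
                for (g1, g2), rep in pw.items()
            }

            class_map = default_class_map(presets)
            exclusions = default_exclusions(presets)
            if len(set(class_map[g] for g in presets if g not in exclusions)) == 2:
                pooled = pooled_binary(
                    features, class_map=class_map, exclusions=exclusions,
                    regularized=True, n_iter=config.n_iter, seed=cls_seed,
                    **opt_kwargs,
                )
                report_json["pooled"] = pooled.to_dict()
                report_json["pooled"]["class_map"] = class_map
                report_json["pooled"]["exclusions"] = exclusions
            else:
                logger.info("pooled analysis skipped: only one pooled class present")

            if len(presets) >= 3:
                nway = nway_report(
                    features, regularized=True, n_iter=config.n_iter,
                    seed=cls_seed, **opt_kwargs,
                )
                report_json["nway"] = nway.to_dict()
            else:
                logger.info("n-way analysis skipped: fewer than 3 genotypes")
        for w in caught:
            logger.warning("%s", w.message)

        stage = "mds"
        means = genotype_means(features)
        D = distance_matrix(means, metric=config.metric)
        D.to_frame().to_csv(out / "distances.csv", float_format="%.17g")
        if len(presets) >= 2:
            emb = mds_embed(D, dims=2, seed=config.stage_seed(STAGE_MDS))
            emb.to_frame().rename_axis("genotype").to_csv(
                out / "embedding.csv", float_format="%.17g"
            )
            class_map_full = {n: s.class_label for n, s in presets.items()}
            hulls = hull_separation(emb, class_map_full)
            hulls_out = {
                "stress": emb.stress,
                "converged": emb.converged,
                "separated": hulls["separated"],
                "pair_separated": {
                    f"{a}|{b}": v for (a, b), v in hulls["pair_separated"].items()
                },
                "containment": hulls["containment"],
                "hull_vertices": hulls["hull_vertices"],
            }
            (out / "hulls.json").write_text(json.dumps(hulls_out, indent=1))
            report_json["mds"] = {
                "stress": emb.stress,
                "converged": emb.converged,
                "separated": hulls["separated"],
            }

        (out / "report.json").write_text(json.dumps(report_json, indent=1))
        logger.info("run complete")
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
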