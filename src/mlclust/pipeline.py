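"""End-to-end orchestration: cohort -> layers -> ESTs -> clustering ->
profiling, network and classifier reports, from a single seeded config.

Every stage logs the instance counts flowing in and out, and a manifest
of all parameters and seeds is written alongside the outputs so a run
can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort_io import (CohortTable, DescriptorSchema, build_layers,
                        impute_for_similarity, read_cohort)
from .cluster_profiling import (compare_clusters, comparison_frame,
                                transition_rates)
from .correlation_network import (build_network, complete_pair_counts,
                                  export_edge_list, export_graph,
                                  spearman_matrix)
from .errors import ConfigurationError, MlclustError, UndefinedStatistic
from .multilayer_clustering import (DEFAULT_MIN_CLUSTER_SIZE, Clustering,
                                    cluster, label_unclustered)
from .rule_similarity import RuleLearnerParams, compute_est
from .subgroup_classifiers import (cross_cohort_validate, make_labeled_frame,
                                   metrics_frame, search_conjunction,
                                   search_univariate)
from .synthetic_cohort import GeneratorConfig, default_config, generate

logger = logging.getLogger(__name__)

#: Default cognitive tests offered to the classifier search.
DEFAULT_CLASSIFIER_FEATURES = ("ADAS11", "ADAS13", "MMSE", "RAVLT_immediate")


@dataclass
class RunConfig:
    """Everything one analysis run needs.  Either ``input_csv`` points to
    a long-format visit table, or ``synthetic`` carries a generator
    config (the default when both are None)."""

    input_csv: str | None = None
    synthetic: GeneratorConfig | None = None
    schema: DescriptorSchema | None = None
    baseline_names: tuple | None = None
    slope_names: tuple | None = None
    est_params: RuleLearnerParams = field(default_factory=RuleLearnerParams)
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    classifier_features: tuple = DEFAULT_CLASSIFIER_FEATURES
    rho_threshold: float = 0.5
    seed: int = 0
    out_dir: str = "mlclust_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("input_csv", "min_cluster_size", "rho_threshold",
                    "seed", "out_dir"):
            if key in doc:
                kwargs[key] = doc[key]
        if "classifier_features" in doc:
            kwargs["classifier_features"] = tuple(doc["classifier_features"])
        if "baseline_names" in doc:
            kwargs["baseline_names"] = tuple(doc["baseline_names"])
        if "slope_names" in doc:
            kwargs["slope_names"] = tuple(doc["slope_names"])
        if "est_params" in doc:
            kwargs["est_params"] = RuleLearnerParams(**doc["est_params"])
        if "schema" in doc:
            kwargs["schema"] = DescriptorSchema.from_yaml(doc["schema"])
        if doc.get("synthetic"):
            syn = doc["synthetic"]
            cfg = default_config(
                n_rapid=syn.get("n_rapid", 240),
                n_slow=syn.get("n_slow", 184),
                n_unclustered=syn.get("n_unclustered", 138),
                seed=syn.get("seed", doc.get("seed", 0)),
            )
            kwargs["synthetic"] = cfg
        return cls(**kwargs)


def name_decliner_clusters(cohort: CohortTable, clustering: Clustering,
                           severity_descriptor: str = "ADAS13") -> dict:
    """Map named clusters to 'rapid'/'slow' decliners by baseline severity.

    Each named cluster is scored by its deviation from the grand mean of
    ``severity_descriptor`` weighted by sqrt(cluster size); the cluster
    with the largest positive score is the rapid decliners, the most
    negative the slow decliners.  The size weight keeps a large,
    clearly impaired cluster ahead of a tiny extreme splinter.
    Intermediate clusters stay unnamed."""
    named = clustering.named_clusters
    if len(named) < 2:
        return {}
    subjects = clustering.subjects or cohort.subjects
    means, sizes = {}, {}
    for label in named:
        vals = [cohort.baseline.get(subjects[i], {}).get(severity_descriptor)
                for i in clustering.indices_of(label)]
        vals = [v for v in vals if v is not None]
        if vals:
            means[label] = float(np.mean(vals))
            sizes[label] = len(vals)
    if len(means) < 2:
        return {}
    grand = float(np.mean([v for label in means
                           for v in [means[label]] * sizes[label]]))
    score = {l: (means[l] - grand) * np.sqrt(sizes[l]) for l in means}
    rapid = max(score, key=score.get)
    slow = min(score, key=score.get)
    if rapid == slow or score[rapid] <= 0 or score[slow] >= 0:
        return {}
    return {rapid: "rapid", slow: "slow"}


def run_analysis(config: RunConfig):
    """Run the full pipeline and write the report bundle to
    ``config.out_dir``.  Returns a dict of the in-memory results.

    On a stage failure, partial outputs already flushed are kept and a
    ``FAILED`` marker naming the stage is written before the error
    propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    stage = "setup"
    try:
        # -- cohort ---------------------------------------------------------
        stage = "cohort"
        truth = None
        if config.input_csv is not None:
            cohort = read_cohort(config.input_csv, schema=config.schema)
            manifest["input"] = {"kind": "csv", "path": str(config.input_csv)}
        else:
            gen = config.synthetic or default_config(seed=config.seed)
            synth = generate(gen)
            cohort, truth = synth.cohort, synth.truth
            cohort.to_csv(out / "cohort.csv")
            manifest["input"] = {
                "kind": "synthetic",
                "counts": gen.counts(),
                "generator_seed": gen.seed,
            }
        manifest["stages"]["cohort"] = {"n_subjects": cohort.n}
        logger.info("cohort stage: %d subjects", cohort.n)

        # -- layers ---------------------------------------------------------
        stage = "layers"
        layer1, layer2 = build_layers(cohort, config.baseline_names,
                                      config.slope_names)
        layer1.to_csv(out / "layer_baseline.csv")
        layer2.to_csv(out / "layer_slope.csv")
        imp1 = impute_for_similarity(layer1)
        imp2 = impute_for_similarity(layer2)
        manifest["stages"]["layers"] = {
            "baseline_shape": list(layer1.data.shape),
            "slope_shape": list(layer2.data.shape),
            "imputed_cells": int(imp1.imputed_mask.sum().sum()
                                 + imp2.imputed_mask.sum().sum()),
        }

        # -- similarity -----------------------------------------------------
        stage = "similarity"
        ss = np.random.SeedSequence(config.seed)
        est_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                     for s in ss.spawn(2)]
        est1 = compute_est(imp1, config.est_params, seed=est_seeds[0])
        est2 = compute_est(imp2, config.est_params, seed=est_seeds[1])
        est1.to_csv(out / "est_baseline.csv")
        est2.to_csv(out / "est_slope.csv")
        manifest["stages"]["similarity"] = {
            "est_seeds": est_seeds,
            "params": dataclasses.asdict(config.est_params),
        }

        # -- clustering -----------------------------------------------------
        stage = "clustering"
        trace = cluster([est1, est2])
        trace.to_json(out / "merge_trace.json")
        clustering = label_unclustered(trace, config.min_cluster_size)
        clustering.to_csv(out / "clustering.csv")
        decliner_names = name_decliner_clusters(cohort, clustering)
        sizes = {label: clustering.size_of(label)
                 for label in clustering.named_clusters}
        sizes["unclustered"] = clustering.size_of("unclustered")
        manifest["stages"]["clustering"] = {
            "n_merges": len(trace.steps),
            "cluster_sizes": sizes,
            "decliner_names": decliner_names,
            "min_cluster_size": config.min_cluster_size,
        }
        logger.info("clustering stage: sizes %s", sizes)

        # -- profiling ------------------------------------------------------
        stage = "profiling"
        reports = {}
        if len(clustering.named_clusters) >= 2:
            if decliner_names:
                by_role = {v: k for k, v in decliner_names.items()}
                order = [by_role["slow"], by_role["rapid"]]
            else:
                order = list(clustering.named_clusters[:2])
            rows = compare_clusters(cohort, clustering, groups=tuple(order))
            comparison_frame(rows).to_csv(out / "cluster_comparison.csv",
                                          index=False)
            reports["comparison"] = rows
            for sex_code in ("F", "M"):
                try:
                    sex_rows = compare_clusters(cohort, clustering,
                                                groups=tuple(order),
                                                stratum=sex_code)
                except (ConfigurationError, UndefinedStatistic):
                    continue
                comparison_frame(sex_rows).to_csv(
                    out / f"cluster_comparison_{sex_code}.csv", index=False)
                reports[f"comparison_{sex_code}"] = sex_rows
        transitions = transition_rates(cohort, clustering)
        transitions.frame().to_csv(out / "transitions.csv", index=False)
        reports["transitions"] = transitions

        # -- network --------------------------------------------------------
        stage = "network"
        import pandas as pd

        all_values = pd.concat([layer1.data, layer2.data], axis=1)
        rho = spearman_matrix(all_values)
        network = build_network(rho, threshold=config.rho_threshold,
                                n_pairs=complete_pair_counts(all_values))
        export_graph(network, out / "correlation_network.graphml",
                     schema=cohort.schema)
        export_edge_list(network, out / "correlation_edges.csv")
        manifest["stages"]["network"] = {
            "n_nodes": len(network.nodes), "n_edges": len(network.edges),
            "rho_threshold": config.rho_threshold,
        }

        # -- classifiers ----------------------------------------------------
        stage = "classifiers"
        classifiers = []
        rapid_label = next((l for l, name in decliner_names.items()
                            if name == "rapid"), None)
        if not config.classifier_features:
            manifest["stages"]["classifiers"] = {"skipped": "no features"}
        elif rapid_label is None:
            manifest["stages"]["classifiers"] = {"skipped": "no rapid cluster"}
        else:
            frame = make_labeled_frame(cohort, clustering,
                                       config.classifier_features, rapid_label)
            tags = sorted(set(frame.cohort.unique()) - {""})
            if len(tags) >= 2:
                train = frame.restrict(tags[0])
                test = frame.restrict(tags[1])
            else:
                train = test = None
            worse = cohort.schema
            for feat in config.classifier_features:
                direction = "<" if worse.worse_of(feat) == "down" else ">"
                try:
                    clf = search_univariate(feat, train or frame, direction)
                    if train is not None:
                        cross_cohort_validate(clf, train, test)
                    classifiers.append(clf)
                except (ConfigurationError, UndefinedStatistic) as exc:
                    logger.warning("classifier search on %r skipped: %s",
                                   feat, exc)
            up_feats = [f for f in config.classifier_features
                        if worse.worse_of(f) == "up"]
            if len(up_feats) >= 2:
                try:
                    clf = search_conjunction(up_feats[0], up_feats[1],
                                             train or frame)
                    if train is not None:
                        cross_cohort_validate(clf, train, test)
                    classifiers.append(clf)
                except (ConfigurationError, UndefinedStatistic) as exc:
                    logger.warning("conjunction search skipped: %s", exc)
            if classifiers:
                metrics_frame(classifiers).to_csv(out / "classifiers.csv",
                                                  index=False)
            manifest["stages"]["classifiers"] = {
                "n_classifiers": len(classifiers),
                "features": list(config.classifier_features),
                "positive_cluster": rapid_label,
            }

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return {
            "cohort": cohort,
            "truth": truth,
            "layers": (layer1, layer2),
            "ests": (est1, est2),
            "trace": trace,
            "clustering": clustering,
            "decliner_names": decliner_names,
            "reports": reports,
            "classifiers": classifiers,
            "network": network,
            "manifest": manifest,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, MlclustError):
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        raise
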