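"""End-to-end orchestration: simulate -> represent -> search scheme ->
classify -> evaluate, with reproducible sub-seeds and on-disk artifacts.

A run directory collects everything a stage produces: the simulated series
(CSV), the five representation datasets, the discretization scheme (JSON),
the scheme-search log, pooled confusion matrices, and a metrics JSON laid out
as method x representation.  Re-running with the same config reproduces every
artifact bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import synthetic
from .classifiers import C45Classifier, KNNClassifier, NaiveBayesClassifier
from .datasets import BINARY_ORDER, MULTICLASS_ORDER, series_to_dataset, write_series_csv
from .evaluation import cross_validate, percent_round
from .representations import (
    DiscretizationScheme,
    build_representations,
    calibrate_scheme,
    standardize_dataset,
    uniform_boundaries,
)
from .scheme_search import EPConfig, evolve_scheme

log = logging.getLogger("acetowhite")

REPRESENTATIONS = ("standardized", "adjusted", "parameters", "pla", "psa")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_baseline: int = 10
    n_post: int = 180
    knn_k: int = 1
    c45_min_leaf: int = 2
    c45_prune: bool = False
    cv_folds: int = 10
    # fixed-scheme defaults used when the evolutionary search is disabled
    default_segments: int = 12
    default_alphabet: int = 5
    optimize_scheme: bool = True
    ep: EPConfig = field(default_factory=lambda: EPConfig(population_size=10, generations=15))
    multiclass: bool = True

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["ep"]["alphabet_range"] = list(d["ep"]["alphabet_range"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        ep = d.pop("ep", None)
        cfg = cls(**d)
        if ep is not None:
            ep["alphabet_range"] = tuple(ep["alphabet_range"])
            cfg.ep = EPConfig(**ep)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def subseed(self, stage: str) -> int:
        """Stable per-stage sub-seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _classifier_factories(config: PipelineConfig) -> dict:
    return {
        "knn": lambda: KNNClassifier(k=config.knn_k),
        "nb": lambda: NaiveBayesClassifier(),
        "c45": lambda: C45Classifier(min_leaf=config.c45_min_leaf, prune=config.c45_prune),
    }


def _report_to_dict(cv) -> dict:
    rep = cv.report
    out = {
        "accuracy": rep.accuracy,
        "correctly_classified_pct": percent_round(rep.accuracy),
        "weighted": {k: round(v, 6) for k, v in sorted(rep.weighted.items())},
        "per_class": {
            str(c): {k: round(v, 6) for k, v in sorted(rep.per_class[c].items())}
            for c in rep.class_list
        },
        "confusion": cv.confusion.counts.tolist(),
        "class_list": [str(c) for c in rep.class_list],
        "undefined_metrics": rep.undefined,
    }
    if rep.extras:
        out["extras"] = {
            k: ([round(float(x), 6) for x in v] if isinstance(v, tuple) else round(float(v), 6))
            for k, v in sorted(rep.extras.items())
            if not k.endswith(("tp", "fn", "fp", "tn"))
        }
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every enabled stage in order; return and write the metrics tree."""
    os.makedirs(outdir, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        fh.write(config.to_yaml())

    # --- simulate -----------------------------------------------------------
    gen_cfg = synthetic.GeneratorConfig(
        n_baseline=config.n_baseline, n_post=config.n_post, seed=config.subseed("simulate")
    )
    series = synthetic.generate_series(gen_cfg)
    write_series_csv(series, os.path.join(outdir, "series.csv"))
    raw = series_to_dataset(series)
    log.info("simulated %d series (seed %d)", len(series), gen_cfg.seed)

    # --- discretization scheme ---------------------------------------------
    std = standardize_dataset(raw, config.n_baseline)
    if config.optimize_scheme:
        ep = dataclasses.replace(config.ep, seed=config.subseed("scheme"))
        best, ep_log = evolve_scheme(std.binarized(), KNNClassifier, ep)
        scheme = calibrate_scheme(std.features, best.scheme.boundaries, best.alphabet_size)
        ep_log.to_csv(os.path.join(outdir, "ep_log.csv"))
        log.info(
            "evolved scheme: %d segments, alphabet %d, fitness %.3f",
            scheme.n_segments,
            scheme.alphabet_size,
            best.fitness,
        )
    else:
        scheme = calibrate_scheme(
            std.features,
            uniform_boundaries(config.n_post, config.default_segments),
            config.default_alphabet,
        )
    with open(os.path.join(outdir, "scheme.json"), "w") as fh:
        fh.write(scheme.to_json())

    # --- representations ----------------------------------------------------
    reps = build_representations(raw, config.n_baseline, scheme)
    for tag, ds in reps.items():
        np.savetxt(
            os.path.join(outdir, f"representation_{tag}.csv"),
            ds.features,
            delimiter=",",
            fmt="%.10g",
        )

    # --- classification + evaluation ---------------------------------------
    factories = _classifier_factories(config)
    cv_seed = config.subseed("cv")
    results: dict = {"stamp": stamp, "binary": {}, "multiclass": {}}
    for method, factory in factories.items():
        results["binary"][method] = {}
        for tag in REPRESENTATIONS:
            cv = cross_validate(
                reps[tag].binarized(),
                factory,
                k=config.cv_folds,
                seed=cv_seed,
                class_list=list(BINARY_ORDER),
            )
            results["binary"][method][tag] = _report_to_dict(cv)
            log.info(
                "binary %s/%s: accuracy %.3f", method, tag, cv.confusion.accuracy
            )
    if config.multiclass:
        cv = cross_validate(
            reps["pla"],
            factories["knn"],
            k=config.cv_folds,
            seed=cv_seed,
            class_list=list(MULTICLASS_ORDER),
        )
        results["multiclass"]["knn_pla"] = _report_to_dict(cv)
        log.info("multiclass knn/pla: accuracy %.3f", cv.confusion.accuracy)

    with open(os.path.join(outdir, "metrics.json"), "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results


def run_scheme(scheme_path) -> DiscretizationScheme:
    with open(scheme_path) as fh:
        return DiscretizationScheme.from_json(fh.read())
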