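"""End-to-end orchestration: simulate -> extract -> select -> classify/cluster.

One seeded :class:`RunConfig` drives the whole analysis; every stage
writes its artifact under the output directory and the run report embeds
the resolved configuration for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as studyio
from .classify import cluster_enrichment, cv_svm, hierarchical_cluster, zscore_table
from .features import FEATURE_NAMES, ExtractionParams, extract_study
from .phantom import PHENOTYPES, generate_study, phenotype_config
from .selection import RankingConfig, compute_rankings, select_signature

log = logging.getLogger("ceus_radiomics")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "ceus_run"
    seed: int = 0
    n_per_class: tuple[int, int, int] = (5, 5, 4)
    phantom_overrides: dict = field(default_factory=dict)  # phenotype -> param dict
    n_levels: int = 32
    beam_width: float = 1.0
    r_max: float = 0.75
    folds: int = 4
    svm_c: float = 1.0
    n_clusters: int = 3
    stages: tuple[str, ...] = ("simulate", "extract", "select", "classify", "cluster")
    write_study: bool = False
    progress: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.n_per_class = tuple(cfg.n_per_class)
        cfg.stages = tuple(cfg.stages)
        return cfg


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}
    configs = {p: phenotype_config(p, **config.phantom_overrides.get(p, {}))
               for p in PHENOTYPES}

    study = None
    features = None
    if "simulate" in config.stages:
        log.info("simulating study (seed=%d)", config.seed)
        study = generate_study(config.n_per_class, configs, seed=config.seed)
        report["n_scans_dataset1"] = len(study.dataset(1))
        report["n_scans_dataset2"] = len(study.dataset(2))
        study.manifest().to_csv(out / "manifest.csv", index=False)
        if config.write_study:
            studyio.write_study(study, out / "scans")

    if "extract" in config.stages:
        if study is None:
            raise RuntimeError("extract stage requires the simulate stage")
        log.info("extracting features")
        params = ExtractionParams(beam_width=config.beam_width)
        features = extract_study(study, params, progress=config.progress)
        features.to_csv(out / "features.csv", index=False)
        report["n_features"] = len(FEATURE_NAMES)
        report["n_rows"] = len(features)

    signature = None
    ranking = None
    if "select" in config.stages:
        if features is None:
            raise RuntimeError("select stage requires the extract stage")
        log.info("selecting signature")
        rcfg = RankingConfig(r_max=config.r_max)
        ranking = compute_rankings(features, rcfg)
        ranking.to_csv(out / "ranking.csv")
        signature = select_signature(ranking, features, rcfg)
        sig_payload = dict(features=signature.features,
                           correlation=signature.correlation.to_dict())
        (out / "signature.json").write_text(json.dumps(sig_payload, indent=1,
                                                       default=_jsonable))
        report["signature"] = signature.features

    if "classify" in config.stages:
        if signature is None:
            raise RuntimeError("classify stage requires the select stage")
        log.info("classifying (linear SVM, %d-fold CV)", config.folds)
        d1 = features[(features["dataset"] == 1) & (features["user_id"] == "user1")]
        x = zscore_table(d1[signature.names])
        res = cv_svm(x, d1["model_label"].to_numpy(), k=config.folds,
                     seed=config.seed, C=config.svm_c)
        payload = dict(confusion_matrix=res.confusion_matrix.to_dict(),
                       accuracy=res.accuracy, wilson_ci=list(res.wilson_ci))
        (out / "classification.json").write_text(json.dumps(payload, indent=1,
                                                            default=_jsonable))
        report["accuracy"] = res.accuracy
        report["wilson_ci"] = list(res.wilson_ci)
        report["confusion_matrix"] = res.confusion_matrix.to_dict()

    if "cluster" in config.stages:
        if features is None:
            raise RuntimeError("cluster stage requires the extract stage")
        log.info("clustering (Euclidean, average linkage)")
        d1 = features[(features["dataset"] == 1) & (features["user_id"] == "user1")]
        x = zscore_table(d1[FEATURE_NAMES])
        clu = hierarchical_cluster(x, n_clusters=config.n_clusters)
        enr = cluster_enrichment(clu.cluster_labels, d1["model_label"].to_numpy())
        pd.DataFrame({"scan_id": d1["scan_id"].to_numpy(),
                      "cluster": clu.cluster_labels}).to_csv(
            out / "clusters.csv", index=False)
        enr.enrichment.to_csv(out / "cluster_enrichment.csv", index=False)
        report["cluster_sizes"] = {int(c): int((clu.cluster_labels == c).sum())
                                   for c in np.unique(clu.cluster_labels)}
        report["cluster_multinomial_p"] = {int(k): float(v)
                                           for k, v in enr.cluster_p.items()}

    (out / "report.json").write_text(json.dumps(report, indent=1, default=_jsonable))
    return report
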