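"""Configuration-driven end-to-end runs with manifests.

A run config is a flat YAML mapping (paths, hyperparameters, one master
seed).  :func:`run_all` executes the stages in order — similarity,
embedding, PU selection, classifier training, optional cross-validation and
ranking — writing every artifact as delimited text plus a ``manifest.json``
recording the config hash, the seed and a content hash per artifact.  A
rerun with the same config reproduces bit-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .data_io import BipartiteAssociations, load_associations, read_matrix
from .dnn import DnnConfig
from .evaluate import CVConfig, rank_candidates, run_cv
from .gate import GateConfig
from .pipeline import MDAPipeline, PipelineConfig
from .pu import PUConfig
from .similarity import SimilarityMatrix

__all__ = ["RunConfig", "load_run_config", "run_all"]

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "edges": None,
    "functional_d": None,
    "functional_m": None,
    "out_dir": "mdalink_run",
    "seed": 0,
    "k_neighbors": 10,
    "embedding_dim": 64,
    "gate_epochs": 200,
    "gate_learning_rate": 1e-3,
    "lam": 1.0,
    "t_fraction": 0.15,
    "n_clusters": 5,
    "dnn_epochs": 300,
    "dnn_learning_rate": 1e-3,
    "dropout": 0.2,
    "batch_size": 32,
    "cv_schemes": [],
    "cv_repeats": 20,
    "cv_folds": 5,
    "rank_diseases": [],
    "rank_top_k": 30,
}


@dataclasses.dataclass
class RunConfig:
    values: dict

    def __getattr__(self, key):
        try:
            return self.values[key]
        except KeyError:
            raise AttributeError(key) from None

    def pipeline_config(self) -> PipelineConfig:
        v = self.values
        return PipelineConfig(
            k_neighbors=int(v["k_neighbors"]),
            gate=GateConfig(embedding_dim=int(v["embedding_dim"]),
                            epochs=int(v["gate_epochs"]),
                            learning_rate=float(v["gate_learning_rate"]),
                            lam=float(v["lam"])),
            pu=PUConfig(t_fraction=float(v["t_fraction"]),
                        n_clusters=int(v["n_clusters"])),
            dnn=DnnConfig(learning_rate=float(v["dnn_learning_rate"]),
                          dropout=float(v["dropout"]),
                          epochs=int(v["dnn_epochs"]),
                          batch_size=int(v["batch_size"])),
            seed=int(v["seed"]),
        )


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: run config must be a flat mapping")
    unknown = set(user) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    values = {**_DEFAULTS, **user}
    if not values["edges"]:
        raise ValueError("config must set 'edges' (association edge list)")
    if not Path(values["edges"]).exists():
        raise FileNotFoundError(f"edges file not found: {values['edges']}")
    for key in ("functional_d", "functional_m"):
        if values[key] and not Path(values[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {values[key]}")
    return RunConfig(values=values)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_functional(path, side: str) -> SimilarityMatrix | None:
    if not path:
        return None
    M = read_matrix(path, square=True)
    return SimilarityMatrix(list(M.index), M.to_numpy(dtype=float),
                            side, "functional")


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.perf_counter()

    def save(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        data_io.write_matrix(frame, path)
        artifacts[name] = _sha256(path)
        logger.info("stage artifact %s written (%.1fs elapsed)",
                    name, time.perf_counter() - t0)

    assoc = load_associations(config.edges)
    functional_d = _load_functional(config.functional_d, "disease")
    functional_m = _load_functional(config.functional_m, "microbe")

    pipe_cfg = config.pipeline_config()
    pipe = MDAPipeline(pipe_cfg).fit(assoc, functional_d, functional_m)

    save("similarity_disease.tsv",
         pd.DataFrame(pipe.fused_d_.S, index=assoc.disease_names,
                      columns=assoc.disease_names))
    save("similarity_microbe.tsv",
         pd.DataFrame(pipe.fused_m_.S, index=assoc.microbe_names,
                      columns=assoc.microbe_names))
    save("embeddings_disease.tsv",
         pd.DataFrame(pipe.emb_d_.H, index=assoc.disease_names))
    save("embeddings_microbe.tsv",
         pd.DataFrame(pipe.emb_m_.H, index=assoc.microbe_names))

    pu = pipe.pu_result_
    pu_frame = pd.DataFrame({
        "disease": [assoc.disease_names[i] for i in pipe.dataset_.pairs[:, 0]],
        "microbe": [assoc.microbe_names[j] for j in pipe.dataset_.pairs[:, 1]],
        "score": pu.scores,
        "is_spy": np.isin(np.arange(len(pu.scores)), pu.spies),
        "is_reliable_negative": np.isin(np.arange(len(pu.scores)),
                                        pu.reliable_negatives),
    })
    save("pu_scores.tsv", pu_frame.set_index("disease"))
    (out / "pu_a_min.txt").write_text(f"{pu.a_min!r}\n")
    artifacts["pu_a_min.txt"] = _sha256(out / "pu_a_min.txt")

    for k, W in enumerate(pipe.model_.weights):
        save(f"dnn_W{k}.tsv", pd.DataFrame(W))
        save(f"dnn_b{k}.tsv", pd.DataFrame(pipe.model_.biases[k]))
    save("predictions.tsv", pipe.score_matrix_)

    cv_results = {}
    for scheme in config.cv_schemes:
        cv = CVConfig(scheme=scheme, n_folds=int(config.cv_folds),
                      repeats=int(config.cv_repeats), seed=int(config.seed))
        result = run_cv(assoc, pipe_cfg, cv, functional_d, functional_m)
        save(f"cv_{scheme}.tsv", result.summary().set_index("repeat"))
        cv_results[scheme] = {"mean_auc": result.mean_auc,
                              "mean_aupr": result.mean_aupr}

    for disease in config.rank_diseases:
        table = rank_candidates(pipe, disease, int(config.rank_top_k))
        slug = "".join(c if c.isalnum() else "_" for c in disease)
        save(f"rank_{slug}.tsv", table.set_index("rank"))

    config_hash = hashlib.sha256(
        json.dumps(config.values, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config": config.values,
        "config_hash": config_hash,
        "seed": int(config.seed),
        "stages": ["similarity", "embed", "pu", "train", "evaluate", "rank"],
        "artifacts": dict(sorted(artifacts.items())),
        "cv": cv_results,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run complete in %.1fs; %d artifacts",
                time.perf_counter() - t0, len(artifacts))
    return manifest
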