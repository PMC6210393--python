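"""End-to-end orchestration of the biomarker-discovery pipeline.

Stages: z-score normalization -> per-layer pooled t statistics -> top-N gene
sets and network reconstruction -> repeated adversarial weight learning +
weighted PageRank with stability selection -> feature-source assignment ->
cross-validated MLP prognosis AUC.

Two evaluation protocols are provided.  ``selection_mode="global"`` selects
biomarkers once on the full cohort and then cross-validates only the
classifier (the historical protocol; its selection step sees the test
labels, so its AUC is optimistic).  ``selection_mode="nested"`` reruns the
entire selection chain inside each training fold, giving an unbiased
estimate; permutation-null checks use this mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .errors import DataError
from .netbuild import (
    GeneSetQuartet,
    ReconstructedNetwork,
    build_quartet,
    build_real_vectors,
    layer_t_stats,
    reconstruct_network,
)
from .omics import POOR, OmicsLayer, drop_missing_genes, zscore_normalize
from .pagerank import RankResult, rank_biomarkers
from .prognosis import (
    FeatureTable,
    _make_mlp,
    assemble_dataset,
    assign_feature_source,
    crossval_auc,
)

log = logging.getLogger("omnirank")


@dataclass
class NetworkStage:
    layers: list[OmicsLayer]  # normalized
    tstats: dict[str, pd.DataFrame]
    quartet: GeneSetQuartet
    network: ReconstructedNetwork
    real: np.ndarray
    source: dict[str, str]


@dataclass
class PipelineResult:
    stage: NetworkStage
    rank: RankResult
    assignment: object
    table: FeatureTable
    metrics: dict


def normalize_layers(raw_layers: list[OmicsLayer], cfg: PipelineConfig) -> list[OmicsLayer]:
    return [
        zscore_normalize(
            drop_missing_genes(layer, cfg.network.missing_policy),
            axis=cfg.network.normalize_axis,
            ddof=cfg.network.zscore_ddof,
        )
        for layer in raw_layers
    ]


def build_network_stage(
    norm_layers: list[OmicsLayer],
    labels: np.ndarray,
    edges: list[tuple[str, str]],
    top_n: int,
) -> NetworkStage:
    """t statistics, top-N quartet, reconstruction and real-vector assembly."""
    tstats = layer_t_stats(norm_layers, labels)
    quartet = build_quartet(tstats, top_n)
    network = reconstruct_network(edges, quartet.union)
    real, source = build_real_vectors(norm_layers, tstats, network)
    log.info(
        "network stage: |U|=%d, %d nodes, %d edges",
        len(quartet.union),
        network.n,
        len(network.edges),
    )
    return NetworkStage(norm_layers, tstats, quartet, network, real, source)


def layer_gene_sets(layers: list[OmicsLayer]) -> dict[str, set[str]]:
    return {layer.layer_tag: set(layer.gene_ids) for layer in layers}


def run_pipeline(
    raw_layers: list[OmicsLayer],
    labels: np.ndarray,
    edges: list[tuple[str, str]],
    cfg: PipelineConfig,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Full discovery + evaluation run under the configured protocol."""
    seed = cfg.seed if seed is None else seed
    labels = np.asarray(labels, dtype=object).astype(str)
    norm = normalize_layers(raw_layers, cfg)
    stage = build_network_stage(norm, labels, edges, cfg.network.top_n)
    rank = rank_biomarkers(stage.real, stage.network, cfg.gan, cfg.rank, seed=seed)
    if not rank.selected:
        raise DataError("stability selection returned no biomarkers; lower min_count")
    assignment = assign_feature_source(
        rank.selected, stage.quartet, stage.network, stage.tstats, layer_gene_sets(norm)
    )
    table = assemble_dataset(assignment, norm, labels)
    if cfg.predict.selection_mode == "nested":
        metrics = nested_cv_auc(norm, labels, edges, cfg, seed=seed)
    else:
        metrics = crossval_auc(table, cfg.predict, seed=seed)
    return PipelineResult(stage=stage, rank=rank, assignment=assignment, table=table, metrics=metrics)


def _subset_samples(layer: OmicsLayer, idx: np.ndarray) -> OmicsLayer:
    return replace(
        layer,
        matrix=layer.matrix[:, idx],
        sample_ids=[layer.sample_ids[i] for i in idx],
    )


def nested_cv_auc(
    norm_layers: list[OmicsLayer],
    labels: np.ndarray,
    edges: list[tuple[str, str]],
    cfg: PipelineConfig,
    seed: int = 0,
) -> dict:
    """Cross-validation with the selection chain refit inside each fold.

    Per training fold: t statistics, top-N quartet, network reconstruction,
    repeated adversarial weight learning, PageRank stability selection and
    feature assignment are all recomputed from training samples only; the
    classifier is then scored on the held-out fold.  Normalization is
    label-free and shared.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    y = (labels == POOR).astype(int)
    n_folds = min(cfg.predict.n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise DataError("a class is too small for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_aucs = []
    pooled = np.zeros(len(y))
    for k, (tr, te) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        train_layers = [_subset_samples(l, tr) for l in norm_layers]
        stage = build_network_stage(train_layers, labels[tr], edges, cfg.network.top_n)
        rank = rank_biomarkers(stage.real, stage.network, cfg.gan, cfg.rank, seed=seed * 1000 + k)
        selected = rank.selected
        if not selected:
            # degenerate fold: fall back to the union of per-run lists
            selected = set().union(*rank.per_run_top)
        assignment = assign_feature_source(
            selected, stage.quartet, stage.network, stage.tstats, layer_gene_sets(norm_layers)
        )
        cols_train = assemble_dataset(assignment, train_layers, labels[tr])
        test_layers = [_subset_samples(l, te) for l in norm_layers]
        cols_test = assemble_dataset(assignment, test_layers, labels[te])
        clf = _make_mlp(cfg.predict, seed + k)
        clf.fit(cols_train.x.to_numpy(), cols_train.y)
        scores = clf.predict_proba(cols_test.x.to_numpy())[:, 1]
        pooled[te] = scores
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(float(roc_auc_score(y[te], scores)))
    return {
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)),
        "pooled_auc": float(roc_auc_score(y, pooled)),
        "n_folds": n_folds,
        "note": "nested selection",
    }


def recovery_stats(selected: set[str], truth: dict[str, str]) -> dict:
    """Planted-gene recovery and contamination of a selected biomarker set."""
    planted = set(truth)
    hit = selected & planted
    return {
        "recovery": len(hit) / len(planted) if planted else float("nan"),
        "contamination": (len(selected - planted) / len(selected)) if selected else float("nan"),
        "n_selected": len(selected),
        "n_planted": len(planted),
    }
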