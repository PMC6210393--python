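"""Feature-source assignment and cross-validated prognosis prediction.

Each stability-selected biomarker gene is mapped back to the omics layer(s)
that drove its selection:

* a gene inside one or more of the top-|t| sets M/C/T/S contributes one
  feature per set it belongs to (a gene in both M and C yields both its
  mRNA and its CNV profile);
* a gene in none of the sets (a retained network neighbor) takes the layer
  that wins a membership vote over its network neighbors — count how often
  neighbors belong to M, C, T and S and use the layer with the largest
  count (ties: fixed layer priority mRNA > CNV > methylation > SNP);
* a neighbor-vote gene whose neighbors hold no memberships at all falls
  back to its own max-|t| layer and is flagged in the provenance.

The assembled samples x features table (columns named ``gene@layer``) feeds
a multi-layer perceptron (relu activation, L2 penalty) evaluated by
stratified k-fold cross-validation with ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import DataError
from .netbuild import GeneSetQuartet, ReconstructedNetwork
from .omics import LAYER_TAGS, POOR, OmicsLayer


class EvalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_folds: int = 10
    hidden_units: int = 64
    alpha: float = 1e-3  # L2 penalty
    max_iter: int = 500
    solver: str = "lbfgs"
    selection_mode: str = "global"  # or "nested" (reselect inside each fold)

    @model_validator(mode="after")
    def _check(self) -> "EvalConfig":
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.selection_mode not in ("global", "nested"):
            raise ValueError("selection_mode must be 'global' or 'nested'")
        return self


@dataclass
class FeatureAssignment:
    """gene -> assigned layers, with provenance and neighbor-vote tallies."""

    layers: dict[str, list[str]]
    provenance: dict[str, str]  # direct-membership | neighbor-vote | fallback-tstat
    votes: dict[str, dict[str, int]]

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.layers)
        return pd.DataFrame(
            {
                "gene": genes,
                "layers": [",".join(self.layers[g]) for g in genes],
                "provenance": [self.provenance[g] for g in genes],
                "votes": [
                    ";".join(f"{t}={c}" for t, c in sorted(self.votes.get(g, {}).items()))
                    for g in genes
                ],
            }
        )


def assign_feature_source(
    biomarkers: set[str],
    quartet: GeneSetQuartet,
    network: ReconstructedNetwork,
    tstat_tables: dict[str, pd.DataFrame] | None = None,
    layer_genes: dict[str, set[str]] | None = None,
) -> FeatureAssignment:
    """Decide which omics layer(s) provide each biomarker's feature values.

    ``layer_genes`` (layer tag -> genes present) restricts votes and
    fallbacks to layers that actually measure the gene; when omitted every
    layer of the quartet is assumed complete.
    """
    node_set = set(network.nodes)
    missing = set(biomarkers) - node_set
    if missing:
        raise DataError(f"biomarkers absent from the network: {sorted(missing)[:5]}")

    def has_gene(tag: str, gene: str) -> bool:
        return layer_genes is None or gene in layer_genes.get(tag, set())

    layers: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    votes: dict[str, dict[str, int]] = {}
    for gene in sorted(biomarkers):
        member_of = quartet.memberships(gene)
        if member_of:
            layers[gene] = member_of
            provenance[gene] = "direct-membership"
            continue
        tally = {
            tag: sum(1 for nbr in network.neighbors(gene) if nbr in quartet.sets.get(tag, ()))
            for tag in LAYER_TAGS
            if tag in quartet.sets and has_gene(tag, gene)
        }
        votes[gene] = tally
        best = max(tally.values(), default=0)
        if best > 0:
            # ties resolved by LAYER_TAGS priority order
            winner = next(t for t in LAYER_TAGS if tally.get(t, 0) == best)
            layers[gene] = [winner]
            provenance[gene] = "neighbor-vote"
        else:
            if tstat_tables is None:
                raise DataError(
                    f"gene {gene!r} has no set membership and no member neighbors; "
                    "t-statistics required for fallback assignment"
                )
            candidates = [
                (tag, float(tbl["abs_t"].get(gene, np.nan)))
                for tag, tbl in tstat_tables.items()
                if has_gene(tag, gene)
            ]
            candidates = [(t, a) for t, a in candidates if np.isfinite(a)]
            if not candidates:
                raise DataError(f"gene {gene!r} has no usable layer for fallback assignment")
            winner = max(candidates, key=lambda ta: (ta[1], -LAYER_TAGS.index(ta[0])))[0]
            layers[gene] = [winner]
            provenance[gene] = "fallback-tstat"
    return FeatureAssignment(layers=layers, provenance=provenance, votes=votes)


@dataclass
class FeatureTable:
    """samples x features design matrix plus aligned binary labels."""

    x: pd.DataFrame
    y: np.ndarray  # 1 = poor prognosis

    def __post_init__(self) -> None:
        if len(self.y) != len(self.x):
            raise DataError("labels length does not match feature table")


def assemble_dataset(
    assignment: FeatureAssignment,
    layers: list[OmicsLayer],
    labels: np.ndarray,
) -> FeatureTable:
    """Build the samples x features table from the normalized layers.

    One column per assigned gene@layer pair; raises on unresolvable pairs.
    """
    by_tag = {layer.layer_tag: layer for layer in layers}
    sample_ids = layers[0].sample_ids
    columns: dict[str, np.ndarray] = {}
    offenders = []
    for gene in sorted(assignment.layers):
        for tag in assignment.layers[gene]:
            layer = by_tag.get(tag)
            if layer is None or gene not in layer.gene_index():
                offenders.append(f"{gene}@{tag}")
                continue
            columns[f"{gene}@{tag}"] = layer.matrix[layer.gene_index()[gene], :]
    if offenders:
        raise DataError(f"unresolvable gene@layer features: {offenders}")
    x = pd.DataFrame(columns, index=sample_ids)
    y = (np.asarray(labels, dtype=object).astype(str) == POOR).astype(int)
    return FeatureTable(x=x, y=y)


def _make_mlp(cfg: EvalConfig, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation="relu",
        alpha=cfg.alpha,
        solver=cfg.solver,
        max_iter=cfg.max_iter,
        random_state=seed,
    )


def crossval_auc(table: FeatureTable, cfg: EvalConfig, seed: int = 0) -> dict:
    """Stratified k-fold ROC-AUC of an MLP on a fixed feature table.

    Folds are stratified and seeded; the fold count is reduced (with a
    warning in the returned dict) if a class has fewer members than folds.
    Returns per-fold AUCs, their mean (the headline number) and the pooled
    AUC over all held-out predictions.
    """
    x = table.x.to_numpy(dtype=float)
    y = np.asarray(table.y)
    if len(np.unique(y)) < 2:
        raise DataError("both prognosis classes must be present")
    n_folds = min(cfg.n_folds, int(np.bincount(y).min()))
    note = None
    if n_folds < cfg.n_folds:
        note = f"folds reduced from {cfg.n_folds} to {n_folds} (small class)"
    if n_folds < 2:
        raise DataError("a class is too small for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_aucs = []
    pooled_scores = np.zeros(len(y))
    for k, (tr, te) in enumerate(skf.split(x, y)):
        clf = _make_mlp(cfg, seed + k)
        clf.fit(x[tr], y[tr])
        scores = clf.predict_proba(x[te])[:, 1]
        pooled_scores[te] = scores
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(float(roc_auc_score(y[te], scores)))
    return {
        "fold_aucs": fold_aucs,
        "mean_auc": float(np.mean(fold_aucs)),
        "pooled_auc": float(roc_auc_score(y, pooled_scores)),
        "n_folds": n_folds,
        "note": note,
    }
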