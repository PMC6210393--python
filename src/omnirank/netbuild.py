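"""Differential statistics and interaction-network reconstruction.

For every omics layer, each gene gets an equal-variance two-sample pooled
t statistic contrasting poor vs good prognosis samples,

    t_i = (x̄_{i,poor} − x̄_{i,good}) / (s_i · sqrt(1/n_p + 1/n_g)),

with s_i the pooled standard deviation

    s_i² = [(n_p − 1)·S²_{i,poor} + (n_g − 1)·S²_{i,good}] / (n_p + n_g − 2).

The top-N genes by |t| per layer form the sets M (mRNA), C (CNV),
T (methylation) and S (SNP); their union U drives reconstruction: an
interaction edge is retained iff at least one endpoint lies in U, and the
reconstructed node set is every gene incident to a retained edge (so non-U
neighbors of U genes remain, which the feature-assignment stage relies on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, EmptyNetworkError
from .omics import GOOD, LAYER_TAGS, POOR, OmicsLayer


def pooled_t_stat(layer: OmicsLayer, labels: np.ndarray) -> pd.DataFrame:
    """Per-gene pooled two-sample t statistics (poor mean minus good mean).

    Returns a DataFrame indexed by gene with columns ``t``, ``abs_t``,
    ``mean_poor``, ``mean_good``, ``s_pooled``, ``n_poor``, ``n_good``.
    Genes with zero pooled variance get ``t = NaN`` and are excluded from
    any |t| ranking downstream.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    if len(labels) != layer.n_samples:
        raise DataError("labels length does not match number of samples")
    poor = labels == POOR
    good = labels == GOOD
    n_p, n_g = int(poor.sum()), int(good.sum())
    if n_p < 2 or n_g < 2:
        raise DataError(f"each group needs >= 2 samples (got poor={n_p}, good={n_g})")
    xp = layer.matrix[:, poor]
    xg = layer.matrix[:, good]
    mean_p = xp.mean(axis=1)
    mean_g = xg.mean(axis=1)
    var_p = xp.var(axis=1, ddof=1)
    var_g = xg.var(axis=1, ddof=1)
    s = np.sqrt(((n_p - 1) * var_p + (n_g - 1) * var_g) / (n_p + n_g - 2))
    denom = s * np.sqrt(1.0 / n_p + 1.0 / n_g)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_p - mean_g) / denom
    t[s == 0] = np.nan
    return pd.DataFrame(
        {
            "t": t,
            "abs_t": np.abs(t),
            "mean_poor": mean_p,
            "mean_good": mean_g,
            "s_pooled": s,
            "n_poor": n_p,
            "n_good": n_g,
        },
        index=pd.Index(layer.gene_ids, name="gene"),
    )


def layer_t_stats(layers: list[OmicsLayer], labels: np.ndarray) -> dict[str, pd.DataFrame]:
    """t-statistic tables for every layer, keyed by layer tag."""
    return {layer.layer_tag: pooled_t_stat(layer, labels) for layer in layers}


def select_top_genes(tstats: pd.DataFrame, n: int) -> list[str]:
    """Top-``n`` genes by |t|, ties broken by gene id (stable, deterministic).

    Genes with undefined t (zero pooled variance) never enter the ranking.
    If the layer holds fewer than ``n`` rankable genes, all are returned.
    """
    if n < 1:
        raise DataError("top-N cutoff must be >= 1")
    ranked = (
        tstats.dropna(subset=["t"])
        .sort_index()  # secondary key: gene id ascending
        .sort_values("abs_t", ascending=False, kind="stable")
    )
    return ranked.index[:n].tolist()


@dataclass
class GeneSetQuartet:
    """Top-N gene sets per layer (M/C/T/S) and their union U."""

    sets: dict[str, set[str]]  # layer tag -> gene set
    n: int

    def __post_init__(self) -> None:
        unknown = set(self.sets) - set(LAYER_TAGS)
        if unknown:
            raise DataError(f"unknown layer tags in quartet: {sorted(unknown)}")

    @property
    def union(self) -> set[str]:
        u: set[str] = set()
        for s in self.sets.values():
            u |= s
        return u

    def memberships(self, gene: str) -> list[str]:
        """Layer tags whose top-N set contains ``gene`` (priority order)."""
        return [tag for tag in LAYER_TAGS if gene in self.sets.get(tag, ())]

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.union)
        cols = {f"in_{tag}": [g in self.sets.get(tag, ()) for g in genes] for tag in LAYER_TAGS}
        return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def build_quartet(tstat_tables: dict[str, pd.DataFrame], n: int) -> GeneSetQuartet:
    return GeneSetQuartet(
        sets={tag: set(select_top_genes(tbl, n)) for tag, tbl in tstat_tables.items()},
        n=n,
    )


@dataclass
class ReconstructedNetwork:
    """The reconstructed interaction network and its 0/1 adjacency."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    adjacency: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def neighbors(self, gene: str) -> list[str]:
        idx = self.node_index()[gene]
        return [self.nodes[j] for j in np.flatnonzero(self.adjacency[idx])]

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["gene_a", "gene_b"])


def reconstruct_network(
    edges: list[tuple[str, str]], union: set[str]
) -> ReconstructedNetwork:
    """Keep every interaction edge with at least one endpoint in U.

    Nodes are the genes incident to a retained edge, sorted for determinism;
    the adjacency is symmetric 0/1 with a zero diagonal.  Raises
    :class:`EmptyNetworkError` if nothing survives.
    """
    if not union:
        raise DataError("the union gene set U is empty")
    retained = []
    seen = set()
    for a, b in edges:
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            continue
        if a in union or b in union:
            seen.add(key)
            retained.append(key)
    if not retained:
        raise EmptyNetworkError("no interaction edge touches the selected gene union")
    nodes = sorted({g for e in retained for g in e})
    index = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
    for a, b in retained:
        adj[index[a], index[b]] = 1
        adj[index[b], index[a]] = 1
    return ReconstructedNetwork(nodes=nodes, edges=retained, adjacency=adj)


def build_real_vectors(
    layers: list[OmicsLayer],
    tstat_tables: dict[str, pd.DataFrame],
    network: ReconstructedNetwork,
) -> tuple[np.ndarray, dict[str, str]]:
    """Assemble the samples x n "real" data matrix for adversarial training.

    For each network gene the value row is copied from the layer where the
    gene's |t| is largest among the layers containing it (ties: fixed layer
    priority).  Returns the matrix (rows ordered like the layers' shared
    sample ordering, columns like ``network.nodes``) and the gene -> source
    layer map.
    """
    by_tag = {layer.layer_tag: layer for layer in layers}
    sample_ids = layers[0].sample_ids
    for layer in layers[1:]:
        if layer.sample_ids != sample_ids:
            raise DataError("all layers must share an identical sample ordering")
    gene_rows = {tag: layer.gene_index() for tag, layer in by_tag.items()}
    x = np.zeros((len(sample_ids), network.n))
    source: dict[str, str] = {}
    for j, gene in enumerate(network.nodes):
        best_tag, best_abs = None, -np.inf
        for tag in LAYER_TAGS:
            if tag not in by_tag or gene not in gene_rows[tag]:
                continue
            val = tstat_tables[tag]["abs_t"].get(gene, np.nan)
            a = -1.0 if not np.isfinite(val) else float(val)
            if a > best_abs:
                best_tag, best_abs = tag, a
        if best_tag is None:
            raise DataError(f"network gene {gene!r} is absent from every layer")
        source[gene] = best_tag
        x[:, j] = by_tag[best_tag].matrix[gene_rows[best_tag][gene], :]
    return x, source
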