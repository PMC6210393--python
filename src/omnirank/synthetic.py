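"""Synthetic multi-omics cohorts with a known interaction network and planted
prognostic genes.

The generator emulates the statistical structure a network-propagation
biomarker method consumes, not the biology of any particular platform:

* a scale-free-ish gene interaction graph built by preferential attachment,
  so hub dominance of PageRank-style scoring is exercisable;
* one to four omics layers of Gaussian measurements (sd ``noise_sd``);
* a planted set of prognosis-associated genes, each carrying a standardized
  mean shift of ``effect_size`` between good- and poor-prognosis samples in
  exactly one designated layer.

By default the planted genes form a connected module (a breadth-first ball
around a random node): network-based prioritization presupposes that disease
genes cluster in the interaction network, and a scattered planting would test
a premise the method does not make.  Set ``planted_module=False`` for a
uniform-random planting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import networkx as nx
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigError, DataError
from .omics import GOOD, LAYER_TAGS, POOR, OmicsLayer


class SimConfig(BaseModel):
    """Parameters of one synthetic cohort.

    Defaults describe the reference study condition used throughout the test
    suite: a pancreatic-cohort-sized design (20 good / 20 poor samples), two
    omics layers, and a 25-gene planted module with a standardized effect of
    2 in a 300-gene preferential-attachment network.
    """

    model_config = ConfigDict(extra="forbid")

    n_genes: int = 300
    n_samples_good: int = 20
    n_samples_poor: int = 20
    n_layers: int = 2
    planted_genes: int = 25
    effect_size: float = 2.0
    attachment: int = 2  # preferential-attachment edges per new node
    noise_sd: float = 1.0
    planted_module: bool = True
    deceased_policy: Literal["exclude", "poor_if_short"] = "exclude"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for name in ("n_genes", "n_samples_good", "n_samples_poor", "n_layers", "planted_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 1 <= self.n_layers <= 4:
            raise ValueError("n_layers must be in 1..4")
        if self.planted_genes > self.n_genes:
            raise ValueError("planted_genes must not exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 1 <= self.attachment < self.n_genes:
            raise ValueError("attachment must be in [1, n_genes)")
        return self


@dataclass
class SyntheticCohort:
    """A generated cohort: omics layers, network, labels and ground truth."""

    layers: list[OmicsLayer]
    edges: list[tuple[str, str]]
    labels: np.ndarray  # per-sample "good"/"poor", aligned with layer columns
    truth: dict[str, str]  # planted gene -> signal-carrying layer tag
    config: SimConfig

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.layers[0].gene_ids

    def write(self, outdir) -> None:
        """Write per-layer TSVs, edge list, clinical table and truth JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for layer in self.layers:
            layer.to_tsv(out / f"{layer.layer_tag}.tsv")
        pd.DataFrame(self.edges).to_csv(
            out / "network.tsv", sep="\t", header=False, index=False
        )
        pd.DataFrame({"sample_id": self.sample_ids, "label": self.labels}).to_csv(
            out / "clinical.tsv", sep="\t", index=False
        )
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "planted": self.truth,
                    "effect_size": self.config.effect_size,
                    "seed": self.config.seed,
                },
                indent=2,
            )
        )


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(cfg: SimConfig) -> list[tuple[str, str]]:
    """Build a connected, simple, undirected scale-free-ish gene graph.

    Uses preferential attachment (Barabási–Albert, star-seeded): each of the
    n − m − 1 later nodes attaches with m = ``attachment`` edges to existing
    nodes with probability proportional to degree, giving a right-skewed
    degree distribution with pronounced hubs.  Edge count is therefore
    m + (n − m − 1)·m.
    """
    if cfg.n_genes < 2:
        raise ConfigError("need at least 2 genes to build a network")
    names = _gene_names(cfg.n_genes)
    if cfg.n_genes == 2:
        return [(names[0], names[1])]
    g = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment, seed=cfg.seed)
    edges = sorted((min(a, b), max(a, b)) for a, b in g.edges())
    return [(names[a], names[b]) for a, b in edges]


def _pick_planted(
    edges: list[tuple[str, str]], k: int, module: bool, rng: np.random.Generator
) -> list[str]:
    g = nx.Graph(edges)
    nodes = sorted(g.nodes())
    if not module:
        return sorted(rng.choice(nodes, size=k, replace=False).tolist())
    start = nodes[int(rng.integers(len(nodes)))]
    # deterministic BFS ball: visit neighbors in sorted order
    picked: list[str] = []
    seen = {start}
    queue = [start]
    while queue and len(picked) < k:
        node = queue.pop(0)
        picked.append(node)
        for nbr in sorted(g.neighbors(node)):
            if nbr not in seen:
                seen.add(nbr)
                queue.append(nbr)
    if len(picked) < k:
        raise DataError("network too small for requested planted module")
    return sorted(picked)


def generate_omics(cfg: SimConfig, edges: list[tuple[str, str]]) -> SyntheticCohort:
    """Draw the omics layers and plant the prognostic signal.

    Each layer is an i.i.d. Gaussian genes x samples matrix; every planted
    gene gets a mean shift of ``effect_size * noise_sd`` added to the poor
    group in exactly one layer (assigned round-robin so layers carry balanced
    signal).  Fully deterministic given ``cfg.seed``.
    """
    genes = _gene_names(cfg.n_genes)
    covered = {g for e in edges for g in e}
    if not covered.issuperset(genes):
        raise DataError("network does not cover all configured genes")
    n_good, n_poor = cfg.n_samples_good, cfg.n_samples_poor
    samples = [f"s{i:03d}" for i in range(1, n_good + n_poor + 1)]
    labels = np.array([GOOD] * n_good + [POOR] * n_poor, dtype=object).astype(str)

    root = np.random.SeedSequence(cfg.seed)
    ss_pick, ss_assign, *ss_layers = root.spawn(2 + cfg.n_layers)
    planted = _pick_planted(edges, cfg.planted_genes, cfg.planted_module, np.random.default_rng(ss_pick))

    tags = list(LAYER_TAGS[: cfg.n_layers])
    order = np.random.default_rng(ss_assign).permutation(len(planted))
    truth = {planted[j]: tags[i % len(tags)] for i, j in enumerate(order)}

    gene_index = {g: i for i, g in enumerate(genes)}
    poor_mask = labels == POOR
    layers = []
    for tag, ss in zip(tags, ss_layers):
        rng = np.random.default_rng(ss)
        m = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(samples)))
        for gene, signal_tag in truth.items():
            if signal_tag == tag:
                m[gene_index[gene], poor_mask] += cfg.effect_size * cfg.noise_sd
        layers.append(OmicsLayer(tag, m, genes, samples))
    return SyntheticCohort(layers=layers, edges=edges, labels=labels, truth=truth, config=cfg)


def simulate(cfg: SimConfig) -> SyntheticCohort:
    """Convenience wrapper: network + omics in one call."""
    return generate_omics(cfg, generate_network(cfg))


def label_samples(
    survival_days,
    vital_status,
    threshold: float,
    deceased_policy: str = "exclude",
) -> pd.Series:
    """Derive good/poor prognosis labels from survival times.

    Alive samples surviving at least ``threshold`` days are labeled good,
    alive samples below it poor.  The clinical convention only defines the
    alive branch; deceased samples are handled per ``deceased_policy``:
    ``"exclude"`` drops them, ``"poor_if_short"`` labels deceased samples
    with time < threshold as poor (and drops the rest).

    Returns a Series indexed like the inputs, containing only labeled samples.
    """
    if threshold <= 0:
        raise ConfigError("survival threshold must be positive")
    if deceased_policy not in ("exclude", "poor_if_short"):
        raise ConfigError(f"unknown deceased_policy {deceased_policy!r}")
    times = pd.Series(survival_days, dtype=float)
    status = pd.Series(vital_status, index=times.index, dtype=object)
    if (times < 0).any():
        raise DataError("negative survival time")
    out = {}
    for idx in times.index:
        alive = str(status.loc[idx]).lower() == "alive"
        t = times.loc[idx]
        if alive:
            out[idx] = GOOD if t >= threshold else POOR
        elif deceased_policy == "poor_if_short" and t < threshold:
            out[idx] = POOR
    return pd.Series(out, dtype=object)
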