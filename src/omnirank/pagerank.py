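"""Weighted PageRank gene scoring and stability selection.

Gene importance is scored by the damped recursion

    PR_i = (1 − d)/n + d · Σ_{j ∈ M_i}  |G_ij| / Σ_{t ∈ M_j} |G_tj| · PR_j,

where M_i is the network neighborhood of gene i and |G_ij| the learned
nonnegative edge weight.  Each node thus splits its score among neighbors in
proportion to edge weight; with all-equal weights this is exactly classic
undirected PageRank.  Iteration starts uniform at 1/n and stops when the
largest absolute score change drops below ``tol``.  Nodes with zero weighted
degree distribute uniformly over all nodes (the classic dangling fix), which
keeps the transition column-stochastic and the total score at 1.

Because single-run rankings inherit the randomness of the adversarial
weight-learning initialization, biomarkers are stability-selected: the
GAN + PageRank stage is repeated t times and genes appearing in the per-run
top-N list at least b of t times (b <= t) are kept.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import DataError
from .gan import GanConfig, train_gan
from .netbuild import ReconstructedNetwork


class PageRankConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    damping: float = 0.85
    tol: float = 0.005
    max_iter: int = 1000
    runs: int = 10  # t: number of repeated weight-learning + ranking runs
    min_count: int = 6  # b: selection threshold over the t runs
    top_n: int = 100  # per-run biomarker list length

    @model_validator(mode="after")
    def _check(self) -> "PageRankConfig":
        if not 0 < self.damping < 1:
            raise ValueError("damping must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if min(self.max_iter, self.runs, self.min_count, self.top_n) < 1:
            raise ValueError("max_iter, runs, min_count and top_n must be positive")
        if self.min_count > self.runs:
            raise ValueError("min_count (b) must not exceed runs (t)")
        return self


def weighted_pagerank(
    weights: np.ndarray,
    damping: float = 0.85,
    tol: float = 0.005,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int, bool]:
    """Iterate the weighted recursion to its fixed point.

    Returns ``(scores, iterations, converged)``.  Non-convergence within
    ``max_iter`` emits a warning and returns the best iterate.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    n = w.shape[0]
    if n == 0:
        raise DataError("empty network")
    if w.shape != (n, n):
        raise DataError("weight matrix must be square")
    col = w.sum(axis=0)
    dangling = col == 0
    p = np.divide(w, col, out=np.zeros_like(w), where=~dangling)
    pr = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        new = (1 - damping) / n + damping * (p @ pr + pr[dangling].sum() / n)
        delta = np.max(np.abs(new - pr))
        pr = new
        if delta < tol:
            return pr, it, True
    warnings.warn(f"PageRank did not reach tol={tol} in {max_iter} iterations")
    return pr, max_iter, False


def top_ranked(scores: np.ndarray, nodes: list[str], n: int) -> list[str]:
    """Top-n genes by score, ties broken by gene id for determinism."""
    order = sorted(range(len(nodes)), key=lambda i: (-scores[i], nodes[i]))
    return [nodes[i] for i in order[:n]]


def stability_select(run_sets: list[set[str]], min_count: int) -> set[str]:
    """Genes appearing in at least ``min_count`` of the per-run top lists."""
    t = len(run_sets)
    if min_count > t:
        raise DataError(f"selection threshold b={min_count} exceeds number of runs t={t}")
    counts = Counter(g for s in run_sets for g in set(s))
    return {g for g, c in counts.items() if c >= min_count}


@dataclass
class RankResult:
    """Outcome of the repeated weight-learning + ranking experiment."""

    scores: pd.DataFrame  # genes x runs PageRank scores
    per_run_top: list[set[str]]
    selected: set[str]
    counts: Counter
    runs: int
    min_count: int
    iterations: list[int]

    def biomarker_frame(self) -> pd.DataFrame:
        mean_pr = self.scores.mean(axis=1)
        genes = sorted(self.selected, key=lambda g: (-self.counts[g], -mean_pr[g], g))
        return pd.DataFrame(
            {
                "gene": genes,
                "appearance_count": [self.counts[g] for g in genes],
                "mean_PR": [mean_pr[g] for g in genes],
            }
        )


def rank_biomarkers(
    real: np.ndarray,
    network: ReconstructedNetwork,
    gan_cfg: GanConfig,
    rank_cfg: PageRankConfig,
    seed: int = 0,
) -> RankResult:
    """Run GAN weight learning + weighted PageRank t times and stability-select.

    Each run re-initializes the adversarial model with a fresh seed derived
    from ``seed``; the per-run top-``top_n`` gene lists are combined by the
    b-of-t appearance rule.
    """
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=rank_cfg.runs)
    per_run_top: list[set[str]] = []
    scores = {}
    iterations = []
    for r, run_seed in enumerate(run_seeds):
        trained = train_gan(real, network.adjacency, gan_cfg, nodes=network.nodes, seed=int(run_seed))
        pr, its, _ = weighted_pagerank(
            trained.weights, rank_cfg.damping, rank_cfg.tol, rank_cfg.max_iter
        )
        scores[f"run{r}"] = pr
        iterations.append(its)
        per_run_top.append(set(top_ranked(pr, network.nodes, rank_cfg.top_n)))
    selected = stability_select(per_run_top, rank_cfg.min_count)
    counts = Counter(g for s in per_run_top for g in s)
    return RankResult(
        scores=pd.DataFrame(scores, index=pd.Index(network.nodes, name="gene")),
        per_run_top=per_run_top,
        selected=selected,
        counts=counts,
        runs=rank_cfg.runs,
        min_count=rank_cfg.min_count,
        iterations=iterations,
    )
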