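"""Adjacency-masked GAN that learns nonnegative symmetric edge weights.

The generator has no hidden layer: noise Z in R^n (standard normal, n =
number of network genes) is mapped through a single masked linear layer,

    Output = relu( Z · (A ⊙ w ⊙ wᵀ) ),

where A is the reconstructed network's 0/1 adjacency and w an n x n
trainable matrix.  The Hadamard product w ⊙ wᵀ enforces symmetry, and the
mask A restricts every trainable connection to an actual interaction edge,
so in the high-dimension/low-sample-size regime the generator stays sparse
and (with |w| < 1 at initialization, since each effective weight is a
product of two sub-unit factors) self-shrinking, much like an L2 penalty.

The discriminator is a dense n -> hidden -> 1 net (relu, then sigmoid)
trained against the standard adversarial value function

    min_G max_D  E[log D(x)] + E[log(1 − D(G(z)))].

Both nets are trained by alternating single-batch Adam steps.  After
training, edge weights are finalized as |A ⊙ w ⊙ wᵀ| (absolute values),
the form the weighted PageRank stage consumes.

The model is small enough (hundreds of nodes, one masked layer) that it is
implemented directly on numpy arrays with explicit gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import DataError

_EPS = 1e-7


def _sigmoid(s: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-s))


class GanConfig(BaseModel):
    """Adversarial-training hyper-parameters.

    The defaults (epochs=2, batch_size=1, learning_rate=2e-4, Adam) are the
    pipeline's standard settings; convergence studies use ``epochs`` in the
    tens to hundreds.  ``generator_loss``: ``"non_saturating"`` maximizes
    log D(G(z)) (the canonical surrogate for the minimax objective, which
    keeps gradients alive while the discriminator is winning);
    ``"saturating"`` minimizes log(1 − D(G(z))) literally.
    """

    model_config = ConfigDict(extra="forbid")

    epochs: int = 2
    batch_size: int = 1
    learning_rate: float = 2e-4
    hidden_units: int = 256
    beta1: float = 0.9
    beta2: float = 0.999
    init_scale: float = 0.1
    generator_activation: str = "relu"  # or "identity"
    generator_loss: str = "non_saturating"  # or "saturating"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GanConfig":
        if min(self.epochs, self.batch_size, self.hidden_units) < 1:
            raise ValueError("epochs, batch_size and hidden_units must be positive")
        if self.learning_rate <= 0 or self.init_scale <= 0:
            raise ValueError("learning_rate and init_scale must be positive")
        if self.generator_activation not in ("relu", "identity"):
            raise ValueError("generator_activation must be 'relu' or 'identity'")
        if self.generator_loss not in ("non_saturating", "saturating"):
            raise ValueError("generator_loss must be 'non_saturating' or 'saturating'")
        return self


class _Adam:
    """Plain Adam optimizer state for one parameter array."""

    def __init__(self, shape, lr, beta1, beta2, eps=1e-8):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps

    def step(self, param: np.ndarray, grad: np.ndarray) -> None:
        # in-place bias-corrected update: lr·m̂/(√v̂ + eps) with scalar correction
        self.t += 1
        m, v = self.m, self.v
        m *= self.b1
        m += (1 - self.b1) * grad
        v *= self.b2
        v += (1 - self.b2) * np.square(grad)
        corr_v = np.sqrt(1 - self.b2**self.t)
        step = self.lr * corr_v / (1 - self.b1**self.t)
        upd = np.sqrt(v)
        upd += self.eps * corr_v
        np.divide(m, upd, out=upd)
        upd *= step
        param -= upd


@dataclass
class GeneratorState:
    """Mask A and raw weights w; effective weights are A ⊙ w ⊙ wᵀ."""

    adjacency: np.ndarray
    w: np.ndarray
    activation: str = "relu"

    @property
    def effective_weights(self) -> np.ndarray:
        return self.adjacency * self.w * self.w.T

    def forward(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.adjacency.shape[0]:
            raise DataError(
                f"noise dimension {z.shape[1]} != network size {self.adjacency.shape[0]}"
            )
        out = z @ self.effective_weights
        if self.activation == "relu":
            out = np.maximum(out, 0.0)
        return out


@dataclass
class DiscriminatorState:
    """Dense n -> hidden -> 1 classifier; relu hidden, sigmoid output."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def forward(self, x: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        pre = x @ self.w1 + self.b1
        h = np.maximum(pre, 0.0)
        s = h @ self.w2 + self.b2
        p = 1.0 / (1.0 + np.exp(-s))
        return p, s, h, pre

    def score(self, x: np.ndarray) -> np.ndarray:
        """P(real) for each row of x."""
        return self.forward(x)[0].ravel()


@dataclass
class TrainedGan:
    """Finalized result of one adversarial-training run."""

    weights: np.ndarray  # |A ⊙ w ⊙ wᵀ|, symmetric, nonnegative
    generator: GeneratorState
    discriminator: DiscriminatorState
    nodes: list[str] | None
    history: pd.DataFrame  # per-epoch d_loss, g_loss, mean_d_real, mean_d_fake
    config: GanConfig = field(repr=False)

    def generate(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n_samples, self.weights.shape[0]))
        return self.generator.forward(z)

    def equilibrium_score(self, real: np.ndarray, rng: np.random.Generator) -> float:
        """Mean discriminator output pooled over real and generated batches.

        At the adversarial equilibrium the discriminator cannot do better
        than 0.5 on either side, so the pooled mean sits at 0.5.
        """
        fake = self.generate(len(real), rng)
        scores = np.concatenate([self.discriminator.score(real), self.discriminator.score(fake)])
        return float(scores.mean())

    def weight_frame(self) -> pd.DataFrame:
        """Weighted edge list (gene_a, gene_b, weight) over the mask support."""
        if self.nodes is None:
            raise DataError("no node names attached to this run")
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame(
            {
                "gene_a": [self.nodes[i] for i in ii],
                "gene_b": [self.nodes[j] for j in jj],
                "weight": self.weights[ii, jj],
            }
        )


def generator_forward(state: GeneratorState, z: np.ndarray) -> np.ndarray:
    """Functional form of the masked generator pass."""
    return state.forward(z)


def extract_weights(state: GeneratorState) -> np.ndarray:
    """Finalize edge weights: elementwise |A ⊙ w ⊙ wᵀ|."""
    return np.abs(state.effective_weights)


def _init_states(adjacency, cfg: GanConfig, rng) -> tuple[GeneratorState, DiscriminatorState]:
    n = adjacency.shape[0]
    a = adjacency.astype(float)
    w = np.where(a > 0, rng.uniform(0.0, cfg.init_scale, size=(n, n)), 0.0)
    gen = GeneratorState(adjacency=a, w=w, activation=cfg.generator_activation)
    h = cfg.hidden_units
    disc = DiscriminatorState(
        w1=rng.normal(0.0, np.sqrt(2.0 / n), size=(n, h)),
        b1=np.zeros(h),
        w2=rng.normal(0.0, np.sqrt(2.0 / h), size=(h, 1)),
        b2=np.zeros(1),
    )
    return gen, disc


def train_gan(
    real: np.ndarray,
    adjacency: np.ndarray,
    cfg: GanConfig,
    nodes: list[str] | None = None,
    seed: int | None = None,
) -> TrainedGan:
    """Alternating adversarial training of the masked generator.

    ``real`` is the samples x n matrix of multi-omics vectors.  Per epoch the
    sample order is shuffled and each batch triggers one discriminator step
    (one real batch vs one generated batch) followed by one generator step on
    fresh noise.  Raises :class:`DataError` on a non-finite loss, with the
    loss trace attached to the message.
    """
    real = np.asarray(real, dtype=float)
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    if adjacency.shape != (n, n):
        raise DataError("adjacency must be square")
    if not np.array_equal(adjacency, adjacency.T):
        raise DataError("adjacency must be symmetric")
    if real.ndim != 2 or real.shape[1] != n:
        raise DataError(f"real data must be samples x {n}")
    if real.shape[0] < 2:
        raise DataError("need at least 2 real samples")

    run_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    gen, disc = _init_states(adjacency, cfg, rng)
    a = gen.adjacency

    opt_w = _Adam(gen.w.shape, cfg.learning_rate, cfg.beta1, cfg.beta2)
    opt_w1 = _Adam(disc.w1.shape, cfg.learning_rate, cfg.beta1, cfg.beta2)
    opt_b1 = _Adam(disc.b1.shape, cfg.learning_rate, cfg.beta1, cfg.beta2)
    opt_w2 = _Adam(disc.w2.shape, cfg.learning_rate, cfg.beta1, cfg.beta2)
    opt_b2 = _Adam(disc.b2.shape, cfg.learning_rate, cfg.beta1, cfg.beta2)

    w1, b1, w2, b2 = disc.w1, disc.b1, disc.w2, disc.b2
    relu_gen = gen.activation == "relu"
    non_sat = cfg.generator_loss == "non_saturating"

    history = []
    n_samples = real.shape[0]
    # the loop below is written against local arrays with fused expressions:
    # at batch size 1 it is numpy-call-bound, not flop-bound
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n_samples)
        d_losses, g_losses, d_reals, d_fakes = [], [], [], []
        w_eff = a * gen.w * gen.w.T
        for start in range(0, n_samples, cfg.batch_size):
            x = real[perm[start : start + cfg.batch_size]]
            b = x.shape[0]

            # -- discriminator step: maximize log D(x) + log(1 - D(G(z)))
            z = rng.standard_normal((b, n))
            fake = z @ w_eff
            if relu_gen:
                np.maximum(fake, 0.0, out=fake)
            pre_r = x @ w1 + b1
            h_r = np.maximum(pre_r, 0.0)
            p_real = _sigmoid(h_r @ w2 + b2)
            pre_f = fake @ w1 + b1
            h_f = np.maximum(pre_f, 0.0)
            p_fake = _sigmoid(h_f @ w2 + b2)
            ds_r = (p_real - 1.0) / b
            ds_f = p_fake / b
            dh_r = (ds_r @ w2.T) * (pre_r > 0)
            dh_f = (ds_f @ w2.T) * (pre_f > 0)
            opt_w2.step(w2, h_r.T @ ds_r + h_f.T @ ds_f)
            opt_b2.step(b2, (ds_r + ds_f).sum(axis=0))
            opt_w1.step(w1, x.T @ dh_r + fake.T @ dh_f)
            opt_b1.step(b1, (dh_r + dh_f).sum(axis=0))
            d_loss = float(
                -(np.log(np.clip(p_real, _EPS, 1 - _EPS)).mean()
                  + np.log(1 - np.clip(p_fake, _EPS, 1 - _EPS)).mean())
            )

            # -- generator step on fresh noise (discriminator fixed)
            z2 = rng.standard_normal((b, n))
            pre_g = z2 @ w_eff
            out = np.maximum(pre_g, 0.0) if relu_gen else pre_g
            pre_d = out @ w1 + b1
            h_g = np.maximum(pre_d, 0.0)
            p_g = _sigmoid(h_g @ w2 + b2)
            pc_g = np.clip(p_g, _EPS, 1 - _EPS)
            if non_sat:
                ds = (p_g - 1.0) / b  # minimize -log D(G(z))
                g_loss = float(-np.log(pc_g).mean())
            else:
                ds = -p_g / b  # d/ds log(1 - sigmoid(s)) = -p; descend on log(1-D)
                g_loss = float(np.log(1 - pc_g).mean())
            dx = ((ds @ w2.T) * (pre_d > 0)) @ w1.T
            if relu_gen:
                dx *= pre_g > 0
            d_weff = z2.T @ dx
            # W_eff_ij = A_ij w_ij w_ji  =>  dL/dw = A ⊙ (dW + dWᵀ) ⊙ wᵀ
            dw = a * (d_weff + d_weff.T) * gen.w.T
            opt_w.step(gen.w, dw)
            w_eff = a * gen.w * gen.w.T

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise DataError(
                    f"non-finite adversarial loss at epoch {epoch}: "
                    f"d_loss={d_loss}, g_loss={g_loss}; trace={history}"
                )
            d_losses.append(d_loss)
            g_losses.append(g_loss)
            d_reals.append(float(p_real.mean()))
            d_fakes.append(float(p_fake.mean()))
        history.append(
            {
                "epoch": epoch,
                "d_loss": float(np.mean(d_losses)),
                "g_loss": float(np.mean(g_losses)),
                "mean_d_real": float(np.mean(d_reals)),
                "mean_d_fake": float(np.mean(d_fakes)),
            }
        )

    gen.w *= a  # drop any numerical dust off the mask support
    weights = extract_weights(gen)
    return TrainedGan(
        weights=weights,
        generator=gen,
        discriminator=disc,
        nodes=list(nodes) if nodes is not None else None,
        history=pd.DataFrame(history),
        config=cfg.model_copy(update={"seed": run_seed}),
    )
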