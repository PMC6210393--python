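# Methods

## Problem and model

`omnirank` discovers prognostic biomarker genes from multi-omics cancer
cohorts and uses them to predict good vs poor prognosis.  The method rests
on three ideas:

1. **Differential evidence per layer.**  For each omics layer (mRNA
   expression, copy number, DNA methylation, somatic mutation scores) and
   each gene, an equal-variance two-sample pooled t statistic contrasts the
   poor- and good-prognosis groups:

       t_i = (x̄_{i,p} − x̄_{i,g}) / (s_i · √(1/n_p + 1/n_g)),
       s_i² = [(n_p−1) S²_{i,p} + (n_g−1) S²_{i,g}] / (n_p + n_g − 2).

   The top-N genes by |t| per layer form the sets M, C, T, S; their union U
   seeds the network: every interaction edge with at least one endpoint in
   U is retained, together with its incident genes.  Retention keeps non-U
   neighbors in the graph — they can still be selected later and are then
   assigned a feature layer by a neighbor membership vote.

2. **Edge weights learned adversarially.**  The retained network's 0/1
   adjacency A masks a single-layer generator, Output = relu(Z(A⊙w⊙wᵀ)),
   trained in a GAN against a dense n→256→1 discriminator on the cohort's
   per-gene "real vectors" (each gene's values taken from its max-|t|
   layer).  w⊙wᵀ enforces symmetric weights; the mask confines learning to
   genuine interactions, which keeps the model identifiable in the
   high-dimension/low-sample-size regime; and because effective weights are
   products of sub-unit factors, they shrink multiplicatively, acting like
   an L2 penalty.  Final edge weights are |A⊙w⊙wᵀ|.

3. **Weighted PageRank with stability selection.**  Genes are scored by
   PR_i = (1−d)/n + d Σ_j (|G_ij| / Σ_t |G_tj|) PR_j, iterated from 1/n
   until max |ΔPR| < tol.  Because adversarial training is stochastic in
   its initialization, the weight-learning + ranking stage is repeated t
   times; genes appearing in the per-run top-N list at least b of t times
   are the biomarkers.  Each biomarker contributes one feature per top-set
   membership (all of them when it belongs to several), and a multi-layer
   perceptron (relu, L2 penalty) evaluated by stratified k-fold
   cross-validation yields the prognosis AUC.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `network.top_n` (N) | 400 | per-layer |t| cutoff; a user parameter, sized to the expected signal set (we use 2× the planted-module size in simulation studies) |
| `network.normalize_axis` | `sample` | z-score each sample profile. Per-sample scaling preserves *between-gene variance differences*, which is what the generator can encode in its column norms and what ultimately lets PageRank favor signal genes; `gene` is available and flattens every gene to unit variance |
| `gan.epochs` / `batch_size` / `learning_rate` | 2 / 1 / 2e-4 | the pipeline's standard Adam settings; convergence studies use an extended-epoch mode (150–200) since 2 epochs on tens of samples is far from the adversarial equilibrium |
| `gan.generator_activation` | `relu` | the generator's output nonlinearity. Note relu output cannot produce negative values although z-scored data are signed; `identity` is available as an escape hatch |
| `gan.generator_loss` | `non_saturating` | maximize log D(G(z)), the canonical surrogate for the minimax objective; it keeps generator gradients alive while the discriminator is winning. The literal `saturating` form (minimize log(1−D(G(z)))) is available |
| `rank.damping` (d) | 0.85 | standard PageRank teleportation |
| `rank.tol` | 0.005 | the max-absolute-change stopping rule. On desk-scale networks (n≈300, PR≈1/300) an absolute 0.005 halts after very few sweeps, so quantitative studies pass a tight tolerance (1e-9); oracle tests use 1e-13 |
| `rank.runs` (t) / `min_count` (b) / `top_n` | 10 / 6 / 100 | stability selection; b=t/2 (simple majority) is a natural operating point and is what the simulation studies use together with a per-run list of 2× the expected biomarker count |
| `predict.*` | 10 folds, 64 relu units, α=1e-3, lbfgs | MLP classifier settings; lbfgs is fast and reproducible at these sample sizes |

Hyper-parameters of the ranking stage (N, t, b, extended epochs) were chosen
by a small grid on simulated cohorts scored by planted-gene recovery — the
method's parameters are explicitly user-tunable and heuristic search is the
intended protocol.

## Evaluation protocols and leakage

`selection_mode="global"` (default) selects biomarkers once on the full
cohort and cross-validates only the classifier.  The selection step then
sees the evaluation labels, so AUCs are optimistic; this mode exists because
it is the historical protocol.  `selection_mode="nested"` reruns the entire
selection chain (t statistics, top sets, reconstruction, adversarial
weighting, stability selection, feature assignment) inside every training
fold.  All permutation-null calibration uses nested mode, where permuted
labels yield AUC ≈ 0.5; z-score normalization is label-free and is shared
across folds.

## The synthetic cohort generator

The generator emulates only the statistical structure the method consumes:

* a preferential-attachment (Barabási–Albert, star-seeded) interaction graph
  whose right-skewed degree distribution exposes PageRank's hub bias;
* Gaussian omics layers (sd `noise_sd`), one to four of them, with identical
  sample ordering;
* a planted module of prognosis-associated genes — a breadth-first ball
  around a random node — each member carrying a standardized mean shift of
  `effect_size` between groups in exactly one round-robin-assigned layer.
  Module planting reflects the premise of network-propagation methods that
  disease genes cluster in interaction networks; a uniform-random planting
  (`planted_module=False`) is available and is a strictly harder target the
  method does not claim to solve.

Default study condition: 300 genes, attachment m=2, a 25-gene module,
two layers, 20 good + 20 poor samples (a pancreatic-cohort-sized design),
effect size 2, noise sd 1.

What the generator does *not* emulate: copy-number segmentation, methylation
beta-value distributions, mutation sparsity, batch effects, censoring, or
correlated background expression.  Passing tests therefore demonstrate that
the implementation realizes the method's mechanics and recovers planted
signal under idealized noise — not that the method succeeds on real tumors.

## Numerical choices

* z-scores use the population sd (ddof=0); constant rows/columns map to 0.
* Zero-pooled-variance genes get t = NaN and never enter any |t| ranking.
* Top-N ties break by (|t| descending, gene id ascending) — deterministic
  across platforms.  Neighbor-vote ties follow the fixed layer priority
  mRNA > CNV > methylation > SNP; a voteless gene falls back to its own
  max-|t| layer and is flagged in the assignment provenance.
* PageRank columns with zero weighted degree distribute uniformly (classic
  dangling fix), keeping the transition column-stochastic and Σ PR = 1.
* The GAN is trained with alternating single-batch Adam steps (β = 0.9,
  0.999), generator weights initialized uniform on (0, 0.1) on the mask
  support, discriminator He-initialized; all randomness flows from one seed
  per run, and repeated runs derive their seeds from the stage seed.
* Missing values: genes with any NA are dropped per layer by default
  (per-layer gene sets may differ); mean imputation is available.
* Clinical labeling: alive samples are good iff survival ≥ threshold;
  deceased samples are excluded by default (`deceased_policy`), since the
  labeling rule is defined only for alive samples.

## Known limitations

* The relu generator output cannot represent negative values, so on signed
  data the discriminator retains a winning feature and per-side equilibrium
  (D ≈ 0.5 on real and fake separately) is unreachable; the *pooled* mean
  over real and generated batches still converges to 0.5, which is what the
  equilibrium check measures.
* Stability-selected biomarker sets contain high-degree union members that
  are statistically indistinguishable from true signal at these sample
  sizes; recovery of a planted module reaches ~85% while precision of the
  selected set remains ~50% under the default study condition.  Low-degree
  module members are the hardest to recover: the teleport floor bounds how
  far learned edge weights can lift a degree-2 gene past well-connected
  competitors.
* With four layers and few samples, per-layer top-N sets overlap little and
  U grows; runtime scales with the retained network size (dense n×n
  training), so cohorts beyond a few thousand retained genes need a sparse
  reimplementation of the generator mask.
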