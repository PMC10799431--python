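# Methods

## Model

Each gene's mRNA life cycle is modelled by the splicing kinetics

    du/dt = α(t) − β u
    ds/dt = β u − γ(t) s

with transcription rate α, splicing rate β and degradation rate γ. The
estimator predicts per-cell, per-gene rates: a two-layer graph
convolutional network (hidden size 64, ReLU, dropout 0.2 between hidden
layers) over the cell kNN graph maps the concatenated smoothed expression
[s‖u] of a cell's neighborhood to rate blocks through a linear output head,
with a softplus activation enforcing nonnegativity. The propagation rule is
the standard symmetric normalization H⁽ˡ⁺¹⁾ = σ(D̃^−1/2 Ã D̃^−1/2 H⁽ˡ⁾ W⁽ˡ⁾)
with Ã the symmetrized kNN adjacency plus self-loops (kNN is directed; the
symmetric normalization presumes an undirected graph, so an edge is kept if
present in either direction). Spliced velocity is v = β∘u − γ∘s on the
smoothed layers. By default only β and γ are predicted; an optional α head
enables the unspliced derivative, for which two conventions exist in the
field — α − βu (consistent with the transcription equation, our default)
and α − βs (available as `spliced_form=True`); the package implements
both rather than guessing intent.

### Continuity objective

For cell i with velocity v_i, candidate future states are the k=30 nearest
neighbors (Euclidean distance on the first 30 PCs of log1p spliced counts)
whose displacement s_j − s_i has strictly positive cosine with v_i; each
receives probability 1/Z (Z = count of such candidates; Z=0 rows are
flagged and contribute no loss). The forward loss is the mean over cells
and genes of (s_i + v_i − Σ_j P(i→j) s_j)²; the backward loss mirrors it
with −v_i. Because the sum of the two extrapolation terms is invariant
under v → −v, a negated Pearson term −(λ_u corr(v,u) + λ_s corr(v,−s))
fixes the sign, with correlations computed per gene across cells (the
per-cell reading — across genes — is the other possible interpretation;
the per-gene one matches the heuristic that a gene's velocity should rise
with its unspliced pool) and genes of zero variance contributing 0. The
total is 1.0·L⁺ + 1.0·L⁻ + 18.0·L_Pearson, with λ_u = λ_s = 1.

Candidate probabilities contain an indicator and are treated as constants
within each optimization step, recomputed every epoch from the current
inference-mode velocity (alternating estimation). Training is full-batch
Adam with AMSGrad, learning rate 10⁻³ decayed by 0.97 per epoch, 100
epochs. The whole network and its backward pass are plain numpy; the
gradients — through the squared extrapolation residuals, the per-gene
Pearson terms, the velocity algebra, softplus, the linear head, dropout
and both graph convolutions — are derived by hand and verified against
central finite differences to ~10⁻⁷ relative error in the test suite. The
per-epoch loss that is logged is evaluated in inference mode (dropout
off), so the logged trajectory is a deterministic function of the weights
and is bit-reproducible under a fixed seed.

## Preprocessing

Fixed order: drop zero-total cells → library-size normalization → highly
variable gene selection (on spliced) → log1p for PCA only → PCA → kNN →
neighbor smoothing of the normalized (non-log) layers.

* Normalization scales each cell's spliced total to the median spliced
  library size and applies the same factor to the unspliced layer,
  preserving the u/s ratios that velocity depends on.
  `normalize_target="none"` skips scaling: simulated concentrations carry
  no count-depth variation, and scaling near-empty early-trajectory cells
  to the median total grossly distorts the geometry the continuity
  objective relies on. All simulation protocols therefore run unscaled;
  median scaling remains the default for real count data.
* HVG statistic: dispersion (var/mean) of log1p spliced, z-scored within 20
  equal-frequency mean bins; ties keep the lower gene index. A variance
  tolerance of 10⁻¹² marks constant genes as unusable.
* PCA on the centered log1p spliced matrix via SVD with a fixed sign
  convention (largest-|loading| coordinate positive), so results are
  reproducible without a seed.
* kNN by brute-force Euclidean distance in PC space with ties broken
  toward the lower cell index and self always excluded; exact rather than
  approximate so the graph is deterministic (N up to a few thousand is the
  intended regime).
* Smoothing replaces each value by the mean over {cell ∪ its k neighbors}
  — a row-stochastic linear operator; smoothed layers are stored beside the
  normalized ones.

## Simulator

The generator emulates spliced/unspliced readouts of cells along a
differentiation trajectory. Per gene, α, β, γ are drawn log-uniformly from
[1, 5], [0.2, 1], [0.1, 0.5]; transcription switches off at a time drawn
uniformly from [0.3 T, 0.7 T] (T = 20), producing an induction phase
followed by repression. Cells receive pseudotimes uniform on [0, T];
observations get multiplicative log-normal noise (σ = 0.1 by default; a
Poisson option exists). Ground truth (noise-free states, exact ds/dt,
kinetics, seed) is stored alongside.

Constant-rate trajectories use the closed form

    u(t) = α/β + (u₀ − α/β) e^{−βt}
    s(t) = α/γ + (s₀ − α/γ) e^{−γt} + (βu₀ − α)(e^{−βt} − e^{−γt})/(γ − β)

(the γ→β limit replaces the last factor by t·e^{−βt}; |γ−β| < 10⁻⁹ selects
it), solved piecewise across the transcription switch. Time-dependent
degradation — γ(t) = γ₀(1 + 4t/T) for the "reversed" genes, which reverses
the late phase portrait — is integrated with adaptive RK45 (rtol 10⁻⁹)
with the switch as a hard breakpoint. Both solvers are validated against
an independent fixed-step RK4 oracle to 10⁻⁶ and the steady-state law
u*β = α, s*γ = α to 10⁻⁹.

The two-regime generator gives one shared gene different kinetics in two
lineages. Per-regime sampling windows matter: the time-average of ds/dt
over a full trajectory from rest is ≈ (s(T) − s(0))/T ≥ 0, so a
"repressing" population only has a negative mean velocity if it is
*observed* after its transcription switch. The canonical two-regime
protocol samples lineage A during induction (t ∈ [0, 10], no switch) and
lineage B after its switch at t = 4 (t ∈ [6, 20]), giving robustly
opposite true mean velocities.

What the generator does not emulate: UMI count noise and sparsity (noise
is smooth multiplicative), batch effects, ambient RNA, doublets, or gene–
gene regulatory correlations. Passing tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to every artefact of real data.

## Metrics

* **Overall consistency**: mean cosine of a cell's velocity with its 30-NN
  neighbors' velocities. **Cell-type consistency**: mean cosine with all
  same-type velocities, including the self term (the defining sum runs
  over every member of the type). Zero-velocity terms are skipped with the
  denominator reduced; all-skipped cells are NaN.
* **Continuity score**: relative extrapolation error ε = |s + v −
  Σ P(i→j) s_j| / max(s, ε₀) with floor ε₀ = 10⁻³ (the plain denominator
  can be 0 on normalized data); CS-cell = 1 − mean_genes tanh ε and
  CS-gene = 1 − mean_cells tanh ε, both in (0, 1].
* **Correlation score** per gene: corr(v, u) + corr(v, −s) across cells,
  with the zero-variance guard of the loss.
* **Direction score**: boundary cells of an annotated transition A→B are
  A-cells with ≥ 1 B-neighbor; DS(i) averages the cosine between the
  neighbor's velocity v_j and the displacement s_j − s_i over B-neighbors
  (a `velocity_of="cell"` switch uses v_i, the conventional cross-boundary
  form). The global score is the unweighted mean over the **union** of
  boundary cells across pairs — not a mean of per-pair means — so every
  cell contributes equally regardless of pair size; a cell on several
  boundaries contributes the mean of its per-pair scores once.
* For simulations, pseudo cell-types are 8 equal-frequency pseudotime bins
  with consecutive pairs as transitions; at the 500-cell protocol scale a
  bin (~60 cells) is comparable to the k=30 neighborhood, keeping
  between-bin displacements local.

## Downstream

The velocity graph holds, on each kNN edge, cos(v_i, s_j − s_i) restricted
to confidence-filtered genes. The filter keeps genes with CS-gene at or
above the dataset median (default), correlation score ≥ 0, and a relative
residual of the per-gene u-on-s regression (RSS over TSS of u about its
mean) strictly inside (0, 0.95) — a perfect linear fit (residual 0, no
kinetic information beyond steady state) and near-unexplained genes are
both excluded; residuals below 10⁻¹² are reported as exactly 0 so the
open lower bound is meaningful. Transition probabilities are the Gaussian
normalization π_ij ∝ exp(w_ij/σ) with σ = 0.05 by default (the scale is a
free parameter; exposed); embedding arrows are Σ_j (π_ij − 1/k_i) δ_ij
with δ_ij the unit embedding direction i→j — subtracting the uniform
baseline makes isotropic transitions produce zero arrows (flag-controlled,
on by default). Driver genes are ranked per branch by positive Pearson
correlation of smoothed spliced expression with pseudotime (top 100 by
default); pseudotime and branch labels are inputs.

## Protocol problem sizes

The canonical experiments (shared by the tests and the acceptance script)
are: 500 cells × 30 genes with 3 reversed genes for the direction
protocol; 300 cells × 20 genes (two groups of 10 with γ = 0.15 vs 0.6,
other rates from the generator ranges) for rate recovery; 2 × 150 cells
with 5 background genes for the two-regime protocol — sizes at which a
full 100-epoch training run takes a few seconds on one CPU while keeping
the neighborhood structure (k = 30) meaningful.

## Known limitations

* The objective identifies the per-gene rate **ratio** γ/β sharply (the
  zero-velocity line of the phase portrait) but pins the absolute rate
  scale only weakly — the velocity magnitude is calibrated by the
  displacement to candidate neighbors, i.e. by the local sampling density
  along the trajectory, not by physical time. Rank recovery of an absolute
  γ contrast is therefore noisy (Spearman ≈ 0.5 at the 300-cell protocol)
  even when the group contrast in means is clear.
* Velocity direction is least reliable where the trajectory folds back on
  itself (cells just after a transcription switch) and where expression
  has decayed to near zero: there the neighborhood mixes dynamic phases
  and softplus-floored rates produce small, noisy velocities.
* Full-batch training holds the whole N×N normalized adjacency and N×2D
  feature matrix in memory; the implementation targets 10²–10⁴ cells.
* The continuity assumption requires the sampled population to cover the
  trajectory densely; sparse regions (trajectory endpoints) receive
  weaker supervision.
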