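# velogcn

Cell-specific RNA velocity from spliced/unspliced single-cell counts, via a
graph convolutional network trained under a self-supervised continuity
objective.

## The problem

RNA velocity infers the time derivative of spliced mRNA abundance per gene
and cell from the ratio of unspliced (pre-mRNA) to spliced counts, giving
each cell a direction of transcriptional change. The underlying splicing
kinetics are

```
du/dt = α(t) − β u        (transcription, splicing)
ds/dt = β u − γ s         (splicing, degradation)
```

Classical estimators assume the rates α, β, γ are shared by all cells of a
gene, which breaks down in multi-lineage data where one gene follows
different kinetic regimes in different cell populations. `velogcn` instead
predicts **cell-specific, gene-specific** rates β<sub>i,g</sub>,
γ<sub>i,g</sub> with a two-layer graph convolutional network (GCN) over the
30-nearest-neighbor cell graph, and computes the velocity as

```
v_i = β_i ∘ u_i − γ_i ∘ s_i     (elementwise over genes)
```

Training is self-supervised by a **continuity assumption**: in a large
sequenced population, a cell's near-future expression state is matched by
some observed neighbor cells. The extrapolated state s<sub>i</sub> +
v<sub>i</sub> is pulled toward the mean expression of the neighbors whose
displacement has positive cosine with v<sub>i</sub> (and s<sub>i</sub> −
v<sub>i</sub> toward the backward cone); a negated Pearson-correlation term
(velocity vs unspliced, velocity vs negative spliced, per gene across
cells) breaks the v → −v symmetry. The three terms are weighted 1.0 / 1.0 /
18.0 and minimized with full-batch Adam (AMSGrad, learning rate 0.001,
0.97 per-epoch decay, 100 epochs).

The package also ships the surrounding toolchain: a splicing-kinetics
simulator with ground truth (constant rates in closed form, time-dependent
degradation by adaptive Runge–Kutta), the evaluation metrics (overall and
cell-type consistency, continuity/confidence scores, correlation score,
cross-boundary direction score), velocity-graph construction with
confidence-based gene filtering, projection of velocities onto a 2-D
embedding, and driver-gene ranking by pseudotime correlation.

Intended users: computational biologists analysing scRNA-seq with spliced/
unspliced quantifications (H5AD, loom, or MTX inputs), and method
developers who need a transparent, fully-tested numpy implementation with a
built-in simulator.

## Worked example

```bash
python examples/02_train_velocity.py
```

```
training loss: 353.89 (epoch 0) -> -13.72 (epoch 99)
velocity matrix: (300, 20), mean |v| = 1.154
direction score: global 0.687; 100.0% of 110 boundary cells positive
```

The script simulates 300 cells along one lineage (20 genes, 2 with a
degradation rate increasing over time), preprocesses (PCA, 30-NN graph,
neighbor smoothing), trains the GCN for 100 epochs and scores the result.
The loss falls from 353.9 to −13.7 (the Pearson term is negative at
convergence); the direction score then asks, for every cell at the boundary
between consecutive pseudotime bins, whether velocities align with the
displacement toward the later bin — here 100% of the 110 boundary cells are
positive with a mean cosine of 0.687, i.e. the learned field points from
earlier to later developmental states.

The other examples cover the simulator (`01`), the evaluation metrics
(`03`), and the velocity graph / embedding arrows / driver genes (`04`).
A thin CLI mirrors the pipeline:

```bash
velogcn simulate --n-cells 500 --n-genes 30 --out sim.h5ad
velogcn run --input sim.h5ad --seed 0 --out results/
```

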