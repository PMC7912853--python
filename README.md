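# rwrfuse

Multi-omics data integration by **random walk with restart (RWR) on a
multiplex sample network**, for cancer subtyping and related
patient-stratification problems.

Given two or more omics layers measured on the same samples (e.g. mRNA
expression, DNA methylation, miRNA expression), `rwrfuse` builds one sample
similarity network per layer, connects replicas of each sample across layers
into a multiplex network, diffuses from every node with a restart walk, and
fuses the stationary profiles into a single integrated similarity network.
The fused network is then spectral-clustered into subtypes; seven
cluster-validity indexes vote on the number of clusters, and subtypes are
scored with the Dunn index, normalized mutual information (NMI) against a
reference partition, and the log-rank test against survival data.

## Model

Per layer *l*, sample affinity uses the scaled exponential kernel

    S_l(x, y) = exp( −dist²(x, y) / (μ · E(x, y)) ),
    E(x, y)   = [ mean(dist(x, N_x)) + mean(dist(y, N_y)) + dist(x, y) ] / 3,

with `N_x` the *N* = 20 nearest neighbors of *x* and μ = 0.5. The *L* layers
are stacked into a multiplex network whose inter-layer blocks `A_jl` are
either the identity (plain variant, **RWRF**) or a directed neighbor
coupling (**RWRNF**): sample *x* sends weight β = 0.9 to its own replica
("mirror node") and (1−β)/m to the mirrors of its *m* = 10 most similar
neighbors in the source layer.

The walk iterates

    p_{t+1} = (1 − γ) Wᵀ p_t + γ p_0,        γ = 0.7,

where `W` is row-stochastic: within layer *j* the walker stays with
probability λ_j = 1/L along the row-normalized similarities, and jumps to
each other layer along the row-normalized coupling block. Iteration stops
when the L1 difference of successive iterates falls below 1e−10 (typically
15–25 iterations). Running one walk per multiplex node gives per-layer
stationary blocks S′_1 … S′_L, fused as

    S_fusion = Σ_j (S′_j + S′_jᵀ) / (2L).

## Worked example

```python
import rwrfuse as rf

# two noisy views of 200 samples in two linearly separable classes
ds = rf.noisy_two_view_dataset(seed=0)                       # Gaussian + Gamma noise
nets = [rf.similarity_from_features(v) for v in ds.views]    # N=20, mu=0.5

for s in nets:
    labels = rf.spectral_clustering(s.values, k=2, seed=0).labels
    print(s.layer_name, round(rf.nmi(labels, ds.truth_labels), 3))

mx = rf.assemble_multiplex(nets)                             # RWRF coupling
fused = rf.fuse_networks(mx, rf.RWRConfig())                 # gamma=0.7, tol=1e-10
labels = rf.spectral_clustering(fused.s_fusion, k=2, seed=0).labels
print("fused", round(rf.nmi(labels, ds.truth_labels), 3))
```

prints

```
gaussian_noise 0.689
gamma_noise 0.508
fused 0.738
```

Each noisy view alone recovers the two classes only partially (NMI ≈ 0.5–0.7);
the fused network recovers more of the truth than either view, which is the
method's anti-noise claim. The same API handles real data read with
`read_feature_matrix` + `preprocess` (sample intersection, >20 %-missingness
filtering, mean imputation, per-feature standardization).

The same pipeline is available from the shell:

```
rwrfuse simulate --study two-cluster --seed 0 --outdir sim/
rwrfuse run sim/gaussian_noise.tsv sim/gamma_noise.tsv --k 2 --outdir out/
```

which writes `s_fusion.tsv`, `labels.tsv`, `validity_table.tsv`,
`metrics.json`, and a `manifest.json` recording every parameter, seed, and
per-seed iteration count.

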