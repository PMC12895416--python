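# mdcompress

Random nonlinear compression of molecular-dynamics feature spaces.

Agnostic featurizations of biomolecular trajectories are large: all
backbone contacts of a 39-residue protein are already 6786 features, and
pair counts grow quadratically with chain length. Linear reductions (PCA,
TICA) struggle at that input dimension, and training nonlinear models on it
is expensive. `mdcompress` takes a different route: it pushes the
high-dimensional feature matrix **X** (N features × T frames, stored
frame-major) through *untrained*, randomly initialized multilayer networks
and uses the min-max-normalized outputs

g<sup>n</sup>(**X**) = { g₁<sup>(h₁)</sup>(**X**), …, gₙ<sup>(hₙ)</sup>(**X**) },  n ≪ N,

as a compressed feature set for downstream analysis. Each random function
is an ELU-activated feed-forward network with random depth and random layer
widths, Xavier-uniform weights and uniform biases; with no hidden layers
the construction reduces exactly to the classical linear random mapping
x = **M X**, which preserves pairwise distances in the
Johnson–Lindenstrauss sense. Because nothing is trained, compression is
cheap, fully reproducible from a master seed, and free of selection bias —
and ensembles of *independent* networks give less mutually correlated
features than one wide network.

The package is aimed at people building Markov state models or other
kinetic analyses from MD trajectories. It provides

- `features` — distances, exponential contacts c₍ᵢⱼ₎ = exp(−d₍ᵢⱼ₎/d₀),
  backbone φ/ψ dihedrals (plain or branch-cut-shifted), and
  reference-aligned flattened positions, from a PDB topology plus
  coordinate tables;
- `compress` — the random-function compressor as a scikit-learn
  transformer (`RandomProjectionCompressor`), plus the linear baseline;
- `tica` / `msm` — TICA, PCA, k-means state assignment,
  symmetrized-count MSMs, implied timescales vs lag with fixed
  assignment, native-contact fractions and cluster-consistency summaries
  across repeated random trials;
- `synthetic` — a metastable-dynamics generator (hidden Markov chain →
  nonlinear observation in N dimensions) with *analytically known*
  relaxation timescales, plus a toy folded/unfolded protein for
  native-contact tests;
- a `mdcompress` CLI (`synth`, `featurize`, `compress`, `tica`, `msm`,
  `trials`, `run`) for end-to-end seeded pipelines with manifests.

## Worked example

Recover a known relaxation time through the full pipeline — simulate a
two-state hidden chain (λ₂ = 0.98), observe it nonlinearly in 50
dimensions, compress to 10 random functions, and build a 2-state MSM on
the leading TICA component:

```python
import numpy as np
from mdcompress import (two_state_model, simulate_chain, embed, EmbeddingSpec,
                        RandomProjectionCompressor, TICA, assign_states,
                        estimate_msm)

model = two_state_model()                      # lambda_2 = 0.98
print(f"analytic t2: {model.timescales()[0]:.2f} steps")

rng = np.random.default_rng(0)
states = simulate_chain(model, 100_000, rng)   # hidden folding state
X = embed(states, EmbeddingSpec(), rng)        # observed in 50 dimensions

comp = RandomProjectionCompressor(n_components=10, mode="multi_net",
                                  random_state=0)
Z = comp.fit_transform(X.values)               # 10 random functions in [0,1]
print(f"compressed: {Z.shape[1]} features from {X.n_features}")

tica = TICA(lag=10, dim=1).fit(Z)
print(f"leading TICA eigenvalue: {tica.eigenvalues_[0]:.4f}")

labels = assign_states(tica.transform(Z), 2, seed=0)
msm = estimate_msm(labels, lag_frames=10, n_states=2)
print(f"estimated t2: {msm.timescales()[0]:.2f} steps")
print(f"state populations: {np.bincount(labels) / len(labels)}")
```

Output:

```
analytic t2: 49.50 steps
compressed: 10 features from 50
leading TICA eigenvalue: 0.7916
estimated t2: 48.93 steps
state populations: [0.50033 0.49967]
```

The analytic relaxation time of the hidden chain is −1/ln 0.98 ≈ 49.5
steps; the pipeline built on 10 random features recovers 48.9 steps (1.2%
error), and the leading TICA eigenvalue 0.7916 is within a few percent of
λ₂¹⁰ = 0.817 — the gap is the (known, noise-induced) attenuation of the
linear estimator, not a compression artifact. A five-stage version of the
same computation, driven by an INI file with per-stage child seeds and a
manifest, runs as `mdcompress run --config run.ini --seed 0`.

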