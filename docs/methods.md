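# Methods

## The compression model

`mdcompress` compresses an N-dimensional molecular feature space (pair
distances, exponential contacts `c_ij = exp(-d_ij/d0)`, backbone dihedrals,
or reference-aligned positions) to n « N dimensions by pushing the feature
matrix through *untrained* feed-forward networks. One random function is

    g(0)(X) = W(0) X + B(0)                      (input projection, linear)
    g(i)(X) = ELU( W(i) g(i-1)(X) + B(i) )       (i = 1..h hidden layers)
    g(h+1)(X) = W(h+1) g(h)(X) + B(h+1)          (output, linear)

with weights drawn Xavier-uniform on ±sqrt(6/(fan_in+fan_out)) and biases
uniform on a configurable interval (default [-1, 1]). Architectures are
random: the depth h is uniform on a configured range and each hidden layer
width is uniform on [w_min, min(w_max, N)]. The input projection shares the
first hidden layer's width, so a depth-h network carries exactly h sampled
widths. Outputs are min-max normalized to [0, 1] over the fitted data. An
n-dimensional compression stacks n independent single-output networks
(`multi_net`, the default), the n output neurons of one network
(`single_net`), or the classical linear random mapping `x = M X` with
`M ~ N(0, 1/n)` (`linear`).

Because nothing is trained, a compression is fully determined by its master
seed: one child seed is spawned per random function
(`numpy.random.SeedSequence` spawning) and recorded in the output metadata.
A function whose output is constant on the fitted data carries no
information; it is resampled with a fresh child seed, at most 10 times,
after which the compressor raises listing the seeds tried. With no hidden
layers and zero biases the construction collapses, exactly and not
approximately, to the linear random mapping — the test suite asserts
bitwise equality of the two code paths.

Min-max statistics are computed in one pass over the fitted data. Applying
a fitted compressor to new frames can therefore produce values outside
[0, 1]; `clip=True` truncates them, off by default and documented here
rather than silently enabled.

## Validation layers

*TICA.* Time-lagged covariances are estimated from pooled pairs
(x_t, x_{t+τ}) that never straddle trajectory boundaries, with the mean
taken over both pair members, C00 averaged over the head and tail windows,
and C0τ symmetrized as (C + Cᵀ)/2. The generalized problem
C0τ v = λ C00 v is solved by whitening C00 with a relative eigenvalue floor
ε (default 1e-6 of the largest eigenvalue; directions below the floor are
discarded). The symmetric whitened problem guarantees a real spectrum.
Eigenvalues are autocorrelations of their components; implied timescales
are t = -τ/ln λ, with λ ≥ 1 reported as +inf and λ ≤ 0 as NaN. The
estimator is the plain symmetrized one; reversible-MLE reweighting is out
of scope.

*State models.* k-means (scikit-learn, k-means++ seeding, fixed seed) on
the TICA projection supplies discrete states; labels are canonicalized by
descending population so clusters are comparable across trials, and any
externally produced integer labeling can be substituted. Transition counts
use a sliding window at lag τ within each trajectory, are symmetrized as
(C + Cᵀ)/2 and row-normalized. The resulting matrix satisfies detailed
balance with respect to the empirical state weights, so its spectrum (via
the similar symmetric matrix) is real and lies in [-1, 1]. Implied
timescales as a function of lag are computed with the assignment held
fixed, only the counting lag varying.

*Native contacts.* A native contact is a heavy-atom pair at least 3
residues apart closer than 4.5 Å in the reference structure; a frame forms
the contact when its distance is below 1.2× the native distance (hard
count). Q(frame) is the formed fraction. These four numbers are
parameters, not constants; the hard count was chosen over a soft switching
function for transparency, and cluster tables bin mean-Q values against
strictly decreasing boundaries with ties assigned to the higher-Q group.

*Dihedrals.* φ(i) = C(i-1)–N(i)–CA(i)–C(i), ψ(i) = N–CA–C–N(i+1), in
radians on [-π, π) with the sign convention of the common MD analysis
codes (checked against mdtraj in the tests). The "shifted" variant moves
each angle's branch cut to the lower edge of the emptiest bin of a 36-bin
circular histogram, which removes wrap-around artifacts for angles
populated near ±π; shifted values live on a per-angle interval of width
2π. For an R-residue chain the enumeration yields 2(R-1) angles; we report
that count as-is (e.g. 68 for a 35-residue chain) rather than forcing any
externally published tally.

*Alignment.* Least-squares rigid-body superposition (proper rotation
enforced) is delegated to `scipy.spatial.transform.Rotation.align_vectors`,
fitted on a selection and applied to all atoms.

## The synthetic generator

Downstream claims are validated against a generator whose ground truth is
known in closed form: a hidden K-state reversible Markov jump process with
per-step transition matrix T, whose relaxation timescales
t_i = -1/ln λ_i(T) are analytic. Hidden states are observed as
`warp(anchor_s + jitter) + noise` in N dimensions, where the anchors are
random state centroids with a prescribed minimal mutual distance, the warp
is a frozen shallow random network (its own seed, so the observation map
is fixed and smooth), and jitter/noise are i.i.d. Gaussian.

Default study conditions:

| parameter | default | why |
| --- | --- | --- |
| two-state chain | p = 0.01 symmetric | λ₂ = 0.98, t₂ = -1/ln 0.98 ≈ 49.5 steps |
| four-state chain | rates 0.008/0.002/0.024 | timescale hierarchy ≈ (546, 58, 20) steps |
| observed dimension N | 50 | N » K while desk-scale |
| anchor separation | 6.0 | see below |
| jitter & noise SD | 0.15 each | see below |
| warp | random, depth 1 | smooth nonlinear observation |

The separation/noise ratio is chosen to mimic what exponential-contact
features look like across a folding transition: a contact that is formed
in one state and broken in the other changes by ~0.8 with within-state
fluctuation ~0.2. Here the per-dimension state difference is
6/sqrt(50) ≈ 0.85 against a fluctuation of sqrt(2)·0.15 ≈ 0.21 — the same
ratio. This matters because a scalar random function sees the state signal
only through one effective direction (a factor Δ²/N in signal-to-noise),
so an unrealistically noisy generator would misrepresent how the method
behaves on real contact features.

The toy protein emits N/CA/C backbone triplets for each residue: the
folded reference is a compact serpentine on a 3.8/4.0 Å grid (so
sequence-distant residues sit within contact range), the unfolded geometry
is a fully extended chain, and intermediate states interpolate linearly.
It exists to give native-contact analyses a controllable Q spectrum, not
to be physical.

What the generator does *not* emulate: continuous within-basin diffusion
(frames are conditionally i.i.d. given the hidden state, so there are no
fast intrastate relaxation modes), state-dependent noise, long-tailed
feature distributions, or memory effects from projecting out slow solvent
degrees of freedom. Passing tests therefore demonstrate that the
compression preserves *discrete metastable* slow dynamics under a smooth
nonlinear observation with realistic SNR — they do not certify behavior on
trajectories whose slow modes are not well separated from the fast ones.

## Benchmark protocols and problem sizes

`mdcompress.benchmarks` freezes the validation protocols used by the tests
and `scripts/acceptance.py`:

- *Timescale recovery*: 25 master seeds; per seed a 1e5-step two-state
  chain (~2000 barrier crossings, so the sampling SE on t₂ is a few
  percent), embedded at N = 50, compressed with n = 10 independent
  networks (depth 5–20, widths 2–N), TICA at lag 10, k-means into 2
  states, MSM at lag 10. Reported: fraction of seeds with |t₂_est −
  t₂_true|/t₂_true ≤ 10%, and the leading TICA eigenvalue of the
  compressed space against the full-feature value.
- *Variational direction*: t₂ estimates from any state decomposition
  underestimate the true relaxation time, so estimates must not exceed
  truth by more than 3 stochastic SEs. The per-seed SE is a delta-method
  propagation of binomial row-probability variance through
  t = -τ/ln λ₂, with sliding-window counts deflated by τ to an effective
  independent count; approximate, but the right scale.
- *Under-compression*: on the four-state chain (three processes), n = 2
  mixes processes 2 and 3 and reports the smaller second eigenvalue
  compared to n = 30 (11 seeds, 6e4 steps).
- *Decorrelation*: mean |off-diagonal correlation| of multi-network vs
  single-network outputs at n = 30 (20 seeds).
- *JL distortion*: worst pairwise squared-distance distortion of the
  linear map for 100 points, 1000 → 300 dimensions.

Chain lengths and seed counts are sized so the whole battery runs in a few
minutes on one CPU while keeping sampling error well below the tolerances
being checked.

## Numerical choices and degenerate inputs

- TICA regularization ε = 1e-6 (relative); rank-deficient feature sets
  (duplicated columns) reduce rank without changing the retained spectrum.
- MSM estimation refuses lags no trajectory exceeds, constant label
  sequences, and states with zero symmetrized counts, naming the state.
- `implied_timescale` treats λ ≥ 1 as +inf and λ ≤ 0 as NaN (reported,
  with a warning, in lag sweeps).
- k-means refuses K < 2 and fewer distinct points than clusters; ties in
  population-based relabeling break by original label index for
  determinism.
- Min-max normalization refuses constant columns (zero range) rather than
  dividing by zero; the compressor converts that refusal into a resample.
- Pair enumeration is lexicographic and deterministic; dihedral values at
  the ±π boundary are reported as -π (half-open convention).
- All randomness flows from `numpy.random.SeedSequence`; spawned child
  seeds are reduced mod 2³¹ before being handed to scikit-learn.

## Known limitations

- The VAMPnet-style trained soft clustering that motivated the evaluation
  layer is deliberately replaced by TICA + k-means + MSM behind a
  pluggable assignment interface; absolute timescales of real proteins
  from millisecond trajectories are out of scope.
- The symmetrized MSM estimator is biased for strongly non-equilibrium
  data; the generator is reversible by construction, so this does not
  affect the bundled studies.
- Compression fidelity degrades gracefully but measurably for very deep
  narrow networks (width-2 bottlenecks); this is inherent to the sampled
  architecture family, not a defect, and is why several independent
  functions are needed.
- No trajectory-format readers beyond delimited text/NPZ tables and PDB
  structures; upstream MD I/O should go through mdtraj/MDAnalysis and
  export feature tables.
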