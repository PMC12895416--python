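"""Reference studies on the synthetic generator.

These functions bundle the standard validation experiments -- timescale
recovery through the full compress/TICA/MSM pipeline, compression fidelity
of the leading TICA eigenvalue, under-compression process mixing,
multi-network decorrelation, and Johnson-Lindenstrauss distortion of the
linear baseline -- so that tests, scripts and users run the exact same
protocol.  All randomness derives from a single master seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compress import (
    RandomProjectionCompressor,
    feature_correlations,
    linear_random_map,
)
from .msm import assign_states, estimate_msm
from .synthetic import EmbeddingSpec, embed, four_state_model, simulate_chain, two_state_model
from .tica import TICA

__all__ = [
    "two_state_recovery_study",
    "undercompression_study",
    "decorrelation_study",
    "jl_distortion",
]


def _seed_rngs(seed: int, n: int):
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _msm_t2_standard_error(msm, lag: int) -> float:
    """Delta-method SE of t2 = -lag/ln(lambda2) for a 2-state MSM.

    Row transition probabilities get binomial variance with the effective
    (sliding-window-corrected) count n_i / lag; the eigenvalue
    lambda2 = 1 - T01 - T10 then propagates through dt/dlambda.
    Approximate, but adequate as a stochastic error scale.
    """
    T = msm.transition_matrix_
    n_eff = msm.counts_.sum(axis=1) / lag
    var_lam = sum(T[i, 1 - i] * (1 - T[i, 1 - i]) / n_eff[i]
                  for i in range(2))
    lam = msm.eigenvalues_[1]
    if not 0 < lam < 1:
        return np.inf
    dt_dlam = lag / (lam * np.log(lam) ** 2)
    return float(dt_dlam * np.sqrt(var_lam))


def two_state_recovery_study(n_seeds: int = 25, n_steps: int = 100_000,
                             master_seed: int = 0, n_components: int = 10,
                             lag: int = 10) -> pd.DataFrame:
    """Full-pipeline timescale recovery on the two-state generator.

    For each seed: simulate the hidden chain (lambda2 = 0.98), observe it
    in N = 50 dimensions, compress with ``n_components`` independent random
    networks, run TICA at the given lag, cluster the leading component into
    2 states, and estimate the slowest implied timescale from the MSM.
    Also records the leading TICA eigenvalue of the compressed space
    against the full-feature value (compression fidelity).

    Returns a tidy DataFrame with one row per seed.
    """
    model = two_state_model()
    t2_true = float(model.timescales()[0])
    rows = []
    for i in range(n_seeds):
        seed = master_seed + i
        chain_rng, embed_rng = _seed_rngs(seed, 2)
        states = simulate_chain(model, n_steps, chain_rng)
        fm = embed(states, EmbeddingSpec(), embed_rng)

        comp = RandomProjectionCompressor(
            n_components=n_components, mode="multi_net", random_state=seed)
        Z = comp.fit_transform(fm.values)

        tica = TICA(lag=lag, dim=1).fit(Z)
        labels = assign_states(tica.transform(Z), 2, seed=seed)
        msm = estimate_msm(labels, lag, 2)
        t2_est = float(msm.timescales()[0])

        eig_full = float(TICA(lag=lag).fit(fm.values).eigenvalues_[0])
        rows.append({
            "seed": seed,
            "t2_true": t2_true,
            "t2_est": t2_est,
            "t2_rel_err": abs(t2_est - t2_true) / t2_true,
            "t2_se": _msm_t2_standard_error(msm, lag),
            "top_eig_compressed": float(tica.eigenvalues_[0]),
            "top_eig_full": eig_full,
            "eig_ratio": float(tica.eigenvalues_[0]) / eig_full,
        })
    return pd.DataFrame(rows)


def undercompression_study(n_seeds: int = 11, n_steps: int = 60_000,
                           master_seed: int = 0, lag: int = 10,
                           n_small: int = 2,
                           n_large: int = 30) -> pd.DataFrame:
    """Process mixing under too-aggressive compression.

    On the four-state generator (three relaxation processes) the second
    TICA eigenvalue from an n_small-dimensional compression is compared
    with the one from n_large dimensions: with too few random functions
    the second and third processes mix, and the mixture reports the
    smaller eigenvalue.
    """
    model = four_state_model()
    rows = []
    for i in range(n_seeds):
        seed = master_seed + i
        chain_rng, embed_rng = _seed_rngs(seed, 2)
        states = simulate_chain(model, n_steps, chain_rng)
        fm = embed(states, EmbeddingSpec(), embed_rng)
        eigs = {}
        for n in (n_small, n_large):
            Z = RandomProjectionCompressor(
                n_components=n, mode="multi_net",
                random_state=seed).fit_transform(fm.values)
            eigs[n] = TICA(lag=lag).fit(Z).eigenvalues_[:2]
        rows.append({
            "seed": seed,
            "second_eig_small": float(eigs[n_small][1]),
            "second_eig_large": float(eigs[n_large][1]),
        })
    return pd.DataFrame(rows)


def decorrelation_study(n_seeds: int = 20, n_steps: int = 3_000,
                        master_seed: int = 0,
                        n_components: int = 30) -> pd.DataFrame:
    """Multi-network vs single-network output correlation.

    Independent networks give mutually less correlated random functions
    than one wide network; reported as the mean absolute off-diagonal
    Pearson correlation for both constructions, per seed.
    """
    model = two_state_model()
    rows = []
    for i in range(n_seeds):
        seed = master_seed + i
        chain_rng, embed_rng = _seed_rngs(seed, 2)
        states = simulate_chain(model, n_steps, chain_rng)
        fm = embed(states, EmbeddingSpec(), embed_rng)
        corr = {}
        for mode in ("multi_net", "single_net"):
            Z = RandomProjectionCompressor(
                n_components=n_components, mode=mode,
                random_state=seed).fit_transform(fm.values)
            corr[mode] = feature_correlations(Z)
        rows.append({"seed": seed, "multi_net": corr["multi_net"],
                     "single_net": corr["single_net"]})
    return pd.DataFrame(rows)


def jl_distortion(n_points: int = 100, dim: int = 1000, n: int = 300,
                  seed: int = 0) -> float:
    """Worst-case relative distortion of pairwise squared distances under
    the linear random mapping (Johnson-Lindenstrauss check)."""
    from scipy.spatial.distance import pdist

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_points, dim))
    Z = linear_random_map(X, n, rng)
    d_orig = pdist(X) ** 2
    d_proj = pdist(Z) ** 2
    return float(np.abs(d_proj / d_orig - 1.0).max())
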