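"""State decomposition and Markov-state-model analysis.

The evaluation layer for compressed feature spaces: cluster a (TICA)
projection into K states, estimate a row-stochastic transition matrix at a
lag, read off implied timescales as a function of lag with the assignment
held fixed, and characterize clusters by population and mean fraction of
native contacts Q.  The state-assignment step is pluggable -- any per-frame
integer labeling (e.g. from an externally trained network) can be fed to
the downstream operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .compress import DegenerateFunctionError, RandomProjectionCompressor
from .containers import FeatureMatrix
from .tica import TICA, implied_timescale

__all__ = [
    "assign_states",
    "MarkovStateModel",
    "estimate_msm",
    "timescales_vs_lag",
    "NativeContactSet",
    "native_contacts",
    "fraction_native",
    "ClusterSummary",
    "cluster_summary",
    "group_by_contact_fraction",
    "TrialConfig",
    "run_trials",
]


def _canonicalize(labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel so that state 0 is the most populated, descending."""
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    return remap[labels]


def assign_states(projection: np.ndarray, n_states: int,
                  seed: int | None = None) -> np.ndarray:
    """k-means state assignment on a projection, labels by population.

    Deterministic given ``seed``; label 0 is the most populated state.
    """
    X = np.asarray(projection, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if X.shape[0] < n_states:
        raise ValueError("fewer frames than states")
    if np.unique(X, axis=0).shape[0] < n_states:
        raise ValueError(
            f"fewer than {n_states} distinct points; cannot form "
            f"{n_states} clusters")
    km = KMeans(n_clusters=n_states, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return _canonicalize(labels, n_states)


def _count_transitions(dtrajs, lag: int, n_states: int) -> np.ndarray:
    counts = np.zeros((n_states, n_states))
    for d in dtrajs:
        if len(d) <= lag:
            continue
        np.add.at(counts, (d[:-lag], d[lag:]), 1.0)
    return counts


class MarkovStateModel(BaseEstimator):
    """Symmetrized-count MSM estimated from discrete trajectories.

    Transition counts use a sliding window at the given lag and never cross
    trajectory boundaries; counts are symmetrized as (C + C^T)/2 before row
    normalization, which enforces detailed balance with respect to the
    empirical state frequencies and guarantees a real spectrum in [-1, 1].

    Attributes
    ----------
    counts_ : symmetrized count matrix
    transition_matrix_ : row-stochastic transition matrix
    eigenvalues_ : descending, real
    stationary_distribution_ : left eigenvector at eigenvalue 1
    """

    def __init__(self, lag: int = 1, n_states: int | None = None,
                 timestep_ns: float = 1.0):
        self.lag = lag
        self.n_states = n_states
        self.timestep_ns = timestep_ns

    def fit(self, dtrajs, y=None):
        if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
            dtrajs = [dtrajs]
        dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not any(len(d) > self.lag for d in dtrajs):
            raise ValueError("no trajectory longer than the lag")
        k = self.n_states
        if k is None:
            k = int(max(d.max() for d in dtrajs)) + 1
        if k < 2:
            raise ValueError("need at least 2 states (constant labels?)")
        raw = _count_transitions(dtrajs, self.lag, k)
        counts = 0.5 * (raw + raw.T)
        rows = counts.sum(axis=1)
        empty = np.flatnonzero(rows == 0)
        if empty.size:
            raise ValueError(
                f"state(s) {empty.tolist()} have no transition counts at "
                f"lag {self.lag}")
        T = counts / rows[:, None]
        # detailed balance w.r.t. pi ~ row sums => similar to a symmetric
        # matrix; use that to get a guaranteed-real sorted spectrum
        pi = rows / rows.sum()
        S = np.sqrt(pi)[:, None] * T / np.sqrt(pi)[None, :]
        w = np.linalg.eigvalsh(0.5 * (S + S.T))[::-1]
        self.counts_ = counts
        self.transition_matrix_ = T
        self.eigenvalues_ = w
        self.stationary_distribution_ = pi
        self.n_states_ = k
        return self

    def timescales(self) -> np.ndarray:
        """Implied timescales (ns) of the nontrivial eigenvalues."""
        tau = self.lag * self.timestep_ns
        return np.array([implied_timescale(float(l), tau)
                         for l in self.eigenvalues_[1:]])


def estimate_msm(dtrajs, lag_frames: int, n_states: int | None = None,
                 timestep_ns: float = 1.0) -> MarkovStateModel:
    """Functional wrapper: fit a MarkovStateModel at one lag."""
    return MarkovStateModel(lag=lag_frames, n_states=n_states,
                            timestep_ns=timestep_ns).fit(dtrajs)


def timescales_vs_lag(dtrajs, lag_list, n_states: int | None = None,
                      timestep_ns: float = 1.0) -> pd.DataFrame:
    """Implied timescales over a list of lags with the assignment fixed.

    The discrete assignment is *not* recomputed per lag: only the transition
    counting changes, mirroring the fixed-assignment protocol used when a
    decomposition is trained at one lag and validated across lags.  Returns
    a tidy table with columns lag_frames, lag_ns, process (2 = slowest),
    timescale_ns; non-positive eigenvalues yield NaN with a warning.
    """
    rows = []
    for lag in lag_list:
        msm = estimate_msm(dtrajs, lag, n_states, timestep_ns)
        ts = msm.timescales()
        if np.any(np.isnan(ts)):
            warnings.warn(f"non-positive eigenvalue at lag {lag}; "
                          "timescale reported as NaN")
        for i, t in enumerate(ts, start=2):
            rows.append({"lag_frames": lag, "lag_ns": lag * timestep_ns,
                         "process": i, "timescale_ns": t})
    return pd.DataFrame(rows)


@dataclass
class NativeContactSet:
    """Reference-structure contacts used for fraction-of-native-contacts Q."""

    pairs: np.ndarray              # (M, 2) atom indices
    native_distances: np.ndarray   # (M,) Angstrom
    cutoff: float
    margin: float
    min_residue_separation: int


def native_contacts(reference: np.ndarray, topology, cutoff: float = 4.5,
                    min_residue_separation: int = 3,
                    margin: float = 1.2) -> NativeContactSet:
    """Heavy-atom pairs in contact in the reference (native) structure.

    A native contact is a heavy-atom pair at least
    ``min_residue_separation`` residues apart whose reference distance is
    below ``cutoff`` Angstrom.  ``margin`` is stored as the formation
    criterion used later: a contact counts as formed in a frame when its
    distance is below margin times the native distance.
    """
    reference = np.asarray(reference, dtype=np.float64)
    idx = topology.select("heavy")
    res = topology.residue_ids[idx]
    ii, jj = np.triu_indices(len(idx), k=1)
    sep_ok = np.abs(res[jj] - res[ii]) >= min_residue_separation
    ai, aj = idx[ii[sep_ok]], idx[jj[sep_ok]]
    d = np.linalg.norm(reference[ai] - reference[aj], axis=1)
    near = d < cutoff
    if not np.any(near):
        raise ValueError(
            f"no native contacts below cutoff {cutoff} A; try a larger "
            f"cutoff or smaller residue separation")
    return NativeContactSet(np.column_stack([ai[near], aj[near]]), d[near],
                            cutoff, margin, min_residue_separation)


def fraction_native(frames: np.ndarray,
                    contact_set: NativeContactSet) -> np.ndarray:
    """Per-frame fraction of native contacts Q in [0, 1] (hard count).

    Q(t) = |{(i,j): d_ij(t) < margin * d_ij(native)}| / M.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    p = contact_set.pairs
    diff = frames[:, p[:, 0], :] - frames[:, p[:, 1], :]
    d = np.sqrt(np.einsum("tpk,tpk->tp", diff, diff))
    formed = d < contact_set.margin * contact_set.native_distances
    return formed.mean(axis=1)


@dataclass
class ClusterSummary:
    """Per-cluster population and mean native-contact fraction, one trial."""

    populations: np.ndarray    # descending, sums to 1
    mean_q: np.ndarray         # aligned with populations (NaN if no Q given)
    trial_id: int = 0


def cluster_summary(assignment: np.ndarray, q_per_frame=None,
                    trial_id: int = 0) -> ClusterSummary:
    """Population fraction and mean Q per cluster, ordered by population."""
    labels = np.asarray(assignment, dtype=np.int64)
    k = labels.max() + 1
    counts = np.bincount(labels, minlength=k).astype(float)
    if q_per_frame is None:
        mean_q = np.full(k, np.nan)
    else:
        q = np.asarray(q_per_frame, dtype=np.float64)
        if len(q) != len(labels):
            raise ValueError("assignment and Q lengths differ")
        mean_q = np.array([q[labels == s].mean() if counts[s] else np.nan
                           for s in range(k)])
    order = np.argsort(-counts, kind="stable")
    return ClusterSummary(counts[order] / counts.sum(), mean_q[order],
                          trial_id)


def group_by_contact_fraction(summaries, boundaries) -> pd.DataFrame:
    """Bin clusters from many trials into groups by their mean Q.

    ``boundaries`` must be strictly decreasing contact fractions; group g
    collects clusters with boundaries[g-1] > Q >= boundaries[g] (group 0 is
    the most native).  A cluster exactly on a boundary joins the higher-Q
    group.  Returns per-group population statistics (median and
    interquartile range of the per-trial summed population) across trials.
    """
    boundaries = list(boundaries)
    if any(b1 <= b2 for b1, b2 in zip(boundaries[:-1], boundaries[1:])):
        raise ValueError("boundaries must be strictly decreasing")
    n_groups = len(boundaries) + 1
    per_trial = {}
    for s in summaries:
        groups = np.array([int(np.sum(q < np.asarray(boundaries)))
                           for q in s.mean_q])
        pops = np.zeros(n_groups)
        for g, p in zip(groups, s.populations):
            pops[g] += p
        per_trial[s.trial_id] = pops
    mat = np.array(list(per_trial.values()))
    q25, q50, q75 = np.percentile(mat, [25, 50, 75], axis=0)
    return pd.DataFrame({
        "group": np.arange(n_groups),
        "population_median": q50,
        "population_iqr": q75 - q25,
        "mean_population": mat.mean(axis=0),
        "n_trials": len(per_trial),
    })


@dataclass
class TrialConfig:
    """Configuration of a multi-trial compression/decomposition study."""

    n_trials: int = 50
    n_components: int = 10
    mode: str = "multi_net"
    depth_range: tuple = (5, 20)
    width_range: tuple = (2, None)
    bias_range: tuple = (-1.0, 1.0)
    tica_lag: int = 10
    n_states: int = 2
    msm_lags: tuple = (10,)
    projection_dim: int | None = None   # default: n_states - 1
    master_seed: int | None = None
    timestep_ns: float = 1.0


@dataclass
class TrialResults:
    """Aggregated outcome of run_trials."""

    timescales: pd.DataFrame          # per trial/lag/process
    timescale_mean: pd.DataFrame      # mean and SD across trials
    summaries: list = field(default_factory=list)
    child_seeds: list = field(default_factory=list)
    failures: list = field(default_factory=list)


def run_trials(features, config: TrialConfig, q_per_frame=None) -> TrialResults:
    """Repeat compress -> TICA -> k-means -> MSM with fresh random functions.

    Each trial draws a new child seed from the master seed, builds a fresh
    compressed feature space, and re-runs the downstream decomposition;
    reported timescales are aggregated as mean +- SD across trials.  Failed
    trials (e.g. a state lost at a long lag) are recorded and excluded; the
    run aborts if more than half the trials fail.
    """
    if config.n_trials < 1:
        raise ValueError("need at least one trial")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    seed_seq = np.random.SeedSequence(config.master_seed)
    rows, summaries, child_seeds, failures = [], [], [], []
    proj_dim = config.projection_dim or max(1, config.n_states - 1)
    for trial in range(config.n_trials):
        child = seed_seq.spawn(1)[0]
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        child_seeds.append(seed)
        try:
            comp = RandomProjectionCompressor(
                n_components=config.n_components, mode=config.mode,
                depth_range=config.depth_range,
                width_range=config.width_range,
                bias_range=config.bias_range, random_state=seed)
            Z = comp.fit_transform(X)
            tica = TICA(lag=config.tica_lag, dim=proj_dim).fit(Z)
            proj = tica.transform(Z)
            labels = assign_states(proj, config.n_states, seed=seed % 2**31)
            for lag in config.msm_lags:
                msm = estimate_msm(labels, lag, config.n_states,
                                   config.timestep_ns)
                for i, t in enumerate(msm.timescales(), start=2):
                    rows.append({"trial": trial, "lag_frames": lag,
                                 "process": i, "timescale_ns": t})
            summaries.append(cluster_summary(labels, q_per_frame, trial))
        except (ValueError, DegenerateFunctionError) as exc:
            warnings.warn(f"trial {trial} failed: {exc}")
            failures.append((trial, str(exc)))
    if len(failures) > config.n_trials / 2:
        raise RuntimeError(
            f"{len(failures)}/{config.n_trials} trials failed; aborting")
    ts = pd.DataFrame(rows)
    agg = (ts.groupby(["lag_frames", "process"])["timescale_ns"]
             .agg(["mean", "std"]).reset_index())
    return TrialResults(ts, agg, summaries, child_seeds, failures)
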