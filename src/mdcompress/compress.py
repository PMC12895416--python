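"""Random projections of feature spaces: linear random mappings and
untrained multilayer ("random function") compressors.

A random function is a feed-forward network that is *never trained*: its
weights are Xavier-uniform samples, its biases uniform samples, and the
high-dimensional feature matrix is simply pushed through it.  An
n-dimensional compressed feature space is the min-max-normalized output of
n such functions -- either n independent single-output networks
(``multi_net``) or one network with n output neurons (``single_net``).
With no hidden layers and zero biases the construction reduces exactly to
the classical linear random-mapping method x = M X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FeatureMatrix

__all__ = [
    "NetworkArchitecture",
    "RandomNetwork",
    "RandomProjectionCompressor",
    "DegenerateFunctionError",
    "sample_architecture",
    "init_network",
    "elu",
    "forward",
    "minmax_normalize",
    "linear_random_map",
    "feature_correlations",
    "compress",
]


class DegenerateFunctionError(ValueError):
    """A random function produced a constant output on the supplied data."""


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x >= 0, alpha*(exp(x) - 1) below."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=np.float64)
    return np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


@dataclass(frozen=True)
class NetworkArchitecture:
    """Shape of one random function network.

    ``depth`` counts the ELU-activated hidden layers.  The first affine map
    (the unactivated input projection) has width ``input_width``; sampled
    architectures set it equal to the first hidden width so a depth-h
    network carries exactly h sampled widths.  ``layer_dims`` lists the
    dimensions the affine maps chain through; a depth-0 network is a single
    affine map and is mathematically a linear random mapping.
    """

    input_dim: int
    output_dim: int
    depth: int
    widths: tuple
    input_width: int

    def __post_init__(self):
        if self.depth != len(self.widths):
            raise ValueError("widths must have one entry per hidden layer")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")

    @property
    def layer_dims(self) -> list[int]:
        if self.depth == 0:
            return [self.input_dim, self.output_dim]
        return [self.input_dim, self.input_width, *self.widths,
                self.output_dim]


@dataclass
class RandomNetwork:
    """Frozen weights/biases of one random function, plus its provenance."""

    weights: list        # W_i, shape (fan_out, fan_in)
    biases: list         # b_i, shape (fan_out,)
    architecture: NetworkArchitecture
    elu_alpha: float = 1.0
    seed: int | None = None

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return forward(self, X)


def sample_architecture(input_dim: int, rng: np.random.Generator,
                        depth_range=(5, 20), width_range=(2, None),
                        output_dim: int = 1) -> NetworkArchitecture:
    """Draw a random architecture: uniform depth, independent uniform widths.

    ``width_range=(lo, None)`` means widths up to the input dimension, the
    default used for contact feature spaces.  If the input dimension is
    smaller than the requested lower width, the range is clamped to
    [2, input_dim] with a warning.
    """
    if input_dim < 2:
        raise ValueError("input_dim must be >= 2")
    h_lo, h_hi = depth_range
    if not (1 <= h_lo <= h_hi):
        raise ValueError(f"bad depth range {depth_range}")
    w_lo, w_hi = width_range
    w_hi = input_dim if w_hi is None else min(int(w_hi), input_dim)
    if input_dim < w_lo:
        warnings.warn(
            f"input_dim {input_dim} below width minimum {w_lo}; "
            f"clamping width range to [2, {input_dim}]")
        w_lo, w_hi = 2, input_dim
    if w_lo > w_hi:
        raise ValueError(f"empty width range [{w_lo}, {w_hi}]")
    depth = int(rng.integers(h_lo, h_hi + 1))
    widths = tuple(int(w) for w in rng.integers(w_lo, w_hi + 1, size=depth))
    # the unactivated input projection shares the first hidden width, so a
    # depth-h network has exactly h sampled widths
    return NetworkArchitecture(input_dim, output_dim, depth, widths,
                               input_width=widths[0])


def init_network(architecture: NetworkArchitecture, rng: np.random.Generator,
                 bias_range=(-1.0, 1.0), elu_alpha: float = 1.0,
                 seed: int | None = None) -> RandomNetwork:
    """Initialize weights Xavier-uniform and biases uniform on bias_range.

    Per layer with fan_in inputs and fan_out outputs, weights are uniform on
    [-a, a] with a = sqrt(6 / (fan_in + fan_out)), so the weight variance is
    a^2/3 = 2/(fan_in + fan_out) -- the Glorot scaling that keeps layer
    output variances comparable through an untrained network.
    """
    b_lo, b_hi = bias_range
    if not b_lo < b_hi:
        raise ValueError(f"bad bias range {bias_range}")
    weights, biases = [], []
    dims = architecture.layer_dims
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
        biases.append(rng.uniform(b_lo, b_hi, size=fan_out))
    return RandomNetwork(weights, biases, architecture, elu_alpha, seed)


def forward(network: RandomNetwork, X: np.ndarray) -> np.ndarray:
    """Push a (T, N) feature matrix through the network; returns (T, out).

    The first affine map carries no activation, each of the ``depth`` hidden
    layers is followed by an ELU, and the final map is again purely affine.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    n_in = network.architecture.input_dim
    if X.shape[1] != n_in:
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns but network expects "
            f"{n_in}")
    n_maps = len(network.weights)
    h = X
    for i, (W, b) in enumerate(zip(network.weights, network.biases)):
        h = h @ W.T + b
        if 0 < i < n_maps - 1:          # hidden layers only
            h = elu(h, network.elu_alpha)
    return h


def minmax_normalize(values: np.ndarray, atol: float = 1e-12):
    """Rescale each column to [0, 1] via (x - min) / (max - min).

    Raises :class:`DegenerateFunctionError` if any column is constant
    (zero range), naming the offending columns; callers resample the
    corresponding random function instead of emitting an uninformative
    constant feature.
    """
    values = np.asarray(values, dtype=np.float64)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    if values.shape[0] < 2:
        raise ValueError("min-max normalization needs at least 2 frames")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    bad = np.flatnonzero(span <= atol * np.maximum(1.0, np.abs(hi)))
    if bad.size:
        raise DegenerateFunctionError(
            f"constant column(s) {bad.tolist()}: min == max")
    out = (values - lo) / span
    return (out[:, 0], lo[0], span[0]) if squeeze else (out, lo, span)


def linear_random_map(X: np.ndarray, n: int, rng: np.random.Generator,
                      matrix: np.ndarray | None = None) -> np.ndarray:
    """Classical linear random mapping x = M X (frame-major: X @ M.T).

    M has standard-normal entries scaled by 1/sqrt(n), so its columns are
    mean-free with unit expected squared norm and the map preserves pairwise
    distances in the Johnson-Lindenstrauss sense when n is large enough.
    A pre-built ``matrix`` may be injected (used by tests).
    """
    X = np.asarray(X, dtype=np.float64)
    N = X.shape[1]
    if n > N:
        warnings.warn(f"target dimension {n} exceeds input dimension {N}")
    if matrix is None:
        matrix = rng.standard_normal((n, N)) / np.sqrt(n)
    return X @ np.asarray(matrix).T


def feature_correlations(values: np.ndarray, return_matrix: bool = False):
    """Mean absolute off-diagonal Pearson correlation across columns."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    stds = values.std(axis=0)
    bad = np.flatnonzero(stds == 0)
    if bad.size:
        raise ValueError(f"constant column(s) {bad.tolist()}")
    corr = np.corrcoef(values, rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    mean_abs = float(np.mean(np.abs(off)))
    return (mean_abs, corr) if return_matrix else mean_abs


class RandomProjectionCompressor(TransformerMixin, BaseEstimator):
    """Compress a feature space with untrained random networks.

    scikit-learn style transformer.  ``fit`` samples the random functions
    and records the min-max statistics of their outputs on the fitted data;
    ``transform`` pushes data through the frozen functions and rescales with
    those statistics.  Constant-output functions are resampled with a fresh
    child seed (they carry no information), up to ``max_retries`` times.

    Parameters
    ----------
    n_components : int
        Compressed dimension n.
    mode : {"multi_net", "single_net", "linear"}
        n independent single-output networks, one n-output network, or the
        linear random-mapping baseline.
    depth_range : (int, int)
        Uniform range for the number of ELU hidden layers.
    width_range : (int, int or None)
        Uniform range for layer widths; ``None`` means the input dimension.
    bias_range : (float, float)
        Uniform support for bias initialization.
    elu_alpha : float
        ELU saturation parameter.
    clip : bool
        Clip transformed values of *new* data into [0, 1] (values outside
        the fitted min/max range otherwise map outside the unit interval).
    random_state : int or None
        Master seed; one child seed is spawned per random function.

    Attributes
    ----------
    networks_ : list of RandomNetwork (empty in linear mode)
    matrix_ : ndarray (linear mode only)
    data_min_, data_range_ : per-column normalization statistics
    function_meta_ : list of dict, per-function seed and architecture
    """

    def __init__(self, n_components: int = 10, mode: str = "multi_net",
                 depth_range=(5, 20), width_range=(2, None),
                 bias_range=(-1.0, 1.0), elu_alpha: float = 1.0,
                 clip: bool = False, max_retries: int = 10,
                 random_state: int | None = None):
        self.n_components = n_components
        self.mode = mode
        self.depth_range = depth_range
        self.width_range = width_range
        self.bias_range = bias_range
        self.elu_alpha = elu_alpha
        self.clip = clip
        self.max_retries = max_retries
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _raw_outputs(self, X: np.ndarray) -> np.ndarray:
        if self.mode == "linear":
            return X @ self.matrix_.T
        cols = [forward(net, X) for net in self.networks_]
        return np.column_stack(cols)

    def _spawn(self, seed_seq: np.random.SeedSequence):
        child = seed_seq.spawn(1)[0]
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        return np.random.default_rng(child), seed

    def _sample_function(self, X, seed_seq, output_dim):
        """Sample one random function, resampling degenerate ones."""
        tried = []
        for _ in range(self.max_retries + 1):
            rng, seed = self._spawn(seed_seq)
            arch = sample_architecture(
                X.shape[1], rng, self.depth_range, self.width_range,
                output_dim=output_dim)
            net = init_network(arch, rng, self.bias_range, self.elu_alpha,
                               seed=seed)
            out = forward(net, X)
            span = out.max(axis=0) - out.min(axis=0)
            if np.all(span > 1e-12 * np.maximum(1.0, np.abs(out).max(axis=0))):
                return net, out
            tried.append(seed)
        raise DegenerateFunctionError(
            f"constant random-function output after {self.max_retries} "
            f"retries (child seeds tried: {tried})")

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 frames to fit")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        seed_seq = np.random.SeedSequence(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.networks_ = []
        self.function_meta_ = []

        if self.mode == "linear":
            rng, seed = self._spawn(seed_seq)
            self.matrix_ = rng.standard_normal(
                (self.n_components, X.shape[1])) / np.sqrt(self.n_components)
            raw = X @ self.matrix_.T
            self.function_meta_.append({"mode": "linear", "seed": seed})
        elif self.mode == "single_net":
            net, raw = self._sample_function(X, seed_seq, self.n_components)
            self.networks_ = [net]
            self.function_meta_.append(self._meta(net))
        elif self.mode == "multi_net":
            raw_cols = []
            for _ in range(self.n_components):
                net, out = self._sample_function(X, seed_seq, 1)
                self.networks_.append(net)
                self.function_meta_.append(self._meta(net))
                raw_cols.append(out)
            raw = np.column_stack(raw_cols)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

        normalized, lo, span = minmax_normalize(raw)
        self.data_min_, self.data_range_ = lo, span
        self._fit_output = normalized
        return self

    def transform(self, X):
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, compressor was fitted on "
                f"{self.n_features_in_}")
        out = (self._raw_outputs(X) - self.data_min_) / self.data_range_
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self._fit_output

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _validate(X):
        if isinstance(X, FeatureMatrix):
            X = X.values
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (frames x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    @staticmethod
    def _meta(net: RandomNetwork) -> dict:
        a = net.architecture
        return {"mode": "network", "seed": net.seed, "depth": a.depth,
                "widths": list(a.widths), "input_width": a.input_width,
                "output_dim": a.output_dim}


def compress(feature_matrix: FeatureMatrix, n_components: int,
             mode: str = "multi_net", random_state: int | None = None,
             **kwargs) -> FeatureMatrix:
    """One-shot functional wrapper around RandomProjectionCompressor."""
    comp = RandomProjectionCompressor(
        n_components=n_components, mode=mode, random_state=random_state,
        **kwargs)
    values = comp.fit_transform(feature_matrix)
    labels = [f"g{i}" for i in range(n_components)]
    ts = (feature_matrix.timestep_ns
          if isinstance(feature_matrix, FeatureMatrix) else 1.0)
    return FeatureMatrix(values, labels, ts,
                         {"functions": comp.function_meta_, "mode": mode,
                          "master_seed": random_state})
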