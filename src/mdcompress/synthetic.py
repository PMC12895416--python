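"""Synthetic metastable dynamics with analytically known relaxation times.

A hidden K-state Markov jump process with a known reversible transition
matrix is observed through a fixed nonlinear map into N >> K dimensions
with additive Gaussian noise.  Because the hidden chain's spectrum is known
in closed form, every downstream estimate (TICA eigenvalues, MSM implied
timescales) can be checked against ground truth.  A toy "protein"
coordinate generator with distinct folded/unfolded geometries supports
native-contact analyses without any external trajectory data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compress import NetworkArchitecture, forward, init_network
from .containers import FeatureMatrix
from .features import Topology

__all__ = [
    "MetastableModel",
    "two_state_model",
    "four_state_model",
    "simulate_chain",
    "analytic_timescales",
    "EmbeddingSpec",
    "embed",
    "make_toy_protein",
    "polyalanine_pdb",
    "alanine_dipeptide_pdb",
]


@dataclass
class MetastableModel:
    """Hidden K-state Markov jump process with a per-step transition matrix."""

    transition_matrix: np.ndarray
    step_time_ns: float = 1.0

    def __post_init__(self):
        T = np.asarray(self.transition_matrix, dtype=np.float64)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows must be nonnegative and sum to 1")
        self.transition_matrix = T

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def stationary_distribution(self) -> np.ndarray:
        w, V = np.linalg.eig(self.transition_matrix.T)
        i = np.argmin(np.abs(w - 1.0))
        pi = np.real(V[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def eigenvalues(self) -> np.ndarray:
        """Real descending spectrum; rejects non-reversible generators."""
        T = self.transition_matrix
        pi = self.stationary_distribution
        flux = pi[:, None] * T
        if not np.allclose(flux, flux.T, atol=1e-10):
            raise ValueError("transition matrix violates detailed balance; "
                             "analytic timescales require a reversible chain")
        S = np.sqrt(pi)[:, None] * T / np.sqrt(pi)[None, :]
        return np.linalg.eigvalsh(0.5 * (S + S.T))[::-1]

    def timescales(self) -> np.ndarray:
        """Analytic implied timescales t_i = -step/ln(lambda_i), i >= 2."""
        return analytic_timescales(self)


def two_state_model(p12: float = 0.01, p21: float = 0.01,
                    step_time_ns: float = 1.0) -> MetastableModel:
    """Two-state chain; lambda_2 = 1 - p12 - p21 in closed form.

    The default symmetric p = 0.01 gives lambda_2 = 0.98 and a relaxation
    time of -1/ln(0.98) ~= 49.5 steps.
    """
    T = np.array([[1 - p12, p12], [p21, 1 - p21]])
    return MetastableModel(T, step_time_ns)


def four_state_model(step_time_ns: float = 1.0) -> MetastableModel:
    """Default benchmark: linear 4-state chain, timescales ~(546, 58, 20).

    Two fast-exchanging pairs separated by a slow barrier, echoing a
    folded / intermediate / unfolded hierarchy with one dominant slow
    process and two faster ones.
    """
    a, b, c = 0.008, 0.002, 0.024
    T = np.array([
        [1 - a, a, 0, 0],
        [a, 1 - a - b, b, 0],
        [0, b, 1 - b - c, c],
        [0, 0, c, 1 - c],
    ])
    return MetastableModel(T, step_time_ns)


def simulate_chain(model: MetastableModel, n_steps: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample a hidden state path, starting from the stationary law."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    cdf = np.cumsum(model.transition_matrix, axis=1)
    cdf[:, -1] = 1.0
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = rng.choice(model.n_states, p=model.stationary_distribution)
    u = rng.random(n_steps)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t])
    return states


def analytic_timescales(model: MetastableModel) -> np.ndarray:
    """Closed-form relaxation times of the generator, slowest first (ns)."""
    lams = model.eigenvalues()[1:]
    out = np.full(len(lams), np.inf)
    pos = lams > 0
    out[pos & (lams < 1)] = (-model.step_time_ns
                             / np.log(lams[pos & (lams < 1)]))
    out[lams <= 0] = np.nan
    return out


@dataclass
class EmbeddingSpec:
    """How hidden states are observed in N dimensions.

    Each state has an anchor vector in R^N; a frame in state s is observed
    as warp(anchor_s + within-state jitter) + observation noise.  The warp
    is a frozen random shallow network (its own seed), so the observation
    map is smooth, nonlinear and identical across calls; ``warp_depth=0``
    or ``warp="identity"`` disables it.
    """

    n_features: int = 50
    anchors: np.ndarray | None = None       # (K, N); generated if None
    anchor_separation: float = 6.0          # pairwise distance scale
    jitter_sd: float = 0.15
    noise_sd: float = 0.15
    warp: str = "random"                    # "random" | "identity"
    warp_depth: int = 1
    warp_seed: int = 7_777

    def make_anchors(self, n_states: int,
                     rng: np.random.Generator) -> np.ndarray:
        """Random directions rescaled to the requested mutual separation."""
        if self.anchors is not None:
            A = np.asarray(self.anchors, dtype=np.float64)
            if A.shape[0] < n_states:
                raise ValueError("not enough anchors for the chain's states")
            return A[:n_states]
        if self.n_features < n_states:
            raise ValueError("observed dimension must be >= number of states")
        A = rng.standard_normal((n_states, self.n_features))
        A -= A.mean(axis=0)
        # rescale so the smallest pairwise anchor distance hits the target
        dmin = min(np.linalg.norm(A[i] - A[j])
                   for i in range(n_states) for j in range(i + 1, n_states))
        return A * (self.anchor_separation / dmin)

    def make_warp(self):
        if self.warp == "identity" or self.warp_depth == 0:
            return None
        if self.warp != "random":
            raise ValueError(f"unknown warp {self.warp!r}")
        wrng = np.random.default_rng(self.warp_seed)
        N = self.n_features
        arch = NetworkArchitecture(
            input_dim=N, output_dim=N, depth=self.warp_depth,
            widths=(N,) * self.warp_depth, input_width=N)
        return init_network(arch, wrng, seed=self.warp_seed)


def embed(states: np.ndarray, spec: EmbeddingSpec,
          rng: np.random.Generator,
          timestep_ns: float = 1.0) -> FeatureMatrix:
    """Observe a hidden state path in N-dimensional feature space."""
    states = np.asarray(states, dtype=np.int64)
    n_states = int(states.max()) + 1
    anchors = spec.make_anchors(n_states, rng)
    latent = anchors[states]
    if spec.jitter_sd > 0:
        latent = latent + spec.jitter_sd * rng.standard_normal(latent.shape)
    warp_net = spec.make_warp()
    observed = latent if warp_net is None else forward(warp_net, latent)
    if spec.noise_sd > 0:
        observed = observed + spec.noise_sd * rng.standard_normal(observed.shape)
    return FeatureMatrix(observed, None, timestep_ns,
                         {"n_states": n_states, "warp": spec.warp,
                          "warp_depth": spec.warp_depth, "anchors": anchors})


# ---------------------------------------------------------------------------
# toy protein geometry
# ---------------------------------------------------------------------------

def _folded_backbone(n_residues: int) -> np.ndarray:
    """Compact serpentine fold: CA atoms on a 3-D grid, 3.8 A apart.

    Rows of 4 residues alternate direction within 4.0 A-spaced layers, so
    residues far apart in sequence sit within native-contact range -- a
    deliberately simple stand-in for a collapsed globule.
    """
    row_len, spacing, row_gap, layer_gap = 4, 3.8, 4.0, 4.0
    coords = np.empty((n_residues, 3))
    per_layer = row_len * row_len
    for r in range(n_residues):
        layer, rem = divmod(r, per_layer)
        row, col = divmod(rem, row_len)
        if row % 2 == 1:
            col = row_len - 1 - col
        coords[r] = (col * spacing, row * row_gap, layer * layer_gap)
    return coords


def _extended_backbone(n_residues: int) -> np.ndarray:
    """Fully extended chain along x, 3.8 A per residue."""
    coords = np.zeros((n_residues, 3))
    coords[:, 0] = 3.8 * np.arange(n_residues)
    return coords


def _backbone_atoms(ca: np.ndarray) -> np.ndarray:
    """Expand CA positions to N, CA, C triplets offset along the chain."""
    n = len(ca)
    tangents = np.zeros_like(ca)
    tangents[1:-1] = ca[2:] - ca[:-2]
    tangents[0] = ca[1] - ca[0]
    tangents[-1] = ca[-1] - ca[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    atoms = np.empty((3 * n, 3))
    atoms[0::3] = ca - 1.2 * tangents      # N
    atoms[1::3] = ca                       # CA
    atoms[2::3] = ca + 1.2 * tangents      # C
    return atoms


def toy_protein_topology(n_residues: int) -> Topology:
    """Backbone-only (N, CA, C) heavy-atom topology for the toy protein."""
    names = np.array(["N", "CA", "C"] * n_residues, dtype=object)
    res = np.repeat(np.arange(1, n_residues + 1), 3)
    return Topology(names, res, np.ones(3 * n_residues, dtype=bool))


def make_toy_protein(n_residues: int, state_sequence: np.ndarray,
                     rng: np.random.Generator, n_states: int | None = None,
                     jitter_sd: float = 0.1):
    """Trajectory of a toy protein driven by a hidden folding state.

    State 0 emits frames jittering around a compact folded reference,
    the highest state emits an extended chain, and intermediate states
    interpolate linearly between the two geometries.

    Returns
    -------
    frames : ndarray (T, 3*n_residues, 3), Angstrom
    reference : ndarray (3*n_residues, 3), the folded mean structure
    topology : Topology
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    states = np.asarray(state_sequence, dtype=np.int64)
    k = n_states if n_states is not None else int(states.max()) + 1
    k = max(k, 2)
    folded = _backbone_atoms(_folded_backbone(n_residues))
    extended = _backbone_atoms(_extended_backbone(n_residues))
    frac = states / (k - 1)
    frames = ((1.0 - frac)[:, None, None] * folded
              + frac[:, None, None] * extended)
    frames = frames + jitter_sd * rng.standard_normal(frames.shape)
    return frames, folded.copy(), toy_protein_topology(n_residues)


# ---------------------------------------------------------------------------
# small synthetic PDB writers (fixtures are generated, never stored)
# ---------------------------------------------------------------------------

def _write_pdb(path, atoms) -> str:
    """Write (name, element, res_name, res_id, xyz) tuples to PDB via biotite."""
    import io

    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    array = struc.AtomArray(len(atoms))
    for i, (name, element, res_name, res_id, xyz) in enumerate(atoms):
        array[i] = struc.Atom(np.asarray(xyz, dtype=float), chain_id="A",
                              res_id=int(res_id), res_name=res_name,
                              atom_name=name, element=element)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    buf = io.StringIO()
    pdb_file.write(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def polyalanine_pdb(n_residues: int, path=None) -> str:
    """Synthetic extended poly-alanine PDB (N, CA, C, O, CB per residue).

    Coordinates are an idealized extended chain; the file exists to exercise
    structure parsing and pair accounting, not to be physically accurate.
    """
    # N and C sit slightly off the chain axis so backbone selections are
    # never collinear (keeps rigid-body superposition well defined)
    offsets = {"N": (-1.2, 0.4, 0.0), "CA": (0.0, 0.0, 0.3),
               "C": (1.2, 0.4, 0.0), "O": (1.2, 1.6, 0.0),
               "CB": (0.0, -1.5, 0.0)}
    atoms = []
    for r in range(1, n_residues + 1):
        base = np.array([3.8 * (r - 1), 0.0, 0.0])
        for name in ("N", "CA", "C", "O", "CB"):
            atoms.append((name, name[0], "ALA", r,
                          base + np.asarray(offsets[name])))
    return _write_pdb(path, atoms)


def alanine_dipeptide_pdb(path=None) -> str:
    """Synthetic alanine-dipeptide (ACE-ALA-NME) PDB with 10 heavy atoms.

    Geometry is schematic; the topology (atom names, elements, residues)
    is what matters for heavy-atom pair accounting (C(10,2) = 45 pair
    distances).
    """
    atoms = [
        ("CH3", "C", "ACE", 1, (-2.5, 1.0, 0.0)),
        ("C", "C", "ACE", 1, (-1.5, 0.0, 0.0)),
        ("O", "O", "ACE", 1, (-1.7, -1.2, 0.0)),
        ("N", "N", "ALA", 2, (-0.3, 0.5, 0.0)),
        ("CA", "C", "ALA", 2, (0.9, -0.3, 0.0)),
        ("CB", "C", "ALA", 2, (0.9, -1.3, 1.2)),
        ("C", "C", "ALA", 2, (2.1, 0.6, 0.0)),
        ("O", "O", "ALA", 2, (2.1, 1.8, 0.2)),
        ("N", "N", "NME", 3, (3.3, 0.0, -0.2)),
        ("C", "C", "NME", 3, (4.5, 0.8, -0.3)),
    ]
    atoms = [(n, e, rn, ri, np.asarray(x, dtype=float))
             for n, e, rn, ri, x in atoms]
    return _write_pdb(path, atoms)
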