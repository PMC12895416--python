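"""Trajectory featurization: distances, exponential contacts, dihedrals,
and reference-aligned positions.

Coordinates are in Angstrom throughout.  Residue indices follow the PDB
convention (1-based); atom indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure.io.pdb as pdb
from scipy.spatial.transform import Rotation

from .containers import FeatureMatrix

__all__ = [
    "Topology",
    "FeatureSpec",
    "read_structure",
    "enumerate_pairs",
    "pairwise_distances",
    "exponential_contacts",
    "backbone_dihedrals",
    "align_and_flatten",
    "build_features",
]

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass
class Topology:
    """Minimal atom bookkeeping: names, residue indices, heavy-atom flags."""

    atom_names: np.ndarray      # str per atom
    residue_ids: np.ndarray     # int per atom, 1-based, nondecreasing
    heavy: np.ndarray           # bool per atom (element != H)

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.heavy = np.asarray(self.heavy, dtype=bool)
        if self.n_atoms < 1:
            raise ValueError("topology needs at least one atom")
        if np.any(np.diff(self.residue_ids) < 0):
            raise ValueError("residue indices must be nondecreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_ids))

    def select(self, selection: str) -> np.ndarray:
        """Return sorted 0-based atom indices for a named selection.

        ``heavy``    -- all non-hydrogen atoms
        ``backbone`` -- atoms named N, CA or C (O excluded)
        ``calpha``   -- atoms named CA
        ``all``      -- every atom
        """
        if selection == "all":
            idx = np.arange(self.n_atoms)
        elif selection == "heavy":
            idx = np.flatnonzero(self.heavy)
        elif selection == "backbone":
            idx = np.flatnonzero(np.isin(self.atom_names.astype(str),
                                         BACKBONE_NAMES))
        elif selection == "calpha":
            idx = np.flatnonzero(self.atom_names.astype(str) == "CA")
        else:
            raise ValueError(f"unknown selection {selection!r}")
        if idx.size == 0:
            raise ValueError(f"selection {selection!r} matched no atoms")
        return idx


@dataclass
class FeatureSpec:
    """Declarative description of one feature family.

    ``family`` is one of ``distance``, ``contact``, ``dihedral`` or
    ``position``.  Distance/contact features use ``selection`` plus
    ``min_residue_separation`` (or an explicit ``pairs`` list); contacts
    additionally use the length scale ``d0`` (Angstrom, always explicit);
    dihedrals honor ``shifted``; positions align on ``selection``.
    """

    family: str
    selection: str = "heavy"
    min_residue_separation: int = 0
    pairs: np.ndarray | None = None
    d0: float = 1.0
    shifted: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("distance", "contact", "dihedral", "position"):
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.pairs is not None:
            p = np.asarray(self.pairs)
            if p.ndim != 2 or p.shape[1] != 2 or np.any(p[:, 0] == p[:, 1]):
                raise ValueError("pairs must be (M, 2) with distinct indices")


def build_features(spec: FeatureSpec, frames: np.ndarray,
                   topology: Topology, reference: np.ndarray | None = None,
                   timestep_ns: float = 1.0) -> FeatureMatrix:
    """Build the feature family a :class:`FeatureSpec` describes."""
    if spec.family in ("distance", "contact"):
        pairs = (np.asarray(spec.pairs) if spec.pairs is not None
                 else enumerate_pairs(topology, spec.selection,
                                      spec.min_residue_separation))
        dists = pairwise_distances(frames, pairs, timestep_ns)
        if spec.family == "distance":
            return dists
        return exponential_contacts(dists, spec.d0)
    if spec.family == "dihedral":
        return backbone_dihedrals(frames, topology, spec.shifted, timestep_ns)
    if reference is None:
        raise ValueError("position features need a reference structure")
    return align_and_flatten(frames, reference,
                             topology.select(spec.selection), timestep_ns)


def read_structure(pdb_path) -> tuple[Topology, np.ndarray]:
    """Read a PDB file's ATOM records into a Topology plus reference coords.

    Returns
    -------
    topology : Topology
    reference : ndarray, shape (n_atoms, 3)
        Coordinates of the (first model's) ATOM records, in Angstrom.
    """
    path = str(pdb_path)
    # serial-number sanity pass: biotite tolerates duplicates silently
    serials = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("ATOM"):
                field = line[6:11].strip()
                if not field:
                    raise ValueError(f"ATOM record without serial: {line!r}")
                serials.append(int(field))
    if not serials:
        raise ValueError(f"{path}: no ATOM records (empty input)")
    if len(set(serials)) != len(serials):
        raise ValueError(f"{path}: duplicate atom serial numbers")

    pdb_file = pdb.PDBFile.read(path)
    atoms = pdb_file.get_structure(model=1)
    atoms = atoms[~atoms.hetero]
    elements = np.asarray(atoms.element, dtype=str)
    top = Topology(
        atom_names=np.asarray(atoms.atom_name, dtype=object),
        residue_ids=np.asarray(atoms.res_id, dtype=np.int64),
        heavy=elements != "H",
    )
    return top, np.asarray(atoms.coord, dtype=np.float64)


def enumerate_pairs(topology: Topology, selection: str,
                    min_residue_separation: int = 0) -> np.ndarray:
    """All unordered atom pairs (i < j) of a selection, in lexicographic order.

    Pairs whose residue-index separation is below ``min_residue_separation``
    are dropped.  With separation 0 this is all C(k, 2) pairs of the k
    selected atoms -- e.g. 6786 pairs for the 117 backbone atoms (N, CA, C)
    of a 39-residue chain.
    """
    idx = topology.select(selection)
    res = topology.residue_ids[idx]
    ii, jj = np.triu_indices(len(idx), k=1)
    keep = np.abs(res[jj] - res[ii]) >= min_residue_separation
    pairs = np.column_stack([idx[ii[keep]], idx[jj[keep]]])
    if pairs.shape[0] == 0:
        raise ValueError(
            f"selection {selection!r} with residue separation >= "
            f"{min_residue_separation} yields no pairs")
    return pairs


def pairwise_distances(frames: np.ndarray, pairs: np.ndarray,
                       timestep_ns: float = 1.0) -> FeatureMatrix:
    """Euclidean distance per pair per frame (Angstrom).

    ``frames`` has shape (T, n_atoms, 3); column order follows pair order.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.size and pairs.max() >= frames.shape[1]:
        raise IndexError(
            f"pair index {pairs.max()} out of range for "
            f"{frames.shape[1]} atoms")
    diff = frames[:, pairs[:, 0], :] - frames[:, pairs[:, 1], :]
    dists = np.sqrt(np.einsum("tpk,tpk->tp", diff, diff))
    labels = [f"d_{i}_{j}" for i, j in pairs]
    return FeatureMatrix(dists, labels, timestep_ns)


def exponential_contacts(distances: FeatureMatrix, d0: float) -> FeatureMatrix:
    """Contact features c_ij = exp(-d_ij / d0) with d0 in Angstrom.

    Maps distances in [0, inf) to contact strengths in (0, 1]; identical
    atoms give c = 1 and the value decays with distance on the scale d0.
    """
    if d0 <= 0:
        raise ValueError(f"d0 must be positive, got {d0}")
    vals = np.asarray(distances.values)
    if np.any(vals < 0):
        raise ValueError("distances must be nonnegative")
    labels = [lab.replace("d_", "c_", 1) for lab in distances.labels]
    return FeatureMatrix(np.exp(-vals / d0), labels, distances.timestep_ns,
                         {"d0": d0})


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral of four point sets, shape (..., 3) each, radians."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(b2n, n1)      # sign matches the IUPAC/Ramachandran usage
    x = np.einsum("...k,...k->...", n1, n2)
    y = np.einsum("...k,...k->...", m1, n2)
    ang = np.arctan2(y, x)
    # half-open convention [-pi, pi): fold the +pi boundary onto -pi
    ang = np.where(ang >= np.pi, ang - 2.0 * np.pi, ang)
    return ang


def _shift_branch_cut(angles: np.ndarray, n_bins: int = 36) -> np.ndarray:
    """Move an angle series' branch cut into its least-populated region.

    The circle is histogrammed into ``n_bins`` bins; the lower edge of the
    emptiest bin becomes the new cut, so the returned values live in
    [cut, cut + 2*pi).  This removes wrap-around artifacts for angles whose
    populated region straddles +-pi.
    """
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    cut = edges[np.argmin(counts)]
    return np.mod(angles - cut, 2.0 * np.pi) + cut


def backbone_dihedrals(frames: np.ndarray, topology: Topology,
                       shifted: bool = False,
                       timestep_ns: float = 1.0) -> FeatureMatrix:
    """Backbone phi/psi torsions per frame, radians in [-pi, pi).

    phi(i) = C(i-1)-N(i)-CA(i)-C(i) for residues 2..R,
    psi(i) = N(i)-CA(i)-C(i)-N(i+1) for residues 1..R-1,
    giving 2*(R-1) angles for an R-residue chain.  With ``shifted`` each
    angle's branch cut is relocated to the sparsest bin of a 36-bin circular
    histogram (values then live on a per-angle interval of width 2*pi).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    names = topology.atom_names.astype(str)
    res_ids = np.unique(topology.residue_ids)

    atom_of = {}
    for k, (name, rid) in enumerate(zip(names, topology.residue_ids)):
        atom_of[(int(rid), name)] = k
    for rid in res_ids:
        for name in BACKBONE_NAMES:
            if (int(rid), name) not in atom_of:
                raise ValueError(
                    f"residue {rid} is missing backbone atom {name}")

    quads, labels = [], []
    for prev, cur in zip(res_ids[:-1], res_ids[1:]):
        prev, cur = int(prev), int(cur)
        quads.append([atom_of[(prev, "C")], atom_of[(cur, "N")],
                      atom_of[(cur, "CA")], atom_of[(cur, "C")]])
        labels.append(f"phi_{cur}")
        quads.append([atom_of[(prev, "N")], atom_of[(prev, "CA")],
                      atom_of[(prev, "C")], atom_of[(cur, "N")]])
        labels.append(f"psi_{prev}")
    if not quads:
        raise ValueError("need at least two residues for backbone dihedrals")
    quads = np.asarray(quads)
    ang = _dihedral(frames[:, quads[:, 0]], frames[:, quads[:, 1]],
                    frames[:, quads[:, 2]], frames[:, quads[:, 3]])
    if shifted:
        ang = np.column_stack([_shift_branch_cut(ang[:, j])
                               for j in range(ang.shape[1])])
    return FeatureMatrix(ang, labels, timestep_ns, {"shifted": shifted})


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray) -> np.ndarray:
    """Rigid-body superpose one frame onto a reference using a selection.

    Least-squares optimal proper rotation (via quaternion/SVD through scipy)
    plus translation, fitted on ``selection`` atoms and applied to all atoms.
    """
    sel = np.asarray(selection, dtype=np.int64)
    if sel.size < 3:
        raise ValueError("alignment needs at least 3 atoms")
    mob_sel = mobile[sel]
    ref_sel = reference[sel]
    mob_c = mob_sel.mean(axis=0)
    ref_c = ref_sel.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sel - ref_c, mob_sel - mob_c)
    return rot.apply(mobile - mob_c) + ref_c


def align_and_flatten(frames: np.ndarray, reference: np.ndarray,
                      selection: np.ndarray,
                      timestep_ns: float = 1.0) -> FeatureMatrix:
    """Superpose every frame onto a reference, flatten to 3*A coordinates.

    Each frame is rigid-body aligned (fit on ``selection``, applied to all
    atoms) and its (A, 3) coordinates are flattened row-major into 3*A
    feature columns -- e.g. 1731 features for a 577-atom structure.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    reference = np.asarray(reference, dtype=np.float64)
    aligned = np.stack([superpose(f, reference, selection) for f in frames])
    n_atoms = reference.shape[0]
    labels = [f"{axis}_{a}" for a in range(n_atoms) for axis in "xyz"]
    return FeatureMatrix(aligned.reshape(len(frames), 3 * n_atoms), labels,
                         timestep_ns)
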