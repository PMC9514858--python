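"""Structure and sequence I/O, superposition, ensemble clustering, and
humanization sequence accounting.

Conformational ensembles travel as multi-model PDB files (one MODEL per
frame); the in-memory container wraps a biotite ``AtomArrayStack`` so that
every model shares one topology.  Region definitions (framework FW1-FW4 and
the paratope loops CDR1, CDR3, HV2, HV4) are residue ranges in the authors'
sequential numbering; they drive both featurization and the framework
identity accounting used to quantify humanization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "StructureModel",
    "RegionMap",
    "default_vnar_region_map",
    "read_structure",
    "write_structure",
    "kabsch_superpose",
    "superposed_rmsd",
    "pairwise_rmsd_matrix",
    "average_linkage_cluster",
    "ClusterResult",
    "framework_identity",
    "read_fasta",
]

# Canonical framework ranges of the humanization scheme (inclusive),
# sequential author numbering; the two canonical framework cysteines sit at
# 23 and 88 and are flagged if a range swallows them.
CANONICAL_CYSTEINES = (23, 88)


@dataclass
class StructureModel:
    """A multi-model structure: ordered coordinate sets over one topology."""

    stack: struc.AtomArrayStack

    def __post_init__(self):
        if isinstance(self.stack, struc.AtomArray):
            self.stack = struc.stack([self.stack])

    @property
    def n_models(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    @property
    def coords(self) -> np.ndarray:
        """(models, atoms, 3) coordinates in Angstrom."""
        return self.stack.coord

    def model(self, i: int) -> struc.AtomArray:
        return self.stack[i]

    def atom_mask(self, atom_names=None, residue_ids=None, chain=None):
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            mask &= np.isin(self.stack.atom_name, list(atom_names))
        if residue_ids is not None:
            mask &= np.isin(self.stack.res_id, list(residue_ids))
        if chain is not None:
            mask &= self.stack.chain_id == chain
        return mask

    def sequence(self, chain=None) -> str:
        """One-letter sequence of (the first model of) a chain."""
        arr = self.stack[0]
        if chain is not None:
            arr = arr[arr.chain_id == chain]
        ids, names = struc.get_residues(arr)
        from biotite.sequence import ProteinSequence

        letters = []
        for name in names:
            try:
                letters.append(ProteinSequence.convert_letter_3to1(name))
            except Exception:
                letters.append("X")
        return "".join(letters)


def read_structure(path) -> StructureModel:
    """Read a (multi-model) PDB file.

    Raises a ``ValueError`` for empty files or inconsistent models; biotite
    reports malformed ATOM records with their line context.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as err:  # biotite raises on inconsistent MODEL sizes
        raise ValueError(f"cannot parse {path}: {err}") from err
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms found")
    return StructureModel(stack=stack)


def write_structure(model: StructureModel, path) -> None:
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(model.stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Region map


@dataclass
class RegionMap:
    """Named residue ranges (inclusive) in author-supplied numbering.

    Ranges must be non-overlapping and non-empty.  The canonical framework
    cysteines (23, 88) are expected outside all ranges; if a range contains
    one, it is recorded in :attr:`flagged_cysteines` and a warning is issued
    (the map remains usable).
    """

    ranges: dict  # name -> (start, stop) inclusive
    numbering: str = "sequential"
    flagged_cysteines: list = field(default_factory=list)

    def __post_init__(self):
        seen = {}
        for name, (start, stop) in self.ranges.items():
            if stop < start:
                raise ValueError(f"region {name}: empty range {start}-{stop}")
            for r in range(start, stop + 1):
                if r in seen:
                    raise ValueError(
                        f"regions {seen[r]} and {name} overlap at residue {r}"
                    )
                seen[r] = name
        for cys in CANONICAL_CYSTEINES:
            if cys in seen:
                self.flagged_cysteines.append((cys, seen[cys]))
        if self.flagged_cysteines:
            warnings.warn(
                f"canonical cysteines inside regions: {self.flagged_cysteines}"
            )

    def __contains__(self, name) -> bool:
        return name in self.ranges

    def residues(self, name) -> list:
        start, stop = self.ranges[name]
        return list(range(start, stop + 1))

    def region_of(self, residue_id: int):
        for name, (start, stop) in self.ranges.items():
            if start <= residue_id <= stop:
                return name
        return None

    def framework_residues(self) -> list:
        out = []
        for name in self.ranges:
            if name.upper().startswith("FW"):
                out.extend(self.residues(name))
        return sorted(out)

    def loop_residues(self) -> list:
        out = []
        for name in self.ranges:
            if not name.upper().startswith("FW"):
                out.extend(self.residues(name))
        return sorted(out)


def default_vnar_region_map() -> RegionMap:
    """Framework/loop ranges of the VNAR humanization scheme.

    FW ranges follow the humanization accounting (FW1 6-21, FW2 38-40,
    FW3 66-82, FW4 99-103); loop ranges are the conventional VNAR paratope
    assignment used throughout the pipeline.
    """
    return RegionMap(
        ranges={
            "FW1": (6, 21),
            "CDR1": (26, 35),
            "FW2": (38, 40),
            "HV2": (44, 52),
            "HV4": (59, 65),
            "FW3": (66, 82),
            "CDR3": (86, 98),
            "FW4": (99, 103),
        }
    )


# ---------------------------------------------------------------------------
# Superposition and ensemble clustering


def kabsch_superpose(mobile, reference, selection=None):
    """Optimal rigid-body superposition (Kabsch, SVD form).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``reference``
    over all proper rotations; the reflection branch is removed by sign
    correction, so ``det(rotation) = +1``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        mobile_sel = mobile[selection]
        reference_sel = reference[selection]
    else:
        mobile_sel, reference_sel = mobile, reference
    if mobile_sel.shape != reference_sel.shape or mobile_sel.ndim != 2:
        raise ValueError("coordinate sets must have matching (n, 3) shapes")
    if mobile_sel.shape[0] < 3:
        raise ValueError("at least 3 atoms are required for superposition")

    mu_m = mobile_sel.mean(axis=0)
    mu_r = reference_sel.mean(axis=0)
    h = (mobile_sel - mu_m).T @ (reference_sel - mu_r)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_r - rotation @ mu_m
    moved = mobile_sel @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference_sel) ** 2, axis=1))))
    return rotation, translation, rmsd


def superposed_rmsd(coords_a, coords_b, selection=None) -> float:
    """Minimum RMSD between two coordinate sets over rigid transforms."""
    return kabsch_superpose(coords_a, coords_b, selection)[2]


def pairwise_rmsd_matrix(model: StructureModel, atom_mask=None) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between all models."""
    coords = model.coords
    if atom_mask is not None:
        coords = coords[:, atom_mask]
    n = coords.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = superposed_rmsd(coords[i], coords[j])
    return dist


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-model cluster id, 0-based, by first appearance
    representatives: np.ndarray  # per-cluster model index
    cutoff: float
    distance_matrix: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def to_frame(self) -> pd.DataFrame:
        rep = np.zeros(len(self.labels), dtype=bool)
        rep[self.representatives] = True
        return pd.DataFrame(
            {
                "model_index": np.arange(len(self.labels)),
                "cluster_id": self.labels,
                "is_representative": rep,
            }
        )


def average_linkage_cluster(
    model: StructureModel, atom_mask=None, cutoff_A: float = 1.3
) -> ClusterResult:
    """Average-linkage hierarchical clustering of a conformational ensemble.

    The pairwise metric is the superposed (Kabsch) RMSD; agglomeration stops
    when the minimum inter-cluster average distance exceeds ``cutoff_A``
    (distance-criterion cut of the dendrogram, default 1.3 Angstrom).  The
    representative of a cluster is the member with minimal mean distance to
    its cluster; ties break to the lowest model index.  Labels are
    renumbered by first appearance so they are deterministic given input
    order.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = model.n_models
    dist = pairwise_rmsd_matrix(model, atom_mask)
    if n == 1:
        return ClusterResult(
            labels=np.zeros(1, dtype=int),
            representatives=np.zeros(1, dtype=int),
            cutoff=cutoff_A,
            distance_matrix=dist,
        )
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=cutoff_A, criterion="distance")
    # renumber by first appearance
    mapping, labels = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]
    reps = []
    for c in range(len(mapping)):
        members = np.flatnonzero(labels == c)
        mean_d = dist[np.ix_(members, members)].mean(axis=1)
        reps.append(int(members[np.argmin(mean_d)]))  # argmin ties -> lowest
    return ClusterResult(
        labels=labels,
        representatives=np.asarray(reps, dtype=int),
        cutoff=cutoff_A,
        distance_matrix=dist,
    )


# ---------------------------------------------------------------------------
# Sequence accounting


def read_fasta(path) -> dict:
    """Minimal FASTA reader returning ``{header: sequence}`` (upper-case)."""
    seqs, header, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    seqs[header] = "".join(chunks).upper()
                header, chunks = line[1:].split()[0] if line[1:] else "", []
            else:
                chunks.append(line)
    if header is not None:
        seqs[header] = "".join(chunks).upper()
    return seqs


def _align_global(seq_a: str, seq_b: str):
    """Global alignment (BLOSUM62, affine gaps) via biotite; returns the two
    gapped strings."""
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import SubstitutionMatrix, align_optimal

    matrix = SubstitutionMatrix.std_protein_matrix()
    ali = align_optimal(
        ProteinSequence(seq_a),
        ProteinSequence(seq_b),
        matrix,
        gap_penalty=(-10, -1),
        terminal_penalty=True,
    )[0]
    gapped = str(ali).split("\n")
    return gapped[0], gapped[1]


def framework_identity(seq_a: str, seq_b: str, region_map: RegionMap, positions="framework"):
    """Percent of selected positions at which two sequences differ.

    ``positions`` is ``"framework"`` (union of FW ranges), ``"non-CDR"``
    (all positions outside CDR/HV loops), or an explicit iterable of residue
    ids (1-based, numbering of ``seq_a``).  Sequences of equal length are
    taken as aligned; unequal lengths trigger a global alignment, and gap
    columns count as differing.  Returns
    ``(percent, mask, selected_positions)`` where ``mask[i]`` marks a
    difference at the i-th selected position, so the denominator of the
    percentage is always visible to the caller.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        seq_a, seq_b = _align_global(seq_a, seq_b)
    # map alignment columns to seq_a residue numbers (1-based, gaps skipped)
    numbering, pos = [], 0
    for ch in seq_a:
        if ch != "-":
            pos += 1
            numbering.append(pos)
        else:
            numbering.append(None)

    if positions == "framework":
        selected = set(region_map.framework_residues())
    elif positions in ("non-CDR", "non_cdr"):
        loops = set(region_map.loop_residues())
        selected = {p for p in range(1, pos + 1) if p not in loops}
    else:
        selected = set(int(p) for p in positions)
    if not selected:
        raise ValueError("empty position selection")

    mask, used = [], []
    for col, num in enumerate(numbering):
        if num is not None and num in selected:
            used.append(num)
            mask.append(seq_a[col] != seq_b[col] or seq_b[col] == "-")
    if not used:
        raise ValueError("selection does not intersect the sequence")
    mask = np.asarray(mask, dtype=bool)
    percent = 100.0 * mask.sum() / len(mask)
    return percent, mask, used
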