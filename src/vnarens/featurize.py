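"""Backbone torsion featurization.

The central ensemble representation is a :class:`TorsionTrajectory`: a
frames x dihedrals matrix of backbone torsion angles (degrees, wrapped to
``[-180, 180)``) with residue/region labels.  Downstream stages (tICA, MSM)
operate on its periodicity-respecting sine/cosine embedding, the standard
dihedral feature map for loop dynamics: each angle theta contributes the
pair ``(sin theta, cos theta)`` so that 179 deg and -179 deg are close.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TorsionTrajectory",
    "FeatureMatrix",
    "dihedral_angle",
    "backbone_torsions",
    "sincos_embed",
    "select_paratope",
    "wrap_degrees",
]


def wrap_degrees(angles):
    """Wrap angles (degrees) into ``[-180, 180)``."""
    return (np.asarray(angles, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class TorsionTrajectory:
    """Frames x dihedrals torsion matrix with per-dihedral labels.

    Parameters
    ----------
    angles : (n_frames, n_dihedrals) float array, degrees in [-180, 180)
        Undefined dihedrals (degenerate geometry, missing neighbors) are NaN
        and flagged in :attr:`defined`.
    residue_ids : (n_dihedrals,) int array
    kinds : (n_dihedrals,) array of "phi" / "psi"
    regions : (n_dihedrals,) array of region tags ("" when untagged)
    frame_interval_ns : nominal time between frames; maps lag times given in
        nanoseconds onto frame counts.  This is a declared convention of the
        trajectory, not a measured quantity.
    """

    angles: np.ndarray
    residue_ids: np.ndarray
    kinds: np.ndarray
    regions: np.ndarray = None
    frame_interval_ns: float = 0.1
    defined: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be 2-D (frames x dihedrals)")
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.kinds = np.asarray(self.kinds, dtype=object)
        n_dih = self.angles.shape[1]
        if len(self.residue_ids) != n_dih or len(self.kinds) != n_dih:
            raise ValueError("label count must equal dihedral column count")
        if self.regions is None:
            self.regions = np.array([""] * n_dih, dtype=object)
        self.regions = np.asarray(self.regions, dtype=object)
        if len(self.regions) != n_dih:
            raise ValueError("region tag count must equal dihedral column count")
        if self.defined is None:
            self.defined = ~np.isnan(self.angles)
        finite = self.angles[self.defined]
        if finite.size and (finite.min() < -180.0 or finite.max() >= 180.0):
            raise ValueError("angles must be wrapped to [-180, 180)")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.angles.shape[1]

    def select(self, mask) -> "TorsionTrajectory":
        if isinstance(mask, slice):
            mask = np.arange(self.n_dihedrals)[mask]
        mask = np.asarray(mask)
        return replace(
            self,
            angles=self.angles[:, mask],
            residue_ids=self.residue_ids[mask],
            kinds=self.kinds[mask],
            regions=self.regions[mask],
            defined=self.defined[:, mask],
        )

    def restrict_residues(self, residue_ids) -> "TorsionTrajectory":
        keep = np.isin(self.residue_ids, np.asarray(list(residue_ids)))
        return self.select(keep)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (frame, residue_id, phi_deg, psi_deg)."""
        records = {}
        for j in range(self.n_dihedrals):
            records.setdefault(self.residue_ids[j], {})[self.kinds[j]] = j
        frames = np.arange(self.n_frames)
        cols = {"frame": np.repeat(frames, len(records))}
        res_sorted = sorted(records)
        cols["residue_id"] = np.tile(res_sorted, self.n_frames)
        for kind in ("phi", "psi"):
            vals = np.full((self.n_frames, len(res_sorted)), np.nan)
            for i, res in enumerate(res_sorted):
                if kind in records[res]:
                    vals[:, i] = self.angles[:, records[res][kind]]
            cols[f"{kind}_deg"] = vals.ravel()
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path, frame_interval_ns: float = 0.1) -> "TorsionTrajectory":
        df = pd.read_csv(path, sep="\t")
        res = np.sort(df["residue_id"].unique())
        n_frames = df["frame"].nunique()
        df = df.sort_values(["frame", "residue_id"])
        cols, res_ids, kinds = [], [], []
        for kind in ("phi", "psi"):
            block = df[f"{kind}_deg"].to_numpy().reshape(n_frames, len(res))
            for i, r in enumerate(res):
                if not np.all(np.isnan(block[:, i])):
                    cols.append(block[:, i])
                    res_ids.append(r)
                    kinds.append(kind)
        order = np.lexsort((np.asarray(kinds) == "psi", res_ids))
        angles = np.column_stack([cols[i] for i in order])
        return cls(
            angles=angles,
            residue_ids=np.asarray(res_ids)[order],
            kinds=np.asarray(kinds, dtype=object)[order],
            frame_interval_ns=frame_interval_ns,
        )


@dataclass
class FeatureMatrix:
    """Frames x (2 x n_dihedrals) sine/cosine dihedral features."""

    values: np.ndarray
    labels: list  # (residue_id, kind, "sin"|"cos") per column
    frame_interval_ns: float = 0.1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count must equal feature column count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def dihedral_angle(p0, p1, p2, p3):
    """Signed dihedral (degrees) for the atom quadruple p0-p1-p2-p3.

    Vectorized over leading axes.  Returns NaN where the geometry is
    degenerate (collinear bonds make the torsion undefined).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b1, axis=-1) / np.where(b1n == 0, np.nan, b1n)
    ang = np.degrees(np.arctan2(y, x))
    degenerate = (np.linalg.norm(n1, axis=-1) < 1e-9) | (
        np.linalg.norm(n2, axis=-1) < 1e-9
    )
    ang = np.where(degenerate, np.nan, ang)
    return wrap_degrees(np.where(np.isnan(ang), np.nan, ang))


def backbone_torsions(structure, residue_ids=None, region_map=None) -> TorsionTrajectory:
    """Compute phi/psi for selected residues of a (multi-model) structure.

    phi(i) is defined by C(i-1), N(i), CA(i), C(i); psi(i) by N(i), CA(i),
    C(i), N(i+1).  Terminal residues yield only the definable angle; a
    residue whose required atoms are missing contributes no column for that
    angle (absent, never zero).

    Parameters
    ----------
    structure : StructureModel or biotite AtomArrayStack
    residue_ids : iterable of residue sequence ids or None for all
    region_map : optional RegionMap used to tag each dihedral with its region
    """
    from .structio import StructureModel

    if isinstance(structure, StructureModel):
        stack = structure.stack
    else:
        stack = structure
    coords = stack.coord  # (models, atoms, 3)
    res_id = stack.res_id
    atom_name = stack.atom_name

    index = {}
    for i in range(stack.array_length()):
        index[(int(res_id[i]), atom_name[i])] = i

    all_res = sorted(set(int(r) for r in res_id))
    if residue_ids is None:
        residue_ids = all_res
    residue_ids = sorted(int(r) for r in residue_ids)

    cols, labels = [], []
    for r in residue_ids:
        n_i = index.get((r, "N"))
        ca_i = index.get((r, "CA"))
        c_i = index.get((r, "C"))
        c_prev = index.get((r - 1, "C"))
        n_next = index.get((r + 1, "N"))
        if None not in (c_prev, n_i, ca_i, c_i):
            phi = dihedral_angle(
                coords[:, c_prev], coords[:, n_i], coords[:, ca_i], coords[:, c_i]
            )
            cols.append(phi)
            labels.append((r, "phi"))
        if None not in (n_i, ca_i, c_i, n_next):
            psi = dihedral_angle(
                coords[:, n_i], coords[:, ca_i], coords[:, c_i], coords[:, n_next]
            )
            cols.append(psi)
            labels.append((r, "psi"))

    if not cols:
        angles = np.empty((coords.shape[0], 0))
        res_arr = np.empty(0, dtype=int)
        kind_arr = np.empty(0, dtype=object)
    else:
        angles = np.column_stack(cols)
        res_arr = np.array([l[0] for l in labels], dtype=int)
        kind_arr = np.array([l[1] for l in labels], dtype=object)
    regions = None
    if region_map is not None and len(res_arr):
        regions = np.array(
            [region_map.region_of(r) or "" for r in res_arr], dtype=object
        )
    return TorsionTrajectory(
        angles=angles, residue_ids=res_arr, kinds=kind_arr, regions=regions
    )


def sincos_embed(traj: TorsionTrajectory, which: str = "both", weights=None) -> FeatureMatrix:
    """Embed torsions as (sin, cos) pairs.

    ``which`` selects "both" (phi and psi) or "psi" (the collective-variable
    convention used for loop sampling, where the psi torsion captures the
    transitions).  Column order is deterministic: by residue id, phi before
    psi, sin before cos.  Optional per-dihedral weights scale both members of
    a pair (unit weights by default).
    """
    if traj.n_dihedrals == 0 or traj.n_frames == 0:
        raise ValueError("cannot embed an empty trajectory")
    if which not in ("both", "psi", "phi"):
        raise ValueError(f"unknown selection {which!r}")
    if which != "both":
        traj = traj.select(traj.kinds == which)
        if traj.n_dihedrals == 0:
            raise ValueError(f"trajectory has no {which} dihedrals")
    order = np.lexsort((traj.kinds == "psi", traj.residue_ids))
    traj = traj.select(order)
    if weights is None:
        weights = np.ones(traj.n_dihedrals)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (traj.n_dihedrals,):
        raise ValueError("one weight per dihedral required")
    rad = np.radians(traj.angles)
    values = np.empty((traj.n_frames, 2 * traj.n_dihedrals))
    labels = []
    for j in range(traj.n_dihedrals):
        values[:, 2 * j] = np.sin(rad[:, j]) * weights[j]
        values[:, 2 * j + 1] = np.cos(rad[:, j]) * weights[j]
        labels.append((int(traj.residue_ids[j]), str(traj.kinds[j]), "sin"))
        labels.append((int(traj.residue_ids[j]), str(traj.kinds[j]), "cos"))
    return FeatureMatrix(
        values=values, labels=labels, frame_interval_ns=traj.frame_interval_ns
    )


def select_paratope(region_map, regions=("CDR1", "CDR3", "HV2")):
    """Union of the paratope regions' residue ids, sorted, duplicate-free."""
    ids = set()
    for name in regions:
        if name not in region_map:
            raise KeyError(f"region {name!r} missing from region map")
        members = region_map.residues(name)
        if not members:
            raise ValueError(f"region {name!r} is empty")
        ids.update(members)
    return sorted(ids)
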