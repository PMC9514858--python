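"""Solvent-accessible surface area and surface hydrophobicity mapping.

SASA is computed by the Shrake-Rupley rolling-probe point-sampling
algorithm with a deterministic golden-spiral sphere lattice, so results are
bit-reproducible.  Surface hydrophobicity assigns each surface-exposed
residue its Wimley-White partitioning free energy (interface scale by
default; the octanol scale ships alongside) and aggregates a SASA-weighted
mean over a residue selection -- the statistic used to compare, e.g., a
former light-chain pairing interface before and after engineering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "sphere_points",
    "sasa",
    "SasaResult",
    "hydrophobicity_map",
    "HydrophobicityMap",
    "load_scale",
    "load_max_sasa",
]

PROBE_RADIUS = 1.4  # water probe, Angstrom
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70


def load_scale(which: str = "interface") -> dict:
    """Published Wimley-White per-residue scale (kcal/mol), as shipped."""
    name = {
        "interface": "wimley_white_interface.tsv",
        "octanol": "wimley_white_octanol.tsv",
    }[which]
    path = resources.files("vnarens.data") / name
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.res_name, df.delta_g_kcal_mol))


def load_max_sasa() -> dict:
    """Per-residue-type maximum SASA (Gly-X-Gly reference values, A^2)."""
    path = resources.files("vnarens.data") / "max_sasa_gxg.tsv"
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.res_name, df.max_sasa_A2))


def sphere_points(n: int = 960) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` unit-sphere points."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class SasaResult:
    per_atom: np.ndarray  # (n_atoms,) A^2
    per_residue: pd.DataFrame  # residue_id, res_name, chain, sasa
    probe_radius: float
    n_sphere_points: int

    def residue_sasa(self, chain, res_id) -> float:
        t = self.per_residue
        hit = t[(t.chain == chain) & (t.residue_id == res_id)]
        return float(hit.sasa.iloc[0]) if len(hit) else 0.0


def sasa(model, probe_radius: float = PROBE_RADIUS, n_sphere_points: int = 960,
         frame: int = 0) -> SasaResult:
    """Shrake-Rupley SASA of one frame of a structure (per atom and residue).

    Each atom's sphere of radius ``r_vdw + probe`` is sampled on the golden
    spiral; a point is accessible if it lies outside every neighbor's
    expanded sphere.  Unknown elements receive a default radius with a
    warning.
    """
    from .structio import StructureModel

    stack = model.stack if isinstance(model, StructureModel) else model
    coords = stack.coord[frame]
    n_atoms = stack.array_length()
    radii = np.empty(n_atoms)
    for i in range(n_atoms):
        elem = stack.element[i] if stack.element[i] else stack.atom_name[i][0]
        if elem not in VDW_RADII:
            warnings.warn(f"unknown element {elem!r}; default vdW radius applied")
        radii[i] = VDW_RADII.get(elem, DEFAULT_RADIUS)
    expanded = radii + probe_radius
    lattice = sphere_points(n_sphere_points)

    per_atom = np.zeros(n_atoms)
    # neighbor lists via a coarse distance screen
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    for i in range(n_atoms):
        cutoff = (expanded[i] + expanded) ** 2
        neighbors = np.flatnonzero((d2[i] < cutoff) & (np.arange(n_atoms) != i))
        points = coords[i] + expanded[i] * lattice
        if len(neighbors):
            diff = points[:, None, :] - coords[neighbors][None, :, :]
            inside = np.any(
                np.sum(diff ** 2, axis=-1) < expanded[neighbors][None, :] ** 2, axis=1
            )
            accessible = np.count_nonzero(~inside)
        else:
            accessible = n_sphere_points
        per_atom[i] = (
            4.0 * np.pi * expanded[i] ** 2 * accessible / n_sphere_points
        )

    rows = {}
    for i in range(n_atoms):
        key = (stack.chain_id[i], int(stack.res_id[i]))
        if key not in rows:
            rows[key] = {
                "chain": key[0], "residue_id": key[1],
                "res_name": stack.res_name[i], "sasa": 0.0,
            }
        rows[key]["sasa"] += per_atom[i]
    per_residue = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["chain"], r["residue_id"])))
    return SasaResult(
        per_atom=per_atom, per_residue=per_residue,
        probe_radius=probe_radius, n_sphere_points=n_sphere_points,
    )


@dataclass
class HydrophobicityMap:
    """Per-residue SASA, relative SASA, scale value and surface flag."""

    table: pd.DataFrame
    scale_name: str
    surface_threshold: float

    def aggregate(self, residue_ids=None, chain=None) -> float:
        """SASA-weighted mean scale value over surface residues of a selection.

        Positive values are hydrophilic (unfavorable membrane-interface
        partitioning), negative hydrophobic, so a decrease of the aggregate
        marks a more hydrophobic patch.
        """
        t = self.table[self.table.surface & ~self.table.nonstandard]
        if chain is not None:
            t = t[t.chain == chain]
        if residue_ids is not None:
            t = t[t.residue_id.isin(list(residue_ids))]
        if not len(t):
            raise ValueError("no surface residues in selection")
        w = t.sasa.to_numpy()
        return float(np.average(t.scale_value.to_numpy(), weights=w))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def bfactor_structure(self, model):
        """Copy of the structure with scale values in the B-factor column."""
        import biotite.structure as struc
        from .structio import StructureModel

        stack = model.stack.copy()
        values = np.zeros(stack.array_length())
        lookup = {
            (row.chain, row.residue_id): row.scale_value
            for row in self.table.itertuples()
        }
        for i in range(stack.array_length()):
            values[i] = lookup.get((stack.chain_id[i], int(stack.res_id[i])), 0.0)
        stack.set_annotation("b_factor", np.zeros(stack.array_length()))
        stack.b_factor = values
        return StructureModel(stack=stack)


def hydrophobicity_map(model, surface_threshold_relSASA: float = 0.2,
                       scale: str = "interface", probe_radius: float = PROBE_RADIUS,
                       n_sphere_points: int = 960, frame: int = 0) -> HydrophobicityMap:
    """Surface hydrophobicity map of one structure frame.

    Residues with relative SASA (fraction of the residue type's Gly-X-Gly
    maximum) at or above the threshold are flagged as surface; each standard
    residue receives its Wimley-White scale value.  Nonstandard residues are
    flagged and excluded from aggregates.
    """
    values = load_scale(scale)
    max_sasa = load_max_sasa()
    result = sasa(model, probe_radius=probe_radius, n_sphere_points=n_sphere_points,
                  frame=frame)
    rows = []
    for row in result.per_residue.itertuples():
        standard = row.res_name in values
        ref = max_sasa.get(row.res_name, np.nan)
        rel = row.sasa / ref if standard and ref > 0 else np.nan
        rows.append(
            {
                "chain": row.chain,
                "residue_id": row.residue_id,
                "res_name": row.res_name,
                "sasa": row.sasa,
                "rel_sasa": rel,
                "scale_value": values.get(row.res_name, np.nan),
                "surface": bool(standard and rel >= surface_threshold_relSASA),
                "nonstandard": not standard,
            }
        )
    table = pd.DataFrame(rows)
    if table.nonstandard.any():
        warnings.warn(
            f"nonstandard residues excluded from aggregates: "
            f"{table[table.nonstandard].res_name.unique().tolist()}"
        )
    return HydrophobicityMap(
        table=table, scale_name=scale, surface_threshold=surface_threshold_relSASA,
    )
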