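"""Typed residue contact detection, per-frame histograms, frequencies,
cross-system interaction fingerprints and flareplot graph export.

Contacts are detected per frame from geometric rules on heavy atoms (the
toy ensembles carry no hydrogens, so hydrogen bonds use the standard
donor/acceptor heavy-atom proxy).  Types are disjointly prioritized per
atom pair: salt bridge > hydrogen bond > van der Waals.  Frequencies are
residue-pair occurrence fractions over frames; fingerprints compare those
frequencies across systems after a retention cutoff, with average-linkage
clustering of the retained pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "detect_contacts",
    "contacts_per_frame",
    "contact_frequencies",
    "ContactFrequencyTable",
    "Fingerprint",
    "fingerprint",
    "flareplot_export",
]

# Heavy-atom chemistry tables for the standard residues (backbone plus the
# side-chain atoms the toy fixtures and common PDB files carry).
POSITIVE_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
DONOR_ATOMS = {
    ("*", "N"),  # backbone amide (PRO excluded below)
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"),
    ("ARG", "NH2"), ("TRP", "NE1"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("CYS", "SG"),
}
ACCEPTOR_ATOMS = {
    ("*", "O"),  # backbone carbonyl
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW_RADIUS = 1.70

# antecedent (bonded heavy neighbor) of each donor, for the donor-angle proxy
DONOR_ANTECEDENT = {
    "N": "CA", "OG": "CB", "OG1": "CB", "OH": "CZ", "ND2": "CG",
    "NE2": "CD", "NZ": "CE", "NE": "CD", "NH1": "CZ", "NH2": "CZ",
    "NE1": "CD1", "ND1": "CG", "SG": "CB",
}
# toy fixtures carry a single functional atom whose antecedent is CB
TOY_ANTECEDENT_FALLBACK = "CB"


def _is_donor(res_name, atom_name):
    if atom_name == "N":
        return res_name != "PRO"
    return (res_name, atom_name) in DONOR_ATOMS


def _is_acceptor(res_name, atom_name):
    return atom_name == "O" or (res_name, atom_name) in ACCEPTOR_ATOMS


def _charge(res_name, atom_name):
    if (res_name, atom_name) in POSITIVE_ATOMS:
        return +1
    if (res_name, atom_name) in NEGATIVE_ATOMS:
        return -1
    return 0


@dataclass
class ContactCriteria:
    """Geometric rules per interaction type (distances in Angstrom, angles
    in degrees).

    Defaults: salt bridge = opposite formal-charge heavy atoms within 4.0 A;
    hydrogen bond = donor/acceptor heavy atoms within 3.5 A with a
    donor-antecedent angle >= 110 deg (heavy-atom proxy, no hydrogens
    required); van der Waals = heavy atoms within the sum of their vdW radii
    plus 0.5 A.  Types are disjointly prioritized for the same atom pair:
    salt bridge > hydrogen bond > vdW.
    """

    salt_bridge_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    hbond_min_angle: float = 110.0
    vdw_margin: float = 0.5
    enabled_types: tuple = ("salt_bridge", "hydrogen_bond", "vdw")

    def __post_init__(self):
        if min(self.salt_bridge_cutoff, self.hbond_cutoff, self.vdw_margin) <= 0:
            raise ValueError("all cutoffs must be > 0")


@dataclass
class ContactRecord:
    frame: int
    res_a: int
    res_b: int
    atom_a: str
    atom_b: str
    chain_a: str
    chain_b: str
    contact_type: str
    distance: float


def _atom_table(stack):
    n = stack.array_length()
    table = []
    antecedent_index = {}
    for i in range(n):
        key = (stack.chain_id[i], int(stack.res_id[i]), stack.atom_name[i])
        antecedent_index[key] = i
    for i in range(n):
        res_name = stack.res_name[i]
        atom_name = stack.atom_name[i]
        elem = stack.element[i] if stack.element[i] else atom_name[0]
        if elem not in VDW_RADII:
            warnings.warn(
                f"unknown element {elem!r} for atom {atom_name}; vdW-only fallback radius"
            )
        ante = DONOR_ANTECEDENT.get(atom_name)
        ante_idx = None
        if ante is not None:
            key = (stack.chain_id[i], int(stack.res_id[i]), ante)
            ante_idx = antecedent_index.get(key)
            if ante_idx is None:  # toy fixtures: functional atom hangs off CB
                key = (stack.chain_id[i], int(stack.res_id[i]), TOY_ANTECEDENT_FALLBACK)
                ante_idx = antecedent_index.get(key)
        table.append(
            {
                "index": i,
                "res_id": int(stack.res_id[i]),
                "res_name": res_name,
                "atom_name": atom_name,
                "chain": stack.chain_id[i],
                "radius": VDW_RADII.get(elem, DEFAULT_VDW_RADIUS),
                "charge": _charge(res_name, atom_name),
                "donor": _is_donor(res_name, atom_name),
                "acceptor": _is_acceptor(res_name, atom_name),
                "antecedent": ante_idx,
            }
        )
    return table


def detect_contacts(model, criteria: ContactCriteria = None, selection_a=None,
                    selection_b=None, min_sequence_separation: int = 2):
    """Detect typed contacts in every frame of a multi-model structure.

    ``selection_a`` / ``selection_b`` are boolean atom masks (None = all
    atoms).  When both selections cover the same chain, pairs of residues
    closer in sequence than ``min_sequence_separation`` are excluded.
    Returns a deterministic, frame-major list of :class:`ContactRecord`.
    """
    from .structio import StructureModel

    if isinstance(model, StructureModel):
        stack = model.stack
    else:
        stack = model
    criteria = criteria or ContactCriteria()
    atoms = _atom_table(stack)
    coords = stack.coord
    n_atoms = stack.array_length()
    mask_a = np.ones(n_atoms, bool) if selection_a is None else np.asarray(selection_a, bool)
    mask_b = np.ones(n_atoms, bool) if selection_b is None else np.asarray(selection_b, bool)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("atom selections must be nonempty")
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)

    pairs = []
    seen = set()
    for i in idx_a:
        for j in idx_b:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            ai, aj = atoms[i], atoms[j]
            same_chain = ai["chain"] == aj["chain"]
            if same_chain and abs(ai["res_id"] - aj["res_id"]) < min_sequence_separation:
                continue
            pairs.append((i, j))
    if not pairs:
        return []
    pair_arr = np.asarray(pairs)

    records = []
    from scipy.spatial.distance import cdist  # noqa: F401  (distance below is direct)

    for f in range(coords.shape[0]):
        d = np.linalg.norm(coords[f, pair_arr[:, 0]] - coords[f, pair_arr[:, 1]], axis=1)
        order = np.argsort(pair_arr[:, 0] * n_atoms + pair_arr[:, 1])
        for p in order:
            i, j = pair_arr[p]
            ai, aj = atoms[i], atoms[j]
            dist = float(d[p])
            ctype = None
            if (
                "salt_bridge" in criteria.enabled_types
                and ai["charge"] * aj["charge"] < 0
                and dist <= criteria.salt_bridge_cutoff
            ):
                ctype = "salt_bridge"
            elif "hydrogen_bond" in criteria.enabled_types and dist <= criteria.hbond_cutoff:
                for donor, acceptor in ((ai, aj), (aj, ai)):
                    if not (donor["donor"] and acceptor["acceptor"]):
                        continue
                    ante = donor["antecedent"]
                    if ante is None:
                        continue
                    v1 = coords[f, ante] - coords[f, donor["index"]]
                    v2 = coords[f, acceptor["index"]] - coords[f, donor["index"]]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if angle >= criteria.hbond_min_angle:
                        ctype = "hydrogen_bond"
                        break
            if ctype is None and "vdw" in criteria.enabled_types:
                if dist <= ai["radius"] + aj["radius"] + criteria.vdw_margin:
                    ctype = "vdw"
            if ctype is not None:
                records.append(
                    ContactRecord(
                        frame=f,
                        res_a=ai["res_id"], res_b=aj["res_id"],
                        atom_a=ai["atom_name"], atom_b=aj["atom_name"],
                        chain_a=ai["chain"], chain_b=aj["chain"],
                        contact_type=ctype, distance=dist,
                    )
                )
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [r.frame for r in records],
            "chainA": [r.chain_a for r in records],
            "resA": [r.res_a for r in records],
            "chainB": [r.chain_b for r in records],
            "resB": [r.res_b for r in records],
            "type": [r.contact_type for r in records],
            "atomA": [r.atom_a for r in records],
            "atomB": [r.atom_b for r in records],
            "distance": [r.distance for r in records],
        }
    )


def contacts_per_frame(records, n_frames: int, bin_width: int = 2, density: bool = False,
                       level: str = "residue"):
    """Histogram of the number of contacts per frame (bin width 2 default).

    Counts residue-pair events per frame (``level="residue"``: a residue
    pair with several atom contacts in one frame counts once) or raw atom
    pairs (``level="atom"``).  Returns ``(bin_edges, counts, per_frame)``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    per_frame = np.zeros(n_frames, dtype=int)
    if level == "residue":
        seen = set()
        for r in records:
            key = (r.frame, r.chain_a, r.res_a, r.chain_b, r.res_b)
            if key not in seen:
                seen.add(key)
                per_frame[r.frame] += 1
    elif level == "atom":
        for r in records:
            per_frame[r.frame] += 1
    else:
        raise ValueError(f"unknown level {level!r}")
    top = int(per_frame.max()) + bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(per_frame, bins=edges, density=density)
    return edges, counts, per_frame


@dataclass
class ContactFrequencyTable:
    """Residue-pair interaction frequencies over frames, in [0, 1]."""

    table: pd.DataFrame  # chainA, resA, chainB, resB, type, frequency
    n_frames: int
    label: str = ""

    def pair_keys(self) -> list:
        return [
            (row.chainA, int(row.resA), row.chainB, int(row.resB), row.type)
            for row in self.table.itertuples()
        ]

    def frequency_of(self, key) -> float:
        chain_a, res_a, chain_b, res_b, ctype = key
        t = self.table
        hit = t[
            (t.chainA == chain_a) & (t.resA == res_a)
            & (t.chainB == chain_b) & (t.resB == res_b) & (t.type == ctype)
        ]
        return float(hit.frequency.iloc[0]) if len(hit) else 0.0


def contact_frequencies(records, n_frames: int, label: str = "") -> ContactFrequencyTable:
    """Per residue pair and type: fraction of frames with >= 1 such contact.

    Pairs are canonicalized (lexicographically smaller (chain, residue)
    first) so the table is symmetric under (i, j) swap.
    """
    hits = {}
    for r in records:
        a = (r.chain_a, r.res_a)
        b = (r.chain_b, r.res_b)
        if b < a:
            a, b = b, a
        key = (a[0], a[1], b[0], b[1], r.contact_type)
        hits.setdefault(key, set()).add(r.frame)
    rows = [
        {
            "chainA": k[0], "resA": k[1], "chainB": k[2], "resB": k[3],
            "type": k[4], "frequency": len(frames) / n_frames,
        }
        for k, frames in sorted(hits.items())
    ]
    table = pd.DataFrame(
        rows, columns=["chainA", "resA", "chainB", "resB", "type", "frequency"]
    )
    return ContactFrequencyTable(table=table, n_frames=n_frames, label=label)


@dataclass
class Fingerprint:
    """Systems x contact-pairs frequency matrix with pair clustering."""

    systems: list
    pair_keys: list  # retained pairs, in clustered leaf order
    frequencies: np.ndarray  # (n_systems, n_retained)
    cutoff: float
    linkage: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.frequencies.T,
            columns=self.systems,
            index=[
                f"{k[0]}:{k[1]}--{k[2]}:{k[3]}:{k[4]}" for k in self.pair_keys
            ],
        )
        df.index.name = "pair"
        return df

    def to_json(self, path=None):
        doc = {
            "systems": self.systems,
            "cutoff": self.cutoff,
            "pairs": [list(k) for k in self.pair_keys],
            "frequencies": self.frequencies.tolist(),
        }
        if path is None:
            return json.dumps(doc, indent=1)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def fingerprint(tables, cutoff: float = 0.5, system_names=None) -> Fingerprint:
    """Cross-system interaction fingerprint.

    Pairs whose frequency stays below ``cutoff`` in every system are
    dropped; the retained pairs are ordered by average-linkage hierarchical
    clustering on the Euclidean distance between their frequency vectors
    (deterministic scipy leaf order).
    """
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import pdist

    if len(tables) < 1:
        raise ValueError("at least one frequency table required")
    if system_names is None:
        system_names = [t.label or f"system_{i}" for i, t in enumerate(tables)]
    all_keys = sorted(set().union(*[set(t.pair_keys()) for t in tables]))
    freq = np.array(
        [[t.frequency_of(k) for k in all_keys] for t in tables]
    )  # systems x pairs
    retained = freq.max(axis=0) >= cutoff
    keys = [k for k, keep in zip(all_keys, retained) if keep]
    freq = freq[:, retained]
    if not keys:
        return Fingerprint(
            systems=list(system_names), pair_keys=[], frequencies=freq,
            cutoff=cutoff,
        )
    if len(keys) > 2:
        z = linkage(pdist(freq.T), method="average")
        order = leaves_list(z)
    else:
        z, order = None, np.arange(len(keys))
    return Fingerprint(
        systems=list(system_names),
        pair_keys=[keys[i] for i in order],
        frequencies=freq[:, order],
        cutoff=cutoff,
        linkage=z,
    )


N_COLOR_BINS = 5  # occurrence color scale for flareplots


def flareplot_export(freq_table: ContactFrequencyTable, region_map=None, path=None):
    """Flareplot graph document: residue nodes (grouped by chain/region)
    and frequency-weighted edges with occurrence color bins.

    Returns the document (dict) and optionally writes schema-stable JSON.
    """
    if not len(freq_table.table):
        raise ValueError("empty frequency table")
    nodes = {}
    for row in freq_table.table.itertuples():
        for chain, res in ((row.chainA, int(row.resA)), (row.chainB, int(row.resB))):
            key = f"{chain}:{res}"
            if key not in nodes:
                region = ""
                if region_map is not None:
                    region = region_map.region_of(res) or ""
                nodes[key] = {"id": key, "chain": chain, "residue": res, "group": region}
    edges = []
    for row in freq_table.table.itertuples():
        f = float(row.frequency)
        color_bin = min(int(f * N_COLOR_BINS), N_COLOR_BINS - 1)
        edges.append(
            {
                "source": f"{row.chainA}:{int(row.resA)}",
                "target": f"{row.chainB}:{int(row.resB)}",
                "type": row.type,
                "frequency": f,
                "color_bin": color_bin,
            }
        )
    doc = {
        "schema": "flareplot-graph/1",
        "n_frames": freq_table.n_frames,
        "nodes": sorted(nodes.values(), key=lambda n: (n["chain"], n["residue"])),
        "edges": edges,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    return doc


def parse_flareplot(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "flareplot-graph/1":
        raise ValueError("not a flareplot graph document")
    return doc
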