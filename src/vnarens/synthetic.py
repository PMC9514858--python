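"""Synthetic metastable torsion ensembles and toy peptide structures.

Real binding-site ensembles come from microsecond enhanced-sampling MD that
is neither deposited nor desk-scale.  This module replaces them with a
generator whose ground truth is exact: a discrete-time hidden Markov chain
over conformational macrostates (row-stochastic transition matrix with a
known stationary distribution) emits backbone torsion angles from per-state
von Mises distributions.  Every downstream stage -- featurization, tICA,
microstate clustering, MSM estimation, PCCA+ coarse-graining, entropies --
can then be checked against the generator's stationary masses, rates and
emission parameters.

Toy 3-D peptide ensembles (ideal backbone geometry, optional single
functional side-chain atom per charged/polar residue) provide fixtures for
the contact and surface stages.

A frame nominally spans 0.1 ns, so lag times quoted in nanoseconds map onto
frame counts; this interval is a declared convention of the generator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .featurize import TorsionTrajectory, wrap_degrees

__all__ = [
    "SyntheticSpec",
    "SyntheticEnsemble",
    "stationary_distribution",
    "sample_markov_chain",
    "emit_torsions",
    "metropolis_transition_matrix",
    "default_emission_means",
    "make_humanization_scenario",
    "build_toy_peptide",
    "DEFAULT_FRAME_INTERVAL_NS",
]

DEFAULT_FRAME_INTERVAL_NS = 0.1

# Paratope-like dihedral layout shared by the default scenarios: five
# residues spanning CDR1, HV2 and CDR3, phi and psi each.
DEFAULT_RESIDUE_IDS = (27, 30, 45, 90, 95)
DEFAULT_RESIDUE_REGIONS = ("CDR1", "CDR1", "HV2", "CDR3", "CDR3")


def _validate_transition_matrix(matrix) -> np.ndarray:
    t = np.asarray(matrix, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(t < 0):
        raise ValueError("transition matrix entries must be non-negative")
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1 (tol 1e-12)")
    return t


def stationary_distribution(matrix) -> np.ndarray:
    """Stationary vector pi with pi T = pi, from the eigenproblem of T^T.

    Emits a warning when the chain is reducible (stationary vector not
    unique); the returned vector then belongs to one recurrent class.
    """
    from scipy.sparse.csgraph import connected_components

    t = _validate_transition_matrix(matrix)
    n_comp, _ = connected_components(t > 0, directed=True, connection="strong")
    if n_comp > 1:
        warnings.warn(
            "transition matrix is reducible; stationary distribution not unique"
        )
    vals, vecs = np.linalg.eig(t.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_markov_chain(transition_matrix, n_steps: int, seed) -> np.ndarray:
    """Sample a state sequence; the first state is a stationary draw.

    Reproducible for a fixed seed (``seed`` may be an int or a numpy
    ``Generator``/``SeedSequence``).
    """
    t = _validate_transition_matrix(transition_matrix)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(t)
    cum = np.cumsum(t, axis=1)
    cum[:, -1] = 1.0  # guard against round-off
    states = np.empty(n_steps, dtype=np.int64)
    u = rng.random(n_steps)
    s = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    s = min(s, t.shape[0] - 1)
    states[0] = s
    for i in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[i], side="right"))
        states[i] = s
    return states


def emit_torsions(
    states,
    means_deg,
    kappas,
    seed,
    residue_ids=None,
    kinds=None,
    regions=None,
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS,
) -> TorsionTrajectory:
    """Emit per-frame torsions from per-state circular distributions.

    ``means_deg`` and ``kappas`` are (n_states, n_dihedrals) arrays: circular
    mean (degrees, in [-180, 180)) and von Mises concentration (> 0) for each
    macrostate and dihedral.
    """
    states = np.asarray(states, dtype=int)
    means = np.asarray(means_deg, dtype=float)
    kap = np.asarray(kappas, dtype=float)
    if means.ndim != 2 or means.shape != kap.shape:
        raise ValueError("means and kappas must share a (n_states, n_dihedrals) shape")
    if states.min() < 0 or states.max() >= means.shape[0]:
        raise ValueError("state index outside emission table")
    if np.any(kap <= 0):
        raise ValueError("concentration parameters must be > 0")
    if np.any(means < -180) or np.any(means >= 180):
        raise ValueError("circular means must lie in [-180, 180)")
    rng = np.random.default_rng(seed)
    mu_rad = np.radians(means)[states]  # (n_frames, n_dih)
    angles = np.degrees(rng.vonmises(mu_rad, kap[states]))
    angles = wrap_degrees(angles)
    n_dih = means.shape[1]
    if residue_ids is None:
        residue_ids = np.repeat(np.arange(1, n_dih // 2 + 2), 2)[:n_dih]
    if kinds is None:
        kinds = np.array(["phi", "psi"] * ((n_dih + 1) // 2), dtype=object)[:n_dih]
    return TorsionTrajectory(
        angles=angles,
        residue_ids=np.asarray(residue_ids),
        kinds=np.asarray(kinds, dtype=object),
        regions=None if regions is None else np.asarray(regions, dtype=object),
        frame_interval_ns=frame_interval_ns,
    )


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic torsion ensemble."""

    transition_matrix: np.ndarray
    means_deg: np.ndarray  # (n_states, n_dihedrals)
    kappas: np.ndarray  # (n_states, n_dihedrals)
    n_frames: int
    seed: int
    residue_ids: np.ndarray = None
    kinds: np.ndarray = None
    regions: np.ndarray = None
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS

    def __post_init__(self):
        self.transition_matrix = _validate_transition_matrix(self.transition_matrix)
        self.means_deg = np.asarray(self.means_deg, dtype=float)
        self.kappas = np.asarray(self.kappas, dtype=float)
        if self.means_deg.shape[0] != self.transition_matrix.shape[0]:
            raise ValueError("one emission row per macrostate required")
        if np.any(self.kappas <= 0):
            raise ValueError("concentration parameters must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def n_macrostates(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def stationary(self) -> np.ndarray:
        return stationary_distribution(self.transition_matrix)

    def sample(self) -> "SyntheticEnsemble":
        ss = np.random.SeedSequence(self.seed)
        chain_seed, emit_seed = ss.spawn(2)
        states = sample_markov_chain(self.transition_matrix, self.n_frames, chain_seed)
        traj = emit_torsions(
            states,
            self.means_deg,
            self.kappas,
            emit_seed,
            residue_ids=self.residue_ids,
            kinds=self.kinds,
            regions=self.regions,
            frame_interval_ns=self.frame_interval_ns,
        )
        return SyntheticEnsemble(
            trajectory=traj,
            true_states=states,
            true_stationary=self.stationary,
            spec=self,
        )

    def ground_truth_dict(self) -> dict:
        return {
            "n_macrostates": int(self.n_macrostates),
            "transition_matrix": self.transition_matrix.tolist(),
            "stationary": self.stationary.tolist(),
            "means_deg": self.means_deg.tolist(),
            "kappas": self.kappas.tolist(),
            "n_frames": int(self.n_frames),
            "seed": int(self.seed),
            "frame_interval_ns": self.frame_interval_ns,
        }


@dataclass
class SyntheticEnsemble:
    trajectory: TorsionTrajectory
    true_states: np.ndarray
    true_stationary: np.ndarray
    spec: SyntheticSpec = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.true_states) != self.trajectory.n_frames:
            raise ValueError("true_states length must equal n_frames")
        if not np.isclose(self.true_stationary.sum(), 1.0):
            raise ValueError("true_stationary must sum to 1")

    def write(self, directory) -> None:
        """Write the torsion table and the ground-truth JSON sidecar."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.trajectory.to_tsv(directory / "torsions.tsv")
        np.savetxt(directory / "true_states.tsv", self.true_states, fmt="%d")
        sidecar = {"true_stationary": self.true_stationary.tolist()}
        if self.spec is not None:
            sidecar["spec"] = self.spec.ground_truth_dict()
        (directory / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# Scenario construction


def metropolis_transition_matrix(
    pi, slowest_timescale_frames: float = 100.0
) -> np.ndarray:
    """Reversible chain with exact stationary vector ``pi``.

    Uses a Metropolis kernel with uniform proposals, globally rescaled so
    that the slowest implied timescale equals ``slowest_timescale_frames``.
    Detailed balance holds exactly, so ``pi`` is the stationary distribution
    by construction; the timescale target (default 100 frames = 10 ns
    nominal) puts the interstate kinetics on a scale that a 5e5-frame
    trajectory samples well while remaining metastable on the analysis lags.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be strictly positive and sum to 1")
    k = len(pi)
    if k < 2:
        raise ValueError("need at least two states")
    kernel = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                kernel[i, j] = min(1.0, pi[j] / pi[i]) / (k - 1)
        kernel[i, i] = 1.0 - kernel[i].sum()
    # second eigenvalue of the full-rate kernel fixes the global rescaling
    vals = np.linalg.eigvals(kernel)
    vals = np.sort(np.real(vals))[::-1]
    lam2 = vals[1]
    target = np.exp(-1.0 / slowest_timescale_frames)
    a = (1.0 - target) / (1.0 - lam2)
    if a > 1.0:
        raise ValueError("requested timescale too short for a valid chain")
    t = (1.0 - a) * np.eye(k) + a * kernel
    return _validate_transition_matrix(t / t.sum(axis=1, keepdims=True))


def default_emission_means(n_states: int, n_dihedrals: int) -> np.ndarray:
    """Well-separated circular means: states spaced 360/n_states degrees
    apart on every dihedral, with a deterministic per-dihedral offset."""
    offsets = wrap_degrees(-180.0 + 17.0 * np.arange(n_dihedrals))
    step = 360.0 / n_states
    means = wrap_degrees(offsets[None, :] + step * np.arange(n_states)[:, None])
    return means


def _scenario_spec(
    dominant_mass: float,
    n_frames: int,
    seed: int,
    n_macrostates: int,
    kappa: float,
    slowest_timescale_frames: float,
) -> SyntheticSpec:
    if not 0.0 < dominant_mass < 1.0:
        raise ValueError("dominant mass must lie in (0, 1)")
    rest = (1.0 - dominant_mass) / (n_macrostates - 1)
    pi = np.full(n_macrostates, rest)
    pi[0] = dominant_mass
    n_dih = 2 * len(DEFAULT_RESIDUE_IDS)
    res_ids = np.repeat(DEFAULT_RESIDUE_IDS, 2)
    kinds = np.array(["phi", "psi"] * len(DEFAULT_RESIDUE_IDS), dtype=object)
    regions = np.repeat(DEFAULT_RESIDUE_REGIONS, 2)
    return SyntheticSpec(
        transition_matrix=metropolis_transition_matrix(pi, slowest_timescale_frames),
        means_deg=default_emission_means(n_macrostates, n_dih),
        kappas=np.full((n_macrostates, n_dih), kappa),
        n_frames=n_frames,
        seed=seed,
        residue_ids=res_ids,
        kinds=kinds,
        regions=regions,
    )


def make_humanization_scenario(
    dominant_mass_parent: float = 0.92,
    dominant_mass_variant: float = 0.16,
    n_frames: int = 500_000,
    seed: int = 0,
    n_macrostates: int = 5,
    kappa: float = 20.0,
    slowest_timescale_frames: float = 100.0,
):
    """Parent/variant ensemble pair sharing emission geometry.

    Emulates the experimental contrast of the humanization study: the parent
    binder keeps one dominant binding-competent macrostate (default mass
    0.92) while the humanized variant redistributes that mass (default 0.16
    for the same state, remainder spread evenly over the other macrostates).
    State 0 is the binding-competent macrostate in both systems.

    Returns ``(parent, variant)`` as :class:`SyntheticEnsemble`.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    parent = _scenario_spec(
        dominant_mass_parent, n_frames, seeds[0], n_macrostates, kappa,
        slowest_timescale_frames,
    ).sample()
    variant = _scenario_spec(
        dominant_mass_variant, n_frames, seeds[1], n_macrostates, kappa,
        slowest_timescale_frames,
    ).sample()
    return parent, variant


# ---------------------------------------------------------------------------
# Toy peptide construction (internal-to-Cartesian, ideal geometry)

# Ideal backbone geometry: bond lengths (Angstrom) and angles (degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5
OMEGA = 180.0  # trans peptide bond

# single representative functional ("pseudo side chain") atom per
# charged/polar residue type: (atom name, element, distance from CB along
# the CA->CB direction, formal charge sign)
FUNCTIONAL_ATOMS = {
    "LYS": ("NZ", "N", 3.3, +1),
    "ARG": ("NH1", "N", 4.1, +1),
    "ASP": ("OD1", "O", 1.6, -1),
    "GLU": ("OE1", "O", 2.6, -1),
    "ASN": ("OD1", "O", 1.6, 0),
    "GLN": ("OE1", "O", 2.6, 0),
    "SER": ("OG", "O", 1.4, 0),
    "THR": ("OG1", "O", 1.4, 0),
    "TYR": ("OH", "O", 4.4, 0),
    "HIS": ("NE2", "N", 2.9, 0),
    "TRP": ("NE1", "N", 2.8, 0),
}

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d given chain a-b-c, internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # a, b, c collinear: any perpendicular frame works
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_toy_peptide(sequence: str, phi_psi_per_frame, side_chain_atoms: bool = False):
    """Multi-model toy peptide from per-frame (phi, psi) torsions.

    Backbone atoms N, CA, C, O (and CB for non-glycine residues) are placed
    by ideal bond lengths/angles via sequential internal-to-Cartesian (NeRF)
    construction with a trans (omega = 180) peptide bond.  phi of the first
    residue and psi of the last are undefined and ignored.  With
    ``side_chain_atoms=True``, charged/polar residues additionally carry one
    labeled functional pseudo-atom extended along the CA->CB axis, for typed
    contact fixtures.

    Returns a :class:`~vnarens.structio.StructureModel`; recomputing phi/psi
    from the coordinates returns the input angles to within 0.5 degrees.
    """
    import biotite.structure as struc

    from .structio import StructureModel

    sequence = sequence.upper()
    for code in sequence:
        if code not in _THREE:
            raise ValueError(f"unknown residue code {code!r}")
    torsions = np.asarray(phi_psi_per_frame, dtype=float)
    if torsions.ndim == 2:
        torsions = torsions[None]
    n_frames, n_res, two = torsions.shape
    if n_res != len(sequence) or two != 2:
        raise ValueError("phi_psi_per_frame must have shape (frames, n_res, 2)")

    atom_names, elements, res_names, res_ids, charges = [], [], [], [], []
    for i, code in enumerate(sequence):
        res3 = _THREE[code]
        names = ["N", "CA", "C", "O"]
        elems = ["N", "C", "C", "O"]
        if res3 != "GLY":
            names.append("CB")
            elems.append("C")
        if side_chain_atoms and res3 in FUNCTIONAL_ATOMS:
            fn, fe, _, fq = FUNCTIONAL_ATOMS[res3]
            names.append(fn)
            elems.append(fe)
        for name, elem in zip(names, elems):
            atom_names.append(name)
            elements.append(elem)
            res_names.append(res3)
            res_ids.append(i + 1)

    coords = np.zeros((n_frames, len(atom_names), 3))
    for f in range(n_frames):
        positions = {}
        # first residue: N at origin, CA on x, C in the xy-plane
        n0 = np.array([0.0, 0.0, 0.0])
        ca0 = np.array([BOND_N_CA, 0.0, 0.0])
        ang = np.radians(ANGLE_N_CA_C)
        c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        positions[(1, "N")], positions[(1, "CA")], positions[(1, "C")] = n0, ca0, c0
        for i in range(2, n_res + 1):
            psi_prev = torsions[f, i - 2, 1]
            phi_i = torsions[f, i - 1, 0]
            n_prev = positions[(i - 1, "N")]
            ca_prev = positions[(i - 1, "CA")]
            c_prev = positions[(i - 1, "C")]
            n_i = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
            ca_i = _place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c_i = _place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
            positions[(i, "N")], positions[(i, "CA")], positions[(i, "C")] = (
                n_i, ca_i, c_i,
            )
        # carbonyl O, CB and functional atoms
        for i in range(1, n_res + 1):
            n_i, ca_i, c_i = (
                positions[(i, "N")], positions[(i, "CA")], positions[(i, "C")],
            )
            if i < n_res:
                # O is anti to the next N across the peptide plane
                psi_i = torsions[f, i - 1, 1]
                o_tor = psi_i + 180.0
            else:
                o_tor = 0.0
            positions[(i, "O")] = _place_atom(
                n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, o_tor
            )
            res3 = _THREE[sequence[i - 1]]
            if res3 != "GLY":
                cb = _place_atom(c_i, n_i, ca_i, BOND_CA_CB, ANGLE_N_CA_CB, -122.0)
                positions[(i, "CB")] = cb
                if side_chain_atoms and res3 in FUNCTIONAL_ATOMS:
                    fn, _, dist, _ = FUNCTIONAL_ATOMS[res3]
                    direction = cb - ca_i
                    direction /= np.linalg.norm(direction)
                    positions[(i, fn)] = cb + dist * direction
        for a, (name, rid) in enumerate(zip(atom_names, res_ids)):
            coords[f, a] = positions[(rid, name)]

    atoms = struc.AtomArray(len(atom_names))
    atoms.atom_name = np.asarray(atom_names)
    atoms.element = np.asarray(elements)
    atoms.res_name = np.asarray(res_names)
    atoms.res_id = np.asarray(res_ids)
    atoms.chain_id = np.asarray(["A"] * len(atom_names))
    atoms.hetero = np.zeros(len(atom_names), dtype=bool)
    stack = struc.from_template(atoms, coords)
    return StructureModel(stack=stack)


def formal_charge(res_name: str, atom_name: str) -> int:
    """Formal charge sign convention of the toy fixtures (side-chain level)."""
    info = FUNCTIONAL_ATOMS.get(res_name)
    if info is not None and info[0] == atom_name:
        return info[3]
    return 0
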