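"""Markov-state model construction and validation.

The kinetic machinery behind the ensemble characterization: k-means
microstates in tICA space, a reversible maximum-likelihood transition
matrix at a lag time, implied timescales, PCCA+ coarse-graining into
metastable macrostates with stationary probabilities and mean first-passage
times, the Chapman-Kolmogorov self-consistency test and the VAMP-2 score.

Thermodynamics (state probabilities) come from the stationary distribution
of the reversible transition matrix; kinetics (transition timescales) from
its eigenvalues and from MFPTs between macrostates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MicrostateAssignment",
    "cluster_microstates",
    "TransitionMatrix",
    "count_transitions",
    "estimate_transition_matrix",
    "implied_timescales",
    "MacrostateModel",
    "pcca",
    "ck_test",
    "CKResult",
    "mfpt",
    "vamp2_score",
]


# ---------------------------------------------------------------------------
# Microstates


@dataclass
class MicrostateAssignment:
    """Per-frame integer microstate labels with their k-means centers."""

    labels: list  # list of (n_frames_i,) int arrays, one per trajectory
    centers: np.ndarray
    k: int
    seed: int
    inertia: float = np.nan

    def __post_init__(self):
        if isinstance(self.labels, np.ndarray):
            self.labels = [self.labels]
        for lab in self.labels:
            if lab.min() < 0 or lab.max() >= self.k:
                raise ValueError("labels must lie in [0, k)")

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.labels)


def cluster_microstates(coords, k: int = 100, seed: int = 0) -> MicrostateAssignment:
    """k-means microstates (k-means++ seeding, deterministic for a seed).

    ``coords`` is a (frames, d) array or a list of such arrays (one per
    trajectory); clustering is performed on the pooled frames and labels are
    returned per trajectory.
    """
    from sklearn.cluster import KMeans

    if isinstance(coords, np.ndarray):
        blocks = [np.asarray(coords, dtype=float)]
    else:
        blocks = [np.asarray(c, dtype=float) for c in coords]
    pooled = np.vstack(blocks)
    if pooled.shape[0] < k:
        raise ValueError(
            f"{pooled.shape[0]} frames cannot support k={k} microstates; "
            "reduce k"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=int(seed))
    flat = km.fit_predict(pooled)
    labels, start = [], 0
    for b in blocks:
        labels.append(flat[start : start + len(b)].astype(np.int64))
        start += len(b)
    return MicrostateAssignment(
        labels=labels, centers=km.cluster_centers_, k=k, seed=int(seed),
        inertia=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# Transition matrix estimation


def count_transitions(label_sequences, lag: int, n_states: int = None) -> np.ndarray:
    """Sliding-window transition counts at integer lag, within-trajectory only."""
    if isinstance(label_sequences, np.ndarray):
        label_sequences = [label_sequences]
    seqs = [np.asarray(s, dtype=np.int64) for s in label_sequences]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if n_states is None:
        n_states = max(int(s.max()) for s in seqs if len(s)) + 1
    counts = np.zeros((n_states, n_states))
    for s in seqs:
        if len(s) <= lag:
            continue
        np.add.at(counts, (s[:-lag], s[lag:]), 1.0)
    return counts


def _largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected set of the count graph."""
    from scipy.sparse.csgraph import connected_components

    n_comp, assign = connected_components(
        counts > 0, directed=True, connection="strong"
    )
    sizes = np.bincount(assign, weights=counts.sum(axis=1) + counts.sum(axis=0))
    best = int(np.argmax(sizes))
    return np.flatnonzero(assign == best)


def _reversible_mle(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1_000_000):
    """Reversible maximum-likelihood transition matrix.

    Classic fixed-point iteration on the symmetric edge weights x_ij:
    ``x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)`` with row sums
    ``x_i = sum_j x_ij`` and row counts ``c_i = sum_j c_ij``; converged when
    ``max |Delta T| < tol``.  Returns (T, pi).
    """
    c_sym = counts + counts.T
    c_row = counts.sum(axis=1)
    x = c_sym.copy()
    x /= x.sum()
    t_prev = None
    for _ in range(max_iter):
        x_row = x.sum(axis=1)
        denom = c_row[:, None] / x_row[:, None] + c_row[None, :] / x_row[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_row = x.sum(axis=1)
        t = x / x_row[:, None]
        if t_prev is not None and np.max(np.abs(t - t_prev)) < tol:
            break
        t_prev = t
    pi = x_row / x_row.sum()
    return t, pi


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix at a lag with stationary vector."""

    matrix: np.ndarray
    lag: int
    counts: np.ndarray = None
    stationary: np.ndarray = None
    estimator: str = "reversible-mle"
    active_set: np.ndarray = None  # original microstate index per matrix row
    fraction_of_states: float = 1.0
    frame_interval_ns: float = 0.1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.matrix < 0):
            raise ValueError("transition matrix entries must be >= 0")
        if self.stationary is None:
            from .synthetic import stationary_distribution

            self.stationary = stationary_distribution(self.matrix)
        if self.active_set is None:
            self.active_set = np.arange(n)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def lag_ns(self) -> float:
        return self.lag * self.frame_interval_ns

    def eigenvalues(self, n: int = None) -> np.ndarray:
        """Real spectrum of the reversible matrix, descending."""
        vals = _reversible_spectrum(self.matrix, self.stationary)[0]
        return vals if n is None else vals[:n]

    def right_eigenvectors(self, n: int) -> np.ndarray:
        return _reversible_spectrum(self.matrix, self.stationary)[1][:, :n]


def _reversible_spectrum(t: np.ndarray, pi: np.ndarray):
    """Eigendecomposition via the pi-symmetrized form (real spectrum).

    Returns (eigenvalues descending, right eigenvectors as columns).  Falls
    back to the non-symmetric solver when detailed balance does not hold.
    """
    from scipy.linalg import eig, eigh

    sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
    s = sqrt_pi[:, None] * t / sqrt_pi[None, :]
    if np.max(np.abs(s - s.T)) < 1e-8 * max(1.0, np.max(np.abs(s))):
        vals, vecs = eigh(0.5 * (s + s.T))
        order = np.argsort(vals)[::-1]
        vals = vals[order]
        right = vecs[:, order] / sqrt_pi[:, None]
    else:
        vals, right = eig(t)
        order = np.argsort(np.real(vals))[::-1]
        vals = np.real(vals[order])
        right = np.real(right[:, order])
    # normalize so the stationary eigenvector is constant 1
    for j in range(right.shape[1]):
        norm = np.sqrt(np.sum(pi * right[:, j] ** 2))
        if norm > 0:
            right[:, j] /= norm
        k = int(np.argmax(np.abs(right[:, j])))
        if right[k, j] < 0:
            right[:, j] = -right[:, j]
    return vals, right


def estimate_transition_matrix(
    label_sequences,
    lag: int,
    estimator: str = "reversible-mle",
    n_states: int = None,
    frame_interval_ns: float = 0.1,
) -> TransitionMatrix:
    """Estimate a transition matrix at integer lag from label sequences.

    Counting is sliding-window and restricted to within-trajectory pairs.
    The estimate is restricted to the largest strongly connected set of the
    count graph (the "fraction of states used" is reported on the result).
    ``estimator`` is ``"reversible-mle"`` (fixed-point iteration, detailed
    balance holds exactly) or ``"symmetrized"`` (row-normalized
    ``(C + C^T)/2``, the small-data fallback).
    """
    counts = count_transitions(label_sequences, lag, n_states)
    if counts.sum() == 0:
        raise ValueError(f"no transitions observed at lag {lag}")
    active = _largest_connected_set(counts)
    if len(active) < counts.shape[0]:
        warnings.warn(
            f"restricting to largest connected set: {len(active)}/{counts.shape[0]} states"
        )
    sub = counts[np.ix_(active, active)]
    if estimator == "reversible-mle":
        t, pi = _reversible_mle(sub)
    elif estimator == "symmetrized":
        c_sym = 0.5 * (sub + sub.T)
        t = c_sym / c_sym.sum(axis=1, keepdims=True)
        pi = c_sym.sum(axis=1) / c_sym.sum()
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return TransitionMatrix(
        matrix=t,
        lag=int(lag),
        counts=sub,
        stationary=pi,
        estimator=estimator,
        active_set=active,
        fraction_of_states=len(active) / counts.shape[0],
        frame_interval_ns=frame_interval_ns,
    )


def implied_timescales(tm: TransitionMatrix, n: int = 5):
    """Implied timescales t_i = -tau / ln|lambda_{i+1}| (frames).

    The stationary eigenvalue (lambda_1 = 1) is excluded.  Negative
    eigenvalues enter through their magnitude and are flagged.  Infinite
    timescales (degenerate unit eigenvalues) are reported as ``inf``.
    Returns ``(timescales, flagged_negative)``.
    """
    vals = tm.eigenvalues()[1 : n + 1]
    flagged = vals < 0
    if np.any(flagged):
        warnings.warn("negative eigenvalues encountered; using magnitudes")
    mag = np.abs(vals)
    ts = np.full(len(mag), np.inf)
    nonunit = mag < 1.0 - 1e-12
    positive = mag > 0
    use = nonunit & positive
    ts[use] = -tm.lag / np.log(mag[use])
    ts[~positive] = 0.0
    return ts, flagged


# ---------------------------------------------------------------------------
# PCCA+


@dataclass
class MacrostateModel:
    """PCCA+ coarse-graining of a microstate MSM."""

    memberships: np.ndarray  # chi, (k, m), rows sum to 1, >= 0
    crisp: np.ndarray  # per-microstate macrostate (argmax chi)
    probabilities: np.ndarray  # per-macrostate stationary mass
    source: TransitionMatrix = field(repr=False, default=None)
    mfpt_lag_units: np.ndarray = None  # (m, m) macrostate MFPTs, lag units
    spectral_gap_report: dict = field(default_factory=dict)

    @property
    def n_macrostates(self) -> int:
        return self.memberships.shape[1]

    @property
    def mfpt_ns(self) -> np.ndarray:
        if self.mfpt_lag_units is None or self.source is None:
            return None
        return self.mfpt_lag_units * self.source.lag * self.source.frame_interval_ns

    def macrostate_of_frames(self, microstate_labels) -> np.ndarray:
        """Map a microstate label sequence to crisp macrostate labels."""
        lookup = np.full(int(self.source.active_set.max()) + 1, -1, dtype=int)
        lookup[self.source.active_set] = self.crisp
        return lookup[np.asarray(microstate_labels, dtype=int)]


def _inner_simplex_vertices(evecs: np.ndarray, m: int) -> np.ndarray:
    """Vertex search of the inner-simplex algorithm.

    First vertex: row of maximal norm; each further vertex maximizes the
    distance to the span of the vertices found so far (via orthogonalized
    residuals).
    """
    x = evecs.copy()
    vertices = np.empty(m, dtype=int)
    norms = np.linalg.norm(x, axis=1)
    vertices[0] = int(np.argmax(norms))
    basis = []
    for j in range(1, m):
        v = x[vertices[j - 1]]
        for b in basis:
            v = v - (v @ b) * b
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            basis.append(v / nv)
        resid = x.copy()
        for b in basis:
            resid = resid - np.outer(resid @ b, b)
        vertices[j] = int(np.argmax(np.linalg.norm(resid, axis=1)))
    return vertices


def pcca(tm: TransitionMatrix, m: int) -> MacrostateModel:
    """PCCA+ coarse-graining into ``m`` metastable macrostates.

    Memberships chi are built from the first ``m`` right eigenvectors of the
    reversible transition matrix via the inner-simplex vertex search; the
    linear transform maps the eigenvector rows into the simplex spanned by
    the vertex rows, after which small negative entries are clipped and rows
    renormalized so chi >= 0 with unit row sums.  Crisp states are
    ``argmax chi`` (ties to the lower macrostate index); macrostate
    probabilities are sums of the stationary vector over crisp members.
    """
    k = tm.n_states
    if m < 1 or m > k:
        raise ValueError(f"m must lie in [1, {k}]")
    if m == 1:
        memberships = np.ones((k, 1))
        crisp = np.zeros(k, dtype=int)
        probs = np.array([1.0])
        return MacrostateModel(
            memberships=memberships, crisp=crisp, probabilities=probs, source=tm
        )
    vals = tm.eigenvalues()
    if m < k:
        gap_num = vals[m - 1] - vals[m]
        gap_den = max(1.0 - vals[m - 1], 1e-12)
        report = {
            "eigenvalues": vals[: min(k, m + 3)].tolist(),
            "gap_after_m": float(gap_num),
        }
        if gap_num < 1e-3:
            warnings.warn(
                f"eigenvalues {m} and {m + 1} nearly degenerate "
                f"(gap {gap_num:.2e}); macrostate count may be ill-determined"
            )
    else:
        report = {"eigenvalues": vals.tolist(), "gap_after_m": np.nan}
    evecs = tm.right_eigenvectors(m)
    vertices = _inner_simplex_vertices(evecs, m)
    chi = evecs @ np.linalg.inv(evecs[vertices])
    chi = np.clip(chi, 0.0, None)
    rows = chi.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    chi = chi / rows
    crisp = np.argmax(chi, axis=1)  # argmax ties -> lower index
    probs = np.array([tm.stationary[crisp == j].sum() for j in range(m)])
    mfpts = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i != j:
                from_set = np.flatnonzero(crisp == i)
                to_set = np.flatnonzero(crisp == j)
                if len(from_set) and len(to_set):
                    mfpts[i, j] = mfpt(tm, from_set, to_set)
                else:
                    mfpts[i, j] = np.inf
    return MacrostateModel(
        memberships=chi,
        crisp=crisp,
        probabilities=probs,
        source=tm,
        mfpt_lag_units=mfpts,
        spectral_gap_report=report,
    )


def n_macrostates_by_spectral_gap(tm: TransitionMatrix, m_max: int = 10, m_min: int = 2) -> int:
    """Macrostate count by the largest relative spectral gap.

    Chooses m maximizing ``(lambda_m - lambda_{m+1}) / lambda_m`` over
    ``m_min <= m <= m_max`` (eigenvalues descending, lambda_1 = 1).
    """
    vals = np.abs(tm.eigenvalues())
    m_max = min(m_max, tm.n_states - 1)
    best_m, best_gap = m_min, -np.inf
    for m in range(m_min, m_max + 1):
        lam_m = max(vals[m - 1], 1e-12)
        gap = (vals[m - 1] - vals[m]) / lam_m
        if gap > best_gap:
            best_m, best_gap = m, gap
    return best_m


# ---------------------------------------------------------------------------
# Validation


@dataclass
class CKResult:
    """Chapman-Kolmogorov set-persistence curves, predicted vs estimated."""

    factors: np.ndarray
    predicted: np.ndarray  # (n_sets, n_factors)
    estimated: np.ndarray
    estimated_se: np.ndarray
    set_labels: list

    @property
    def deviations(self) -> np.ndarray:
        return np.abs(self.predicted - self.estimated)

    def max_sigma_deviation(self) -> float:
        """Largest deviation in units of the bootstrap standard error."""
        se = np.where(self.estimated_se > 0, self.estimated_se, np.nan)
        with np.errstate(invalid="ignore"):
            sig = self.deviations / se
        return float(np.nanmax(sig))

    def passes(self, n_se: float = 3.0) -> bool:
        return self.max_sigma_deviation() <= n_se


def _set_persistence(tm_matrix: np.ndarray, pi: np.ndarray, sets) -> np.ndarray:
    """P(state in A at time t | started in A, stationary within A)."""
    out = np.empty(len(sets))
    for i, members in enumerate(sets):
        w = np.zeros(len(pi))
        w[members] = pi[members]
        total = w.sum()
        if total == 0:
            out[i] = np.nan
            continue
        w /= total
        out[i] = float((w @ tm_matrix)[members].sum())
    return out


def ck_test(
    label_sequences,
    lag: int,
    macrostate_sets,
    factors=(1, 2, 3, 4, 5),
    estimator: str = "reversible-mle",
    n_bootstrap: int = 50,
    seed: int = 0,
) -> CKResult:
    """Chapman-Kolmogorov test on macrostate set persistences.

    For each factor f, compares the prediction ``[T(tau)]^f`` against a
    transition matrix estimated directly at ``f * tau``, both projected on
    the given macrostate sets (lists of microstate indices).  Standard
    errors of the direct estimates come from a trajectory-chunk bootstrap.
    Factors for which no trajectory supports the lag are omitted with a
    warning.
    """
    if isinstance(label_sequences, np.ndarray):
        label_sequences = [label_sequences]
    seqs = [np.asarray(s, dtype=np.int64) for s in label_sequences]
    n_states = max(int(s.max()) for s in seqs) + 1

    base = estimate_transition_matrix(seqs, lag, estimator, n_states=n_states)
    if len(base.active_set) < n_states:
        raise ValueError("CK test requires a fully connected base estimate")
    sets = [np.asarray(list(s), dtype=int) for s in macrostate_sets]

    usable_factors = []
    for f in factors:
        if any(len(s) > f * lag for s in seqs):
            usable_factors.append(int(f))
        else:
            warnings.warn(f"factor {f}: insufficient data at lag {f * lag}; omitted")
    factors = np.asarray(usable_factors)

    predicted = np.empty((len(sets), len(factors)))
    estimated = np.empty_like(predicted)
    estimated_se = np.empty_like(predicted)

    rng = np.random.default_rng(seed)
    chunk = max(10 * lag * max(factors), 100)
    chunks = []
    for s in seqs:
        for start in range(0, len(s), chunk):
            piece = s[start : start + chunk]
            if len(piece) > lag:
                chunks.append(piece)

    power = np.eye(n_states)
    t_base = base.matrix
    for col, f in enumerate(factors):
        power = np.linalg.matrix_power(t_base, f)
        predicted[:, col] = _set_persistence(power, base.stationary, sets)
        direct = estimate_transition_matrix(
            seqs, f * lag, estimator, n_states=n_states
        )
        if len(direct.active_set) < n_states:
            full = np.eye(n_states)
            full_pi = np.zeros(n_states)
            idx = direct.active_set
            full[np.ix_(idx, idx)] = direct.matrix
            full_pi[idx] = direct.stationary
            estimated[:, col] = _set_persistence(full, full_pi, sets)
        else:
            estimated[:, col] = _set_persistence(
                direct.matrix, direct.stationary, sets
            )
        boot = np.empty((n_bootstrap, len(sets)))
        for b in range(n_bootstrap):
            pick = rng.integers(0, len(chunks), size=len(chunks))
            resampled = [chunks[i] for i in pick]
            counts = count_transitions(resampled, f * lag, n_states)
            if counts.sum() == 0:
                boot[b] = np.nan
                continue
            c_sym = 0.5 * (counts + counts.T)
            row = c_sym.sum(axis=1)
            row[row == 0] = 1.0
            t_b = c_sym / row[:, None]
            pi_b = c_sym.sum(axis=1) / c_sym.sum()
            boot[b] = _set_persistence(t_b, pi_b, sets)
        estimated_se[:, col] = np.nanstd(boot, axis=0, ddof=1)

    return CKResult(
        factors=factors,
        predicted=predicted,
        estimated=estimated,
        estimated_se=estimated_se,
        set_labels=[list(map(int, s)) for s in sets],
    )


def mfpt(tm: TransitionMatrix, from_set, to_set) -> float:
    """Mean first-passage time (lag units) from ``from_set`` to ``to_set``.

    Solves ``m = 1 + T m`` with ``m = 0`` on the target set; the reported
    value averages the start states under the stationary distribution
    restricted to ``from_set``.  Returns ``inf`` if the target is
    unreachable.
    """
    from_set = np.asarray(list(np.atleast_1d(from_set)), dtype=int)
    to_set = np.asarray(list(np.atleast_1d(to_set)), dtype=int)
    if len(from_set) == 0 or len(to_set) == 0:
        raise ValueError("state sets must be nonempty")
    if np.intersect1d(from_set, to_set).size:
        raise ValueError("state sets must be disjoint")
    n = tm.n_states
    others = np.setdiff1d(np.arange(n), to_set)
    a = np.eye(len(others)) - tm.matrix[np.ix_(others, others)]
    try:
        m_others = np.linalg.solve(a, np.ones(len(others)))
    except np.linalg.LinAlgError:
        return np.inf
    if np.any(m_others < -1e-6):
        return np.inf
    m_full = np.zeros(n)
    m_full[others] = m_others
    w = tm.stationary[from_set]
    w = w / w.sum()
    return float(w @ m_full[from_set])


def vamp2_score(label_sequences, lag: int, n_components: int = 5) -> float:
    """VAMP-2 score of the discrete dynamics at a lag.

    Sum of the squared top singular values of the half-weighted transition
    operator estimate ``C00^{-1/2} C0t Ctt^{-1/2}`` built from one-hot
    indicator features.  The constant function contributes a unit singular
    value, so the score is >= 1; a perfectly metastable partition into r
    sets approaches r.  Rank-deficient estimates reduce the component count
    with a note.
    """
    if isinstance(label_sequences, np.ndarray):
        label_sequences = [label_sequences]
    seqs = [np.asarray(s, dtype=np.int64) for s in label_sequences]
    n_states = max(int(s.max()) for s in seqs) + 1
    c00 = np.zeros(n_states)
    ctt = np.zeros(n_states)
    c0t = np.zeros((n_states, n_states))
    n_pairs = 0
    for s in seqs:
        if len(s) <= lag:
            continue
        x0, xt = s[:-lag], s[lag:]
        c00 += np.bincount(x0, minlength=n_states)
        ctt += np.bincount(xt, minlength=n_states)
        np.add.at(c0t, (x0, xt), 1.0)
        n_pairs += len(x0)
    if n_pairs == 0:
        raise ValueError("no transition pairs at this lag")
    c00 /= n_pairs
    ctt /= n_pairs
    c0t /= n_pairs
    pos0 = c00 > 0
    post = ctt > 0
    rank = int(min(pos0.sum(), post.sum()))
    if n_components > rank:
        warnings.warn(
            f"rank deficiency: reducing components from {n_components} to {rank}"
        )
        n_components = rank
    inv0 = np.zeros(n_states)
    invt = np.zeros(n_states)
    inv0[pos0] = 1.0 / np.sqrt(c00[pos0])
    invt[post] = 1.0 / np.sqrt(ctt[post])
    k = inv0[:, None] * c0t * invt[None, :]
    sv = np.linalg.svd(k, compute_uv=False)
    return float(np.sum(sv[:n_components] ** 2))
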