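"""Time-lagged independent component analysis and free-energy landscapes.

tICA finds the linear combinations of input features with maximal
autocorrelation at a lag time tau: it solves the symmetrized generalized
eigenproblem ``C_sym v = lambda C0 v`` with ``C_sym = (C_tau + C_tau^T)/2``,
where ``C0`` is the instantaneous and ``C_tau`` the time-lagged covariance
of the mean-free features.  The symmetrized (reversible) estimator is the
default because equilibrium free-energy surfaces are the downstream use.

Two systems are compared "in the same coordinate system" by fitting one
model on their pooled features and projecting each system with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .featurize import FeatureMatrix

__all__ = ["TicaModel", "fit_tica", "project", "FreeEnergySurface", "free_energy_surface"]


@dataclass
class TicaModel:
    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ct: np.ndarray  # symmetrized time-lagged covariance
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, C0-orthonormal
    ridge: float
    frame_interval_ns: float = 0.1

    @property
    def n_features(self) -> int:
        return len(self.mean)

    def timescales(self) -> np.ndarray:
        """Relaxation timescales -tau/ln|lambda| in frames."""
        lam = np.clip(np.abs(self.eigenvalues), 1e-15, 1 - 1e-15)
        return -self.lag / np.log(lam)


def _as_value_list(features):
    if isinstance(features, (FeatureMatrix, np.ndarray)):
        features = [features]
    return [f.values if isinstance(f, FeatureMatrix) else np.asarray(f, float)
            for f in features]


def fit_tica(features, lag: int, reversible: bool = True, ridge: float = None) -> TicaModel:
    """Fit tICA at integer lag (frames) on one or more feature trajectories.

    Time-lagged pairs are formed only within each trajectory (sliding
    window).  Trajectories shorter than ``lag + 1`` frames are skipped with
    a warning.  A ridge ``eps`` (default ``1e-8 * trace(C0)/dim``) is added
    to C0 to regularize collinear features; the value used is reported on
    the model.
    """
    frame_interval = 0.1
    if isinstance(features, FeatureMatrix):
        frame_interval = features.frame_interval_ns
    elif isinstance(features, (list, tuple)) and features and isinstance(features[0], FeatureMatrix):
        frame_interval = features[0].frame_interval_ns
    blocks = _as_value_list(features)
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    dim = blocks[0].shape[1]
    if dim < 2:
        raise ValueError("tICA needs at least 2 features")

    usable = []
    for b in blocks:
        if b.shape[0] <= lag:
            warnings.warn(f"trajectory of {b.shape[0]} frames skipped (lag {lag})")
            continue
        usable.append(b)
    if not usable:
        raise ValueError("no trajectory longer than the lag")
    n_pairs = sum(b.shape[0] - lag for b in usable)

    # mean over both ends of all pairs (so the estimator is exactly
    # symmetric under time reversal)
    total = np.zeros(dim)
    for b in usable:
        total += b[:-lag].sum(axis=0) + b[lag:].sum(axis=0)
    mean = total / (2 * n_pairs)

    c0 = np.zeros((dim, dim))
    ct = np.zeros((dim, dim))
    for b in usable:
        x0 = b[:-lag] - mean
        xt = b[lag:] - mean
        c0 += x0.T @ x0 + xt.T @ xt
        ct += x0.T @ xt
    c0 /= 2 * n_pairs
    ct /= n_pairs
    if reversible:
        ct = 0.5 * (ct + ct.T)

    if ridge is None:
        ridge = 1e-8 * np.trace(c0) / dim
    c0_reg = c0 + ridge * np.eye(dim)

    from scipy.linalg import eigh

    vals, vecs = eigh(0.5 * (ct + ct.T), c0_reg)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return TicaModel(
        lag=int(lag), mean=mean, c0=c0, ct=ct,
        eigenvalues=vals, eigenvectors=vecs, ridge=float(ridge),
        frame_interval_ns=frame_interval,
    )


def project(model: TicaModel, features, n_components: int = 2) -> np.ndarray:
    """Project features onto the leading independent components."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model ({model.n_features})"
        )
    return (x - model.mean) @ model.eigenvectors[:, :n_components]


@dataclass
class FreeEnergySurface:
    """2-D free-energy surface Delta G = -ln(p / p_max) in kT units."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    delta_g: np.ndarray  # NaN on empty bins (flagged, never zero)
    temperature_K: float

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def max_delta_g(self) -> float:
        return float(np.nanmax(self.delta_g))

    def occupied_area_fraction(self) -> float:
        """Fraction of grid bins visited; a breadth measure for landscapes."""
        return float(self.occupied.mean())


def free_energy_surface(
    coords, n_bins: int = 100, temperature_K: float = 300.0, ranges=None
) -> FreeEnergySurface:
    """Histogram-based free-energy surface over the first two coordinates.

    Delta G_i = -ln(c_i / c_max) (kT); empty bins are NaN.  The grid covers
    the data with a 5% margin on each side unless explicit ``ranges``
    ((xmin, xmax), (ymin, ymax)) are given -- pass shared ranges to compare
    two systems on one grid.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] < 2:
        raise ValueError("need (frames, >=2) projected coordinates")
    x, y = coords[:, 0], coords[:, 1]
    if ranges is None:
        def pad(v):
            lo, hi = v.min(), v.max()
            margin = 0.05 * (hi - lo) if hi > lo else 0.5
            return lo - margin, hi + margin
        ranges = (pad(x), pad(y))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins, range=ranges)
    if (counts > 0).sum() < 2:
        warnings.warn("degenerate free-energy surface: fewer than 2 occupied bins")
    with np.errstate(divide="ignore"):
        delta_g = -np.log(counts / counts.max())
    delta_g[counts == 0] = np.nan
    return FreeEnergySurface(
        x_edges=x_edges, y_edges=y_edges, counts=counts,
        delta_g=delta_g, temperature_K=temperature_K,
    )
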