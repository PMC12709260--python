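"""Slow-mode landscapes and conformational clustering.

Time-lagged independent component analysis (tICA) implemented from scratch
on dihedral or distance features, free-energy and observable-colored
surfaces over the leading projections, and GROMOS (Daura) neighbor-count
clustering under a pairwise-RMSD cutoff.

The tICA estimator symmetrizes the time-lagged covariance,
Ctau = (C(tau) + C(tau)^T)/2, so eigenvalues are real and bounded by 1 (up
to numerical noise); lagged pairs never straddle replica boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.stats import binned_statistic_2d

from .ensemble import Ensemble
from .rg_decompose import pairwise_rmsd
from .structure_obs import backbone_dihedrals


class LandscapeError(ValueError):
    """Invalid featurization or estimator inputs."""


@dataclass
class FeatureSeries:
    """Per-frame feature vectors plus the replica id of every frame."""

    X: np.ndarray                  # (n_frames, n_features)
    replica: np.ndarray            # (n_frames,)
    scheme: str = "custom"

    def lagged_pairs(self, tau: int) -> tuple[np.ndarray, np.ndarray]:
        """Frame-index pairs (t, t+tau) that stay within one replica."""
        t0, t1 = [], []
        for rep in np.unique(self.replica):
            idx = np.flatnonzero(self.replica == rep)
            if len(idx) > tau:
                t0.append(idx[:-tau] if tau else idx)
                t1.append(idx[tau:] if tau else idx)
        if not t0:
            raise LandscapeError(f"lag {tau} >= every replica length")
        return np.concatenate(t0), np.concatenate(t1)


def featurize(ens: Ensemble, scheme: str = "dihedral-sincos") -> FeatureSeries:
    """Deterministic feature matrix for tICA.

    ``dihedral-sincos``: sin/cos of phi and psi for interior residues
    (4(L-2) features) plus the two chain-end singleton angles (psi of the
    first residue, phi of the last) entering as cosines only, for a total
    of 4(L-2)+2.

    ``ca-distances``: all Calpha pair distances with |i-j| >= 2, Angstrom.
    """
    if scheme == "dihedral-sincos":
        phi, psi = backbone_dihedrals(ens)
        L = ens.topology.n_residues
        cols = []
        for r in range(1, L - 1):
            a, b = np.deg2rad(phi[:, r]), np.deg2rad(psi[:, r])
            cols += [np.sin(a), np.cos(a), np.sin(b), np.cos(b)]
        cols.append(np.cos(np.deg2rad(psi[:, 0])))
        cols.append(np.cos(np.deg2rad(phi[:, L - 1])))
        X = np.column_stack(cols)
    elif scheme == "ca-distances":
        ca = ens.topology.atom_indices("CA")
        ii, jj = np.triu_indices(len(ca), k=2)
        X = np.linalg.norm(ens.coords[:, ca[ii]] - ens.coords[:, ca[jj]],
                           axis=-1)
    else:
        raise LandscapeError(f"unknown featurization scheme {scheme!r}")
    return FeatureSeries(X, ens.replica.copy(), scheme)


@dataclass
class TicaModel:
    """Fitted tICA estimator and projections of the training data."""

    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray        # descending
    eigenvectors: np.ndarray       # columns, C0-orthonormal
    projections: np.ndarray        # (n_frames, n_components)
    lag: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.eigenvectors


def fit_tica(fs: FeatureSeries, tau: int, epsilon: float = 1e-8,
             n_components: int | None = None) -> TicaModel:
    """Fit tICA at lag ``tau`` (frames) by the symmetrized estimator.

    Solves the generalized eigenproblem Ctau v = lambda (C0 + eps I) v with
    mean-free, pair-symmetric covariance estimates over all valid lagged
    pairs. Eigenvalues are returned in descending order.
    """
    t0, t1 = fs.lagged_pairs(tau)
    A = fs.X[t0]
    B = fs.X[t1]
    mean = 0.5 * (A.mean(axis=0) + B.mean(axis=0))
    A = A - mean
    B = B - mean
    n = len(A)
    c0 = 0.5 * (A.T @ A + B.T @ B) / n
    ct = A.T @ B / n
    ctau = 0.5 * (ct + ct.T)
    if np.any(np.diag(c0) <= 0):
        raise LandscapeError("zero-variance feature; remove constant columns")
    w, v = eigh(ctau, c0 + epsilon * np.eye(len(c0)))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if n_components:
        w, v = w[:n_components], v[:, :n_components]
    proj = (fs.X - mean) @ v
    return TicaModel(mean, c0, ctau, w, v, proj, tau)


def free_energy_surface(x: np.ndarray, y: np.ndarray, bins: int = 60,
                        ranges=None) -> dict:
    """Free energy F = -ln(rho/rho_max) in kBT over a 2D histogram.

    Empty bins are NaN (undefined), not infinite; min over occupied bins is
    exactly 0 by the rho_max normalization.
    """
    H, xe, ye = np.histogram2d(np.asarray(x), np.asarray(y), bins=bins,
                               range=ranges, density=True)
    F = np.full_like(H, np.nan)
    occ = H > 0
    F[occ] = -np.log(H[occ] / H.max())
    return {"F": F, "x_edges": xe, "y_edges": ye}


def observable_landscape(x: np.ndarray, y: np.ndarray, values: np.ndarray,
                         bins: int = 60, ranges=None) -> dict:
    """Per-bin mean of an observable (e.g. total SASA) over (x, y)."""
    x, y, values = map(np.asarray, (x, y, values))
    if not (len(x) == len(y) == len(values)):
        raise LandscapeError("x, y and values must have equal length")
    stat, xe, ye, _ = binned_statistic_2d(x, y, values, statistic="mean",
                                          bins=bins, range=ranges)
    return {"mean": stat, "x_edges": xe, "y_edges": ye}


# backwards-friendly alias used by the pipeline
sasa_landscape = observable_landscape


@dataclass
class ClusterResult:
    """GROMOS clustering output: per-frame cluster ids (discovery order),
    center frame of each cluster, and population fractions."""

    labels: np.ndarray
    centers: list
    populations: list
    stride: int = 1


def gromos_cluster(ens: Ensemble, cutoff_nm: float = 0.9,
                   selection: str | None = None,
                   max_frames: int = 20000) -> ClusterResult:
    """Daura neighbor-count clustering under a superposed-RMSD cutoff.

    The frame with the most neighbors within ``cutoff_nm`` seeds a cluster;
    it and its neighbors are removed; repeat. Ties break to the lowest
    frame index. Ensembles larger than ``max_frames`` are strided (the
    stride is recorded in the result).
    """
    stride = int(np.ceil(ens.n_frames / max_frames))
    sub = ens.coords[::stride]
    if selection is not None:
        sel = ens.topology.atom_indices(selection)
        if sel.size == 0:
            raise LandscapeError(f"selection {selection!r} matches no atoms")
        sub = sub[:, sel]
    n = len(sub)
    d = pairwise_rmsd(sub) / 10.0           # Angstrom -> nm
    within = d <= cutoff_nm
    labels = np.full(n, -1, dtype=int)
    centers: list[int] = []
    populations: list[float] = []
    remaining = np.ones(n, dtype=bool)
    cid = 0
    while remaining.any():
        counts = (within & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))      # argmax takes the lowest index
        members = np.flatnonzero(within[center] & remaining)
        labels[members] = cid
        centers.append(center * stride)
        populations.append(len(members) / n)
        remaining[members] = False
        cid += 1
    return ClusterResult(labels, centers, populations, stride)
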