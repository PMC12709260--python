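"""Forward small-angle X-ray scattering from coordinates.

Debye-sum intensities with Cromer-Mann form factors and a Gaussian
dummy-atom excluded-volume term (hydration-shell contrast fixed at zero),
ensemble/group averaging, Guinier and dimensionless Kratky analyses, the
pair-distance distribution P(r) by regularized indirect transform and by
direct histogramming, and the chi-square comparison

    chi2 = sum_i (E_i - S_i)^2 / S_i^2

between an experimental and a simulated curve (note the simulated-intensity
denominator; a conventional sigma-weighted reduced chi-square is provided
separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from . import constants as C
from .ensemble import Ensemble, Topology

FOUR_PI = 4.0 * np.pi


class SaxsError(ValueError):
    """Invalid scattering input."""


@dataclass
class ScatteringProfile:
    """I(q) on a strictly increasing q grid (1/Angstrom), arbitrary units."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    rg_meta: float | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if np.any(np.diff(self.q) <= 0) or np.any(self.q < 0):
            raise SaxsError("q grid must be non-negative, strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise SaxsError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise SaxsError("sigma must be positive where present")


@dataclass
class PrCurve:
    """Pair-distance distribution on [0, Dmax] (P(0) = P(Dmax) = 0)."""

    r: np.ndarray
    P: np.ndarray
    dmax: float
    chi2: float | None = None       # fit quality of the indirect transform
    I_fit: np.ndarray | None = None  # forward-transformed fit on the q grid

    @property
    def mode(self) -> float:
        return float(self.r[np.argmax(self.P)])


def default_q_grid(qmin: float = 0.0078, qmax: float = 0.495,
                   n: int = 100) -> np.ndarray:
    """Log-spaced measurement-like q grid (1/Angstrom), 100 points."""
    return np.geomspace(qmin, qmax, n)


def _cm_factor(element: str, q: np.ndarray) -> np.ndarray:
    """Cromer-Mann atomic form factor f(q) in electrons."""
    cm = C.CROMER_MANN[element]
    s2 = (q / FOUR_PI) ** 2
    f = np.full_like(q, cm["c"], dtype=float)
    for a, b in zip(cm["a"], cm["b"]):
        f = f + a * np.exp(-b * s2)
    return f


@dataclass
class FormFactorTable:
    """Per-atom effective X-ray form factors for a topology.

    For the reduced backbone+CB topology, the side-chain atoms absent beyond
    CB (plus the alpha hydrogen and terminal extras) are absorbed into the
    CB scatterer (CA for Gly) by summing their Cromer-Mann factors and
    excluded volumes, so f(0) of the lumped atom equals the residue's
    missing electron count plus carbon's. ``solvent_density`` = 0 disables
    the excluded-volume (vacuum) term.
    """

    elements: list          # per atom: list of (element, count) summed
    volumes: np.ndarray     # per atom excluded volume, A^3
    solvent_density: float = C.SOLVENT_DENSITY
    constant_contrast: bool = False   # freeze f at f(0): point scatterers

    @classmethod
    def for_topology(cls, top: Topology, vacuum: bool = False,
                     constant_contrast: bool = False) -> "FormFactorTable":
        reduced = set(top.atom_names) <= {"N", "H", "CA", "C", "O", "CB"}
        comp: list[list[tuple[str, int]]] = []
        vols: list[float] = []
        for a in range(top.n_atoms):
            el = top.atom_elements[a]
            if el not in C.CROMER_MANN:
                raise SaxsError(
                    f"no form factor for element {el!r} (atom {a}, "
                    f"{top.atom_names[a]})")
            comp.append([(el, 1)])
            vols.append(C.EXCLUDED_VOLUME[el])
        if reduced:
            for r, aa in enumerate(top.residue_codes):
                missing = dict(C.RESIDUE_FORMULA[aa])
                # explicitly present: N, H, CA, C, O (+CB)
                missing["N"] -= 1
                missing["H"] -= 1
                missing["C"] -= 2
                missing["O"] -= 1
                lump = top.atom_index(r, "CB")
                if lump >= 0:
                    missing["C"] -= 1
                else:
                    lump = top.atom_index(r, "CA")
                if r == 0:
                    missing["H"] += 2          # charged N-terminus extras
                if r == top.n_residues - 1:
                    missing["O"] += 1          # C-terminal carboxylate O
                for el, n in missing.items():
                    if n > 0:
                        comp[lump].append((el, n))
                        vols[lump] += n * C.EXCLUDED_VOLUME[el]
        return cls(comp, np.asarray(vols),
                   0.0 if vacuum else C.SOLVENT_DENSITY,
                   constant_contrast)

    def effective(self, q: np.ndarray) -> np.ndarray:
        """Effective f per atom on the q grid, shape (n_atoms, n_q).

        f_eff = f_CM(q) - rho_s V exp(-q^2 V^(2/3) / (4 pi)). With
        ``constant_contrast`` every atom scatters as a point with its f(0)
        (the contrast model under which P(r) and I(q) are exact Fourier
        mates, used for cross-validating the indirect transform).
        """
        q = np.asarray(q, dtype=float)
        if self.constant_contrast:
            f0 = self._effective_q_dependent(np.array([0.0]))[:, 0]
            return np.repeat(f0[:, None], len(q), axis=1)
        return self._effective_q_dependent(q)

    def _effective_q_dependent(self, q: np.ndarray) -> np.ndarray:
        cache = {el: _cm_factor(el, q) for el in
                 {el for at in self.elements for el, _n in at}}
        f = np.stack([sum(n * cache[el] for el, n in at)
                      for at in self.elements])
        if self.solvent_density:
            V = self.volumes[:, None]
            f = f - self.solvent_density * V * np.exp(
                -q[None, :] ** 2 * V ** (2.0 / 3.0) / FOUR_PI)
        return f


def debye_profile(coords: np.ndarray, fft: FormFactorTable,
                  q: np.ndarray) -> ScatteringProfile:
    """Debye-sum intensity of one frame.

    I(q) = sum_ij f_i(q) f_j(q) sin(q r_ij)/(q r_ij), the q -> 0 sinc limit
    handled analytically (np.sinc).
    """
    q = np.asarray(q, dtype=float)
    f = fft.effective(q)                      # (n_atoms, n_q)
    r = pdist(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    sinc = np.sinc(np.outer(r, q) / np.pi)    # (n_pairs, n_q)
    cross = np.einsum("pq,pq->q", f[ii] * f[jj], sinc)
    I = np.sum(f ** 2, axis=0) + 2.0 * cross
    return ScatteringProfile(q, I)


def ensemble_average(ens: Ensemble, fft: FormFactorTable, q: np.ndarray,
                     stride: int = 1) -> ScatteringProfile:
    """Unweighted mean Debye profile over (optionally strided) frames."""
    q = np.asarray(q, dtype=float)
    frames = ens.coords[::stride]
    acc = np.zeros_like(q)
    for c in frames:
        acc += debye_profile(c, fft, q).I
    return ScatteringProfile(q, acc / len(frames))


def average_profiles(profiles: list[ScatteringProfile]) -> ScatteringProfile:
    """Unweighted mean of profiles sharing a q grid."""
    q0 = profiles[0].q
    for p in profiles[1:]:
        if len(p.q) != len(q0) or not np.allclose(p.q, q0):
            raise SaxsError("profiles must share a q grid")
    return ScatteringProfile(q0, np.mean([p.I for p in profiles], axis=0))


def guinier_rg(sp: ScatteringProfile, qmax_rg: float = 1.3,
               min_points: int = 5) -> tuple[float, dict]:
    """Guinier radius of gyration from the low-q linear fit of ln I vs q^2.

    Iterates the fit, re-restricting to q*Rg < qmax_rg until the window is
    stable. Returns (Rg in Angstrom, fit diagnostics).
    """
    q, I = sp.q, sp.I
    if np.any(I <= 0):
        raise SaxsError("intensities must be positive for a Guinier fit")
    # seed the iteration from the low-q end, then let qRg < qmax_rg set
    # the window; starting from the full range can lock onto a spurious
    # fixed point when the curve has wide-angle structure
    mask = np.zeros_like(q, dtype=bool)
    mask[:max(min_points, len(q) // 10)] = True
    rg = None
    for _ in range(50):
        if mask.sum() < min_points:
            raise SaxsError("too few points in the Guinier window")
        slope, intercept = np.polyfit(q[mask] ** 2, np.log(I[mask]), 1)
        if slope >= 0:
            raise SaxsError("non-Guinier data (ln I rising with q^2)")
        new_rg = float(np.sqrt(-3.0 * slope))
        new_mask = q * new_rg < qmax_rg
        if rg is not None and np.array_equal(new_mask, mask):
            rg = new_rg
            break
        rg, mask = new_rg, new_mask
    resid = np.log(I[mask]) - (slope * q[mask] ** 2 + intercept)
    return rg, {"I0": float(np.exp(intercept)), "n_points": int(mask.sum()),
                "q_window": (float(q[mask][0]), float(q[mask][-1])),
                "rms_residual": float(np.sqrt(np.mean(resid ** 2)))}


def kratky(sp: ScatteringProfile, rg: float,
           I0: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky transform: x = qRg, y = (qRg)^2 I(q)/I(0)."""
    i0 = float(sp.I[0]) if I0 is None else float(I0)
    if i0 <= 0:
        raise SaxsError("I(0) must be positive")
    x = sp.q * rg
    return x, x ** 2 * sp.I / i0


def pr_direct(coords: np.ndarray, fft: FormFactorTable | None = None,
              dmax: float | None = None, n_bins: int = 80,
              f0: np.ndarray | None = None) -> PrCurve:
    """Pair-distance histogram of one frame or a frame stack, unit area.

    Pairs are weighted by f_i(0) f_j(0) (electron-count products when a
    form-factor table is given, else unweighted).
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if f0 is None:
        f0 = (fft.effective(np.array([0.0]))[:, 0] if fft is not None
              else np.ones(X.shape[1]))
    n = X.shape[1]
    ii, jj = np.triu_indices(n, k=1)
    w = f0[ii] * f0[jj]
    alld = np.concatenate([pdist(fr) for fr in X])
    allw = np.tile(w, X.shape[0])
    if dmax is None:
        dmax = float(alld.max()) * 1.02
    hist, edges = np.histogram(alld, bins=n_bins, range=(0.0, dmax),
                               weights=allw)
    centers = 0.5 * (edges[:-1] + edges[1:])
    r = np.concatenate([[0.0], centers, [dmax]])
    P = np.concatenate([[0.0], hist, [0.0]])
    area = np.trapezoid(P, r)
    if area > 0:
        P = P / area
    return PrCurve(r, P, dmax)


def pr_indirect(sp: ScatteringProfile, dmax: float, n_basis: int = 20,
                alpha: float = 1e-4, nonneg: bool = False,
                n_r: int = 201, fit_self_constant: bool = True) -> PrCurve:
    """P(r) by regularized indirect transform of I(q).

    P(r) is expanded in sines vanishing at 0 and Dmax,
    P(r) = sum_k a_k sin(k pi r / Dmax); coefficients minimise
    ||I - A a||^2 + alpha ||P''||^2 where A_k(q) = 4 pi
    integral basis_k(r) sinc(qr) dr (trapezoid). With ``nonneg`` the same
    functional is minimised under P >= 0 on the r grid (NNLS on grid values).

    ``fit_self_constant`` adds a free q-independent term absorbing atomic
    self-scattering (a delta at r = 0 that no basis vanishing there can
    carry); it is excluded from the returned P(r).
    """
    if dmax <= 0:
        raise SaxsError("Dmax must be positive")
    q, I = sp.q, sp.I
    r = np.linspace(0.0, dmax, n_r)
    sinc_qr = np.sinc(np.outer(q, r) / np.pi)            # (n_q, n_r)
    w = np.full(n_r, dmax / (n_r - 1)); w[0] *= 0.5; w[-1] *= 0.5
    scale = max(float(np.abs(I).max()), 1e-300)
    const_col = np.ones((len(q), 1)) if fit_self_constant else \
        np.zeros((len(q), 0))

    if not nonneg:
        k = np.arange(1, n_basis + 1)
        B = np.sin(np.outer(r, k) * np.pi / dmax)        # (n_r, n_basis)
        A = FOUR_PI * (sinc_qr * w) @ B                  # (n_q, n_basis)
        curv = (k * np.pi / dmax) ** 2 * np.sqrt(dmax / 2.0)
        reg = np.hstack([np.diag(curv),
                         np.zeros((n_basis, const_col.shape[1]))])
        M = np.vstack([np.hstack([A, const_col]) / scale, alpha ** 0.5 * reg])
        y = np.concatenate([I / scale, np.zeros(n_basis)])
        a, *_ = np.linalg.lstsq(M, y, rcond=None)
        if not np.all(np.isfinite(a)):
            raise SaxsError("singular indirect-transform system; "
                            "increase alpha")
        P = B @ a[:n_basis]
        I_fit = np.hstack([A, const_col]) @ a
    else:
        # grid parameterization, endpoints pinned at zero
        A = (FOUR_PI * sinc_qr * w)[:, 1:-1]             # (n_q, n_r-2)
        D2 = (np.diag(np.full(n_r - 2, -2.0))
              + np.diag(np.ones(n_r - 3), 1) + np.diag(np.ones(n_r - 3), -1))
        dr = r[1] - r[0]
        reg = np.hstack([D2 / dr ** 1.5,
                         np.zeros((n_r - 2, const_col.shape[1]))])
        M = np.vstack([np.hstack([A, const_col]) / scale, alpha ** 0.5 * reg])
        y = np.concatenate([I / scale, np.zeros(n_r - 2)])
        pfit, _res = nnls(M, y)
        P = np.concatenate([[0.0], pfit[:n_r - 2], [0.0]])
        I_fit = np.hstack([A, const_col]) @ pfit
    # P is returned in fit units (not area-normalized) so that the
    # regularization limit alpha -> inf sends P -> 0 identically.
    chi2 = float(np.sum((I - I_fit) ** 2 / np.maximum(I_fit, 1e-30) ** 2)) \
        if np.all(I_fit > 0) else None
    return PrCurve(r, P, float(dmax), chi2=chi2, I_fit=I_fit)


def chi_square(expt: ScatteringProfile, sim: ScatteringProfile,
               scale: str = "fixed") -> tuple[float, float]:
    """chi2 = sum (E_i - S_i)^2 / S_i^2 on the experimental q grid.

    The simulated curve is linearly interpolated onto the experimental grid
    when the grids differ. ``scale="fit"`` first applies the least-squares
    factor c = sum(E S)/sum(S^2) to S. Returns (chi2, scale_factor).
    """
    S = sim.I
    if len(sim.q) != len(expt.q) or not np.allclose(sim.q, expt.q):
        if expt.q[0] < sim.q[0] - 1e-12 or expt.q[-1] > sim.q[-1] + 1e-12:
            raise SaxsError("simulated grid does not cover experimental grid")
        S = np.interp(expt.q, sim.q, sim.I)
    c = 1.0
    if scale == "fit":
        c = float(np.dot(expt.I, S) / np.dot(S, S))
    S = c * S
    if np.any(S == 0):
        raise SaxsError("simulated intensity contains zeros")
    return float(np.sum((expt.I - S) ** 2 / S ** 2)), c


def reduced_chi2_sigma(expt: ScatteringProfile,
                       sim: ScatteringProfile) -> float:
    """Conventional sigma-weighted reduced chi-square (for comparison only)."""
    if expt.sigma is None:
        raise SaxsError("experimental sigmas required")
    S = sim.I if np.array_equal(sim.q, expt.q) else np.interp(expt.q, sim.q,
                                                              sim.I)
    return float(np.mean(((expt.I - S) / expt.sigma) ** 2))


def read_dat(path: str | Path) -> ScatteringProfile:
    """Read a 3-column ASCII curve: q (1/A), I, [sigma]; '#' comments."""
    data = np.loadtxt(path, comments="#")
    sigma = data[:, 2] if data.shape[1] > 2 else None
    return ScatteringProfile(data[:, 0], data[:, 1], sigma)


def write_dat(sp: ScatteringProfile, path: str | Path) -> None:
    cols = [sp.q, sp.I] + ([sp.sigma] if sp.sigma is not None else [])
    np.savetxt(path, np.column_stack(cols),
               header="q(1/A) I(a.u.)" + (" sigma" if sp.sigma is not None
                                          else ""))
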