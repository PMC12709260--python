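"""Circular dichroism: unit conversion, ensemble prediction, decomposition.

Measured ellipticity (mdeg) converts to molar circular dichroism via

    delta_eps = CD(mdeg) * MRW / (32980 * l * c)

with pathlength l in cm, concentration c in g/L and mean residue weight MRW
in Da. Ensemble spectra are predicted as secondary-structure-fraction
weighted sums of per-class reference basis spectra, and an observed
spectrum can be decomposed back onto that basis by constrained least
squares (a deliberately simple stand-in for full empirical deconvolution
suites).

The packaged basis curves are SYNTHETIC parametric band shapes (sums of
Gaussians reproducing the canonical features: helix 192+/208-/222-, strand
195+/217-, coil 198-), not digitized experimental reference sets; they are
adequate for linear-algebra round-trips and qualitative ensemble spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CD_CONSTANT = 32980.0

CD_CLASSES = ("helix", "strand", "turn", "coil")

# Gaussian bands per class: list of (center nm, sigma nm, amplitude dEps)
_BANDS = {
    "helix": [(192.0, 8.0, 6.5), (208.0, 7.0, -3.7), (222.0, 9.0, -3.6)],
    "strand": [(196.0, 8.0, 4.0), (217.0, 9.0, -2.5)],
    "turn": [(190.0, 8.0, -1.2), (206.0, 9.0, 0.9)],
    "coil": [(197.0, 8.0, -4.5), (222.0, 12.0, 0.3)],
}


class CdError(ValueError):
    """Invalid CD input (missing metadata, unit mismatch, bad basis)."""


@dataclass
class CdSpectrum:
    """A CD curve on a strictly increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    signal: np.ndarray
    units: str = "mdeg"            # "mdeg" | "delta_epsilon"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise CdError("wavelength grid must be strictly increasing")
        if self.units not in ("mdeg", "delta_epsilon"):
            raise CdError(f"unknown unit tag {self.units!r}")


def reference_basis(wavelength: np.ndarray | None = None) -> pd.DataFrame:
    """Synthetic per-class basis spectra (delta_epsilon, M^-1 cm^-1).

    Index: wavelength (180-260 nm default); columns: CD_CLASSES.
    """
    wl = (np.arange(180.0, 261.0) if wavelength is None
          else np.asarray(wavelength, dtype=float))
    data = {}
    for cls in CD_CLASSES:
        y = np.zeros_like(wl)
        for c, s, a in _BANDS[cls]:
            y = y + a * np.exp(-0.5 * ((wl - c) / s) ** 2)
        data[cls] = y
    return pd.DataFrame(data, index=pd.Index(wl, name="wavelength"))


def _require_meta(s: CdSpectrum):
    missing = [k for k in ("pathlength_cm", "conc_g_per_L", "mrw")
               if k not in s.meta or s.meta[k] is None]
    if missing:
        raise CdError(f"missing metadata: {missing}")
    if s.meta["pathlength_cm"] <= 0 or s.meta["conc_g_per_L"] <= 0 \
            or s.meta["mrw"] <= 0:
        raise CdError("pathlength, concentration and MRW must be positive")


def mdeg_to_delta_epsilon(s: CdSpectrum) -> CdSpectrum:
    """Convert measured ellipticity to molar circular dichroism."""
    if s.units != "mdeg":
        raise CdError("input spectrum is not in mdeg")
    _require_meta(s)
    factor = s.meta["mrw"] / (CD_CONSTANT * s.meta["pathlength_cm"]
                              * s.meta["conc_g_per_L"])
    return CdSpectrum(s.wavelength, s.signal * factor, "delta_epsilon",
                      dict(s.meta))


def delta_epsilon_to_mdeg(s: CdSpectrum) -> CdSpectrum:
    """Inverse of :func:`mdeg_to_delta_epsilon`."""
    if s.units != "delta_epsilon":
        raise CdError("input spectrum is not in delta_epsilon")
    _require_meta(s)
    factor = s.meta["mrw"] / (CD_CONSTANT * s.meta["pathlength_cm"]
                              * s.meta["conc_g_per_L"])
    return CdSpectrum(s.wavelength, s.signal / factor, "mdeg", dict(s.meta))


def ensemble_cd(fractions: np.ndarray, basis: pd.DataFrame | None = None,
                class_names: tuple = CD_CLASSES) -> CdSpectrum:
    """Ensemble CD spectrum from secondary-structure fractions.

    ``fractions`` is (n_classes,) mean fractions or (n_frames, n_classes)
    per-frame fractions; by linearity the frame-average spectrum equals the
    spectrum of the average fractions, which is what is computed.
    """
    basis = reference_basis() if basis is None else basis
    if list(basis.columns) != list(class_names):
        raise CdError(f"basis classes {list(basis.columns)} != "
                      f"{list(class_names)}")
    f = np.asarray(fractions, dtype=float)
    if f.ndim == 2:
        f = f.mean(axis=0)
    if f.shape[0] != basis.shape[1]:
        raise CdError("fraction vector does not match basis classes")
    y = basis.to_numpy() @ f
    return CdSpectrum(basis.index.to_numpy(), y, "delta_epsilon")


def five_to_four_class(fractions5: np.ndarray) -> np.ndarray:
    """Map (…, 5) helix/strand/turn/bend/coil fractions onto the 4-class
    CD basis (bend folded into coil)."""
    f = np.asarray(fractions5, dtype=float)
    out = np.stack([f[..., 0], f[..., 1], f[..., 2], f[..., 3] + f[..., 4]],
                   axis=-1)
    return out


def decompose_cd(expt: CdSpectrum, basis: pd.DataFrame | None = None) -> dict:
    """Non-negative least-squares fractions (sum <= 1) and fit residual.

    The spectrum must be in delta_epsilon units on (a subset of) the basis
    wavelength grid.
    """
    from scipy.optimize import nnls

    if expt.units != "delta_epsilon":
        raise CdError("decompose_cd expects delta_epsilon units")
    basis = reference_basis() if basis is None else basis
    B = np.stack([np.interp(expt.wavelength, basis.index.to_numpy(),
                            basis[c].to_numpy()) for c in basis.columns],
                 axis=1)
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise CdError("degenerate basis (rank-deficient)")
    frac, _ = nnls(B, expt.signal)
    if frac.sum() > 1.0 + 1e-9:
        from scipy.optimize import minimize
        res = minimize(
            lambda f: np.sum((B @ f - expt.signal) ** 2), frac / frac.sum(),
            bounds=[(0.0, 1.0)] * B.shape[1],
            constraints=[{"type": "ineq", "fun": lambda f: 1.0 - f.sum()}],
            method="SLSQP")
        frac = res.x
    resid = float(np.linalg.norm(B @ frac - expt.signal))
    return {"fractions": dict(zip(basis.columns, frac)), "residual": resid}


def read_spectrum(path, units: str = "mdeg", **meta) -> CdSpectrum:
    """Read a 2-column ASCII spectrum (wavelength nm, value); '#' comments."""
    data = np.loadtxt(path, comments="#")
    order = np.argsort(data[:, 0])
    return CdSpectrum(data[order, 0], data[order, 1], units, meta)


def write_spectrum(s: CdSpectrum, path) -> None:
    np.savetxt(path, np.column_stack([s.wavelength, s.signal]),
               header=f"wavelength(nm) signal({s.units})")
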