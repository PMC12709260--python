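"""Per-frame and per-group structural observables.

Shrake-Rupley solvent-accessible surface area, minimal Calpha-Calpha
contact maps, geometric backbone hydrogen-bond occupancy maps, a compact
Kabsch-Sander secondary-structure assignment collapsed to five classes
(helix, strand, turn, bend, coil), Ramachandran histograms with named
region fractions, and Karplus scalar J-couplings from backbone dihedrals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .ensemble import Ensemble, Topology
from .geometry import dihedrals_vectorized
from .rg_decompose import RgPartition

SS_CLASSES = ("helix", "strand", "turn", "bend", "coil")

# default Ramachandran regions: (phi_min, phi_max, psi_min, psi_max) degrees
DEFAULT_RAMA_REGIONS = {
    "alphaR": (-100.0, -30.0, -67.0, -7.0),
    "beta": (-180.0, -90.0, 90.0, 180.0),
    "PPII": (-90.0, -20.0, 120.0, 180.0),
    "alphaL": (30.0, 100.0, 7.0, 67.0),
}


class ObservableError(ValueError):
    """Missing atoms or malformed inputs for an observable."""


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

@dataclass
class SasaResult:
    """Total and per-residue SASA in nm^2, one row per frame."""

    total: np.ndarray                # (n_frames,)
    per_residue: np.ndarray          # (n_frames, n_residues)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n)
    inc = np.pi * (3.0 - np.sqrt(5.0))
    z = (2.0 * k + 1.0) / n - 1.0
    rho = np.sqrt(1.0 - z * z)
    phi = k * inc
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(ens: Ensemble, probe: float = 1.4, n_points: int = 960,
         radii: dict[str, float] | None = None) -> SasaResult:
    """Shrake-Rupley SASA per frame and residue.

    Every atom with a van der Waals radius (Bondi set by default) carries a
    sphere of ``n_points`` test points at radius r+probe; the accessible
    fraction times the sphere area is the atom's SASA. Output in nm^2.
    """
    radii = radii or C.VDW_RADII
    top = ens.topology
    try:
        r_atom = np.array([radii[el] for el in top.atom_elements])
    except KeyError as e:
        raise ObservableError(f"no van der Waals radius for element {e}")
    r_ext = r_atom + probe
    pts = _sphere_points(n_points)
    n_res = top.n_residues
    total = np.empty(ens.n_frames)
    per_res = np.zeros((ens.n_frames, n_res))
    areas = 4.0 * np.pi * r_ext ** 2
    for fidx in range(ens.n_frames):
        X = ens.coords[fidx]
        d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        cut = r_ext[:, None] + r_ext[None, :]
        atom_sasa = np.empty(top.n_atoms)
        for i in range(top.n_atoms):
            nb = np.flatnonzero((d[i] < cut[i]) & (np.arange(len(X)) != i))
            if nb.size == 0:
                atom_sasa[i] = areas[i]
                continue
            p = X[i] + r_ext[i] * pts
            dist2 = np.sum((p[:, None, :] - X[nb][None, :, :]) ** 2, axis=-1)
            free = np.all(dist2 >= (r_ext[nb] ** 2)[None, :], axis=1)
            atom_sasa[i] = areas[i] * free.mean()
        total[fidx] = atom_sasa.sum() / 100.0            # A^2 -> nm^2
        np.add.at(per_res[fidx], top.atom_residue, atom_sasa / 100.0)
    return SasaResult(total, per_res)


def sasa_group_summary(sr: SasaResult, part: RgPartition,
                       frame_weighted_mean: bool = False) -> dict:
    """Group SASA tables and deviations from the across-group mean.

    The grand mean is the unweighted mean over group means (each Rg group
    counts once); ``frame_weighted_mean`` switches to the mean over frames.
    Returns per-group totals with SD, normalized (grand-mean-subtracted)
    totals, per-residue group means, their normalized counterparts, and the
    per-residue SASA variance across all frames (nm^4).
    """
    labels = part.labels
    rows, res_rows = [], []
    for lab in labels:
        m = part.assignment == lab
        if not m.any():
            continue
        rows.append({"group": lab, "mean_total": sr.total[m].mean(),
                     "sd_total": sr.total[m].std(ddof=0),
                     "n_frames": int(m.sum())})
        res_rows.append(sr.per_residue[m].mean(axis=0))
    totals = pd.DataFrame(rows)
    grand = (sr.total.mean() if frame_weighted_mean
             else totals["mean_total"].mean())
    totals["normalized"] = totals["mean_total"] - grand
    per_res = pd.DataFrame(
        np.array(res_rows), index=totals["group"],
        columns=np.arange(1, sr.per_residue.shape[1] + 1))
    per_res_norm = per_res - per_res.mean(axis=0)
    return {
        "totals": totals,
        "grand_mean": float(grand),
        "per_residue": per_res,
        "per_residue_normalized": per_res_norm,
        "per_residue_variance": sr.per_residue.var(axis=0, ddof=0),
    }


# ---------------------------------------------------------------------------
# contact and hydrogen-bond maps
# ---------------------------------------------------------------------------

def min_ca_distance_map(ens: Ensemble) -> np.ndarray:
    """Per residue pair, the minimum Calpha-Calpha distance (A) over frames."""
    ca = ens.topology.atom_indices("CA")
    if len(ca) != ens.topology.n_residues:
        raise ObservableError("every residue needs a CA atom")
    X = ens.coords[:, ca]
    d = np.linalg.norm(X[:, :, None, :] - X[:, None, :, :], axis=-1)
    out = d.min(axis=0)
    np.fill_diagonal(out, 0.0)
    return out


def _backbone_indices(top: Topology):
    idx = {}
    for name in ("N", "H", "CA", "C", "O"):
        ids = [top.atom_index(r, name) for r in range(top.n_residues)]
        if any(i < 0 for i in ids):
            missing = [r + 1 for r, i in enumerate(ids) if i < 0]
            raise ObservableError(
                f"backbone atom {name} missing in residue(s) {missing}")
        idx[name] = np.array(ids)
    return idx


def hbond_map(ens: Ensemble, d_cut: float = 3.5,
              angle_cut: float = 30.0) -> np.ndarray:
    """Backbone H-bond occupancy per residue pair.

    Geometric criterion (GROMACS-hbond style): donor(N)-acceptor(O)
    distance <= d_cut A and H-N...O angle <= angle_cut degrees. Entry (i, j)
    is the fraction of frames with at least one bond between residues i and
    j in either direction; diagonal is zero.
    """
    top = ens.topology
    bb = _backbone_indices(top)
    n_res = top.n_residues
    Nx = ens.coords[:, bb["N"]]
    Hx = ens.coords[:, bb["H"]]
    Ox = ens.coords[:, bb["O"]]
    occ = np.zeros((n_res, n_res))
    cos_cut = np.cos(np.deg2rad(angle_cut))
    for f in range(ens.n_frames):
        dNO = np.linalg.norm(Nx[f][:, None] - Ox[f][None, :], axis=-1)
        nh = Hx[f] - Nx[f]
        nh /= np.linalg.norm(nh, axis=1, keepdims=True)
        no = Ox[f][None, :, :] - Nx[f][:, None, :]
        no = no / np.maximum(np.linalg.norm(no, axis=-1, keepdims=True), 1e-12)
        cosang = np.einsum("di,dai->da", nh, no)
        bond = (dNO <= d_cut) & (cosang >= cos_cut)
        np.fill_diagonal(bond, False)
        occ += bond | bond.T
    return occ / ens.n_frames


# ---------------------------------------------------------------------------
# secondary structure (Kabsch-Sander, collapsed to 5 classes)
# ---------------------------------------------------------------------------

def _ks_hbonds(Nx, Hx, Cx, Ox, min_sep: int = 2) -> np.ndarray:
    """Kabsch-Sander electrostatic H-bond matrix for one frame.

    bond[d, a] is True when the N-H of residue d donates to the C=O of
    residue a: E = 27.888 (1/rON + 1/rCH - 1/rOH - 1/rCN) < -0.5 kcal/mol.
    """
    def dist(A, B):
        return np.maximum(np.linalg.norm(A[:, None] - B[None, :], axis=-1),
                          1e-6)
    # rows: donors (N,H); cols: acceptors (C,O)
    E = 27.888 * (1.0 / dist(Nx, Ox) + 1.0 / dist(Hx, Cx)
                  - 1.0 / dist(Hx, Ox) - 1.0 / dist(Nx, Cx))
    n = len(Nx)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return (E < -0.5) & (sep >= min_sep)


def assign_frame_ss(coords: np.ndarray, top: Topology) -> np.ndarray:
    """Five-class secondary structure of one frame.

    Helix: runs of >= 2 consecutive i -> i+4 (or i+3 / i+5, folded in)
    turns; strand: Kabsch-Sander parallel/antiparallel bridges; turn:
    isolated n-turns; bend: >70 degree Calpha direction change; coil
    otherwise. Priority helix > strand > turn > bend.
    """
    bb = _backbone_indices(top)
    n = top.n_residues
    hb = _ks_hbonds(coords[bb["N"]], coords[bb["H"]],
                    coords[bb["C"]], coords[bb["O"]])

    def turn(nlen):
        # turn[i] true when H-bond (i+nlen) -> i
        t = np.zeros(n, dtype=bool)
        for i in range(n - nlen):
            if hb[i + nlen, i]:
                t[i] = True
        return t

    turns = {k: turn(k) for k in (3, 4, 5)}
    cls = np.full(n, 4, dtype=int)                        # coil

    # bend: direction change of the CA trace
    ca = coords[bb["CA"]]
    for i in range(2, n - 2):
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            cls[i] = 3                                    # bend

    # turns: residues spanned by any isolated n-turn
    for k, t in turns.items():
        for i in np.flatnonzero(t):
            cls[i + 1: i + k] = np.minimum(cls[i + 1: i + k], 2)

    # bridges -> strand
    strand = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or \
                   (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or \
                   (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                strand[i] = strand[j] = True
    cls[strand] = 1

    # helices: two consecutive n-turns, n = 4 first (alpha), 3 and 5 folded in
    helix = np.zeros(n, dtype=bool)
    for k in (4, 3, 5):
        t = turns[k]
        for i in range(n - k - 1):
            if t[i] and t[i + 1]:
                helix[i + 1: i + k + 1] = True
    cls[helix] = 0
    return cls


def assign_secondary_structure(ens: Ensemble,
                               part: RgPartition | None = None) -> dict:
    """Per-frame labels, per-residue class probabilities, per-group fractions.

    Returns ``labels`` (n_frames, n_residues) ints indexing SS_CLASSES,
    ``per_residue`` (n_residues, 5) probabilities, and, when a partition is
    given, ``group_fractions`` (DataFrame group x class).
    """
    labels = np.stack([assign_frame_ss(ens.coords[f], ens.topology)
                       for f in range(ens.n_frames)])
    per_res = np.stack([(labels == k).mean(axis=0) for k in range(5)], axis=1)
    out = {"labels": labels, "per_residue": per_res}
    if part is not None:
        rows = {}
        for lab in part.labels:
            m = part.assignment == lab
            rows[lab] = [(labels[m] == k).mean() for k in range(5)]
        out["group_fractions"] = pd.DataFrame.from_dict(
            rows, orient="index", columns=SS_CLASSES)
    return out


# ---------------------------------------------------------------------------
# Ramachandran & J-couplings
# ---------------------------------------------------------------------------

def backbone_dihedrals(ens: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) in degrees, shape (n_frames, n_residues), NaN where undefined.

    phi is undefined for the first residue, psi for the last.
    """
    top = ens.topology
    bb = _backbone_indices(top)
    n = top.n_residues
    phi_quads = np.array([[bb["C"][i - 1], bb["N"][i], bb["CA"][i], bb["C"][i]]
                          for i in range(1, n)])
    psi_quads = np.array([[bb["N"][i], bb["CA"][i], bb["C"][i], bb["N"][i + 1]]
                          for i in range(n - 1)])
    phi = np.full((ens.n_frames, n), np.nan)
    psi = np.full((ens.n_frames, n), np.nan)
    phi[:, 1:] = dihedrals_vectorized(ens.coords, phi_quads)
    psi[:, :-1] = dihedrals_vectorized(ens.coords, psi_quads)
    return phi, psi


def ramachandran(ens: Ensemble, regions: dict | None = None,
                 bins: int = 72) -> dict:
    """2D (phi, psi) histogram (5-degree bins) and named-region fractions.

    Only interior residues (both dihedrals defined) contribute. Region
    fractions are counts of raw data points inside each (phi, psi)
    rectangle divided by the total.
    """
    if ens.topology.n_residues < 3:
        raise ObservableError("need >= 3 residues for interior dihedrals")
    regions = DEFAULT_RAMA_REGIONS if regions is None else regions
    phi, psi = backbone_dihedrals(ens)
    m = ~(np.isnan(phi) | np.isnan(psi))
    ph, ps = phi[m], psi[m]
    H, xe, ye = np.histogram2d(ph, ps, bins=bins,
                               range=[[-180, 180], [-180, 180]])
    fractions = {}
    for name, (p0, p1, s0, s1) in regions.items():
        inside = (ph >= p0) & (ph <= p1) & (ps >= s0) & (ps <= s1)
        fractions[name] = float(inside.mean())
    return {"hist": H, "phi_edges": xe, "psi_edges": ye,
            "fractions": fractions, "n_points": int(m.sum())}


@dataclass(frozen=True)
class KarplusParams:
    """Karplus coefficients (Hz) for 3J(HN-Ha) on phi and 2J(N-Ca) on psi."""

    A: float = 6.4
    B: float = -1.4
    C: float = 1.9
    A2: float = 2.0
    B2: float = -0.5
    C2: float = 0.5
    phi_offset: float = 0.0    # degrees added to phi before evaluation
    psi_offset: float = 0.0


def karplus_j3(phi_deg, kp: KarplusParams = KarplusParams()) -> np.ndarray:
    """3J(HN-Ha) = A cos^2(phi+off) + B cos(phi+off) + C, Hz."""
    c = np.cos(np.deg2rad(np.asarray(phi_deg, dtype=float) + kp.phi_offset))
    return kp.A * c ** 2 + kp.B * c + kp.C


def karplus_j2(psi_deg, kp: KarplusParams = KarplusParams()) -> np.ndarray:
    """2J(N-Ca) = A' cos^2(psi+off) + B' cos(psi+off) + C', Hz."""
    c = np.cos(np.deg2rad(np.asarray(psi_deg, dtype=float) + kp.psi_offset))
    return kp.A2 * c ** 2 + kp.B2 * c + kp.C2


def j_couplings(ens: Ensemble, kp: KarplusParams = KarplusParams(),
                part: RgPartition | None = None) -> pd.DataFrame:
    """Per-residue ensemble mean and SD of both couplings, per Rg group.

    Residues lacking phi (first) or psi (last) get NaN for that coupling.
    """
    phi, psi = backbone_dihedrals(ens)
    j3 = karplus_j3(phi, kp)
    j2 = karplus_j2(psi, kp)
    groups = ({lab: part.assignment == lab for lab in part.labels}
              if part is not None else
              {"all": np.ones(ens.n_frames, dtype=bool)})
    def _stat(fn, v):
        v = v[np.isfinite(v)]
        return float(fn(v)) if v.size else np.nan

    rows = []
    for lab, m in groups.items():
        for r in range(ens.topology.n_residues):
            rows.append({
                "group": lab, "residue": r + 1,
                "j3_mean": _stat(np.mean, j3[m, r]),
                "j3_sd": _stat(np.std, j3[m, r]),
                "j2_mean": _stat(np.mean, j2[m, r]),
                "j2_sd": _stat(np.std, j2[m, r]),
            })
    return pd.DataFrame(rows)
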