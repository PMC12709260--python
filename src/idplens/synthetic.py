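"""Synthetic conformer-ensemble generator.

Stands in for the MD engine: builds backbone+CB peptide conformers from
(phi, psi) dihedrals with ideal covalent geometry, and samples autocorrelated
ensembles by a per-replica Markov chain over dihedral space — single-residue
redraws from a mixture of Ramachandran basins, hard-sphere clash rejection,
and an optional harmonic Metropolis bias on the radius of gyration. Kinetics
are not physical; the chain is merely autocorrelated, which is all the
time-lagged analyses downstream require.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .ensemble import Ensemble, Topology, topology_for
from .seqprofile import Peptide

log = logging.getLogger(__name__)

# ideal covalent geometry (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
B_C_O, B_N_H, B_CA_CB = 1.231, 1.010, 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.0, 116.6, 121.9
A_CA_C_O, A_C_N_H, A_N_CA_CB = 120.5, 119.2, 110.4
OMEGA = 180.0
CHI_CB = 122.69  # improper C-N-CA-CB, L-configuration


class GeneratorError(RuntimeError):
    """Sampling failed (e.g. zero acceptance within the attempt budget)."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic ensemble generator.

    Defaults emulate the study conditions: five independent replicas and a
    disordered basin mixture (alpha-R 0.30, beta 0.35, PPII 0.25, alpha-L
    0.10, sigma 15 deg) yielding transient structure without a stable fold.
    ``rg_target``/``rg_spring`` (kBT/A^2) add a harmonic compaction bias so
    ensembles centred on chosen Rg values can be produced.
    """

    seed: int = 0
    n_replicas: int = 5
    frames_per_replica: int = 1000
    basin_weights: tuple = (0.30, 0.35, 0.25, 0.10)
    basin_centers: tuple = ((-63.0, -43.0), (-120.0, 130.0),
                            (-75.0, 150.0), (60.0, 45.0))
    basin_sigma: float = 15.0
    rg_target: float | None = None
    rg_spring: float = 0.0        # kBT per A^2
    clash_cutoff: float = 2.8     # A, heavy atoms >= 2 residues apart
    record_every: int = 2         # accepted moves between recorded frames
    burnin: int = 300             # accepted moves discarded before recording
    max_attempts: int = 50000     # consecutive rejections tolerated

    def __post_init__(self):
        w = np.asarray(self.basin_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("basin_weights must be non-negative and sum to 1")
        if len(self.basin_centers) != len(w):
            raise ValueError("basin_centers/basin_weights length mismatch")
        if self.frames_per_replica < 1:
            raise ValueError("frames_per_replica must be >= 1")
        if self.clash_cutoff <= 0:
            raise ValueError("clash_cutoff must be positive")


def _place(ax, ay, az, bx, by, bz, cx, cy, cz, bond, theta, chi):
    """Scalar NeRF placement (theta, chi in radians). Hot path of the sampler."""
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    ibc = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx *= ibc; bcy *= ibc; bcz *= ibc
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inn = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx *= inn; ny *= inn; nz *= inn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    st = math.sin(theta)
    d0 = -bond * math.cos(theta)
    d1 = bond * st * math.cos(chi)
    d2 = bond * st * math.sin(chi)
    return (cx + d0 * bcx + d1 * mx + d2 * nx,
            cy + d0 * bcy + d1 * my + d2 * ny,
            cz + d0 * bcz + d1 * mz + d2 * nz)


_RAD = math.pi / 180.0
_T_NCAC = A_N_CA_C * _RAD
_T_CACN = A_CA_C_N * _RAD
_T_CNCA = A_C_N_CA * _RAD
_T_CACO = A_CA_C_O * _RAD
_T_CNH = A_C_N_H * _RAD
_T_NCACB = A_N_CA_CB * _RAD
_CHI_CB = CHI_CB * _RAD
_PI = math.pi


def build_chain(p: Peptide, phi_psi: np.ndarray,
                topology: Topology | None = None) -> np.ndarray:
    """Build one conformer from per-residue (phi, psi) in degrees.

    Backbone constructed residue-by-residue with ideal bond lengths/angles
    and trans (omega = 180) peptide planes; the amide H and carbonyl O are
    placed in the peptide plane and CB at the tetrahedral L-position. phi of
    the first residue and psi of the last merely orient terminal H/O.

    Returns coordinates (n_atoms, 3) in the atom order of ``topology_for``.
    """
    pp = np.asarray(phi_psi, dtype=float)
    L = len(p)
    if pp.shape != (L, 2):
        raise ValueError(f"phi_psi must have shape ({L}, 2), got {pp.shape}")
    top = topology if topology is not None else topology_for(p)

    phi = [v * _RAD for v in pp[:, 0]]
    psi = [v * _RAD for v in pp[:, 1]]
    N = [(0.0, 0.0, 0.0)] * L
    CA = [(0.0, 0.0, 0.0)] * L
    Cc = [(0.0, 0.0, 0.0)] * L
    CA[0] = (B_N_CA, 0.0, 0.0)
    Cc[0] = (B_N_CA - B_CA_C * math.cos(_T_NCAC),
             B_CA_C * math.sin(_T_NCAC), 0.0)
    for i in range(L - 1):
        n = _place(*N[i], *CA[i], *Cc[i], B_C_N, _T_CACN, psi[i])
        ca = _place(*CA[i], *Cc[i], *n, B_N_CA, _T_CNCA, _PI)
        cc = _place(*Cc[i], *n, *ca, B_CA_C, _T_NCAC, phi[i + 1])
        N[i + 1], CA[i + 1], Cc[i + 1] = n, ca, cc

    coords = np.empty((top.n_atoms, 3))
    k = 0
    for i, aa in enumerate(p.sequence):
        o = _place(*N[i], *CA[i], *Cc[i], B_C_O, _T_CACO, psi[i] + _PI)
        if i == 0:
            h = _place(*Cc[0], *CA[0], *N[0], B_N_H, 109.5 * _RAD, _PI)
        else:
            # trans peptide plane: H anti to the carbonyl O, cis to CA(i-1)
            h = _place(*CA[i - 1], *Cc[i - 1], *N[i], B_N_H, _T_CNH, 0.0)
        coords[k] = N[i]; coords[k + 1] = h; coords[k + 2] = CA[i]
        coords[k + 3] = Cc[i]; coords[k + 4] = o
        k += 5
        if aa != "G":
            coords[k] = _place(*Cc[i], *N[i], *CA[i], B_CA_CB,
                               _T_NCACB, _CHI_CB)
            k += 1
    return coords


def _pair_mask(heavy: np.ndarray, res_idx: np.ndarray) -> np.ndarray:
    """Condensed-form mask of heavy-atom pairs from residues >= 2 apart."""
    r = res_idx[heavy]
    sep = np.abs(r[:, None] - r[None, :])
    iu = np.triu_indices(len(heavy), k=1)
    return sep[iu] >= 2


def _clash(coords: np.ndarray, heavy: np.ndarray, res_idx: np.ndarray,
           cutoff: float, mask: np.ndarray | None = None) -> bool:
    """Any heavy-atom pair from residues >= 2 apart closer than cutoff?"""
    d = pdist(coords[heavy])
    if mask is None:
        mask = _pair_mask(heavy, res_idx)
    return bool(np.any(d[mask] < cutoff))


def _mass_rg(coords: np.ndarray, masses: np.ndarray) -> float:
    com = np.average(coords, axis=0, weights=masses)
    d2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=masses)))


def _draw_basin(rng, cfg: GeneratorConfig) -> np.ndarray:
    b = rng.choice(len(cfg.basin_weights), p=cfg.basin_weights)
    c = np.asarray(cfg.basin_centers[b])
    return c + rng.normal(0.0, cfg.basin_sigma, size=2)


def sample_ensemble(p: Peptide, cfg: GeneratorConfig) -> Ensemble:
    """Sample an autocorrelated conformer ensemble, one Markov chain per replica.

    Replica r uses the stream ``seed + r`` so replicas are independent yet the
    whole ensemble is bit-reproducible from ``cfg.seed``. Frames are recorded
    every ``cfg.record_every`` accepted moves after ``cfg.burnin`` accepted
    moves of equilibration.
    """
    top = topology_for(p)
    heavy = np.array([i for i, el in enumerate(top.atom_elements) if el != "H"])
    pmask = _pair_mask(heavy, top.atom_residue)
    L = len(p)
    all_frames = []
    replica_ids = []
    frame_ids = []
    stats = {"acceptance": [], "mean_rg": []}

    for r in range(cfg.n_replicas):
        rng = np.random.default_rng(cfg.seed + r)
        # clash-free start from the PPII basin
        for _ in range(200):
            pp = np.tile((-75.0, 150.0), (L, 1)) + rng.normal(0, 5.0, (L, 2))
            coords = build_chain(p, pp, top)
            if not _clash(coords, heavy, top.atom_residue, cfg.clash_cutoff, pmask):
                break
        else:
            raise GeneratorError("could not build a clash-free starting conformer")
        rg = _mass_rg(coords, top.masses)

        accepted = 0
        proposed = 0
        rejected_run = 0
        frames = []
        target_accepts = cfg.burnin + cfg.frames_per_replica * cfg.record_every
        while accepted < target_accepts:
            proposed += 1
            k = int(rng.integers(L))
            new_pp = pp.copy()
            new_pp[k] = _draw_basin(rng, cfg)
            new_coords = build_chain(p, new_pp, top)
            ok = not _clash(new_coords, heavy, top.atom_residue, cfg.clash_cutoff, pmask)
            new_rg = _mass_rg(new_coords, top.masses) if ok else rg
            if ok and cfg.rg_target is not None and cfg.rg_spring > 0:
                du = cfg.rg_spring * ((new_rg - cfg.rg_target) ** 2
                                      - (rg - cfg.rg_target) ** 2)
                if du > 0 and rng.random() >= np.exp(-du):
                    ok = False
            if ok:
                pp, coords, rg = new_pp, new_coords, new_rg
                accepted += 1
                rejected_run = 0
                if (accepted > cfg.burnin
                        and (accepted - cfg.burnin) % cfg.record_every == 0):
                    frames.append(coords.copy())
            else:
                rejected_run += 1
                if rejected_run > cfg.max_attempts:
                    raise GeneratorError(
                        f"replica {r}: {rejected_run} consecutive rejections "
                        f"(acceptance {accepted}/{proposed}); relax clash_cutoff "
                        "or rg_spring")
        frames = frames[: cfg.frames_per_replica]
        rgs = [_mass_rg(f, top.masses) for f in frames]
        stats["acceptance"].append(accepted / proposed)
        stats["mean_rg"].append(float(np.mean(rgs)))
        log.info("replica %d: acceptance %.3f mean Rg %.2f A",
                 r, accepted / proposed, np.mean(rgs))
        all_frames.extend(frames)
        replica_ids.extend([r] * len(frames))
        frame_ids.extend(range(len(frames)))

    ens = Ensemble(top, np.array(all_frames), np.array(replica_ids),
                   np.array(frame_ids))
    ens.sampling_stats = stats
    return ens


def emulate_protocol(ens: Ensemble, time_per_frame_ps: float) -> Ensemble:
    """Assign pseudo-times: frame index within replica x time_per_frame_ps."""
    if time_per_frame_ps <= 0:
        raise ValueError("time_per_frame_ps must be positive")
    ens.time_ps = ens.frame_in_replica * float(time_per_frame_ps)
    return ens
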