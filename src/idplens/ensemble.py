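"""In-memory conformer-ensemble container.

An :class:`Ensemble` is an ordered stack of coordinate frames (Angstrom)
over a shared :class:`Topology` (atom names, residue mapping, elements,
masses), with per-frame replica/time metadata. It is the common currency of
every analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .seqprofile import Peptide

# atom order within a residue; CB omitted for glycine
BACKBONE_ORDER = ("N", "H", "CA", "C", "O", "CB")


@dataclass(frozen=True)
class Topology:
    """Shared atom layout of every frame in an ensemble."""

    atom_names: tuple[str, ...]
    atom_elements: tuple[str, ...]
    atom_residue: np.ndarray          # 0-based residue index per atom
    residue_codes: tuple[str, ...]    # one-letter code per residue
    masses: np.ndarray                # Da per atom

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_codes)

    def atom_index(self, residue: int, name: str) -> int:
        """Index of atom ``name`` in residue ``residue`` (0-based); -1 if absent."""
        for i in np.flatnonzero(self.atom_residue == residue):
            if self.atom_names[i] == name:
                return int(i)
        return -1

    def atom_indices(self, name: str) -> np.ndarray:
        """Indices of all atoms called ``name``, in residue order."""
        return np.array([i for i, n in enumerate(self.atom_names) if n == name])


def topology_for(p: Peptide) -> Topology:
    """Reduced backbone+CB topology for a peptide.

    Each residue carries N, H, CA, C, O and (except Gly) CB. Every atom gets
    its element mass; the residue's remaining mass (side chain beyond CB,
    alpha hydrogen, terminal extras) is lumped onto CB (CA for Gly) so the
    topology's total mass equals the peptide MW.
    """
    names: list[str] = []
    elements: list[str] = []
    res_idx: list[int] = []
    masses: list[float] = []
    water = C.WATER_MONO if p.monoisotopic else C.WATER_AVERAGE
    for i, aa in enumerate(p.sequence):
        atoms = [n for n in BACKBONE_ORDER if not (aa == "G" and n == "CB")]
        in_chain_mass = p.residue_masses[i] - water
        if i == 0:
            in_chain_mass += 1.008           # extra terminal H
        if i == len(p) - 1:
            in_chain_mass += water - 1.008   # terminal OH
        explicit = 0.0
        for n in atoms:
            el = n[0]
            names.append(n)
            elements.append(el)
            res_idx.append(i)
            masses.append(C.ELEMENT_MASS[el])
            explicit += C.ELEMENT_MASS[el]
        lump = names.index("CB", len(names) - len(atoms)) if aa != "G" else \
            names.index("CA", len(names) - len(atoms))
        masses[lump] += max(in_chain_mass - explicit, 0.0)
    return Topology(tuple(names), tuple(elements), np.array(res_idx),
                    tuple(p.sequence), np.array(masses))


@dataclass
class Ensemble:
    """Frames of coordinates over a shared topology, with replica metadata."""

    topology: Topology
    coords: np.ndarray                 # (n_frames, n_atoms, 3) Angstrom
    replica: np.ndarray = field(default=None)        # int per frame
    frame_in_replica: np.ndarray = field(default=None)
    time_ps: np.ndarray = field(default=None)        # pseudo-time per frame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        n = self.n_frames
        if self.replica is None:
            self.replica = np.zeros(n, dtype=int)
        if self.frame_in_replica is None:
            self.frame_in_replica = np.arange(n)
        if self.time_ps is None:
            self.time_ps = np.full(n, np.nan)
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate/topology atom-count mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset(self, frame_indices) -> "Ensemble":
        """New ensemble containing the given frames (metadata carried along)."""
        idx = np.asarray(frame_indices, dtype=int)
        return Ensemble(self.topology, self.coords[idx].copy(),
                        self.replica[idx].copy(),
                        self.frame_in_replica[idx].copy(),
                        self.time_ps[idx].copy())


def concatenate(ensembles: list[Ensemble]) -> Ensemble:
    """Concatenate ensembles sharing a topology, in list order."""
    top = ensembles[0].topology
    for e in ensembles[1:]:
        if e.topology.n_atoms != top.n_atoms:
            raise ValueError("cannot concatenate ensembles with different topologies")
    return Ensemble(
        top,
        np.concatenate([e.coords for e in ensembles]),
        np.concatenate([e.replica for e in ensembles]),
        np.concatenate([e.frame_in_replica for e in ensembles]),
        np.concatenate([e.time_ps for e in ensembles]),
    )
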