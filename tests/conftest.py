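import numpy as np
import pytest

from idplens import constants as C
from idplens.ensemble import Ensemble, topology_for
from idplens.seqprofile import load_peptide
from idplens.synthetic import GeneratorConfig, build_chain, sample_ensemble

HELIX = (-63.0, -43.0)
EXTENDED = (180.0, 180.0)
STRAND = (-140.0, 135.0)
# type II' beta-turn connecting antiparallel strands
TURN_II = [(60.0, -120.0), (-80.0, 0.0)]


@pytest.fixture(scope="session")
def aicd():
    return load_peptide(C.AICD_SEQUENCE)


@pytest.fixture(scope="session")
def ala16_top():
    return topology_for(load_peptide("A" * 16))


@pytest.fixture(scope="session")
def helix16(ala16_top):
    p = load_peptide("A" * 16)
    return build_chain(p, np.tile(HELIX, (16, 1)), ala16_top)


@pytest.fixture(scope="session")
def hairpin12():
    """Two antiparallel strands joined by a type II' turn (single chain)."""
    p = load_peptide("A" * 12)
    top = topology_for(p)
    pp = np.array([STRAND] * 5 + TURN_II + [STRAND] * 5)
    return build_chain(p, pp, top), top


@pytest.fixture(scope="session")
def free_ensemble(aicd):
    """Unbiased default-mixture ensemble: 1 replica x 200 frames, seed 11."""
    cfg = GeneratorConfig(seed=11, n_replicas=1, frames_per_replica=200)
    return sample_ensemble(aicd, cfg)


@pytest.fixture(scope="session")
def compact_extended(aicd):
    """Rg-biased ensembles at 10 and 20 A (seed 13), 150 frames each."""
    out = {}
    for t in (10.0, 20.0):
        cfg = GeneratorConfig(seed=13, n_replicas=1, frames_per_replica=150,
                              rg_target=t, rg_spring=2.0)
        out[t] = sample_ensemble(aicd, cfg)
    return out


def mdtraj_topology(top):
    """Convert an idplens Topology into an mdtraj.Topology."""
    import mdtraj as md
    from mdtraj.core import element as mdel

    elmap = {"H": mdel.hydrogen, "C": mdel.carbon, "N": mdel.nitrogen,
             "O": mdel.oxygen, "S": mdel.sulfur}
    aa3 = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
           "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
           "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
           "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL"}
    t = md.Topology()
    ch = t.add_chain()
    last, res = -1, None
    for i in range(top.n_atoms):
        r = int(top.atom_residue[i])
        if r != last:
            res = t.add_residue(aa3[top.residue_codes[r]], ch)
            last = r
        t.add_atom(top.atom_names[i], elmap[top.atom_elements[i]], res)
    return t


def as_mdtraj(ens_or_coords, top):
    """idplens frames (Angstrom) -> mdtraj.Trajectory (nm)."""
    import mdtraj as md

    coords = (ens_or_coords.coords if isinstance(ens_or_coords, Ensemble)
              else np.asarray(ens_or_coords))
    if coords.ndim == 2:
        coords = coords[None]
    return md.Trajectory(coords / 10.0, mdtraj_topology(top))
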