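"""Ensemble I/O and trajectory bookkeeping.

Multi-model PDB and concatenated-XYZ readers/writers, GROMACS-style NDX
frame-index files, equilibration trimming, and per-group frame extraction.

Conventions: frame numbering is 0-based in memory and 1-based in every
on-disk index file (GROMACS convention). Replica/time metadata round-trips
through PDB REMARK 250 lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ensemble import Ensemble, Topology, concatenate

_AA_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_AA_1 = {v: k for k, v in _AA_3.items()}


class TrajectoryError(ValueError):
    """Malformed trajectory input or inconsistent bookkeeping."""


@dataclass(frozen=True)
class FrameIndex:
    """A named, strictly increasing list of global frame numbers (0-based)."""

    group: str
    frames: tuple[int, ...]

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=int)
        if len(f) and (np.any(np.diff(f) <= 0) or f[0] < 0):
            raise TrajectoryError(
                f"frame index '{self.group}': numbers must be strictly "
                "increasing and non-negative")


def write_ensemble(ens: Ensemble, path: str | Path, fmt: str | None = None) -> None:
    """Write a multi-model PDB (.pdb) or concatenated XYZ (.xyz)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        _write_pdb(ens, path)
    elif fmt == "xyz":
        _write_xyz(ens, path)
    else:
        raise TrajectoryError(f"unknown trajectory format {fmt!r}")


def read_ensemble(path: str | Path, topology: Topology | None = None) -> Ensemble:
    """Read a multi-model PDB or XYZ written by :func:`write_ensemble`.

    XYZ carries no topology, so one must be supplied for it; PDB rebuilds a
    reduced topology from its own records via :func:`ensemble.topology_for`.
    """
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        if topology is None:
            raise TrajectoryError("reading XYZ requires an explicit topology")
        return _read_xyz(path, topology)
    raise TrajectoryError(f"unknown trajectory format {fmt!r}")


def _write_pdb(ens: Ensemble, path: Path) -> None:
    top = ens.topology
    with open(path, "w") as fh:
        fh.write("REMARK 250 GENERATED BY IDPLENS (REDUCED BACKBONE+CB TOPOLOGY)\n")
        for m in range(ens.n_frames):
            fh.write(f"REMARK 250 FRAME {m + 1} REPLICA {int(ens.replica[m])} "
                     f"INDEX {int(ens.frame_in_replica[m])} "
                     f"TIME_PS {ens.time_ps[m]:.3f}\n")
        for m in range(ens.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for a in range(top.n_atoms):
                r = int(top.atom_residue[a])
                x, y, z = ens.coords[m, a]
                fh.write(
                    "ATOM  {serial:5d} {name:^4s} {res:>3s} A{resseq:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{el:>2s}\n".format(
                        serial=a + 1, name=top.atom_names[a],
                        res=_AA_3[top.residue_codes[r]], resseq=r + 1,
                        x=x, y=y, z=z, occ=1.00, b=0.00,
                        el=top.atom_elements[a]))
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")


def _read_pdb(path: Path) -> Ensemble:
    from .seqprofile import Peptide
    from .ensemble import topology_for

    frames: list[list[tuple[float, float, float]]] = []
    meta: dict[int, tuple[int, int, float]] = {}
    seq: list[str] = []
    names_first: list[str] = []
    cur: list | None = None
    model_no = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 250 FRAME"):
                parts = line.split()
                meta[int(parts[3]) - 1] = (int(parts[5]), int(parts[7]),
                                           float(parts[9]))
            elif line.startswith("MODEL"):
                model_no += 1
                cur = []
            elif line.startswith("ATOM"):
                if cur is None:       # single-model file without MODEL card
                    model_no, cur = 1, []
                cur.append((float(line[30:38]), float(line[38:46]),
                            float(line[46:54])))
                if model_no == 1:
                    names_first.append(line[12:16].strip())
                    resseq = int(line[22:26])
                    if resseq > len(seq):
                        seq.append(_AA_1[line[17:20].strip()])
            elif line.startswith(("ENDMDL", "END")) and cur is not None:
                if frames and len(cur) != len(frames[0]):
                    raise TrajectoryError(
                        f"model {model_no}: atom count {len(cur)} != "
                        f"{len(frames[0])} of model 1")
                if cur:
                    frames.append(cur)
                cur = None
    if cur:
        frames.append(cur)
    if not frames:
        raise TrajectoryError(f"no coordinates found in {path}")
    top = topology_for(Peptide("".join(seq)))
    if list(top.atom_names) != names_first:
        raise TrajectoryError("PDB atom layout is not the reduced backbone+CB "
                              "topology this reader supports")
    n = len(frames)
    replica = np.array([meta.get(i, (0, i, np.nan))[0] for i in range(n)])
    fidx = np.array([meta.get(i, (0, i, np.nan))[1] for i in range(n)])
    tps = np.array([meta.get(i, (0, i, np.nan))[2] for i in range(n)])
    return Ensemble(top, np.array(frames, dtype=float), replica, fidx, tps)


def _write_xyz(ens: Ensemble, path: Path) -> None:
    top = ens.topology
    with open(path, "w") as fh:
        for m in range(ens.n_frames):
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"frame {m} replica {int(ens.replica[m])} "
                     f"index {int(ens.frame_in_replica[m])} "
                     f"time_ps {ens.time_ps[m]:.3f}\n")
            for a in range(top.n_atoms):
                x, y, z = ens.coords[m, a]
                fh.write(f"{top.atom_elements[a]:2s} {x:12.6f} {y:12.6f} "
                         f"{z:12.6f}\n")


def _read_xyz(path: Path, top: Topology) -> Ensemble:
    frames = []
    replica, fidx, tps = [], [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nat = int(lines[i])
        if nat != top.n_atoms:
            raise TrajectoryError(
                f"XYZ frame {len(frames) + 1}: {nat} atoms != topology "
                f"{top.n_atoms}")
        comment = lines[i + 1].split()
        if "replica" in comment:
            replica.append(int(comment[comment.index("replica") + 1]))
            fidx.append(int(comment[comment.index("index") + 1]))
            tps.append(float(comment[comment.index("time_ps") + 1]))
        else:
            replica.append(0); fidx.append(len(frames)); tps.append(np.nan)
        block = lines[i + 2: i + 2 + nat]
        frames.append([[float(v) for v in l.split()[1:4]] for l in block])
        i += 2 + nat
    return Ensemble(top, np.array(frames), np.array(replica),
                    np.array(fidx), np.array(tps, dtype=float))


def trim_and_concatenate(replicas: list[Ensemble], discard_ns: float) -> Ensemble:
    """Drop the first ``discard_ns`` of each replica, then concatenate.

    A frame with pseudo-time exactly equal to the cutoff is kept (strict
    less-than discard). Global frame numbering follows replica order.
    """
    discard_ps = discard_ns * 1000.0
    kept = []
    for k, rep in enumerate(replicas):
        if np.any(np.isnan(rep.time_ps)):
            raise TrajectoryError(f"replica {k} lacks pseudo-time metadata")
        if discard_ps > rep.time_ps.max():
            raise TrajectoryError(
                f"discard {discard_ns} ns exceeds replica {k} span "
                f"({rep.time_ps.max() / 1000:.3f} ns)")
        kept.append(rep.subset(np.flatnonzero(rep.time_ps >= discard_ps)))
    return concatenate(kept)


def write_index(fi: FrameIndex, path: str | Path) -> None:
    """Write an NDX-style index: ``[ group ]`` then 1-based numbers, <=15/line."""
    with open(path, "w") as fh:
        fh.write(f"[ {fi.group} ]\n")
        nums = [n + 1 for n in fi.frames]
        for i in range(0, len(nums), 15):
            fh.write(" ".join(f"{n}" for n in nums[i:i + 15]) + "\n")


def read_index(path: str | Path) -> FrameIndex:
    """Read an NDX-style index file written by :func:`write_index`."""
    group = None
    frames: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                group = line.strip("[] ").strip()
            elif line:
                frames.extend(int(v) - 1 for v in line.split())
    if group is None:
        raise TrajectoryError(f"no group header in {path}")
    return FrameIndex(group, tuple(frames))


def extract_group(ens: Ensemble, fi: FrameIndex) -> Ensemble:
    """Sub-ensemble of the indexed frames, in index order, sharing topology."""
    idx = np.asarray(fi.frames, dtype=int)
    if len(idx) and idx.max() >= ens.n_frames:
        raise TrajectoryError(
            f"index '{fi.group}' references frame {idx.max()} but ensemble "
            f"has {ens.n_frames}")
    return ens.subset(idx)
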