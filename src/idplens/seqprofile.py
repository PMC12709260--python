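"""Sequence-level annotation of a peptide.

Hydropathy and charge profiles, net charge, motif location, molecular weight
and mean residue weight (MRW) for a peptide given as one-letter codes. The
charge model is the integer assignment at neutral pH used in classical MD
setups: Asp/Glu -1, Lys/Arg +1, His neutral (optionally +1), plus +1/-1 for
charged N/C termini. No fractional (Henderson-Hasselbalch) titration is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C


class SequenceError(ValueError):
    """Raised for invalid sequences or invalid per-sequence parameters."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with its physical bookkeeping.

    Parameters
    ----------
    sequence
        One-letter residue codes (standard 20-letter alphabet).
    termini_charged
        Model the N-terminus as NH3+ (+1) and the C-terminus as COO- (-1).
    his_neutral
        Model histidine side chains as neutral (charge 0); when False they
        carry +1.
    monoisotopic
        Use monoisotopic instead of average residue masses.
    """

    sequence: str
    termini_charged: bool = True
    his_neutral: bool = True
    monoisotopic: bool = False
    residue_masses: tuple = field(init=False)

    def __post_init__(self):
        seq = self.sequence
        if len(seq) < 2:
            raise SequenceError(f"sequence must have >= 2 residues, got {len(seq)}")
        for i, aa in enumerate(seq, start=1):
            if aa not in C.AMINO_ACIDS:
                raise SequenceError(f"unknown residue code {aa!r} at position {i}")
        table = C.RESIDUE_MASS_MONO if self.monoisotopic else C.RESIDUE_MASS_AVERAGE
        object.__setattr__(self, "residue_masses", tuple(table[a] for a in seq))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def molecular_weight(self) -> float:
        """Peptide MW in Da: free-residue masses minus (n-1) condensation waters."""
        water = C.WATER_MONO if self.monoisotopic else C.WATER_AVERAGE
        return float(sum(self.residue_masses) - (len(self) - 1) * water)


def load_peptide(sequence: str, *, termini_charged: bool = True,
                 his_neutral: bool = True, monoisotopic: bool = False) -> Peptide:
    """Validate a one-letter sequence (or single-record FASTA text) into a Peptide."""
    seq = sequence.strip()
    if seq.startswith(">"):
        lines = seq.splitlines()
        seq = "".join(l.strip() for l in lines[1:] if not l.startswith(">"))
    return Peptide(seq, termini_charged=termini_charged,
                   his_neutral=his_neutral, monoisotopic=monoisotopic)


def hydropathy_profile(p: Peptide, window: int = 1) -> pd.DataFrame:
    """Per-residue Kyte-Doolittle hydropathy, optionally sliding-window averaged.

    Windowed values are centred means over min(window, available span); the
    profile keeps one entry per residue.
    """
    if window < 1 or window > len(p):
        raise SequenceError(f"window must be in [1, {len(p)}], got {window}")
    raw = np.array([C.KYTE_DOOLITTLE[a] for a in p.sequence])
    if window == 1:
        vals = raw
    else:
        half = window // 2
        vals = np.array([
            raw[max(0, i - half): i + half + 1].mean() for i in range(len(raw))
        ])
    return pd.DataFrame({
        "position": np.arange(1, len(p) + 1),
        "residue": list(p.sequence),
        "hydropathy": vals,
    })


def charge_profile(p: Peptide) -> tuple[pd.DataFrame, int]:
    """Integer per-residue charges at neutral pH and the peptide net charge.

    Terminal charges (+1 N-term, -1 C-term when modelled charged) are folded
    into the first and last residue entries.
    """
    charges = np.zeros(len(p), dtype=int)
    for i, aa in enumerate(p.sequence):
        if aa == "H":
            charges[i] = 0 if p.his_neutral else 1
        else:
            charges[i] = C.SIDECHAIN_CHARGE.get(aa, 0)
    if p.termini_charged:
        charges[0] += 1
        charges[-1] -= 1
    df = pd.DataFrame({
        "position": np.arange(1, len(p) + 1),
        "residue": list(p.sequence),
        "charge": charges,
    })
    return df, int(charges.sum())


def find_motif(p: Peptide, motif: str) -> tuple[int, int] | None:
    """1-based (start, end) of the first exact occurrence of ``motif``, or None."""
    if not motif:
        raise SequenceError("motif must be non-empty")
    idx = p.sequence.find(motif)
    if idx < 0:
        return None
    return idx + 1, idx + len(motif)


def mean_residue_weight(p: Peptide) -> float:
    """MRW = MW / (n_residues - 1), in Da (the per-peptide-bond mass used in CD)."""
    return p.molecular_weight / (len(p) - 1)


def write_profile_tsv(p: Peptide, path: str | Path, window: int = 1) -> pd.DataFrame:
    """Write the combined hydropathy/charge profile as TSV and return it."""
    hyd = hydropathy_profile(p, window=window)
    chg, _net = charge_profile(p)
    df = hyd.merge(chg, on=["position", "residue"])
    df.to_csv(path, sep="\t", index=False)
    return df
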