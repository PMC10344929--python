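"""Protein sequence handling, charge annotation and residue census.

Charge calculations use the Henderson-Hasselbalch equation per ionizable
side chain with a single documented pKa table (EMBOSS-style values, see
:data:`PKA_TABLE`).  All residue positions use the construct's own
("paper") numbering carried by ``first_residue_number`` so that results
line up with crosslink tables, HDX maps and NMR peak lists from the same
construct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "PKA_TABLE",
    "ProteinSequence",
    "ChargeProfile",
    "net_charge",
    "charge_profile",
    "residue_inventory",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Side-chain and termini pKa values (EMBOSS defaults).  ``sign`` is the
#: charge carried by the deprotonated (-1) or protonated (+1) species.
PKA_TABLE: dict[str, float] = {
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
    "Nterm": 8.6,
    "Cterm": 3.6,
}

_NEGATIVE = frozenset("DECY")
_POSITIVE = frozenset("KRH")


@dataclass(frozen=True)
class ProteinSequence:
    """A one-letter amino acid sequence with explicit construct numbering.

    Parameters
    ----------
    id:
        Construct label, e.g. ``"IDR"`` or ``"NTD"``.
    residues:
        One-letter string over the 20 canonical amino acids.
    first_residue_number:
        Number of the first residue in construct numbering (>= 1).  The
        IDR construct starts at residue 2, for example.
    """

    id: str
    residues: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        if self.first_residue_number < 1:
            raise ValueError("first_residue_number must be >= 1")
        for i, aa in enumerate(self.residues):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"unknown residue letter {aa!r} at position "
                    f"{self.first_residue_number + i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.arange(
            self.first_residue_number, self.first_residue_number + len(self.residues)
        )

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.residues) - 1

    def letter_at(self, position: int) -> str:
        """Residue letter at a construct-numbered position."""
        idx = position - self.first_residue_number
        if not 0 <= idx < len(self.residues):
            raise ValueError(f"position {position} outside sequence {self.id}")
        return self.residues[idx]

    def subsequence(self, start: int, end: int, id: str | None = None) -> "ProteinSequence":
        """Inclusive slice in construct numbering."""
        i = start - self.first_residue_number
        j = end - self.first_residue_number
        if i < 0 or j >= len(self.residues) or i > j:
            raise ValueError(f"range {start}-{end} outside sequence {self.id}")
        return ProteinSequence(
            id=id or f"{self.id}:{start}-{end}",
            residues=self.residues[i : j + 1],
            first_residue_number=start,
        )


@dataclass
class ChargeProfile:
    """Sliding-window net charge per residue (full windows only)."""

    positions: np.ndarray
    window_charge: np.ndarray
    pH: float
    window_size: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"position": self.positions, "window_charge": self.window_charge}
        )


def _hh_charge(aa: str, pH: float) -> float:
    if aa in _POSITIVE:
        return 1.0 / (1.0 + 10.0 ** (pH - PKA_TABLE[aa]))
    if aa in _NEGATIVE:
        return -1.0 / (1.0 + 10.0 ** (PKA_TABLE[aa] - pH))
    return 0.0


def net_charge(
    seq: ProteinSequence | str, pH: float = 7.4, include_termini: bool = False
) -> float:
    """Net charge in elementary charges at a given pH.

    Henderson-Hasselbalch sum over ionizable side chains (D, E, C, Y
    negative; K, R, H positive), optionally adding the free alpha-amino
    and carboxy termini.  Histidine carries its partial positive charge
    at pH 7.4 as given by the pKa table; termini are excluded by default.
    """
    if isinstance(seq, str):
        seq = ProteinSequence("anon", seq)
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    z = sum(_hh_charge(aa, pH) for aa in seq.residues)
    if include_termini:
        z += 1.0 / (1.0 + 10.0 ** (pH - PKA_TABLE["Nterm"]))
        z -= 1.0 / (1.0 + 10.0 ** (PKA_TABLE["Cterm"] - pH))
    return z


def charge_profile(
    seq: ProteinSequence | str, pH: float = 7.4, window: int = 5
) -> ChargeProfile:
    """Sliding-window net charge centred on each residue.

    Only residues with a full window are reported (edge windows are
    truncated and therefore omitted); termini contributions are never
    included inside windows.
    """
    if isinstance(seq, str):
        seq = ProteinSequence("anon", seq)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window larger than sequence")
    per_residue = np.array([_hh_charge(aa, pH) for aa in seq.residues])
    kernel = np.ones(window)
    sums = np.convolve(per_residue, kernel, mode="valid")
    half = window // 2
    positions = seq.residue_numbers[half : len(seq) - half]
    return ChargeProfile(
        positions=positions, window_charge=sums, pH=pH, window_size=window
    )


def residue_inventory(
    seq: ProteinSequence, residue: str, from_position: int | None = None
) -> list[int]:
    """Positions (construct numbering) carrying ``residue`` at or after
    ``from_position``."""
    if residue not in AMINO_ACIDS:
        raise ValueError(f"invalid residue letter {residue!r}")
    if from_position is None:
        from_position = seq.first_residue_number
    if not seq.first_residue_number <= from_position <= seq.last_residue_number:
        raise ValueError(
            f"from_position {from_position} outside sequence "
            f"({seq.first_residue_number}-{seq.last_residue_number})"
        )
    return [
        int(pos)
        for pos, aa in zip(seq.residue_numbers, seq.residues)
        if aa == residue and pos >= from_position
    ]


def read_fasta(path, first_residue_number: int = 1) -> list[ProteinSequence]:
    """Read sequences from a FASTA file (via biotite)."""
    import biotite.sequence.io.fasta as fasta

    ff = fasta.FastaFile.read(str(path))
    return [
        ProteinSequence(id=header.split()[0], residues=str(seq),
                        first_residue_number=first_residue_number)
        for header, seq in ff.items()
    ]


def write_fasta(path, sequences: Iterable[ProteinSequence]) -> None:
    import biotite.sequence.io.fasta as fasta

    ff = fasta.FastaFile()
    for s in sequences:
        ff[f"{s.id} first_residue={s.first_residue_number}"] = s.residues
    ff.write(str(path))
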