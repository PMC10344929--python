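"""Residue-level HDX-MS mapping and disorder classification.

Peptide-level deuterium uptake is projected onto residues with the
shortest-covering-peptide rule: a residue covered by one peptide takes
that peptide's uptake; with overlapping peptides the shortest wins, and
length ties are broken by the peptide whose C-terminus lies closest to
the residue.  Exchange-incompetent positions (each peptide's first
residue, which loses its deuterium during back-exchange, and prolines,
which lack an amide proton) are excluded from coverage by default.

A residue is classified intrinsically disordered when its uptake
exceeds 50% after 10 s of exchange and no consecutive-timepoint
increment exceeds 5% — fast initial exchange that is already complete.
Both thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sequence import ProteinSequence

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "HdxPeptide",
    "ResidueUptakeMap",
    "residue_uptake_map",
    "classify_disorder",
    "coverage_fraction",
    "hdx_difference",
    "read_peptide_csv",
]

#: Standard deuteration timepoints, seconds.
DEFAULT_TIMEPOINTS = (10.0, 30.0, 100.0, 1000.0, 10000.0)


@dataclass(frozen=True)
class HdxPeptide:
    """One peptic peptide with percent deuteration per timepoint."""

    start: int  # first residue, inclusive, construct numbering
    end: int  # last residue, inclusive
    sequence: str
    uptake_pct: tuple  # one value (or None) per timepoint
    timepoints: tuple = DEFAULT_TIMEPOINTS

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("peptide start must be <= end")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"peptide {self.start}-{self.end}: sequence length mismatch"
            )
        if len(self.uptake_pct) != len(self.timepoints):
            raise ValueError("uptake values must match timepoints")
        if any(t2 <= t1 for t1, t2 in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be increasing")
        for u in self.uptake_pct:
            if u is not None and not -1e-9 <= u <= 110.0:
                raise ValueError("uptake must lie in [0, 110]%")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def competent_residues(self, exclude_first: bool = True) -> list[int]:
        """Residues of this peptide that can retain exchange information."""
        first = self.start + 1 if exclude_first else self.start
        return [
            pos
            for pos in range(first, self.end + 1)
            if self.sequence[pos - self.start] != "P"
        ]


@dataclass
class ResidueUptakeMap:
    """Per-residue uptake with provenance peptide per residue."""

    residues: np.ndarray  # covered residues, ascending
    timepoints: tuple
    uptake: np.ndarray  # (n_residues, n_timepoints), NaN where missing
    source_peptide: list  # (start, end) per residue

    def uptake_at(self, residue: int) -> np.ndarray:
        i = int(np.searchsorted(self.residues, residue))
        if i >= len(self.residues) or self.residues[i] != residue:
            raise KeyError(f"residue {residue} not covered")
        return self.uptake[i]

    def covered(self, residue: int) -> bool:
        i = int(np.searchsorted(self.residues, residue))
        return i < len(self.residues) and self.residues[i] == residue


def _winning_peptide(candidates: Sequence[HdxPeptide], residue: int) -> HdxPeptide:
    """Shortest covering peptide; ties broken by closest C-terminus."""
    return min(candidates, key=lambda p: (p.length, p.end - residue))


def residue_uptake_map(
    peptides: Sequence[HdxPeptide],
    seq: ProteinSequence,
    exclude_first_residue: bool = True,
) -> ResidueUptakeMap:
    """Project peptide uptake onto residues by the shortest-peptide rule.

    ``exclude_first_residue=False`` gives strict-literal mode in which
    each peptide's first residue also inherits its uptake (prolines are
    always excluded).  Deterministic and independent of peptide input
    order.
    """
    for p in peptides:
        if p.start < seq.first_residue_number or p.end > seq.last_residue_number:
            raise ValueError(
                f"peptide {p.start}-{p.end} outside sequence "
                f"{seq.first_residue_number}-{seq.last_residue_number}"
            )
    timepoints = peptides[0].timepoints if peptides else DEFAULT_TIMEPOINTS
    for p in peptides:
        if p.timepoints != timepoints:
            raise ValueError("all peptides must share one timepoint grid")
    covering: dict[int, list[HdxPeptide]] = {}
    for p in peptides:
        for res in p.competent_residues(exclude_first=exclude_first_residue):
            covering.setdefault(res, []).append(p)
    residues = np.array(sorted(covering), dtype=int)
    nt = len(timepoints)
    uptake = np.full((len(residues), nt), np.nan)
    provenance = []
    for i, res in enumerate(residues):
        win = _winning_peptide(covering[int(res)], int(res))
        provenance.append((win.start, win.end))
        uptake[i] = [np.nan if u is None else u for u in win.uptake_pct]
    return ResidueUptakeMap(
        residues=residues, timepoints=timepoints, uptake=uptake,
        source_peptide=provenance,
    )


def classify_disorder(
    m: ResidueUptakeMap,
    threshold_fast: float = 50.0,
    max_increment: float = 5.0,
    fast_time: float = 10.0,
) -> dict[int, bool | None]:
    """Flag residues as disordered by the fast-exchange rule.

    True iff uptake at the 10 s timepoint is strictly above
    ``threshold_fast`` percent AND no consecutive-timepoint increment
    exceeds ``max_increment`` percent.  Residues with missing
    timepoints map to ``None`` (unclassifiable).
    """
    if fast_time not in m.timepoints:
        raise ValueError(f"{fast_time} s timepoint not present")
    it = m.timepoints.index(fast_time)
    out: dict[int, bool | None] = {}
    for res, row in zip(m.residues, m.uptake):
        if np.any(np.isnan(row)):
            out[int(res)] = None
            continue
        fast = row[it] > threshold_fast
        increments = np.diff(row)
        plateau = not np.any(increments > max_increment)
        out[int(res)] = bool(fast and plateau)
    return out


def coverage_fraction(
    peptides: Sequence[HdxPeptide],
    region: tuple[int, int],
    mode: str = "raw",
) -> float:
    """Percent of a residue range covered by at least one peptide.

    ``raw`` counts every residue of the region as coverable and a
    residue as covered when any peptide spans it (the convention that
    reproduces whole-region coverage figures); ``competent`` restricts
    both numerator and denominator to exchange-competent positions
    (peptide first residues excluded, prolines excluded where sequence
    information is available).
    """
    start, end = region
    if start > end:
        raise ValueError("empty region")
    region_residues = range(start, end + 1)
    if mode == "raw":
        covered = set()
        for p in peptides:
            covered.update(range(p.start, p.end + 1))
        hit = sum(1 for r in region_residues if r in covered)
        return 100.0 * hit / len(region_residues)
    if mode == "competent":
        coverable = set(region_residues)
        prolines = set()
        for p in peptides:
            for i, aa in enumerate(p.sequence):
                if aa == "P":
                    prolines.add(p.start + i)
        coverable -= prolines
        covered = set()
        for p in peptides:
            covered.update(p.competent_residues(exclude_first=True))
        hit = len(coverable & covered)
        if not coverable:
            raise ValueError("no coverable residues in region")
        return 100.0 * hit / len(coverable)
    raise ValueError("mode must be 'raw' or 'competent'")


def hdx_difference(
    map_a: ResidueUptakeMap, map_b: ResidueUptakeMap
) -> ResidueUptakeMap:
    """Per-residue uptake difference (a - b) on the shared coverage.

    Residues covered in only one map are dropped; disjoint coverage
    yields an empty map with a warning.
    """
    if map_a.timepoints != map_b.timepoints:
        raise ValueError("timepoint grids differ")
    shared = np.intersect1d(map_a.residues, map_b.residues)
    if len(shared) == 0:
        import warnings

        warnings.warn("maps have disjoint coverage; empty difference")
    ia = np.searchsorted(map_a.residues, shared)
    ib = np.searchsorted(map_b.residues, shared)
    diff = map_a.uptake[ia] - map_b.uptake[ib]
    prov = [
        (map_a.source_peptide[int(x)], map_b.source_peptide[int(y)])
        for x, y in zip(ia, ib)
    ]
    return ResidueUptakeMap(
        residues=shared, timepoints=map_a.timepoints, uptake=diff,
        source_peptide=prov,
    )


def read_peptide_csv(path, timepoints=DEFAULT_TIMEPOINTS) -> list[HdxPeptide]:
    """Read a peptide uptake table.

    Expected columns: ``start, end, sequence`` plus one uptake column
    per timepoint named ``t<seconds>`` (e.g. ``t10, t30, ...``), in
    percent; empty cells are missing values.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = [f"t{int(t)}" for t in timepoints]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing uptake columns: {missing}")
    peptides = []
    for row in df.itertuples():
        uptake = tuple(
            None if pd.isna(getattr(row, c)) else float(getattr(row, c)) for c in cols
        )
        peptides.append(
            HdxPeptide(
                start=int(row.start), end=int(row.end), sequence=str(row.sequence),
                uptake_pct=uptake, timepoints=tuple(float(t) for t in timepoints),
            )
        )
    return peptides
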