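"""Dummy-residue chain ensembles and crosslink validation.

Disordered segments are modelled at one bead per residue (virtual
C-alpha trace): consecutive beads sit at a fixed virtual bond length
(default 0.38 nm), consecutive bond angles are drawn from a coarse
Ramachandran-like window, and non-bonded beads may not approach closer
than a hard excluded diameter, giving self-avoiding walks.  Chains can
be grown off a rigid folded anchor (e.g. a Calpha trace read from a
PDB file) whose coordinates are never modified.

Internally all coordinates are in nm; crosslink-facing distances are in
Angstrom, matching how DSS crosslinking distances are conventionally
quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "ChainParams",
    "Conformer",
    "Ensemble",
    "CrosslinkRecord",
    "ChainGenerationError",
    "generate_conformer",
    "grow_on_anchor",
    "synthetic_anchor",
    "conformer_metrics",
    "assert_self_avoiding",
    "distance_map",
    "filter_crosslinks",
    "crosslink_satisfaction",
    "read_ca_pdb",
    "write_pdb",
    "read_crosslink_csv",
]

NM_TO_ANGSTROM = 10.0


class ChainGenerationError(RuntimeError):
    """Raised when the retry budget for self-avoiding growth is exhausted."""


@dataclass(frozen=True)
class ChainParams:
    """Geometry of the dummy-residue chain model.

    bond_length:
        Virtual Calpha-Calpha bond, nm.
    excluded_diameter:
        Hard-sphere diameter between non-bonded beads, nm.  Must be
        smaller than twice the bond length so a step always exists.
    angle_range_deg:
        Range of the pseudo bond angle between consecutive virtual
        bonds; a coarse stand-in for Ramachandran constraints on the
        Calpha trace.
    retry_budget:
        Placement attempts per bead before backtracking one bead.
    """

    bond_length: float = 0.38
    excluded_diameter: float = 0.40
    angle_range_deg: tuple[float, float] = (65.0, 165.0)
    retry_budget: int = 100

    def __post_init__(self):
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if not 0 <= self.excluded_diameter < 2 * self.bond_length:
            raise ValueError("excluded_diameter must lie in [0, 2*bond_length)")


@dataclass
class Conformer:
    """Bead-per-residue chain with an optional rigid anchor part."""

    residue_numbers: np.ndarray
    coordinates: np.ndarray  # (n, 3) nm
    anchor_mask: np.ndarray | None = None  # True where rigid anchor

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if len(self.residue_numbers) != len(self.coordinates):
            raise ValueError("residue_numbers and coordinates length mismatch")
        if self.anchor_mask is None:
            self.anchor_mask = np.zeros(len(self.coordinates), dtype=bool)
        else:
            self.anchor_mask = np.asarray(self.anchor_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.coordinates)

    def index_of(self, residue_number: int) -> int:
        hits = np.nonzero(self.residue_numbers == residue_number)[0]
        if len(hits) != 1:
            raise ValueError(f"residue {residue_number} not present exactly once")
        return int(hits[0])


@dataclass
class Ensemble:
    """Weighted collection of conformers sharing one residue set."""

    conformers: list
    weights: np.ndarray | None = None

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        n = len(self.conformers)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != n:
            raise ValueError("weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        ref = self.conformers[0].residue_numbers
        for c in self.conformers[1:]:
            if not np.array_equal(c.residue_numbers, ref):
                raise ValueError("conformers must share residue_numbers")

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.conformers[0].residue_numbers

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass(frozen=True)
class CrosslinkRecord:
    """One DSS crosslink identification between two lysine residues."""

    residue_i: int
    residue_j: int
    replicate_count: int = 1
    delta_s: float = 0.0
    best_id_score: float = 0.0

    def __post_init__(self):
        if self.residue_i == self.residue_j:
            raise ValueError("crosslink endpoints must differ")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


# ---------------------------------------------------------------------------
# chain growth


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _next_direction(
    prev_dir: np.ndarray, params: ChainParams, rng: np.random.Generator
) -> np.ndarray:
    """Direction of the next virtual bond given the previous one.

    The pseudo bond angle theta (between bond vectors b_{i-1} and b_i
    reversed, i.e. the chain angle) is uniform on ``angle_range_deg``;
    the dihedral is uniform on [0, 2pi).
    """
    lo, hi = np.deg2rad(params.angle_range_deg)
    theta = rng.uniform(lo, hi)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # supplementary angle: the new bond deviates from the previous bond
    # direction by (pi - theta)
    dev = np.pi - theta
    # orthonormal frame around prev_dir
    a = np.array([1.0, 0.0, 0.0])
    if abs(prev_dir @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(prev_dir, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(prev_dir, e1)
    return (
        np.cos(dev) * prev_dir
        + np.sin(dev) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    )


def _grow_chain(
    fixed: np.ndarray,
    start_point: np.ndarray,
    n_new: int,
    params: ChainParams,
    rng: np.random.Generator,
    bonded_fixed_index: int | None,
) -> np.ndarray:
    """Grow ``n_new`` beads from ``start_point`` avoiding ``fixed`` beads.

    ``bonded_fixed_index`` marks the fixed bead covalently bonded to the
    first new bead (excluded from its clash check).  Returns the (n_new,
    3) coordinates or raises :class:`ChainGenerationError`.
    """
    b = params.bond_length
    d2 = params.excluded_diameter**2
    new = np.empty((n_new, 3))
    placed = 0
    attempts = np.zeros(n_new, dtype=int)
    total_budget = params.retry_budget * max(n_new, 1) * 10
    total = 0
    while placed < n_new:
        if placed == 0:
            direction = _random_unit(rng)
            candidate = start_point + b * direction
        else:
            prev_dir = (
                (new[placed - 1] - (new[placed - 2] if placed >= 2 else start_point))
            )
            prev_dir = prev_dir / np.linalg.norm(prev_dir)
            candidate = new[placed - 1] + b * _next_direction(prev_dir, params, rng)
        ok = True
        if len(fixed):
            dist2 = np.sum((fixed - candidate) ** 2, axis=1)
            if bonded_fixed_index is not None and placed == 0:
                dist2[bonded_fixed_index] = np.inf
            # the bead bonded to the anchor attachment keeps only the
            # bond-length guarantee to it; all other fixed beads are hard
            if np.any(dist2 < d2):
                ok = False
        if ok and placed >= 2:
            # non-bonded new beads: exclude the directly bonded predecessor
            dist2 = np.sum((new[: placed - 1] - candidate) ** 2, axis=1)
            if np.any(dist2 < d2):
                ok = False
        if ok:
            new[placed] = candidate
            attempts[placed] = 0
            placed += 1
        else:
            attempts[placed] += 1
            total += 1
            if attempts[placed] > params.retry_budget:
                # backtrack one bead
                attempts[placed] = 0
                if placed == 0:
                    raise ChainGenerationError(
                        "no valid first step from attachment point"
                    )
                placed -= 1
            if total > total_budget:
                raise ChainGenerationError(
                    f"retry budget exhausted after {total} attempts"
                )
    return new


def generate_conformer(
    n_residues: int,
    params: ChainParams | None = None,
    seed: int | np.random.Generator = 0,
    first_residue_number: int = 1,
) -> Conformer:
    """Generate one self-avoiding dummy-residue chain.

    Deterministic for a fixed seed.  Raises
    :class:`ChainGenerationError` if the geometry is over-constrained.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    params = params or ChainParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    if n_residues > 1:
        coords[1:] = _grow_chain(
            fixed=coords[:1],
            start_point=coords[0],
            n_new=n_residues - 1,
            params=params,
            rng=rng,
            bonded_fixed_index=0,
        )
    numbers = np.arange(first_residue_number, first_residue_number + n_residues)
    return Conformer(residue_numbers=numbers, coordinates=coords)


def grow_on_anchor(
    anchor: Conformer,
    attach_residue: int,
    n_new: int,
    params: ChainParams | None = None,
    seed: int | np.random.Generator = 0,
    direction: Literal["prepend", "append"] = "prepend",
) -> Conformer:
    """Grow a disordered chain off a rigid anchor conformer.

    The anchor coordinates are carried over bitwise unchanged; new beads
    are numbered consecutively before (``prepend``) or after
    (``append``) the anchor residue range and clash-checked against
    every anchor bead.  ``n_new == 0`` returns the anchor itself.
    """
    params = params or ChainParams()
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_new == 0:
        return anchor
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ai = anchor.index_of(attach_residue)
    new = _grow_chain(
        fixed=anchor.coordinates,
        start_point=anchor.coordinates[ai],
        n_new=n_new,
        params=params,
        rng=rng,
        bonded_fixed_index=ai,
    )
    if direction == "prepend":
        numbers = np.concatenate(
            [
                np.arange(
                    anchor.residue_numbers.min() - n_new,
                    anchor.residue_numbers.min(),
                ),
                anchor.residue_numbers,
            ]
        )
        # chain grows away from the attachment: first new bead is the
        # residue adjacent to the attachment, so reverse for ascending order
        coords = np.vstack([new[::-1], anchor.coordinates])
        mask = np.concatenate(
            [np.zeros(n_new, dtype=bool), np.ones(len(anchor), dtype=bool)]
        )
    elif direction == "append":
        numbers = np.concatenate(
            [
                anchor.residue_numbers,
                np.arange(
                    anchor.residue_numbers.max() + 1,
                    anchor.residue_numbers.max() + 1 + n_new,
                ),
            ]
        )
        coords = np.vstack([anchor.coordinates, new])
        mask = np.concatenate(
            [np.ones(len(anchor), dtype=bool), np.zeros(n_new, dtype=bool)]
        )
    else:
        raise ValueError("direction must be 'prepend' or 'append'")
    return Conformer(residue_numbers=numbers, coordinates=coords, anchor_mask=mask)


def synthetic_anchor(
    n_residues: int = 248,
    radius: float = 2.0,
    min_separation: float = 0.40,
    seed: int = 0,
    first_residue_number: int = 135,
) -> Conformer:
    """Synthetic compact globular anchor (stand-in for a folded domain).

    Beads are placed by random sequential addition inside a sphere with
    a minimum pair separation, emulating the bead density of a folded
    Calpha trace.  This is a synthetic object: it reproduces size and
    packing, not any real domain's fold.
    """
    rng = np.random.default_rng(seed)
    coords = np.empty((n_residues, 3))
    placed = 0
    tries = 0
    while placed < n_residues:
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius**2:
            continue
        if placed and np.any(
            np.sum((coords[:placed] - p) ** 2, axis=1) < min_separation**2
        ):
            tries += 1
            if tries > 200000:
                raise ChainGenerationError("anchor packing too dense")
            continue
        coords[placed] = p
        placed += 1
    numbers = np.arange(first_residue_number, first_residue_number + n_residues)
    mask = np.ones(n_residues, dtype=bool)
    return Conformer(residue_numbers=numbers, coordinates=coords, anchor_mask=mask)


# ---------------------------------------------------------------------------
# geometry


def assert_self_avoiding(c: Conformer, params: ChainParams) -> None:
    """Raise if any non-bonded bead pair violates the excluded diameter
    or any generated bond deviates from the virtual bond length."""
    x = c.coordinates
    n = len(x)
    if n < 2:
        return
    d = squareform(pdist(x))
    nb = ~np.eye(n, dtype=bool)
    off = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) == 1
    nb &= ~off
    if np.any(d[nb] < params.excluded_diameter - 1e-9):
        raise AssertionError("excluded-diameter violation")
    gen = ~c.anchor_mask
    for i in range(n - 1):
        if gen[i] and gen[i + 1]:
            if abs(d[i, i + 1] - params.bond_length) > 1e-6:
                raise AssertionError("virtual bond length violation")


def conformer_metrics(c: Conformer) -> tuple[float, float, float]:
    """(Rg, Dmax, end-to-end distance), all nm, unit bead masses."""
    x = c.coordinates
    if len(x) == 0:
        raise ValueError("empty conformer")
    rg = float(np.sqrt(np.mean(np.sum((x - x.mean(axis=0)) ** 2, axis=1))))
    if len(x) == 1:
        return 0.0, 0.0, 0.0
    dmax = float(pdist(x).max())
    ete = float(np.linalg.norm(x[-1] - x[0]))
    return rg, dmax, ete


def radius_of_gyration(c: Conformer) -> float:
    return conformer_metrics(c)[0]


def distance_map(
    e: Ensemble | Conformer, statistic: Literal["min", "mean"] = "min"
) -> np.ndarray:
    """Symmetric residue-by-residue Calpha distance matrix in Angstrom.

    ``min`` takes the elementwise minimum over conformers (the relevant
    statistic for crosslink compatibility), ``mean`` the weighted mean.
    """
    if isinstance(e, Conformer):
        e = Ensemble([e])
    if statistic not in ("min", "mean"):
        raise ValueError("statistic must be 'min' or 'mean'")
    mats = np.stack(
        [squareform(pdist(c.coordinates)) for c in e.conformers]
    )  # (k, n, n) nm
    if statistic == "min":
        out = mats.min(axis=0)
    else:
        out = np.tensordot(e.weights, mats, axes=1)
    return out * NM_TO_ANGSTROM


# ---------------------------------------------------------------------------
# crosslinks


def filter_crosslinks(
    raw: Sequence[CrosslinkRecord],
    min_replicates: int = 2,
    max_delta_s: float = 0.95,
    min_id_score: float = 25.0,
) -> list[CrosslinkRecord]:
    """Identification-quality filter for crosslink records.

    Keeps records seen in at least ``min_replicates`` biological
    replicates with deltaS strictly below ``max_delta_s`` and a best Id
    score of at least ``min_id_score``; input order is preserved.
    """
    return [
        r
        for r in raw
        if r.replicate_count >= min_replicates
        and r.delta_s < max_delta_s
        and r.best_id_score >= min_id_score
    ]


def crosslink_satisfaction(
    xls: Sequence[CrosslinkRecord],
    e: Ensemble | Conformer,
    cutoff: float = 30.0,
) -> tuple[np.ndarray, float]:
    """Check crosslinks against an ensemble's Calpha distances.

    A crosslink is satisfied when the minimum-over-conformers
    Calpha-Calpha distance between its two residues is at most
    ``cutoff`` (Angstrom; 30 A is the DSS convention).  Returns the
    per-crosslink boolean flags and the satisfied fraction.
    """
    if isinstance(e, Conformer):
        e = Ensemble([e])
    numbers = e.residue_numbers
    idx = {int(n): i for i, n in enumerate(numbers)}
    for r in xls:
        for res in (r.residue_i, r.residue_j):
            if res not in idx:
                raise ValueError(f"crosslink residue {res} not in ensemble")
    dmin = distance_map(e, "min")
    flags = np.array(
        [dmin[idx[r.residue_i], idx[r.residue_j]] <= cutoff for r in xls], dtype=bool
    )
    frac = float(flags.mean()) if len(flags) else float("nan")
    return flags, frac


# ---------------------------------------------------------------------------
# I/O


def read_ca_pdb(path, chain: str | None = None) -> Conformer:
    """Read a Calpha trace from a PDB file into a rigid anchor conformer.

    Coordinates are converted Angstrom -> nm; residue numbers are taken
    from the PDB.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    sel = atoms.atom_name == "CA"
    if chain is not None:
        sel &= atoms.chain_id == chain
    ca = atoms[sel]
    if ca.array_length() == 0:
        raise ValueError("no CA atoms found")
    mask = np.ones(ca.array_length(), dtype=bool)
    return Conformer(
        residue_numbers=ca.res_id.astype(int),
        coordinates=ca.coord / NM_TO_ANGSTROM,
        anchor_mask=mask,
    )


def write_pdb(path, c: Conformer, element: str = "C") -> None:
    """Write a conformer as a pseudo-Calpha PDB file (nm -> Angstrom)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(c)
    atoms = struc.AtomArray(n)
    atoms.coord = c.coordinates * NM_TO_ANGSTROM
    atoms.atom_name = np.full(n, "CA")
    atoms.res_name = np.full(n, "GLY")
    atoms.res_id = c.residue_numbers
    atoms.chain_id = np.full(n, "A")
    atoms.element = np.full(n, element)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_crosslink_csv(path) -> list[CrosslinkRecord]:
    """Read crosslink records from CSV with columns
    ``res_i,res_j,replicates,deltaS,best_id``."""
    import pandas as pd

    df = pd.read_csv(path)
    return [
        CrosslinkRecord(
            residue_i=int(r.res_i),
            residue_j=int(r.res_j),
            replicate_count=int(r.replicates),
            delta_s=float(r.deltaS),
            best_id_score=float(r.best_id),
        )
        for r in df.itertuples()
    ]
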