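"""Bespoke trajectory post-processing for membrane-tethered chains.

Three analyses operate on lightweight in-memory trajectory slices:

* per-residue membrane contact counts (optionally restricted to one
  lipid type, e.g. PIP2), averaged over an analysis window;
* harmonic-restraint forces on a tethered chain terminus, recomputed
  from bead positions and the force constant (engine-independent), and
  their aggregation into force-displacement curves with replicate SEMs
  and effective force-constant fits;
* residue fluctuations projected on a channel principal axis defined by
  the cross product of two inter-subunit vectors (axial RMSF).

Units: coordinates nm, times microseconds, forces pN.  A restraint
force of k (kJ mol^-1 nm^-2) times a displacement (nm) converts to pN
by the factor 1.66054 (1 kJ mol^-1 nm^-1 per Avogadro's number).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KJ_PER_MOL_NM_TO_PN",
    "TrajectorySlice",
    "RestraintRecord",
    "ForceCurvePoint",
    "ForceCurve",
    "residue_membrane_contacts",
    "restraint_forces",
    "force_displacement_curve",
    "effective_force_constant",
    "force_constant_ratio",
    "axial_rmsf",
    "read_frame_table",
    "load_trajectory_mda",
]

KJ_PER_MOL_NM_TO_PN = 1.66054


@dataclass
class TrajectorySlice:
    """Per-frame bead coordinates grouped by residue and chain.

    coords has shape (n_frames, n_beads, 3); ``bead_residues`` and
    ``bead_chains`` assign each bead column to a residue number and a
    chain label.  Membrane information is optional: a per-frame
    membrane center-of-mass z and lipid (headgroup) bead coordinates
    with a per-bead lipid type.
    """

    times: np.ndarray  # microseconds, increasing
    coords: np.ndarray  # (T, n_beads, 3) nm
    bead_residues: np.ndarray  # (n_beads,) int
    bead_chains: np.ndarray | None = None  # (n_beads,) labels
    membrane_z: np.ndarray | None = None  # (T,)
    lipid_coords: np.ndarray | None = None  # (T, n_lipid_beads, 3)
    lipid_types: np.ndarray | None = None  # (n_lipid_beads,)
    box: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.bead_residues = np.asarray(self.bead_residues, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_beads, 3)")
        if self.coords.shape[0] != len(self.times):
            raise ValueError("times / frames mismatch")
        if self.coords.shape[1] != len(self.bead_residues):
            raise ValueError("bead grouping mismatch")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if self.bead_chains is not None:
            self.bead_chains = np.asarray(self.bead_chains)
            if len(self.bead_chains) != self.coords.shape[1]:
                raise ValueError("bead_chains length mismatch")
        if self.lipid_coords is not None:
            self.lipid_coords = np.asarray(self.lipid_coords, dtype=float)
            if self.lipid_coords.shape[0] != len(self.times):
                raise ValueError("lipid frames mismatch")
            if self.lipid_types is not None:
                self.lipid_types = np.asarray(self.lipid_types)
                if len(self.lipid_types) != self.lipid_coords.shape[1]:
                    raise ValueError("lipid_types length mismatch")

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.bead_residues)

    def window(self, equilibration_cut: float) -> "TrajectorySlice":
        """Frames with time >= equilibration_cut (microseconds)."""
        keep = self.times >= equilibration_cut
        if not np.any(keep):
            raise ValueError("no frames after the equilibration cut")
        return TrajectorySlice(
            times=self.times[keep],
            coords=self.coords[keep],
            bead_residues=self.bead_residues,
            bead_chains=self.bead_chains,
            membrane_z=None if self.membrane_z is None else self.membrane_z[keep],
            lipid_coords=None if self.lipid_coords is None else self.lipid_coords[keep],
            lipid_types=self.lipid_types,
            box=self.box,
        )


@dataclass
class RestraintRecord:
    """One restrained simulation: harmonic tether on a chain terminus."""

    target_height: float  # nm above the membrane midplane
    force_constant: float  # kJ mol^-1 nm^-2
    times: np.ndarray  # microseconds
    z: np.ndarray  # per-frame restrained-bead height above midplane, nm
    replicate_id: int = 0
    condition: str = ""

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.shape != self.z.shape:
            raise ValueError("times / z mismatch")


@dataclass
class ForceCurvePoint:
    condition: str
    target_height: float
    mean_height: float  # nm
    mean_force: float  # pN
    sem_force: float  # pN; NaN when only one replicate
    n_replicates: int


@dataclass
class ForceCurve:
    points: list

    def for_condition(self, condition: str) -> "ForceCurve":
        return ForceCurve([p for p in self.points if p.condition == condition])

    @property
    def mean_heights(self) -> np.ndarray:
        return np.array([p.mean_height for p in self.points])

    @property
    def mean_forces(self) -> np.ndarray:
        return np.array([p.mean_force for p in self.points])

    @property
    def sem_forces(self) -> np.ndarray:
        return np.array([p.sem_force for p in self.points])


# ---------------------------------------------------------------------------
# contacts


def residue_membrane_contacts(
    t: TrajectorySlice,
    cutoff: float = 0.6,
    equilibration_cut: float = 0.0,
    lipid_filter: str | None = None,
    binary: bool = False,
) -> dict[int, float]:
    """Mean lipid-bead contact count per residue over the analysis window.

    A contact is a lipid bead within ``cutoff`` nm of any bead of the
    residue.  By default the per-frame value is the number of lipid
    beads in contact; ``binary=True`` counts 1 when any contact exists.
    ``lipid_filter`` restricts to one lipid type (e.g. ``"PIP2"``).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if t.lipid_coords is None:
        raise ValueError("trajectory carries no lipid coordinates")
    w = t.window(equilibration_cut)
    lipids = w.lipid_coords
    if lipid_filter is not None:
        if w.lipid_types is None:
            raise ValueError("lipid_filter given but no lipid types present")
        sel = w.lipid_types == lipid_filter
        if not np.any(sel):
            raise ValueError(f"no lipid beads of type {lipid_filter!r}")
        lipids = lipids[:, sel]
    out: dict[int, float] = {}
    c2 = cutoff**2
    for res in w.residue_numbers:
        beads = w.coords[:, w.bead_residues == res]  # (T, nb, 3)
        # (T, nb, nl) squared distances
        diff = beads[:, :, None, :] - lipids[:, None, :, :]
        d2 = np.einsum("tblx,tblx->tbl", diff, diff)
        in_contact = (d2 <= c2).any(axis=1)  # (T, nl): lipid bead near residue
        per_frame = in_contact.any(axis=1).astype(float) if binary else in_contact.sum(axis=1)
        out[int(res)] = float(np.mean(per_frame))
    return out


# ---------------------------------------------------------------------------
# restraint forces


def restraint_forces(
    r: RestraintRecord, equilibration_cut: float = 0.0, min_frames: int = 100
) -> tuple[float, float]:
    """(mean restraint force in pN, mean tether height in nm).

    The per-frame force is k (z_target - z(t)) in kJ mol^-1 nm^-1,
    converted to pN; the sign convention is positive when the chain
    pulls the tether below its target (membrane adhesion pulling down).
    """
    keep = r.times >= equilibration_cut
    if keep.sum() < min_frames:
        raise ValueError(
            f"only {int(keep.sum())} frames after cut; need >= {min_frames}"
        )
    z = r.z[keep]
    force_kj = r.force_constant * (r.target_height - z)
    return (
        float(np.mean(force_kj) * KJ_PER_MOL_NM_TO_PN),
        float(np.mean(z)),
    )


def force_displacement_curve(
    records: Sequence[RestraintRecord],
    equilibration_cut: float = 0.0,
    min_frames: int = 100,
) -> ForceCurve:
    """Aggregate restrained replicates into a force-displacement curve.

    One point per (condition, target height): the mean over replicate
    means, with SEM = Bessel-corrected SD of replicate means divided by
    sqrt(n_replicates).  Single-replicate points carry SEM = NaN.
    """
    groups: dict[tuple[str, float], list[RestraintRecord]] = {}
    for r in records:
        groups.setdefault((r.condition, r.target_height), []).append(r)
    points = []
    for (cond, h), reps in sorted(groups.items()):
        means = []
        heights = []
        for r in reps:
            f, z = restraint_forces(r, equilibration_cut, min_frames)
            means.append(f)
            heights.append(z)
        n = len(means)
        sem = float(np.std(means, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        points.append(
            ForceCurvePoint(
                condition=cond, target_height=h,
                mean_height=float(np.mean(heights)),
                mean_force=float(np.mean(means)), sem_force=sem, n_replicates=n,
            )
        )
    return ForceCurve(points)


def effective_force_constant(
    curve: ForceCurve, height_min: float = 6.5
) -> tuple[float, float, tuple[float, float]]:
    """Slope of mean force vs mean height beyond ``height_min`` (pN/nm).

    Weighted least squares with weights 1/SEM^2 where SEMs are finite
    and positive, otherwise unweighted.  Returns (slope, intercept,
    CI on the slope).  The slope is the effective force constant of the
    membrane attachment acting on the tethered terminus.
    """
    from scipy.stats import t as t_dist

    pts = [p for p in curve.points if p.mean_height >= height_min]
    if len(pts) < 2:
        raise ValueError("need at least 2 points beyond height_min")
    x = np.array([p.mean_height for p in pts])
    y = np.array([p.mean_force for p in pts])
    sem = np.array([p.sem_force for p in pts])
    if np.all(np.isfinite(sem)) and np.all(sem > 0):
        w = 1.0 / sem**2
    else:
        w = np.ones_like(x)
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * y).sum() / W
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    dof = max(len(x) - 2, 1)
    s2 = (w * resid**2).sum() / dof
    se = float(np.sqrt(s2 / sxx))
    tq = t_dist.ppf(0.975, dof)
    return float(slope), float(intercept), (float(slope - tq * se), float(slope + tq * se))


def force_constant_ratio(
    curve_a: ForceCurve, curve_b: ForceCurve, height_min: float = 6.5
) -> float:
    """Ratio of effective force constants (slope_a / slope_b)."""
    sa, *_ = effective_force_constant(curve_a, height_min)
    sb, *_ = effective_force_constant(curve_b, height_min)
    if sb == 0:
        raise ZeroDivisionError("second curve has zero slope")
    return sa / sb


# ---------------------------------------------------------------------------
# axial RMSF


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R P + t - Q||."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def axial_rmsf(
    t: TrajectorySlice,
    axis_pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    align_selection: np.ndarray | None = None,
    degenerate_tol: float = 1e-8,
) -> dict:
    """RMSF of each residue along the channel principal axis.

    ``axis_pairs`` gives two pairs of (chain, residue) on opposite
    subunits; per frame the axis is the normalized cross product of the
    two connecting vectors.  Frames are first aligned (Kabsch) onto the
    first frame using ``align_selection`` bead indices (default: all
    beads).  Positions are projected on the per-frame axis; RMSF is the
    square root of the projection variance per bead, then averaged over
    the subunits residue-wise with SEM = Bessel SD / sqrt(n_subunits).
    Frames with a degenerate (near-parallel) axis are dropped with a
    count reported.
    """
    if t.bead_chains is None:
        raise ValueError("axial_rmsf needs chain labels")
    if len(axis_pairs) != 2:
        raise ValueError("exactly two axis residue pairs required")
    coords = t.coords.copy()
    sel = (
        np.arange(coords.shape[1]) if align_selection is None else np.asarray(align_selection)
    )
    ref = coords[0][sel]
    for f in range(1, coords.shape[0]):
        R, tr = _kabsch(coords[f][sel], ref)
        coords[f] = coords[f] @ R.T + tr

    def bead_index(chain, residue):
        hits = np.nonzero((t.bead_chains == chain) & (t.bead_residues == residue))[0]
        if len(hits) != 1:
            raise ValueError(f"axis residue ({chain}, {residue}) not unique")
        return int(hits[0])

    (a1, a2), (b1, b2) = axis_pairs
    i1, i2 = bead_index(*a1), bead_index(*a2)
    j1, j2 = bead_index(*b1), bead_index(*b2)
    v1 = coords[:, i2] - coords[:, i1]
    v2 = coords[:, j2] - coords[:, j1]
    axes = np.cross(v1, v2)
    norms = np.linalg.norm(axes, axis=1)
    good = norms > degenerate_tol
    n_dropped = int(np.sum(~good))
    if not np.any(good):
        raise ValueError("all frames have a degenerate axis")
    axes = axes[good] / norms[good, None]
    proj = np.einsum("fbx,fx->fb", coords[good], axes)  # (F, n_beads)
    rmsf_per_bead = proj.std(axis=0, ddof=0)
    chains = np.unique(t.bead_chains)
    residues = t.residue_numbers
    per_subunit = np.full((len(chains), len(residues)), np.nan)
    for ci, ch in enumerate(chains):
        for ri, res in enumerate(residues):
            hits = (t.bead_chains == ch) & (t.bead_residues == res)
            if np.any(hits):
                per_subunit[ci, ri] = rmsf_per_bead[hits].mean()
    mean = np.nanmean(per_subunit, axis=0)
    n_sub = np.sum(~np.isnan(per_subunit), axis=0)
    sem = np.full(len(residues), np.nan)
    for ri in range(len(residues)):
        col = per_subunit[:, ri]
        col = col[~np.isnan(col)]
        if len(col) >= 2:
            sem[ri] = np.std(col, ddof=1) / np.sqrt(len(col))
    return {
        "residues": residues,
        "rmsf_per_bead": rmsf_per_bead,
        "per_subunit": per_subunit,
        "mean": mean,
        "sem": sem,
        "n_frames_used": int(np.sum(good)),
        "n_frames_dropped": n_dropped,
    }


# ---------------------------------------------------------------------------
# I/O


def read_frame_table(path) -> TrajectorySlice:
    """Read a plain CSV frame table (time, chain, residue, bead, x, y, z).

    Times in microseconds, coordinates nm.  Every frame must contain
    the same beads in the same order.
    """
    import pandas as pd

    df = pd.read_csv(path)
    needed = {"time", "chain", "residue", "bead", "x", "y", "z"}
    if not needed <= set(df.columns):
        raise ValueError(f"frame table needs columns {sorted(needed)}")
    times = np.sort(df["time"].unique())
    first = df[df["time"] == times[0]].sort_values(["chain", "residue", "bead"])
    bead_res = first["residue"].to_numpy(int)
    bead_chain = first["chain"].to_numpy()
    coords = np.empty((len(times), len(first), 3))
    for i, tt in enumerate(times):
        frame = df[df["time"] == tt].sort_values(["chain", "residue", "bead"])
        if len(frame) != len(first):
            raise ValueError(f"frame at t={tt} has inconsistent beads")
        coords[i] = frame[["x", "y", "z"]].to_numpy(float)
    return TrajectorySlice(
        times=times, coords=coords, bead_residues=bead_res, bead_chains=bead_chain
    )


def load_trajectory_mda(
    topology, trajectory, selection: str = "protein", time_unit: float = 1e-6
) -> TrajectorySlice:
    """Load a standard MD trajectory (XTC/TRR/DCD + PDB/GRO) via
    MDAnalysis into a TrajectorySlice.

    ``time_unit`` converts the trajectory's time stamps (ps in
    MDAnalysis) to microseconds.  Coordinates are converted A -> nm.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(trajectory))
    group = u.select_atoms(selection)
    times = []
    frames = []
    for ts in u.trajectory:
        times.append(ts.time * time_unit)
        frames.append(group.positions / 10.0)
    return TrajectorySlice(
        times=np.array(times),
        coords=np.array(frames),
        bead_residues=group.resids.astype(int),
        bead_chains=np.array(group.segids),
    )
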