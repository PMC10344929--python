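"""Synthetic input generators with recorded ground truth.

Every analysis stage in this package has a generator here that produces
inputs of the same shape as the experimental data it emulates, together
with a truth record sufficient to predict the downstream result
analytically (or by a short brute-force computation).  All generators
are deterministic per seed.

The module also provides :func:`synthetic_ntd_sequence`, a SYNTHETIC
stand-in for a TRPV4-like N-terminal domain sequence.  It is not the
real protein sequence: it is constructed to reproduce the documented
census features this package's annotations operate on — an IDR
(residues 2-134) followed by a folded-domain region (135-382), no
lysine before residue 50 and exactly 25 lysines from 50 onward, the
KRWRR basic motif at 107-111 containing the single tryptophan (W109),
a proline-rich stretch ending at V134, and an acidic-to-basic charge
gradient along the IDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chains import Conformer, Ensemble
from .hdx import DEFAULT_TIMEPOINTS, HdxPeptide
from .membranemd import KJ_PER_MOL_NM_TO_PN, RestraintRecord, TrajectorySlice
from .saxs import ScatteringProfile, debye_profile
from .sequence import ProteinSequence
from .spectro import BindingCurve, PeakShiftPair

__all__ = [
    "synthetic_ntd_sequence",
    "synth_saxs_mixture",
    "synth_hdx_table",
    "synth_titration",
    "synth_peaklist",
    "synth_tether_traj",
    "synth_contact_traj",
    "KT_KJ_PER_MOL_310K",
]

#: Thermal energy at 310 K in kJ/mol (k_B T, used by the tether dynamics).
KT_KJ_PER_MOL_310K = 2.577


# ---------------------------------------------------------------------------
# synthetic sequence


def synthetic_ntd_sequence() -> ProteinSequence:
    """SYNTHETIC stand-in NTD sequence (residues 2-382), see module docs.

    Construction (deterministic): acidic N-terminal segment, conserved
    patch FPLSSLANLFE at 19-29, lysine-free region up to residue 49,
    25 lysines from residue 50 on (7 in the IDR including K50, K56,
    K107, K116, K122; 18 evenly spaced in the folded region), the
    KRWRR motif at 107-111 with the sole tryptophan at 109, a
    proline-rich stretch 121-134 ending in V134, and an ankyrin-like
    repeat filler for 135-382.
    """
    seq = {}

    def put(start: int, letters: str):
        for i, aa in enumerate(letters):
            seq[start + i] = aa

    put(2, "ADDESSDEELAGDDSEE")  # 2-18 acidic
    put(19, "FPLSSLANLFE")  # 19-29 conserved patch
    put(30, "DSGDLEATSDEVGSAEDLSA")  # 30-49, no Lys
    # 50-106 central region filler (basic-leaning), Lys overwritten below
    filler = "GSTNRALEDS"
    for pos in range(50, 107):
        seq[pos] = filler[(pos - 50) % len(filler)]
    put(107, "KRWRR")  # 107-111 basic motif, W109 sole Trp
    put(112, "AGRSARSGA")  # 112-120
    put(121, "AKPPPLPPVPPSPV")  # 121-134 proline-rich, ends V134
    repeat = "DLHTAARNGHLEVVQLLLDRGADVNARDSFGRT"  # ankyrin-like, no K/W/C
    for pos in range(135, 383):
        seq[pos] = repeat[(pos - 135) % len(repeat)]
    idr_lys = [50, 56, 77, 90, 116, 122]  # K107 sits in the motif
    fold_lys = list(range(140, 383, 14))[:18]
    for pos in idr_lys + fold_lys:
        seq[pos] = "K"
    residues = "".join(seq[p] for p in range(2, 383))
    out = ProteinSequence(id="synthetic-NTD", residues=residues, first_residue_number=2)
    # construction invariants
    ks = [p for p in range(2, 383) if seq[p] == "K"]
    assert min(ks) >= 50 and len(ks) == 25
    assert residues.count("W") == 1 and seq[109] == "W"
    assert seq[134] == "V"
    return out


# ---------------------------------------------------------------------------
# SAXS


def synth_saxs_mixture(
    pool,
    true_weights: Sequence[float],
    sigma_scale: float = 0.01,
    q_dependence: float = 0.0,
    seed: int = 0,
) -> tuple[ScatteringProfile, dict]:
    """Noisy SAXS curve from a known conformer mixture.

    ``pool`` is an eom.Pool (or a list of Conformers with a shared q
    grid via Ensemble); ``true_weights`` are per-member volume
    fractions summing to 1.  Noise is Gaussian with
    sigma(q) = sigma_scale * I(q) * (1 + q_dependence * q / q_max).
    Returns the profile (sigma column populated) and a truth record.
    """
    w = np.asarray(true_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if hasattr(pool, "profiles"):
        if len(w) != len(pool):
            raise ValueError("one weight per pool member required")
        q = pool.q
        I_true = w @ pool.profiles
        rg_true = float(np.sqrt(w @ pool.rg_values**2))
    else:
        raise TypeError("pool must provide precomputed profiles")
    rng = np.random.default_rng(seed)
    sigma = sigma_scale * np.abs(I_true) * (1.0 + q_dependence * q / q.max())
    sigma = np.maximum(sigma, 1e-12)
    I_noisy = I_true + rng.normal(scale=sigma)
    truth = {
        "weights": w,
        "I_true": I_true,
        "weighted_rg_rms": rg_true,
        "weighted_rg_mean": float(w @ pool.rg_values),
        "seed": seed,
    }
    return ScatteringProfile(q, I_noisy, sigma), truth


# ---------------------------------------------------------------------------
# HDX


def synth_hdx_table(
    seq: ProteinSequence,
    protection_factors: dict[int, float],
    k_int: float = 1.0,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    peptide_length: int = 9,
    peptide_step: int = 5,
    noise_pct: float = 0.0,
    seed: int = 0,
) -> tuple[list[HdxPeptide], dict]:
    """Peptide uptake table from known per-residue protection factors.

    Per-residue deuteration follows standard exchange kinetics,
    D(t) = 100 (1 - exp(-k_int t / P)) with a single intrinsic rate
    ``k_int`` (1/s) and protection factor P >= 1; peptide uptake is
    the mean over the peptide's exchange-competent residues (first
    residue and prolines excluded).  The truth record carries the
    per-residue uptake matrix and the fast/slow partition implied by
    the disorder rule evaluated directly on the per-residue kinetics.
    """
    rng = np.random.default_rng(seed)
    tps = tuple(float(t) for t in timepoints)
    first, last = seq.first_residue_number, seq.last_residue_number

    def res_uptake(pos: int) -> np.ndarray:
        P = protection_factors.get(pos, 1.0)
        if P < 1.0:
            raise ValueError("protection factors must be >= 1")
        return 100.0 * (1.0 - np.exp(-k_int * np.array(tps) / P))

    peptides = []
    start = first
    while start <= last:
        end = min(start + peptide_length - 1, last)
        sub = seq.subsequence(start, end)
        competent = [
            p for p in range(start + 1, end + 1) if seq.letter_at(p) != "P"
        ]
        if competent:
            mat = np.stack([res_uptake(p) for p in competent])
            uptake = mat.mean(axis=0)
            if noise_pct > 0:
                uptake = np.clip(uptake + rng.normal(scale=noise_pct, size=len(tps)), 0, 110)
            peptides.append(
                HdxPeptide(
                    start=start, end=end, sequence=sub.residues,
                    uptake_pct=tuple(float(u) for u in uptake), timepoints=tps,
                )
            )
        if end == last:
            break
        start += peptide_step
    truth_uptake = {
        pos: res_uptake(pos)
        for pos in range(first, last + 1)
        if seq.letter_at(pos) != "P"
    }
    truth_disordered = {}
    it = tps.index(10.0) if 10.0 in tps else 0
    for pos, row in truth_uptake.items():
        fast = row[it] > 50.0
        plateau = not np.any(np.diff(row) > 5.0)
        truth_disordered[pos] = bool(fast and plateau)
    truth = {
        "per_residue_uptake": truth_uptake,
        "disordered": truth_disordered,
        "protection_factors": dict(protection_factors),
        "k_int": k_int,
        "seed": seed,
    }
    return peptides, truth


# ---------------------------------------------------------------------------
# titrations / peak lists


def synth_titration(
    Kd: float,
    delta_max: float,
    conc_grid: Sequence[float],
    accessible_fraction: float = 0.5,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[BindingCurve, dict]:
    """Langmuir binding series with known Kd (accessible units) and
    saturation amplitude."""
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    rng = np.random.default_rng(seed)
    lipid = np.asarray(conc_grid, dtype=float)
    c = accessible_fraction * lipid
    obs = delta_max * c / (Kd + c)
    if noise > 0:
        obs = obs + rng.normal(scale=noise, size=len(obs))
    curve = BindingCurve(
        lipid_total=lipid, observable=obs, accessible_fraction=accessible_fraction
    )
    return curve, {"Kd": Kd, "delta_max": delta_max, "seed": seed}


def synth_peaklist(
    seq: ProteinSequence,
    shift_deltas: dict[int, tuple[float, float]],
    intensity_ratios: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Paired reference/perturbed peak lists with planted CSPs.

    ``shift_deltas`` maps residue -> (dH, dN) in ppm; residues not
    listed shift by zero.  ``intensity_ratios`` plants line broadening
    (I_perturbed / I_reference).  Prolines carry no amide peak and are
    skipped.  Returns ({"reference": ..., "perturbed": ...}, truth);
    each peak list maps residue -> (dH ppm, dN ppm, intensity).
    """
    for mapping in (shift_deltas, intensity_ratios or {}):
        for pos in mapping:
            if not seq.first_residue_number <= pos <= seq.last_residue_number:
                raise ValueError(f"planted residue {pos} outside sequence")
            if seq.letter_at(pos) == "P":
                raise ValueError(
                    f"residue {pos} is a proline and carries no amide peak"
                )
    rng = np.random.default_rng(seed)
    reference = {}
    perturbed = {}
    for pos in seq.residue_numbers:
        if seq.letter_at(int(pos)) == "P":
            continue
        h = rng.uniform(7.5, 8.8)
        n = rng.uniform(108.0, 128.0)
        i0 = rng.uniform(0.8, 1.2)
        dh, dn = shift_deltas.get(int(pos), (0.0, 0.0))
        ratio = 1.0 if intensity_ratios is None else intensity_ratios.get(int(pos), 1.0)
        reference[int(pos)] = (h, n, i0)
        perturbed[int(pos)] = (h + dh, n + dn, i0 * ratio)
    truth = {
        "csp": {
            pos: float(np.hypot(dh, dn / 6.5))
            for pos, (dh, dn) in shift_deltas.items()
        },
        "intensity_ratios": dict(intensity_ratios or {}),
        "seed": seed,
    }
    return {"reference": reference, "perturbed": perturbed}, truth


# ---------------------------------------------------------------------------
# tethered-chain trajectories


@dataclass(frozen=True)
class TetherSpec:
    """One restrained tether simulation: planted truth + bookkeeping."""

    adhesion_force_pn: float
    restraint_height: float  # nm
    condition: str = "synthetic"
    replicate_id: int = 0
    seed: int = 0


def _integrate_tethered(
    specs: Sequence[TetherSpec],
    chain_length: int,
    adhesion_site: int,
    restraint_k: float,
    bond_k: float,
    bond_length: float,
    gamma: float,
    kT: float,
    dt: float,
    n_steps: int,
    sample_every: int,
    equilibration_steps: int,
    keep_frames: bool,
):
    """Batched overdamped Langevin integrator for tethered chains.

    All simulations advance in lock-step on a (n_sims, n_beads, 3)
    array; each simulation has its own restraint target, planted
    adhesion force and noise stream (seeded per spec).
    """
    S = len(specs)
    n = chain_length
    if not 0 <= adhesion_site < n:
        raise ValueError("adhesion_site outside chain")
    if dt * max(bond_k, restraint_k) / gamma > 0.25:
        raise ValueError("unstable integration: reduce dt or force constants")
    heights = np.array([s.restraint_height for s in specs])
    f_adh = np.array([s.adhesion_force_pn for s in specs]) / KJ_PER_MOL_NM_TO_PN
    # one stream for the whole batch, keyed on every spec seed: batch
    # results are reproducible for a given spec list
    rng = np.random.default_rng(
        np.random.SeedSequence([int(s.seed) for s in specs])
    )
    x = np.zeros((S, n, 3))
    x[:, :, 2] = heights[:, None] - bond_length * np.arange(n)[::-1]
    noise_scale = np.sqrt(2.0 * kT * dt / gamma)
    n_samples = max((n_steps - equilibration_steps) // sample_every, 0)
    frames = np.empty((S, n_samples, n, 3)) if keep_frames else None
    times = np.empty(n_samples)
    zs = np.empty((S, n_samples))
    si = 0
    inv_g = dt / gamma
    for step in range(n_steps):
        bond = x[:, 1:] - x[:, :-1]
        blen = np.sqrt(np.einsum("sbx,sbx->sb", bond, bond))[..., None]
        fb = bond_k * (blen - bond_length) * bond / np.maximum(blen, 1e-12)
        f = np.zeros_like(x)
        f[:, :-1] += fb
        f[:, 1:] -= fb
        f[:, -1, 2] += restraint_k * (heights - x[:, -1, 2])
        f[:, adhesion_site, 2] -= f_adh
        x = x + inv_g * f + noise_scale * rng.normal(size=(S, n, 3))
        if step >= equilibration_steps and (step - equilibration_steps) % sample_every == 0:
            if keep_frames:
                frames[:, si] = x
            times[si] = step * dt
            zs[:, si] = x[:, -1, 2]
            si += 1
    return frames, times[:si], zs[:, :si]


def synth_tether_traj(
    chain_length: int = 6,
    adhesion_site: int = 3,
    adhesion_force_pn: float = 10.0,
    restraint_height: float = 5.0,
    restraint_k: float = 50.0,
    bond_k: float = 50.0,
    bond_length: float = 0.38,
    gamma: float = 1.0,
    kT: float = KT_KJ_PER_MOL_310K,
    dt: float = 4e-3,
    n_steps: int = 300_000,
    sample_every: int = 10,
    equilibration_steps: int = 30_000,
    seed: int = 0,
    replicate_id: int = 0,
    condition: str = "synthetic",
) -> tuple[TrajectorySlice, RestraintRecord, dict]:
    """Overdamped Langevin trajectory of a tethered bead-spring chain.

    The chain's last bead is harmonically restrained to
    ``restraint_height`` nm above an implicit membrane midplane at
    z = 0; one site bead experiences a planted constant downward
    adhesion force (pN), emulating membrane adhesion of a lipid-binding
    site.  At equilibrium the mean restraint force balances the planted
    force exactly (force balance on the whole chain), giving an
    analytic truth for
    :func:`idrflex.membranemd.restraint_forces` without any membrane
    physics.  Energies are kJ/mol, lengths nm; time is in reduced units
    of gamma nm^2 / (kJ/mol).
    """
    spec = TetherSpec(
        adhesion_force_pn=adhesion_force_pn, restraint_height=restraint_height,
        condition=condition, replicate_id=replicate_id, seed=seed,
    )
    frames, times, zs = _integrate_tethered(
        [spec], chain_length, adhesion_site, restraint_k, bond_k, bond_length,
        gamma, kT, dt, n_steps, sample_every, equilibration_steps, keep_frames=True,
    )
    traj = TrajectorySlice(
        times=times, coords=frames[0],
        bead_residues=np.arange(1, chain_length + 1),
        bead_chains=np.full(chain_length, "A"),
        membrane_z=np.zeros(len(times)),
    )
    record = RestraintRecord(
        target_height=restraint_height, force_constant=restraint_k,
        times=times, z=zs[0], replicate_id=replicate_id, condition=condition,
    )
    truth = {
        "adhesion_force_pn": adhesion_force_pn,
        "adhesion_site": adhesion_site,
        "restraint_height": restraint_height,
        "restraint_k": restraint_k,
        "seed": seed,
    }
    return traj, record, truth


def synth_tether_records(
    specs: Sequence[TetherSpec],
    chain_length: int = 6,
    adhesion_site: int = 3,
    restraint_k: float = 50.0,
    bond_k: float = 50.0,
    bond_length: float = 0.38,
    gamma: float = 1.0,
    kT: float = KT_KJ_PER_MOL_310K,
    dt: float = 4e-3,
    n_steps: int = 300_000,
    sample_every: int = 10,
    equilibration_steps: int = 30_000,
) -> list[RestraintRecord]:
    """Batched restrained simulations (one RestraintRecord per spec).

    All chains share the mechanical parameters; adhesion force, target
    height, condition label and seed vary per spec.  Frames are not
    retained — only the restrained-bead heights needed for force
    analysis — so large replicate sets stay cheap.
    """
    _, times, zs = _integrate_tethered(
        specs, chain_length, adhesion_site, restraint_k, bond_k, bond_length,
        gamma, kT, dt, n_steps, sample_every, equilibration_steps, keep_frames=False,
    )
    return [
        RestraintRecord(
            target_height=s.restraint_height, force_constant=restraint_k,
            times=times, z=zs[i], replicate_id=s.replicate_id,
            condition=s.condition,
        )
        for i, s in enumerate(specs)
    ]


def tether_specs_for_force_law(
    slope_pn_per_nm: float,
    offset_pn: float,
    heights: Sequence[float],
    href: float = 6.5,
    restraint_k: float = 50.0,
    n_replicates: int = 4,
    condition: str = "synthetic",
    seed0: int = 0,
) -> tuple[list[TetherSpec], dict]:
    """Specs planting a linear force law F = slope (h - href) + offset.

    The law is expressed against the *equilibrium* tether height.  At
    equilibrium the restrained bead sits F/k below its target, so the
    applied adhesion force for a target height h solves
    F = slope (h - F/k - href) + offset, i.e.
    F = (slope (h - href) + offset) / (1 + slope / (k * c)) with the
    kJ/mol/nm -> pN conversion c.  The truth record states the exact
    slope and per-height forces the analysis should recover.
    """
    c = KJ_PER_MOL_NM_TO_PN
    specs = []
    truth_forces = {}
    for hi, h in enumerate(heights):
        F = (slope_pn_per_nm * (h - href) + offset_pn) / (
            1.0 + slope_pn_per_nm / (restraint_k * c)
        )
        truth_forces[float(h)] = F
        for rep in range(n_replicates):
            specs.append(
                TetherSpec(
                    adhesion_force_pn=F, restraint_height=float(h),
                    condition=condition, replicate_id=rep,
                    seed=seed0 + 1000 * hi + rep,
                )
            )
    truth = {
        "slope_pn_per_nm": slope_pn_per_nm,
        "offset_pn": offset_pn,
        "href": href,
        "forces_by_target_height": truth_forces,
        "restraint_k": restraint_k,
    }
    return specs, truth


def synth_contact_traj(
    contact_fraction: float,
    n_frames: int = 100,
    cutoff: float = 0.6,
    n_residues: int = 3,
    contact_residue: int = 2,
    lipid_type: str = "PIP2",
    n_other_lipid: int = 4,
    seed: int = 0,
) -> tuple[TrajectorySlice, dict]:
    """Deterministic trajectory with a planted membrane-contact fraction.

    One residue bead sits inside the contact cutoff of a single lipid
    bead of type ``lipid_type`` in exactly
    ``round(contact_fraction * n_frames)`` frames and far outside it
    otherwise; the remaining residues never contact.  ``n_other_lipid``
    beads of a different type are placed near the contact residue in
    all frames to exercise lipid-type filtering.
    """
    if not 0.0 <= contact_fraction <= 1.0:
        raise ValueError("contact_fraction must lie in [0, 1]")
    n_contact = round(contact_fraction * n_frames)
    times = np.arange(n_frames, dtype=float)
    coords = np.zeros((n_frames, n_residues, 3))
    for r in range(n_residues):
        coords[:, r, 0] = 5.0 * r  # well separated along x
    coords[:, :, 2] = 5.0  # high above the membrane by default
    ci = contact_residue - 1
    coords[:n_contact, ci, 2] = 0.1  # inside cutoff of the lipid bead
    lipid = np.zeros((n_frames, 1 + n_other_lipid, 3))
    lipid[:, 0, 0] = 5.0 * ci  # the PIP2 bead under the contact residue
    for k in range(n_other_lipid):
        lipid[:, 1 + k, 0] = 5.0 * ci
        lipid[:, 1 + k, 1] = 0.3  # also within cutoff while in contact
    types = np.array([lipid_type] + ["POPC"] * n_other_lipid)
    traj = TrajectorySlice(
        times=times, coords=coords,
        bead_residues=np.arange(1, n_residues + 1),
        bead_chains=np.full(n_residues, "A"),
        membrane_z=np.zeros(n_frames),
        lipid_coords=lipid, lipid_types=types,
    )
    truth = {
        "contact_fraction": n_contact / n_frames,
        "contact_residue": contact_residue,
        "lipid_type": lipid_type,
        "cutoff": cutoff,
    }
    return traj, truth
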