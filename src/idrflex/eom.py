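"""Genetic-algorithm sub-ensemble selection against SAXS data.

A pool of dummy-residue conformers (with precomputed Debye profiles) is
searched for a small sub-ensemble whose volume-fraction weighted average
profile best fits an experimental curve.  A chromosome is a multiset of
``ensemble_size`` pool indices; repeated indices encode volume fractions
as multiplicity / ensemble size.  Fitness is the reduced chi^2 of the
weight-averaged profile against the data (with the usual free intensity
scale), so the best-ever fitness is monotone nonincreasing across
generations under elitism.

Comparing the selected Rg distribution with the pool's reveals whether
the data prefer compact states (negative mean shift), the signature of
transient intradomain contacts in disordered chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chains import ChainParams, Conformer, Ensemble, conformer_metrics, generate_conformer, grow_on_anchor
from .saxs import ScatteringProfile, chi2_reduced, cormap_test, FitQuality

__all__ = ["GAConfig", "Pool", "Selection", "build_pool", "ga_select",
           "ga_select_restarts", "rg_distribution_compare"]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the memetic genetic algorithm.

    ``local_refine`` applies exhaustive single-slot coordinate descent
    to the best-ever chromosome after the generational loop (a standard
    memetic refinement); it can only lower the fitness.
    """

    population: int = 100
    generations: int = 300
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 2
    seed: int = 0
    local_refine: bool = True
    refine_sweeps: int = 20


@dataclass
class Pool:
    """Conformer library with per-member Debye profiles and Rg values."""

    conformers: list
    profiles: np.ndarray  # (n_members, n_q)
    q: np.ndarray
    rg_values: np.ndarray

    def __post_init__(self):
        if not (
            len(self.conformers) == len(self.profiles) == len(self.rg_values)
        ):
            raise ValueError("pool member count mismatch")

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class Selection:
    member_indices: np.ndarray  # multiset into pool
    weights: np.ndarray  # per unique member, parallel to unique_indices
    unique_indices: np.ndarray
    fit: FitQuality
    rg_distribution: np.ndarray  # Rg per chromosome slot (with repeats)
    fitness_trace: np.ndarray  # best-ever chi2 per generation

    @property
    def weighted_rg_mean(self) -> float:
        return float(self.rg_distribution.mean())


def build_pool(
    n: int,
    n_residues: int,
    q_grid: np.ndarray,
    params: ChainParams | None = None,
    anchor: Conformer | None = None,
    attach_residue: int | None = None,
    seed: int = 0,
    progress: Callable[[int], None] | None = None,
) -> Pool:
    """Generate ``n`` conformers and their scattering profiles.

    Without an anchor, free chains of ``n_residues`` beads are grown;
    with an anchor, ``n_residues`` new beads are grown off
    ``attach_residue`` (prepended in numbering).  Deterministic per
    seed.  Individual growth failures are retried with fresh draws from
    the same stream; the failure count is reported on error.
    """
    from .saxs import debye_profile

    if n < 1:
        raise ValueError("pool size must be >= 1")
    params = params or ChainParams()
    rng = np.random.default_rng(seed)
    q = np.asarray(q_grid, dtype=float)
    conformers = []
    profiles = np.empty((n, len(q)))
    rgs = np.empty(n)
    failures = 0
    while len(conformers) < n:
        i = len(conformers)
        try:
            if anchor is None:
                c = generate_conformer(n_residues, params, rng)
            else:
                if attach_residue is None:
                    attach_residue = int(anchor.residue_numbers.min())
                c = grow_on_anchor(anchor, attach_residue, n_residues, params, rng)
        except Exception:
            failures += 1
            if failures > 10 * n:
                raise RuntimeError(
                    f"pool generation failed {failures} times; geometry too constrained"
                )
            continue
        conformers.append(c)
        profiles[i] = debye_profile(c, q).I
        rgs[i] = conformer_metrics(c)[0]
        if progress is not None:
            progress(i + 1)
    return Pool(conformers=conformers, profiles=profiles, q=q, rg_values=rgs)


def _population_chi2(
    pop: np.ndarray, profiles: np.ndarray, data_I: np.ndarray, w: np.ndarray, dof: int
) -> np.ndarray:
    """Vectorized reduced chi^2 (free scale) for each chromosome row."""
    mean_profiles = profiles[pop].mean(axis=1)  # (pop, n_q)
    num = mean_profiles @ (w * data_I)
    den = np.einsum("ij,ij->i", mean_profiles**2, np.broadcast_to(w, mean_profiles.shape))
    s = num / den
    resid = data_I[None, :] - s[:, None] * mean_profiles
    return (resid**2 @ w) / dof


def _coordinate_descent(
    chrom: np.ndarray,
    fit: float,
    profiles: np.ndarray,
    data_I: np.ndarray,
    w: np.ndarray,
    dof: int,
    max_sweeps: int,
) -> tuple[np.ndarray, float]:
    """Exhaustive single-slot replacement until no swap improves chi^2."""
    K = len(chrom)
    total = profiles[chrom].sum(axis=0)
    for _ in range(max_sweeps):
        improved = False
        for j in range(K):
            cand_means = (total[None, :] - profiles[chrom[j]] + profiles) / K
            num = cand_means @ (w * data_I)
            den = (cand_means**2) @ w
            s = num / den
            resid = data_I[None, :] - s[:, None] * cand_means
            chis = (resid**2 @ w) / dof
            best_i = int(np.argmin(chis))
            if chis[best_i] < fit - 1e-15:
                total = total - profiles[chrom[j]] + profiles[best_i]
                chrom[j] = best_i
                fit = float(chis[best_i])
                improved = True
        if not improved:
            break
    return chrom, fit


def ga_select(
    pool: Pool,
    data: ScatteringProfile,
    ensemble_size: int = 10,
    ga: GAConfig | None = None,
) -> Selection:
    """Select a volume-fraction weighted sub-ensemble fitting the data.

    Returns the best-ever chromosome over all generations together with
    its fit statistics and the best-fitness trace.  Deterministic per
    ``ga.seed``.
    """
    ga = ga or GAConfig()
    if len(pool) < 1:
        raise ValueError("empty pool")
    if data.sigma is None or np.any(data.sigma <= 0):
        raise ValueError("data must carry positive errors")
    if not np.array_equal(data.q, pool.q):
        I_interp = np.interp(pool.q, data.q, data.I)
        s_interp = np.interp(pool.q, data.q, data.sigma)
        data = ScatteringProfile(pool.q, I_interp, s_interp)
    rng = np.random.default_rng(ga.seed)
    n_pool = len(pool)
    K = ensemble_size
    dof = max(len(data) - 1, 1)
    w = 1.0 / data.sigma**2
    pop = rng.integers(0, n_pool, size=(ga.population, K))
    # seed half the population with homogeneous chromosomes of the
    # best-fitting single members: covers the single-conformer limit and
    # gives crossover meaningful building blocks
    single_chi = _population_chi2(
        np.arange(n_pool)[:, None], pool.profiles, data.I, w, dof
    )
    n_seed = min(ga.population // 2, n_pool)
    best_singles = np.argsort(single_chi)[:n_seed]
    pop[:n_seed] = best_singles[:, None]
    best_chrom = None
    best_fit = np.inf
    trace = np.empty(ga.generations)
    for g in range(ga.generations):
        fit = _population_chi2(pop, pool.profiles, data.I, w, dof)
        order = np.argsort(fit)
        if fit[order[0]] < best_fit:
            best_fit = float(fit[order[0]])
            best_chrom = pop[order[0]].copy()
        trace[g] = best_fit
        # next generation: elites + tournament-selected offspring
        elites = pop[order[: ga.elitism]]
        n_off = ga.population - ga.elitism
        a = rng.integers(0, ga.population, size=n_off)
        b = rng.integers(0, ga.population, size=n_off)
        parents1 = pop[np.where(fit[a] <= fit[b], a, b)]
        a = rng.integers(0, ga.population, size=n_off)
        b = rng.integers(0, ga.population, size=n_off)
        parents2 = pop[np.where(fit[a] <= fit[b], a, b)]
        do_cross = rng.random(n_off) < ga.crossover_rate
        gene_mask = rng.random((n_off, K)) < 0.5
        off = np.where(gene_mask, parents1, parents2)
        off[~do_cross] = parents1[~do_cross]
        mut = rng.random((n_off, K)) < ga.mutation_rate
        off[mut] = rng.integers(0, n_pool, size=int(mut.sum()))
        pop = np.vstack([elites, off])
    if ga.local_refine:
        # multi-start refinement: the GA optimum plus homogeneous
        # chromosomes of the best single members and of members spanning
        # the pool's Rg range (quantiles), kept if they win
        starts = [best_chrom.copy()]
        seed_ids = list(best_singles[: min(5, len(best_singles))])
        order = np.argsort(pool.rg_values)
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            seed_ids.append(order[int(frac * (n_pool - 1))])
        for idx in dict.fromkeys(int(i) for i in seed_ids):
            starts.append(np.full(K, idx, dtype=best_chrom.dtype))
        for st in starts:
            f0 = float(
                _population_chi2(st[None, :], pool.profiles, data.I, w, dof)[0]
            )
            c, f = _coordinate_descent(
                st, min(f0, np.inf), pool.profiles, data.I, w, dof, ga.refine_sweeps
            )
            if f < best_fit:
                best_chrom, best_fit = c, f
    uniq, counts = np.unique(best_chrom, return_counts=True)
    weights = counts / K
    sel_profile = ScatteringProfile(pool.q, pool.profiles[best_chrom].mean(axis=0))
    quality = cormap_test(sel_profile, data)
    return Selection(
        member_indices=best_chrom,
        weights=weights,
        unique_indices=uniq,
        fit=quality,
        rg_distribution=pool.rg_values[best_chrom],
        fitness_trace=trace,
    )


def ga_select_restarts(
    pool: Pool,
    data: ScatteringProfile,
    ensemble_size: int = 10,
    ga: GAConfig | None = None,
    n_restarts: int = 5,
) -> tuple[Selection, list[Selection]]:
    """Run the GA from ``n_restarts`` seeds; return the best selection
    (lowest chi^2) and all restart selections for stability inspection."""
    ga = ga or GAConfig()
    sels = []
    for k in range(n_restarts):
        cfg = GAConfig(
            population=ga.population, generations=ga.generations,
            crossover_rate=ga.crossover_rate, mutation_rate=ga.mutation_rate,
            elitism=ga.elitism, seed=ga.seed + 1000 * k,
        )
        sels.append(ga_select(pool, data, ensemble_size, cfg))
    best = min(sels, key=lambda s: s.fit.chi2_reduced)
    return best, sels


def rg_distribution_compare(
    sel: Selection, pool: Pool, n_bins: int = 30
) -> dict:
    """Selected-vs-pool Rg comparison.

    Returns the mean shift (selected weighted mean minus pool mean, nm;
    negative means the data prefer compaction), the Kolmogorov-Smirnov
    distance between the two distributions, and common-grid histograms.
    """
    sel_rg = sel.rg_distribution
    pool_rg = pool.rg_values
    mean_shift = float(sel_rg.mean() - pool_rg.mean())
    # weighted empirical CDF distance on the pooled support
    grid = np.sort(np.unique(np.concatenate([sel_rg, pool_rg])))
    cdf_sel = np.searchsorted(np.sort(sel_rg), grid, side="right") / len(sel_rg)
    cdf_pool = np.searchsorted(np.sort(pool_rg), grid, side="right") / len(pool_rg)
    ks = float(np.abs(cdf_sel - cdf_pool).max())
    lo = min(sel_rg.min(), pool_rg.min())
    hi = max(sel_rg.max(), pool_rg.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    h_sel, _ = np.histogram(sel_rg, bins=edges, density=True)
    h_pool, _ = np.histogram(pool_rg, bins=edges, density=True)
    return {
        "mean_shift": mean_shift,
        "ks_distance": ks,
        "bin_edges": edges,
        "selected_hist": h_sel,
        "pool_hist": h_pool,
    }
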