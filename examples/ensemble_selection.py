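"""Genetic-algorithm sub-ensemble selection against SAXS data.

Builds a 300-member pool of self-avoiding chains, synthesizes a SAXS
curve from a planted 50/50 mixture of its most compact and most
expanded members, and lets the optimizer recover the mixture.  The
pool-vs-selected Rg comparison then quantifies how strongly the data
constrain the ensemble.
"""

import numpy as np

from idrflex.eom import GAConfig, build_pool, ga_select, rg_distribution_compare
from idrflex.synthetic import synth_saxs_mixture

q = np.linspace(0.05, 2.0, 60)
pool = build_pool(n=300, n_residues=60, q_grid=q, seed=42)
i_lo = int(np.argmin(pool.rg_values))
i_hi = int(np.argmax(pool.rg_values))
print(f"pool Rg range: {pool.rg_values.min():.2f}-{pool.rg_values.max():.2f} nm")

weights = np.zeros(len(pool))
weights[i_lo] = weights[i_hi] = 0.5
data, truth = synth_saxs_mixture(pool, weights, sigma_scale=0.001, seed=2)

sel = ga_select(pool, data, ensemble_size=10, ga=GAConfig(seed=3))
for idx, w in zip(sel.unique_indices, sel.weights):
    tag = {i_lo: "planted compact", i_hi: "planted expanded"}.get(int(idx), "other")
    print(f"  member {idx:>3}: weight {w:.2f}  ({tag})")
print(f"fit: reduced chi2 = {sel.fit.chi2_reduced:.2f}, "
      f"CorMap p = {sel.fit.cormap_p:.3f}")

cmp_out = rg_distribution_compare(sel, pool)
print(f"selected-vs-pool Rg mean shift: {cmp_out['mean_shift']:+.2f} nm, "
      f"KS distance {cmp_out['ks_distance']:.2f}")
# Recovered weights of 0.5/0.5 on the planted members and chi2 ~ 1 show
# the selection is identifiable at this noise level; the mean shift
# would be negative if the data preferred compact states.
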