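"""Self-avoiding chain ensembles and crosslink validation.

Generates a pool of dummy-residue conformers for a 133-residue
disordered region, reports its size statistics, and validates two
synthetic lysine-lysine crosslinks against the ensemble's minimum
Calpha-Calpha distances (30 A is the span of a DSS crosslinker).
"""

import numpy as np

from idrflex.chains import (
    ChainParams,
    CrosslinkRecord,
    Ensemble,
    conformer_metrics,
    crosslink_satisfaction,
    filter_crosslinks,
    generate_conformer,
)

params = ChainParams()  # 0.38 nm virtual bonds, 0.4 nm excluded diameter
conformers = [generate_conformer(133, params, seed=s, first_residue_number=2)
              for s in range(200)]
rgs = [conformer_metrics(c)[0] for c in conformers]
print(f"pool of {len(conformers)} chains: mean Rg {np.mean(rgs):.2f} nm, "
      f"5-95% range {np.percentile(rgs, 5):.2f}-{np.percentile(rgs, 95):.2f} nm")

ensemble = Ensemble(conformers)
raw = [
    CrosslinkRecord(50, 116, replicate_count=3, delta_s=0.5, best_id_score=40),
    CrosslinkRecord(56, 122, replicate_count=2, delta_s=0.8, best_id_score=30),
    CrosslinkRecord(50, 122, replicate_count=1, delta_s=0.2, best_id_score=50),
]
xls = filter_crosslinks(raw)  # >= 2 replicates, deltaS < 0.95, Id >= 25
print(f"{len(xls)}/{len(raw)} crosslinks survive the identification filter")
flags, frac = crosslink_satisfaction(xls, ensemble, cutoff=30.0)
print(f"fraction satisfied at 30 A: {frac:.2f}")
# A flexible ensemble easily brings sequence-distant lysines within the
# crosslinker span in at least one conformer, so high satisfaction is
# expected; violations would indicate an over-restricted ensemble.
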