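# idrflex

Integrative ensemble analysis of intrinsically disordered regions
(IDRs) of membrane proteins, built around the workflow used to
characterize the ~130-residue N-terminal IDR of the TRPV4-class ion
channels: the IDR is represented as a conformational ensemble, pinned
down jointly by small-angle X-ray scattering (SAXS), hydrogen/deuterium
exchange mass spectrometry (HDX-MS), crosslinking mass spectrometry,
NMR/CD/fluorescence observables, and coarse-grained simulations of the
membrane-tethered chain.

For structural biologists and biophysicists who have these data types
and want the analysis layer as a reusable, tested Python library.

## What it computes

* **Conformer ensembles** (`idrflex.chains`) — self-avoiding
  dummy-residue chains (0.38 nm virtual Calpha bonds, hard excluded
  volume, Ramachandran-like angle window), optionally grown on a rigid
  folded anchor from a PDB file; per-conformer Rg/Dmax/end-to-end;
  ensemble Calpha distance maps; DSS crosslink filtering
  (>= 2 of 3 replicates, deltaS < 0.95, Id score >= 25) and validation
  against the 30 A Calpha-Calpha span.
* **SAXS** (`idrflex.saxs`) — Debye profiles I(q) = sum_ij
  sin(q r_ij)/(q r_ij); Guinier fits (ln I vs q^2, q Rg < 1.3);
  regularized indirect Fourier transform to the pair-distance
  distribution p(r) with Dmax estimation, Rg^2 = \int r^2 p dr /
  (2 \int p dr); dimensionless Kratky plots (q Rg)^2 I/I(0); reduced
  chi^2 with free intensity scale; the exact CorMap longest-run test.
* **Ensemble optimization** (`idrflex.eom`) — genetic-algorithm
  selection of a volume-fraction-weighted sub-ensemble whose averaged
  profile fits a SAXS curve, plus pool-vs-selected Rg distribution
  comparison (compaction = negative mean shift).
* **HDX-MS** (`idrflex.hdx`) — peptide-to-residue uptake projection by
  the shortest-peptide / closest-C-terminus rule, coverage fractions,
  state differences, and the fast-exchange disorder rule (>50% uptake
  at 10 s, no increment >5%).
* **Spectroscopy** (`idrflex.spectro`) — SEC Stokes radii
  (Ve = m log Rs + b), SEC-MALS mass MW = R(0)/(K c (dn/dc)^2), CD
  mean residue ellipticity, NMR chemical shift perturbations
  sqrt(dH^2 + (dN/6.5)^2), line-broadening ratios, R1/R2 exponential
  fits, hetNOE, fluorescence mean emission wavelength, Langmuir
  lipid-binding isotherms with outer-leaflet accessibility.
* **Membrane-tether mechanics** (`idrflex.membranemd`) — per-residue
  lipid contacts, harmonic-restraint force-displacement curves with
  replicate SEMs, effective force constants (slope beyond 6.5 nm), and
  RMSF along the channel principal axis.
* **Synthetic data** (`idrflex.synthetic`) — ground-truth generators
  for every stage, including an overdamped Langevin tethered-chain
  simulator whose mean restraint force has an exact force-balance
  oracle, and a clearly labelled synthetic stand-in NTD sequence.

## Worked example

`examples/` holds one short script per capability.  A condensed run:

```pycon
>>> import numpy as np
>>> from idrflex.eom import GAConfig, build_pool, ga_select
>>> from idrflex.synthetic import synth_saxs_mixture
>>> q = np.linspace(0.05, 2.0, 60)
>>> pool = build_pool(n=300, n_residues=60, q_grid=q, seed=42)
>>> w = np.zeros(len(pool)); w[[163, 247]] = 0.5   # planted 50/50 mixture
>>> data, truth = synth_saxs_mixture(pool, w, sigma_scale=0.001, seed=2)
>>> sel = ga_select(pool, data, ensemble_size=10, ga=GAConfig(seed=3))
>>> {int(i): float(w) for i, w in zip(sel.unique_indices, sel.weights)}
{163: 0.5, 247: 0.5}
>>> round(sel.fit.chi2_reduced, 2)
1.01
```

The optimizer recovers the planted two-conformer mixture with the
correct 0.5/0.5 volume fractions, and the reduced chi^2 of ~1 says the
selected ensemble reproduces the synthetic scattering curve to within
its noise.  `examples/saxs_analysis.py` prints the matching single-
particle chain — for an analytic 3 nm sphere: Guinier Rg 2.36 nm, p(r)
Rg 2.32 nm and Dmax 5.8 nm against the exact 2.32/6.0 nm, and a
dimensionless Kratky peak at q Rg = 1.6 of height 1.0, the globular
signature (a disordered chain instead plateaus near 2).

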