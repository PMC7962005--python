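# trpscope

Tryptophan microenvironment analysis for multi-fluorophore proteins:
steady-state emission processing, PARAFAC decomposition of
total-synchronous-fluorescence (TSFS) cubes, multi-channel TCSPC
lifetime fitting, and per-tryptophan structural/electrostatic
descriptors — with a synthetic-data module that generates every input
with known ground truth.

## The problem

The intrinsic fluorescence of a protein with several tryptophans is a
blend of emitters whose band positions and decay times report on each
residue's local environment: solvent exposure, packing density and the
local electrostatic potential. Untangling that blend requires three
coordinated analyses, each implemented here as a library module:

* **Steady-state spectra** (`trpscope.steady_state`) — blank
  subtraction, inner-filter correction `G = 10^((ΔA_exc + ΔA_em)/2)`,
  peak normalisation `I_norm(λ) = I(λ)/I_max`, normalised difference
  spectra and maximum/shoulder location.
* **Multi-dimensional fluorescence** (`trpscope.mdf`) — TSFS cubes
  (sample × λ_exc × Δλ) re-laid onto the trilinear t-EEM grid
  (λ_em = λ_exc + Δλ), scatter-corrected and smoothed, then factored by
  nonnegative PARAFAC: `X ≈ Σ_k score_k ⊗ exc_k ⊗ em_k`, with the
  core-consistency (CONCORDIA) diagnostic guiding the number of
  components K.
* **Time-resolved decays** (`trpscope.tcspc`) — per-channel photon
  histograms fitted with 1–3 exponentials reconvolved with the IRF,
  Poisson-weighted, selected by reduced χ²; intensity fractions
  `a_n = α_n τ_n / Σ α_m τ_m` and the mean lifetime
  `τ_av = Σ (a_n/100) τ_n`.
* **Structure descriptors** (`trpscope.descriptors`,
  `trpscope.potential`) — for each tryptophan's indole ring: solvent
  accessibility Acc (Shrake–Rupley, GETAREA-style scale / 1.5), packing
  density Den2 (heavy atoms within 7.5 Å of the ring), the
  electrostatic potential at the benzene and pyrrole ring centroids
  sampled from an OpenDX grid, its change Δ = EP_pyrrole − EP_benzene
  along the indole long axis, and empirical spectral classes
  (A/S/I/I-II/II/III). Synthetic potential grids use screened-Coulomb
  (Debye–Hückel) superposition; real solver output (APBS `.dx`) is a
  first-class input.
* **Photophysics** (`trpscope.photophysics`) — the electron-transfer
  rate law `k_ET = k_0 exp(−β(R − R_0))` and the lifetime decomposition
  `1/τ = k_r + k_isc + k_sq + k_pt + k_ET` connecting descriptors to
  decay times.

`trpscope.synthetic` generates all inputs (fluorophore banks, TSFS
cubes, TCSPC decays, toy structures with geometrically correct indole
rings, potential grids) from explicit seeds, and `trpscope.pipeline` /
the `trpscope` CLI orchestrate full runs.

## Worked example

```python
import numpy as np
from trpscope import synthetic as syn, mdf, tcspc

# a 20-sample TSFS cube of two Trp emitters (em. maxima 330/362 nm)
rng = np.random.default_rng(0)
bank = syn.default_trp_bank()
scores = rng.uniform(0.5, 2.0, (20, 2))
cube = syn.simulate_tsfs(bank, scores, noise_sd=0.02, seed=1)

teem = mdf.preprocess_teem(mdf.tsfs_to_teem(cube))
sel = mdf.select_n_components(teem, k_max=3, n_starts=3, seed=0)
print(sel["diagnostics"].to_string(index=False))
print(mdf.summarize_components(sel["model"]).to_string(index=False))

out = tcspc.weighted_lifetimes((1.32, 5.5), fractions=(86.0, 14.5))
print(f"tau_av = {out['tau_av']:.4f} ns")
```

prints

```
 K  core_consistency  residual_fraction  converged
 1        100.000000           0.011371       True
 2         99.522524           0.000296       True
 3       -358.996014           0.000294       True
 component  exc_max  em_max  score_share
         1    282.0   330.0     0.563381
         2    284.0   362.0     0.436619
tau_av = 1.9327 ns
```

Two components are supported (core consistency collapses at K=3), and
their recovered excitation/emission maxima match the generator's ground
truth exactly on the 2 nm grid. The last line is the intensity-weighted
mean lifetime of a two-component decay with lifetimes 1.32/5.5 ns and
intensity fractions 86/14.5%.

A full synthetic run (simulate → steady-state → PARAFAC → TCSPC →
descriptors → report):

```sh
trpscope run --seed 1 --outdir demo_run
```

which writes descriptor and lifetime report tables plus a manifest of
all derived seeds.

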