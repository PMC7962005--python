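# Methods

This note records the models, numerical choices and limitations behind
each module, in the order data flows through the pipeline.

## Synthetic data: what it emulates, and what it does not

No raw measurement ships with this package, so `trpscope.synthetic`
generates every input with known ground truth.

**Fluorophore bank.** The default bank holds two emitters standing in
for the two tryptophan emission classes of a multi-Trp protein: a
"blue" component (excitation max 282 nm, emission max 330 nm) for
buried residues and a "red" component (284/362 nm) for the anomalous
red-shifted emitter. Band profiles are Gaussian in wavelength by
default (σ 9 nm excitation; 22/26 nm emission, giving realistic
~55 nm FWHM protein Trp bands); a log-normal shape (Gaussian in
log-wavelength, heavier red tail) is available for realism. Profiles
are peak-normalised to 1, so mixing weights carry all magnitude.

**TSFS cubes.** A cube value at (sample s, λ_exc, Δλ) is the exact
multilinear mixture Σ_k score[s,k]·exc_k(λ_exc)·em_k(λ_exc+Δλ), plus an
optional second-order-scatter ridge — a Gaussian cross-section of
configurable width (default 5 nm) centred on λ_em = 2λ_exc, amplitude
20% of the signal maximum unless given — plus additive Gaussian noise.
The default grids are excitation 260–320 nm and offsets 20–160 nm in
2 nm steps (S × 31 × 71). What is *not* emulated: polarisation,
detector nonlinearity, Raman structure beyond a flat blank, and
wavelength-dependent instrument response. Passing tests therefore show
the estimators recover multilinear structure under additive noise, not
that they are robust to every instrumental artefact of real cubes.

**TCSPC decays.** The expectation curve is Σ α_n exp(−t/τ_n) convolved
with a Gaussian IRF (default FWHM 0.5 ns — a stand-in; real instrument
IRFs are asymmetric), scaled so its maximum equals `peak_counts`
(default 20 000, the usual stopping criterion), then Poisson-sampled
per bin. Defaults: 1024 bins over 25 ns; 16 emission channels of
12.5 nm starting at 300 nm. No afterpulsing or pile-up; a constant
background is optional.

**Toy structures.** Tryptophans are built from an ideal planar indole:
a benzene hexagon and pyrrole pentagon with 1.40 Å bonds sharing the
CE2–CD2 edge, giving a benzene→pyrrole centroid separation of 2.18 Å.
All nine indole heavy atoms (CG, CD1, NE1, CE2, CD2, CE3, CZ2, CZ3,
CH2) carry correct names so that descriptor code paths are exercised
exactly as on real structures; rings are placed with random rigid-body
transforms. Decoy atoms with random charges (±0.5 e) and radii
(1.5–1.9 Å) provide neighbours for Den2/Acc. These are *not*
force-field geometries; only the indole moiety is structurally
faithful.

All generators are bit-reproducible given their parameters and an
explicit integer seed.

## Steady-state processing

Correction order is: blank subtraction, inner-filter multiplication by
G = 10^((ΔA_exc+ΔA_em)/2), then normalisation — correction before
normalisation, since G is intensity-scale-dependent. Negative
intensities after blank subtraction are clipped at zero (they carry no
physical meaning at this SNR). Spectra on slightly different grids
(step difference ≤ 1 nm) are linearly resampled; a coarser mismatch is
an error. Difference spectra require both inputs normalised, matching
the standard workflow for comparing band shapes across variants.

Band location: candidate centres are local minima of the
Savitzky–Golay-smoothed second derivative (window 7, order 2 by
default). A candidate within two grid points of a local maximum of the
smoothed intensity is reported as a maximum; any other curvature dip
deeper than `shoulder_sensitivity` (default 1%) of the strongest dip is
a shoulder. This is a deterministic stand-in for identification by eye;
the sensitivity is exposed because shoulder prominence varies.

## TSFS → t-EEM and PARAFAC

Each TSFS datum at (λ_exc, Δλ) belongs at emission wavelength
λ_em = λ_exc + Δλ. Per excitation row the data are linearly
interpolated onto a common emission grid; grid cells outside the
measured offset span form a missing-value mask. The mask is part of the
data structure and every downstream fit honours it.

Pre-processing: blank-cube subtraction; second-order scatter is removed
by replacing cells within ±10 nm (default) of λ_em = 2λ_exc with linear
interpolation along the emission axis from the flanking signal; each
emission row is then Savitzky–Golay smoothed (window 7, order 2
defaults — the window is exact on polynomials up to the order, so
smooth bands are not distorted).

The PARAFAC model X ≈ Σ_k a_k ⊗ b_k ⊗ c_k is fitted by alternating
least squares with HALS (column-wise) updates under nonnegativity.
Missing cells are handled EM-style: each sweep refills them from the
current model, which maximises the observed-data least-squares
objective with mask weights 0 — masked values never influence the
result (perturbing them leaves the fit bit-identical). Initialisation
is random nonnegative; the best of `n_starts` (default 10) by observed
residual wins. Convergence: the change in the residual *fraction*
(observed-cell SSE over observed-cell sum of squares) falls below
`tol = 1e-8`, or 2000 iterations — non-convergence is flagged on the
result, not raised. Scale and permutation indeterminacy are resolved by
peak-normalising loadings (magnitudes absorbed into scores) and sorting
components by ascending emission-maximum.

Core consistency (CONCORDIA) is 100·(1 − ‖G−T‖²/‖T‖²) where G is the
least-squares Tucker core given the fitted loadings (mode-wise
pseudoinverses, masked cells model-filled) and T the superdiagonal of
ones. For K=1 it is exactly 100 at any ALS stationary point; for an
overfactored model it collapses, usually far below zero. Component
count selection takes the largest K whose core consistency stays above
a threshold (default 90%) *and* whose residual improves on K−1 by at
least 5% relative; a chosen model explaining less than half the
variance raises a `no_structure` warning.

The recovery study (`trpscope.studies.parafac_recovery_study`) runs
20-sample cubes at SNR 50 over a seed set; across all tested seeds the
recovered emission maxima sit within one 2 nm grid step of ground truth
and K=2 core consistency stays above 95% while K=3 is strictly lower.

## TCSPC fitting

The expected curve is the multi-exponential convolved with the sampled
IRF. The convolution is evaluated on an 8× oversampled internal grid
(FFT convolution, then decimation to bin centers) because the decay's
kink at time zero otherwise biases the rising edge by ~2% of peak;
against a 10×-oversampled brute-force convolution the model agrees to
<0.1% of peak.

Fitting is weighted least squares with Neyman weights 1/max(counts,1),
over a window starting where the rising edge reaches 1% of peak. The
model is linear in the amplitudes and background, so these are solved
by weighted nonnegative least squares inside the residual and the
nonlinear search runs over log-lifetimes only (variable projection);
multi-start initial lifetimes are seed-controlled perturbations of a
log-spaced base. Two lifetimes collapsing within 1%, or a vanishing
amplitude, mark the fit degenerate and the component count is reduced.

Model selection adds components while the reduced χ² improves by more
than 10% (relative), reporting every candidate χ². At 20k peak counts a
correct two-component model fits with χ²_red ≈ 0.93–1.16 across seeds,
consistent with the 1–1.6 range expected for well-measured curves. A
three-component truth whose two long lifetimes differ by only ~10%
(6.0 vs 6.6 ns) is selected as two components at low counts — the
expected, documented behaviour of χ²-based selection near
identifiability limits.

Reported fractions are intensity fractions a_n = α_n τ_n/Σ α_m τ_m
(the convention of standard decay-analysis software), and
τ_av = Σ (a_n/100) τ_n. When printed-style fractions are supplied they
are used exactly as given, without renormalising to 100 — this
reproduces published table arithmetic; rows where the published
rounding breaks the identity are left as they are rather than forced.

## Electrostatics

Synthetic potentials are screened-Coulomb superpositions
φ(r) = Σ q_i·l_B·e^(−κr_i)/r_i in kT/e, with the Bjerrum length l_B
(~7.1 Å in water at 298.15 K) and Debye screening κ from the standard
closed form (1/κ ≈ 7.86 Å at 0.15 M monovalent salt). This uses a
single uniform solvent dielectric: it is a desk-scale stand-in with the
correct length scales, superposition structure and units, **not** a
two-dielectric Poisson–Boltzmann solution; grids from a real solver are
read from OpenDX and treated identically. Grid nodes coinciding with a
charge are filled from the nearest clean node and flagged — never
infinities. Sampling is trilinear (exact at nodes and on linear
fields; second-order convergent). The OpenDX dialect written matches
solver output: `gridpositions` header, z-fastest data, three values per
line, 6-significant-digit round trip.

## Descriptors

* **Geometry** — benzene centroid over {CD2, CE2, CE3, CZ2, CZ3, CH2},
  pyrrole centroid over {CG, CD1, NE1, CE2, CD2}; the fused-edge atoms
  CE2/CD2 deliberately enter both. The long axis is the unit vector
  benzene→pyrrole.
* **Δ** — potential sampled at the two ring centroids (no out-of-plane
  offset), Δ = EP_pyrrole − EP_benzene; positive means the potential
  rises along the axis. Antisymmetric under exchanging ring roles.
* **Den2** — heavy atoms of other residues (ligands included, waters
  excluded by default, hydrogens never) whose minimum distance to any
  of the nine indole heavy atoms is < 7.5 Å. "Distance to the ring" is
  taken as nearest-ring-atom; a brute-force pair loop is the test
  oracle.
* **Acc** — Shrake–Rupley SASA (via biotite, probe 1.4 Å, radii from
  the PQR when present, else a Bondi-style table) of the side-chain
  atoms, as a percentage of a free side-chain reference surface
  (255 Å²), divided by 1.5 to land on the empirical classification
  scale.
* **Classes** — thresholds calibrated to reproduce published
  descriptor-to-class labellings: Acc — S < 2.0 ≤ I < 7.4 ≤ I/II
  < 10.0 ≤ II < 20.0 ≤ III; Den2 — S ≥ 140 > I ≥ 125 > I/II ≥ 121 > II,
  with III below 90 as an extrapolated boundary. The class-A boundary
  is not reachable from these descriptors alone and is not assigned.
  The original numeric cut-offs of the classification literature are
  not published; these calibrated thresholds are a design choice and
  are documented as such.

## Pipeline and reproducibility

One top-level seed is expanded per stage via
`numpy.random.SeedSequence(seed).generate_state`, so toggling one stage
never shifts another's randomness; the manifest records config, derived
seeds and timings. Identical config + seed gives bit-identical outputs.
Report tables print the potential pair as "benzene → pyrrole" and Δ
with an explicit sign.

Default problem sizes (20-sample cubes, 1024-bin decays, 10–20 seed
recovery studies, 50-structure oracle sets) were chosen so the full
validation suite completes in a couple of minutes on one CPU while
keeping every estimator in its well-conditioned regime.

## Known limitations

* The PARAFAC missing-data scheme (EM refill) converges slowly on
  heavily masked noiseless cubes; residuals reach ~1e−7 rather than
  machine precision there.
* The uniform-dielectric synthetic potential cannot reproduce the
  dielectric-boundary effects of real protein electrostatics; absolute
  synthetic EP values are illustrative, only the machinery (grids,
  sampling, Δ) transfers.
* Acc depends on the side-chain reference surface constant; it is a
  ratio scale, not an absolute SASA.
* Decay model selection near lifetime-identifiability limits is
  count-limited by design; no lifetime-distribution models are
  offered.
* Global (linked-lifetime) analysis across emission channels and
  time-resolved anisotropy are out of scope.
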