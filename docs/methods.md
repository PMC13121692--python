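# Methods

This note records the models implemented in `acudyn`, the estimators and
defaults chosen where several reasonable options exist, and what the
synthetic-data generators do and do not emulate.

## Order parameters and free-energy surfaces

The AcuB dimer's conformational state is summarised by two centre-of-mass
(COM) distances per frame:

* **opening** — between the N-terminal CBS modules (residues 1–82) of the
  two monomers; reports the transverse opening of the scissor-shaped
  dimer.
* **jacking** — between the ACT domain (residues 135–214) and the
  Bateman-domain region (residues 1–134) of a monomer; reports
  longitudinal extension (ACT detachment).

COMs are mass-weighted by default (`mass_mode="atomic"`, standard atomic
weights via gemmi; unknown elements fall back to unit mass with a
warning).  Geometric centres are available with `mass_mode="unit"`.
Jacking is computed per monomer and aggregated; the default is the
**maximum** over the two monomers, because detachment of either ACT
domain is the signature of the extended state and a mean would dilute a
one-sided excursion.  `mean` and `per-monomer` are exposed.

The joint distribution is binned (default 60×60 over the data range
padded 2%) and converted to a free-energy surface by Boltzmann
inversion, ΔG = −RT·ln(P/max P), with R = 1.987204×10⁻³ kcal/(mol·K) and
T = 310 K (the simulation base temperature), i.e. RT ≈ 0.616 kcal/mol.
ΔG depends only on P/max(P), so the modal bin is exactly 0 and the
surface is invariant to rescaling of P.  Empty bins are *masked* as
undefined rather than set to 0 or an infinite sentinel; this keeps the
grid safe for downstream arithmetic.

## Basin clustering

Clustering operates on the raw per-frame (opening, jacking) points, not
on the binned surface: the points carry the full sample density, and
density clustering on a histogram would conflate bin size with density.
Both axes are standardised to unit variance first so that the two
distances contribute equally.

OPTICS (scikit-learn) computes the density ordering; clusters are
extracted either with the ξ steepness method (default ξ = 0.05,
min_samples = 50) or with a flat eps cut, which reproduces DBSCAN
core-point labelling at the same eps/min_samples.  Border points may
differ from a direct DBSCAN run — they are order-dependent in both
algorithms — so equivalence is defined (and tested) on core points.

For quantitative population recovery the eps-cut extraction with
eps = 0.6 (standardised units) is used: a flat density threshold assigns
cluster membership out to the basin edges, whereas ξ extraction trims
cluster boundaries and biases populations low.  Populations are cluster
sizes divided by total frames; noise points are excluded, so fractions
sum to ≤ 1.

Basins are categorised from their centroids: *extended* when the jacking
centroid exceeds its threshold, otherwise *closed/compact* vs
*open/compact* split on the opening centroid.  Thresholds default to the
medians of the basin centroids (data-driven) and can be overridden with
absolute values in Å; a centroid exactly on a threshold falls in the
lower category.

## Binding-stability RMSD and decorrelation

Stability of AcuC on the AcuB dimer is measured per frame: Kabsch-fit
the non-hydrogen atoms of both AcuB chains onto the first frame, apply
that rigid transform to the whole frame, and compute the unweighted RMSD
of the AcuC chains against the reference.  Larger values mean weaker
binding or increased flexibility of the bound partner.

Merged replica-exchange ensembles are temporally correlated, so the RMSD
series is decorrelated before hypothesis testing.  The sample
autocorrelation function ρ(t) (mean-removed, FFT-based) gives the
integrated autocorrelation time

    τ = 1 + 2·Σ_{t=1..M} ρ(t),

truncated at the lag before the first non-positive ρ(t)
(initial-positive-sequence rule: simple and conservative; Sokal's
self-consistent window, M ≥ 5τ, is available via `method="sokal"`).
τ is clipped to ≥ 1 and each series is subsampled every ceil(τ) frames
starting at frame 0 (deterministic phase).  Groups of decorrelated
values are compared with an ordinary (not Welch) one-way ANOVA and
Tukey's HSD studentized-range test; pairwise significance is annotated
with the standard star thresholds (0.05/0.01/0.001/0.0001).

Striding by ceil(τ) leaves a small residual lag-1 correlation
(φ^ceil(τ) ≈ 0.13 for an AR(1) process with φ = 0.9), so the realised
false-positive rate sits slightly above the nominal 0.05 — about 0.07 on
10,000-frame null ensembles — versus above 0.6 without decorrelation.
That contrast is the reason the subsampling step exists; exact
nominal-level inference would require block bootstrap or stride
inflation, both out of scope.

Convergence is checked with a centred 500-frame running mean of the RMSD
series; the verdict is the least-squares slope of that running mean over
the last half of the series, compared against a tolerance of
10⁻⁴ Å/frame (well above the sampling noise of a stationary 10⁴-frame
series, well below drifts of practical concern, e.g. 10⁻³ Å/frame).

## Superposition and structure comparison

Superposition is Kabsch via SVD of the weighted covariance matrix, with
the smallest singular direction sign-corrected so only proper rotations
(det = +1) are returned; ≥ 3 non-collinear pairs are required.  Crystal
comparisons use an explicit fit region (Cα of Bateman residues 1–132)
with a user-supplied chain mapping rather than secondary-structure
matching: the fit region is stated by the experiment, which makes the
graph-matching machinery unnecessary.  Displacements of reported atoms
(e.g. the His31 Cα) are measured after a single rigid fit, without
re-fitting the reported region.

The two adenine-nucleotide sites of a Bateman domain are distinguished
by which backbone groups hydrogen-bond the adenine N6/N1 edge: Ile13 and
His35 backbone for type I, Cys106 and Ile84 backbone for type II
(GsAcuB numbering; residue sets and the 3.6 Å contact cutoff are
configurable).  Deposited-entry chain labels for "monomer A/B" are not
assumed; comparisons scan both chain mappings.

## Assay models

* **Nucleotide loading** — c(protein) = (A280ᵇᵉᶠᵒʳᵉ − A280ᵃᶠᵗᵉʳ)/ε_protein,
  c(nucleotide) = A260ᵃᶠᵗᵉʳ/ε_nucleotide, loading % = 100·c(nuc)/c(prot).
  Protein ε defaults: BsAcuB 8730 (an alternative printed value is 8480;
  both accepted, the tabulated value is the default), GsAcuB 9970,
  GsAcuB H87W 15470, BsAcuC 78520, GsAcuC 80800 M⁻¹cm⁻¹.  The adenine
  ε₂₆₀ used experimentally is not published; the package defaults to the
  literature value 15,400 M⁻¹cm⁻¹ and treats it as a
  required-to-confirm setting for quantitative loading numbers.
* **HPLC peak ratios** — trapezoid areas over user-specified elution
  windows above a straight-line baseline drawn between window endpoints;
  negative net areas are clipped to 0 before normalising to 100%.
* **Dose-response IC50** — four-parameter logistic with the Hill slope
  fixed at −1 and exponent (log₁₀IC50 − log₁₀c)·HillSlope.  Raw
  fluorescence is min–max normalised before fitting (the instrument
  protocol's variant, which keeps the additive minimum outside the
  ratio, is implemented for reproduction; the offset is absorbed by the
  fitted `minimum` either way).  The least squares are weighted
  proportionally to the raw signal, the usual error model for
  fluorescence intensities.  The sigmoid is rejected in favour of a
  linear-trend fallback when the optimiser fails, the fitted IC50 falls
  more than two decades outside the measured range, or the fitted
  amplitude does not exceed 4× the residual RMS (a flat series can
  otherwise "converge" to a spurious transition).
* **Melting temperatures** — first derivative of the Em350/Em330 ratio
  via a Savitzky–Golay filter (9-point window, order 3, on a uniform
  resampled grid); Tm values are parabolic-interpolated local extrema of
  the derivative with prominence ≥ 20% of the largest |d ratio/dT|,
  reported largest first.  A pure baseline yields no transition.
* **Non-additivity interaction test** — for non-interacting components
  the intensities and their temperature derivatives are additive, so the
  mixture derivative is regressed on the component derivatives; the RMS
  misfit is compared against 3× the high-frequency noise RMS estimated
  from the first 10 °C of the mixture derivative (no instrument
  threshold is published, so the verdict is noise-scaled).  Collinear
  component derivatives leave only a+b identifiable and are flagged.
* **SEC calibration** — Kav = (Ve − V0)/(Vc − V0) regressed log-linearly
  against MW.  Stoichiometry inference enumerates integer compositions
  (0–4 copies per species, at least one subunit) and minimises
  |Σ nᵢMᵢ − MW|, breaking ties toward fewer subunits.  With the
  published monomer masses (BsAcuB 25,405 Da, BsAcuC 44,272 Da) the
  observed complex mass of 139,354 Da resolves to the 2:2
  heterotetramer, 2·25,405 + 2·44,272 = 139,354 Da.

## Synthetic-data generators

The generators define the study conditions for all pipeline tests.

**Dimer ensembles** use two 214-residue pseudo-monomers, one pseudo-atom
per residue, built from rigid Bateman (1–134) and ACT (135–214) blocks.
Per frame a hidden state is drawn from a Markov chain and a target
(opening, jacking) pair from that state's Gaussian with AR(1) temporal
smoothing (φ = 0.8); blocks are rigidly translated so the realised COM
distances equal the targets to machine precision, and the same jacking
is planted on both monomers so any aggregation rule recovers it.  The
default mixture has three states — closed/compact (20, 14) Å dominant at
0.6, open/compact (32, 14) Å at 0.3, extended (22, 26) Å at 0.1, unit
variances — i.e. ≥ 8 Å separation on the discriminating axis, mirroring
well-resolved basins.  The transition matrix is
(1−α)·I + α·1πᵀ with mixing α = 0.4, whose stationary distribution is
exactly the stated populations; α sets dwell times of a few saved frames,
appropriate for merged replica-exchange ensembles in which successive
stored frames are only weakly coupled.

**Bound-complex ensembles** hold the AcuB chains internally rigid and
displace the AcuC chains along a fixed axis by a stationary AR(1) series
(φ = 0.9) of condition-dependent σ — apo 3.0 Å, AMP 0.75 Å, AMP/ADP
1.0 Å, ATP 1.5 Å by default, encoding "nucleotide-free binds loosely,
AMP most tightly".  Every frame also receives a random global rigid
rotation+translation that reference alignment must remove; the planted
|d(t)| is then exactly the aligned RMSD, which validates the whole
alignment-and-measure chain.

**Assay tables** are drawn from the corresponding forward models
(logistic dose-response with multiplicative noise, logistic melt curves
on sloped baselines, Gaussian chromatogram peaks, an exact log-linear
Kav law).  Generator settings reuse the experimentally observed values —
IC50 38 nM, Tm 68 °C, 29% loading, 99:1 AMP:ADP — so round-trip tests
exercise realistic magnitudes.

What the generators deliberately do **not** emulate: atomic detail and
side chains, internal-domain deformation (blocks are rigid, so order
parameters are exact rather than estimated), replica-exchange
thermodynamics and reweighting, state-dependent kinetics beyond a single
mixing rate, instrument drift and outliers in assay traces.  Passing
tests therefore demonstrate the correctness of the estimators and
pipelines under known ground truth — not the physics of real ensembles.
All generators are deterministic per (spec, seed); the package-wide
default seed is 20260424.

## Problem sizes and reproducibility

Study-scale defaults: population-recovery runs use 20,000 frames
(5 seeds in the test suite); IAT validation uses 10⁵-frame AR(1) series;
the false-positive-rate simulation uses 500 replicate pairs of
10,000-frame null ensembles; IC50 noise recovery uses 100 seeds at 5%
multiplicative noise.  `scripts/acceptance.py` recomputes all headline
quantities from a single command-line seed; child seeds are spawned via
`numpy.random.SeedSequence` and stay below 2³¹.

## Known limitations

* The crystal-structure comparison path is fully implemented but its
  reference checks require the deposited entries (9SAV, 9SAW, 9S52 and
  related) to be supplied locally; they are not redistributable here.
* ceil(τ)-stride subsampling leaves a small residual correlation (see
  above); reported p-values on strongly correlated ensembles are mildly
  anti-conservative.
* The eps-cut population workflow assumes basins that are separated at a
  common density level; strongly overlapping basins would require
  model-based (e.g. mixture) assignment instead.
* The literal instrument normalisation of fluorescence (minimum added
  outside the ratio) is retained only for reproduction; fits use plain
  min–max scaling.
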