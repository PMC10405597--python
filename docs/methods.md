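# Methods

## Scope and model

`saxsensemble` models a flexible protein in solution as a finite weighted
ensemble of rigid conformers. Three assumptions define the method:

1. **Additivity.** The solution scatters as the population-weighted average
   of the conformers' profiles: I(q) = Σ f_i I_i(q) and likewise for P(r).
   This holds exactly for dilute, non-interacting particles.
2. **Rigid domains, flexible linkers.** Conformational variability is
   confined to user-declared (or confidence-suggested) backbone segments;
   everything else moves as a rigid body. Per-residue confidence (pLDDT,
   read from the B-factor column) is the default flexibility cue: runs of
   at least `min_length` residues below `confidence_threshold` (default 60)
   are suggested, but an explicit segment list always overrides.
3. **Dry-structure scattering.** P(r) and I(q) are computed on the bare
   structure with solvent handled only through the displaced-volume term
   b0 = 10 (r/1.93 Å)³ per atomic group. No hydration layer is modelled.
   For multi-domain proteins the hydration contribution shifts P(r) by
   about one bin; it is deliberately out of scope, and ensembles selected
   here should be re-scored with a hydration-aware intensity calculator
   when absolute χ² against wide-q data matters.

## Scattering factors

Atomic groups follow a united-atom convention: implicit hydrogens add
their electrons to the parent heavy atom (predicted models carry no H).
The shipped table (`data/scattering_groups.tsv`, one row per
residue/atom with electrons and group radius) uses neutral-atom electron
counting and van-der-Waals-like group radii (bare C 1.72 Å … CH3 2.00 Å,
N 1.55–1.70 Å, O 1.52/1.54 Å, S 1.80/1.85 Å). These radii enter both the
b0 term and the steric-clash criterion. The table is a versioned resource;
alternative tables can be passed to `assign_scattering_factors`.

## P(r), I(q) and their consistency

Distances are binned as floor(r/Δr) with Δr = 1 Å by default; bin centers
are reported at (k + ½)Δr and `dmax` is the largest inter-atomic distance.
Self terms (i = j) are excluded from P(r) — keeping P(0) = 0 as indirect
transform conventions assume — and carried separately so that

    I(q) = self_term + Σ_k p_k sin(q r_k)/(q r_k)

reproduces the Debye sum. **Quadrature choice:** the sinc kernel is
evaluated at each bin's contrast-weighted mean distance rather than the
bin center. This makes the single-distance case exact and keeps the
histogram route within ~0.05% of the direct Debye sum at 0.1 Å bins for
q ≤ 0.5 Å⁻¹; bin-center evaluation plateaus near 1% and degrades sharply
near intensity minima of dumbbell-like shapes. The histogram itself is
unchanged. The same mean distances are used for the P(r) second-moment Rg,
whose normalization includes the self pairs (Σ_ij w_i w_j r_ij² =
2 (Σw)² Rg²), so real-space and coordinate Rg agree to well under half a
bin even for models with few atoms.

## Monte Carlo conformer sampling

Each trial perturbs one backbone dihedral — φ (N–CA) or ψ (CA–C) for
all-atom chains, the CA–CA pseudo-dihedral for bead chains — of a residue
drawn uniformly from the flexible segments, by a uniform angle in
±`max_step_deg` (default 30°), rotating all atoms C-terminal of the bond
(the N-terminal part anchors the frame). A trial is accepted iff clash-free,
and the chain continues from the accepted conformer. A clash is a heavy-atom
pair, excluding 1-2 (bonded) and 1-3 (angle) neighbours, closer than
`overlap_fraction` × (r_i + r_j) with `overlap_fraction` = 0.8 — united-atom
radii are inflated relative to van der Waals, so a full-sum criterion would
reject valid packing. There is no energy function and no Ramachandran
filter: clash rejection is the only acceptance criterion, a documented
simplification relative to torsion samplers that restrict moves to allowed
Ramachandran regions. Runs are bit-reproducible from the seed.

Sub-selection keeps the last conformer of each complete block of `stride`
accepted conformers (floor(n/stride) representatives; 15 661 at stride 9
gives 1 740). Representativeness is checked by comparing density-normalized
Rg histograms of the subset and the full pool.

## Experimental-data analysis

**Guinier.** Least squares on (q², ln I) over the window starting after
`n_skip_low_q` points and extending while qRg ≤ `max_qrg`; since Rg is
unknown a priori the window is iterated to self-consistency (a 2-cycle
settles on the smaller window; 50-iteration cap). The fit is unweighted,
so ideal Guinier-law data is recovered to machine precision.

**Indirect Fourier transform.** P(r) is parameterized as a histogram on a
uniform 1 Å grid over [0, dmax] with P(0) = P(dmax) = 0, solved by
σ-weighted linear least squares with a second-difference (curvature)
penalty α, under non-negativity by default (solved as a stacked NNLS).
α defaults to the discrepancy principle: the largest value on a 33-point
log scan (anchored to (σ/I)² so the scan is scale-invariant) whose
regularized fit keeps mean squared weighted residual ≤ 1 — i.e. the
smoothest P(r) consistent with the data. Per-bin errors are estimated the
way indirect-transform programs do, by repeating the inversion on
noise-resampled copies of the data (16 samples by default, seeded).
This is a histogram-Tikhonov engine, not a reimplementation of any
specific program; the transform engine is treated as interchangeable.

**dmax selection.** Candidates on a 2 Å grid are each solved twice, with
and without the P(dmax) = 0 endpoint constraint; the chosen dmax is the
smallest whose released endpoint stays below 1% (configurable) of the P(r)
peak. "No significant rise at the endpoint when the constraint is
released" is thereby quantified; on noise-free sphere data the rule
recovers the diameter within a few bins.

**Rebinning.** Experimental P(r) curves are rebinned to 1 Å by linear
interpolation of both values and errors. Errors are interpolated, not
√n-rescaled — error magnitudes from different transform programs already
differ by up to an order of magnitude, so no error model is imposed.

**Quality checks.** The report records q_min, q_max, π/q_min as the
largest reliably characterizable dmax, and the number of points in the
Guinier window.

**Sequence mass** uses average (not monoisotopic) residue masses plus one
water.

## Ensemble fitting

`EnsembleNNLS` solves min ‖Ax − b‖₂, x ≥ 0 (Lawson–Hanson via
scipy.optimize.nnls) with optional 1/σ row weighting. Coefficients below
1e-8 of the maximum are treated as numerical dust and dropped before
renormalization. No sparsity penalty or ensemble-size cap is imposed; the
projection algorithm's empirical tendency to return few members is relied
on as behaviour, not a guarantee. χ² against intensity data uses N − 1
degrees of freedom (one spent on the analytic scale). Experimental I(q)
is never rebinned before fitting — oversampled grids therefore give
optimistic absolute χ², and reports should be read as relative
comparisons between fits on the same grid. P(r)-target fits default to
*no* error weighting: the long-r tail carries the largest transform
errors, and weighting systematically suppresses the extended conformers
that generate it. In pipeline reports, P(r)-selected ensembles are scored
by building the fraction-weighted composite I(q) of their members and
scaling it against the measured data, so χ² values of P(r)- and
I(q)-target fits are directly comparable. The union refit pools every
conformer selected by any fit, plus the unmodified starting structure,
and refits against I(q); by nesting its residual can never exceed the
best member fit's.

Normalization order: NNLS fractions are renormalized to sum to one before
ensemble statistics are computed (results for reported quantities are
unchanged either way, since fractions are quoted as proportions).

## Synthetic data generator

`make_flexible_model` builds Cα-bead chains: helical-rod domains
(3.8 Å virtual bonds, ~10 beads/turn, 5.5 Å pitch, confidence 90) joined
by extended zigzag linkers (confidence 30), with constant per-residue
scattering factor (55 electrons, 1.9 Å bead radius) and a small seeded
coordinate jitter. The geometry is self-avoiding by construction and the
chains expose pseudo-dihedrals, so the Monte Carlo sampler, the
scattering calculators and the fitting stack all run the identical code
paths as all-atom models. `simulate_experiment` produces the
fraction-weighted composite I(q) with multiplicative Gaussian noise
σ(q) = noise_rel·I(q) + floor (σ column set to the generating values) and
the matching noise-free composite P(r) as ground truth.

What the generator does *not* emulate: atomic side-chain detail,
hydration-layer scattering, instrumental smearing, buffer-subtraction
artefacts, or beamline-specific error structure. Passing tests therefore
demonstrate the correctness of the bookkeeping, the sampler, the inverse
problem and the weight recovery under idealized noise — not the absolute
accuracy of dry-structure profiles against real measurements.

Default study conditions: 2% relative noise; pools of ~300
representatives; three-component truth weights (0.5, 0.3, 0.2); a
1869-point q grid over [0.0025, 0.5] Å⁻¹ matching the sampling of modern
deposited datasets. Weight recovery is assessed per truth component:
serially correlated pools contain conformers whose profiles are
indistinguishable from a truth member within the noise, so fractions are
aggregated over each selected member's nearest truth component (by Rg)
before comparison.

## Numerical choices and degenerate inputs

- NNLS iteration cap raised to 30× the column count for the IFT's stacked
  systems (the default cap can trip on wide smoothness-augmented designs).
- Guinier windows need ≥ 5 points; non-positive intensities in a window
  are an error, as is a non-negative slope.
- `ift` refuses dmax < 10 Å, α ≤ 0, and profiles without positive σ.
- Multi-chain structure files are refused unless a chain is named; altloc
  handling takes the first conformer; hydrogens, waters and heteroatoms
  are dropped on read.
- Stride sub-selection of a pool smaller than the stride warns and returns
  an empty pool; a Monte Carlo run with zero acceptances warns likewise.
- Multi-model PDB round trips are exact at PDB precision (3 decimals).
- Pipeline stages are not cached; runs at the shipped problem sizes are
  cheap enough that caching would only add state.

## Problem sizes

The test suite and the acceptance script use bead chains of ~100–170
residues, pools of 300 representatives (from 3 000 Monte Carlo trials),
50 random models for bookkeeping checks, 20 seeds for χ² calibration and
10 noise seeds for weight recovery. The full suite runs in about a minute
on one CPU; the acceptance script in under a minute.

## Known limitations

- Dry-structure profiles: no hydration shell, so absolute agreement with
  measured wide-angle data is not expected.
- Clash-only acceptance can admit backbone geometries outside favoured
  Ramachandran regions.
- NNLS returns one of possibly many minimum-residual supports when pool
  profiles are collinear; member identities are not identifiable below
  the noise level even when component weights are.
- The IFT error bars inherit the arbitrariness of all indirect-transform
  error estimates; error-weighted P(r) fits should be read with that in
  mind.
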