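# saxsensemble

Ensemble modelling of flexible multi-domain proteins against small-angle
X-ray scattering (SAXS) data.

Structure-prediction models (AlphaFold-style, with per-residue confidence
pLDDT stored in the B-factor column) are single static conformations.
Proteins with flexible linkers between folded domains populate a broad
conformational ensemble in solution, and their measured SAXS profiles —
the intensity I(q) and its real-space mate, the pair-distance distribution
P(r) — often disagree sharply with the single predicted structure.
`saxsensemble` reconciles the two: it treats low-confidence segments as
flexible, samples alternative conformations by torsion-angle Monte Carlo,
computes each conformer's P(r) and I(q) from the dry structure, and selects
a weighted ensemble by non-negative least squares (NNLS) against the
experimental P(r) or I(q).

It is aimed at structural biologists who have a predicted structure, a
SAXS profile (3-column `q, I, σ` ASCII) and optionally a GNOM-style `.out`
P(r), and want a quantitative answer to "what ensemble of conformers
explains my data, and how much better than the prediction alone?"

## The model

**P(r) from coordinates.** For atomic groups *i*, *j* with effective
contrasts w_i = b_i − b0_i, where b_i is the group's electron count
(implicit hydrogens folded into their parent heavy atom) and
b0_i = 10 (r_i / r_wat)³ is the solvent-displacement term
(r_wat = 1.93 Å, 10 electrons per water):

    P(r_k) = Σ_{i≠j} w_i w_j   for r_ij in bin k        (1 Å bins)

**I(q) from coordinates** (Debye equation, dry structure, no hydration
shell):

    I(q) = Σ_i w_i² + Σ_{i≠j} w_i w_j sin(q r_ij)/(q r_ij)

**Ensemble selection.** With pool profiles as columns of A and the
experimental curve as b:

    min ‖Ax − b‖₂   subject to  x ≥ 0

optionally with rows weighted by 1/σ. Non-zero coefficients, renormalized
to sum to one, are the conformer population fractions f_i. Ensemble
statistics follow: ⟨Rg⟩ = (Σ f_i Rg_i²)^½ (r.m.s.), ⟨dmax⟩ = Σ f_i dmax_i,
and the largest member dmax with its fraction. Model-vs-data goodness of
fit is χ² = Σ[(c·I_m − I_e)/σ]²/(N−1) at the analytic optimal scale c.

**Experimental-data analysis** included: Guinier fits with a
self-consistent qRg window, a regularized indirect Fourier transform
(histogram P(r), second-difference smoothness penalty, non-negativity,
Monte Carlo error bars), a standardized dmax selection rule (smallest dmax
whose released P(dmax) endpoint stays below 1% of the P(r) peak), 1 Å
rebinning of P(r) curves, and data-quality checks (q_min < π/dmax).

## Worked example

The synthetic generator builds pseudo-atomic multi-domain chains with
known ground truth, so the whole workflow runs without any downloads:

```python
import numpy as np
import saxsensemble as sx

model = sx.make_flexible_model(n_domains=2, domain_radius=12.0,
                               linker_length=12, seed=5)
segments = sx.suggest_flexible_segments(model, confidence_threshold=60,
                                        min_length=5)
print("flexible segments:", segments.ranges)

pool = sx.sample_pool(model, segments, n_trials=800, seed=5)
sub = sx.subselect_pool(pool, stride=8)

q = np.linspace(0.008, 0.5, 300)
ids = [5, len(sub) // 2, len(sub) - 3]
data, pr_truth, truth = sx.simulate_experiment(
    sub, [0.5, 0.3, 0.2], q, noise_rel=0.02, seed=5, member_ids=ids)

cfg = sx.RunConfig(seed=5, n_trials=800, stride=8, dmax="auto")
report = sx.run_pipeline(cfg, model=model, data=data)
print(report.summary())
```

prints

```
flexible segments: [(45, 56)]
run 'synthetic' (seed 5)
  baseline chi^2 17.677, Rg 33.29 Å
  pool 798 accepted -> 99 representatives (acceptance 100%)
  pr_unweighted: chi^2 1.893, 9 members, <Rg> 26.87 Å
  pr_weighted: chi^2 2.257, 6 members, <Rg> 26.40 Å
  iq: chi^2 0.947, 9 members, <Rg> 27.38 Å
  union: chi^2 0.947, 9 members, <Rg> 27.38 Å
```

Reading: the unmodified starting structure fits the data poorly
(χ² ≈ 17.7); every NNLS ensemble is an order of magnitude better; the
P(r)-target fit *with* error weighting is worse than without (the long-r
tail of the experimental P(r) carries the largest errors and gets
suppressed); and the recovered ensemble ⟨Rg⟩ of 27.4 Å matches the
generator's true r.m.s. ⟨Rg⟩ of 27.2 Å. P(r)-target fits are scored by
building the fraction-weighted composite I(q) of the selected members and
scaling it against the measured intensities, so all χ² values in a report
are directly comparable.

The same workflow runs from the shell:

```sh
fit-ensemble run --config run.yaml        # full pipeline from a config file
fit-ensemble guinier data.dat --skip 25 --max-qrg 1.0
fit-ensemble ift data.dat --dmax 170 --out data_pr.out
fit-ensemble simulate --seed 5            # synthetic end-to-end run
```

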