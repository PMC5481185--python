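# Methods

## The thermodynamic model

A cis-regulatory element (CRE) is bound by one of two proteins competing
for overlapping sites: an RNAP-like activator whose binding leads to
transcription, and a repressor whose binding blocks it. With Boltzmann
weights 1 (empty site), `B = P·e^(−E_P)` (RNAP bound) and
`A = R·e^(−E_R)` (repressor bound), the probability of a
transcription-competent configuration is

```
p_ON = B / (1 + A + B)
```

Energies are in natural units (kT, β = 1); `P` and `R` are dimensionless
activities standing in for concentrations. A point mutation perturbs the
two binding energies additively by `(p, r)` — positive values weaken
binding — and a double mutant's perturbations are the sums of its
singles'. Multiplicative epistasis between two mutations is

```
ε = (p_ON^WT · p_ON^m12) / (p_ON^m1 · p_ON^m2)
```

Because the `B·e^(−p)` numerators cancel, `log ε` is a combination of the
four log partition functions `log(1 + A·e^(−r) + B·e^(−p))`; all
arithmetic is carried out with `logaddexp` so effects of tens of kT and
activities spanning many decades neither overflow nor lose precision.

## Sign analysis

Without the repressor (`A = 0`) the sign of epistasis depends only on the
RNAP perturbations:

```
sign(ε − 1) = −sign((1 − e^(−p1)) · (1 − e^(−p2)))
```

so two mutations that move RNAP binding in the same direction are always
in negative epistasis and opposite directions always in positive
epistasis, independent of `B`.

At general `A`, expanding `ε − 1` over the common positive denominator
gives a numerator proportional to

```
S = −A·(1 − y1)(1 − y2) − B·(1 − x1)(1 − x2) − A·B·(x1 − y1)(x2 − y2)
```

with `x_i = e^(−p_i)`, `y_i = e^(−r_i)`. Two consequences shape the
design of this package:

1. **Equal relative effects never switch sign.** If both mutations have
   the same relative impact on the two proteins (`p_i = r_i`), the cross
   term vanishes and `S` keeps one sign at every repressor activity. Sign
   transitions along a repressor titration therefore require *opposite
   relative dominance*: one mutation hitting RNAP binding harder than
   repressor binding, the other the reverse, making
   `(x1 − y1)(x2 − y2) < 0`.
2. **Epistasis vanishes at saturating repressor.** As `R → ∞`, all four
   partition functions are dominated by the repressor term and
   `log ε → 0`, so every sign trajectory ends in "none". Trajectory
   classification strips this universal trailing asymptote before
   matching the collapsed sign sequence to a category.

`sign_trajectory` evaluates the thresholded sign (default tolerance
`|ε − 1| ≤ 1e−9`) on a sweep of `R = 0` plus 241 log-spaced activities
over 24 decades centred on `e^(E_R)`, collapses consecutive duplicates,
bisects each sign change to relative precision 1e−6, and maps the
sequence to one of seven categories (always positive/negative, neg→pos,
pos→neg, zero-then-positive/negative, no epistasis). An unrecognised
sequence raises an error carrying the sequence rather than being coerced.

`derive_sign_table` tabulates the trajectory category for every
combination of single-effect signs. Because of consequence (1) above, a
representative pair with *identical* magnitudes would hide every
transition; each cell is therefore evaluated on an asymmetric pair — the
first mutation RNAP-dominant (`|p| = magnitude`,
`|r| = magnitude·dominance_ratio`), the second repressor-dominant — which
is the generic situation for two random point mutations in overlapping
sites. Cells are canonicalised on the sorted pair of sign tuples, so the
table is exactly symmetric under swapping the two mutations.

## Energy matrices and mutation effects

An `EnergyMatrix` assigns each (position, base) pair an additive kT
contribution over a half-open footprint `[offset, offset + length)` of
the CRE (0-based, sense strand); larger energy means weaker binding.
Mutation effects `(p, r)` are the energy differences between mutant and
wildtype sequence under the RNAP and repressor matrices; mutations
outside a footprint contribute zero to that protein. Additivity makes a
double mutant's `(p, r)` the exact sum of its singles'.

`reduce_spacer_position` drops the position within a designated spacer
interval whose four entries span the smallest range (max − min), breaking
ties toward the 5' end — used when a matrix carries one more spacer
position than the promoter it is applied to. `design_sign_category_panel`
buckets all single substitutions by the signs of their `(p, r)` effects
(threshold 1e−9 kT) and samples double mutants uniformly without
replacement for each requested sign-pair category, flagging categories
with no qualifying pair as infeasible (on a strong site, no point
mutation improves binding of both proteins at once).

## Empirical pipeline

Raw replicate fluorescence is processed per environment:

- **Normalization.** `f = (mean − blank) / (mean_WT − blank)`; the
  squared relative error of `f` (its log-variance) is the sum of the
  squared relative standard errors of the corrected mutant and wildtype
  means. Non-positive corrected means are floored at 1e−4 of the
  corrected wildtype with a warning and a `floored` flag.
- **Epistasis.** `ε = f_m12 / (f_m1 · f_m2)`;
  `var(log ε) = Σ relvar(f)` over the three values. The wildtype term
  enters through each `f`, which triple-counts the shared wildtype
  uncertainty; this is deliberate and conservative (it can only inflate
  the standard error and suppress false positives).
- **Testing.** `t = log ε / sd(log ε)` with `df = n − 1` replicates,
  two-sided p-values, Benjamini–Hochberg FDR at α = 0.05 within each
  environment. The reported sign is positive/negative only for
  significant estimates.
- **Classification.** A mutation "flips" when its effect direction on the
  wildtype background (`f_mi` vs 1) reverses on the other single's
  background (`f_m12/f_mj` vs 1). Two flips → reciprocal sign epistasis,
  one → sign epistasis, none → positive/negative magnitude by ε vs 1;
  non-significant estimates are "no epistasis", with a caveat flag when
  flips were present but unsupported.
- **Environment comparison.** Strict mode compares signs only where both
  environments are significant; lenient mode uses point-estimate signs
  for every mutant. The per-mutant output includes
  `log10(ε_repressor) − log10(ε_no_repressor)`.
- **Cohort statistics.** Sign bias: Pearson χ² of significant
  positive/negative counts against equal proportions. GxGxE: one-way
  ANOVA of per-pair `log ε` on environment, F with df (1, 2n − 2) — the
  simplest model in which a significant environment effect means the
  mutation interaction itself depends on the environment. Conformity:
  observed sign counts among significant estimates versus the
  distribution of predicted signs, plus a per-mutant agreement fraction;
  predictions can come from measured single-mutant directions (same
  direction → negative, opposite → positive).

## Activity fitting

Predicted `log ε` per double mutant follows from composing matrix-derived
`(p, r)` effects with the closed-form model. The two free parameters —
effective activities `P` and `R` (with `R = 0` in the repressor-free
environment) — are estimated by maximizing the Pearson correlation
between predicted and measured `log ε`, pooled over both environments: a
25×25 grid over `log10 P, log10 R ∈ [−6, 6]` followed by Nelder–Mead
refinement. Only the products `B = P·e^(−E_P)` and `A = R·e^(−E_R)` are
identifiable; the baseline energies are absorbed into the fitted
activities and the output carries an identifiability note. A
per-environment linear regression of measured on predicted `log ε`
summarises fit quality. By default, mutants without significant measured
epistasis are excluded (their measured sign is noise); `--all-mutants`
disables the filter.

## Synthetic studies

The generator emulates the study design this pipeline targets: a 43-bp
CRE, 141 random double mutants with all their single mutants, six
replicates, two environments (repressor absent/present), multiplicative
lognormal noise (sd 0.1 ≈ replicate CV), and blank wells at 5 % of the
wildtype signal. Mean fluorescence is
`blank + wildtype_scale · p_ON(g)/p_ON(WT)`. Ground truth (occupancies,
true ε and its sign per environment) is computed from the model directly
and written separately; the pipeline under test never reads it.

Default parameters, chosen a priori:

- Geometry: RNAP footprint `[0, 30)`, repressor footprint `[9, 43)` —
  the repressor (think: two operator half-sites tiling the downstream
  promoter) covers the 3' half of the RNAP site, so most positions affect
  both proteins, nine affect only RNAP and thirteen only the repressor.
- Matrix entries: mismatch penalties drawn from a Gaussian of mean
  `scale` truncated at 0 (RNAP scale 2 kT; repressor scale 3 kT —
  operator sites are typically more specific per position).
- `improving_fraction = 0.25`: at a quarter of positions one
  non-reference base binds *better* than wildtype. A strong natural
  promoter sits near, not at, its matrices' optima, and without any
  improving bases every mutation weakens both proteins identically in
  direction, which (by the sign decomposition above) starves the cohort
  of the opposite-dominance pairs that produce sign switches.
- Activities: `B = 2.5` (strong promoter, wildtype `p_ON ≈ 0.71`) and
  `A = 100` with repressor (~30-fold repression).

With these defaults the cohort reproduces the qualitative pattern the
model predicts: the majority of point-estimate ε are negative without the
repressor, and the majority of *ground-truth* ε signs switch between the
two environments (0.62–0.73 across seeds). The *measured* switch fraction
at noise sd 0.1 is attenuated (≈ 0.3–0.55): many no-repressor ε are
exactly 1 in truth (pairs involving repressor-only positions), and noise
flips their estimated sign to either side, while the
significance-gated strict comparison discards most of them. This
attenuation is a property of the measurement, not the generator, and is
reported rather than tuned away.

## Numerical and reproducibility notes

- Every stochastic step is seeded; a study derives four child seeds
  (wildtype, two matrices, library/noise) from one root seed via a PCG64
  generator, each below 2³¹.
- All ε arithmetic is in log space; sign thresholds are configurable
  (`1e−9` on `|ε − 1|` for model signs, `1e−9` kT for matrix effect
  signs).
- File formats: energy matrices as TSV (`pos A C G T`, kT) with a JSON
  sidecar for name/offset/reference written at full float precision and
  read with round-trip parsing; genotypes as CSV (`id,position,ref,alt`);
  the CRE as FASTA; fluorescence and estimates as CSV. Readers validate
  strictly and report offending line numbers.

## Limitations

- The model ignores cooperativity, dimerization, looping, and activator
  recruitment; it is a single-site competition model by construction.
- Only `A` and `B` are identifiable from epistasis data; reported
  activities are relative to the supplied baseline energies.
- The error propagation triple-counts the shared wildtype variance
  (conservative by design).
- Synthetic matrices and noise are stand-ins, not measured values; the
  generator reproduces qualitative cohort behaviour, not any specific
  experimental dataset.
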