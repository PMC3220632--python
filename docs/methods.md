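# Methods

This note documents the model behind `cryosim`, the choices made where the
design was genuinely open, and what the simulations can and cannot say.

## Population and selection model

The simulated breed is a closed dairy population with discrete,
non-overlapping generations: 100 young bulls and 10,000 cows per
generation, 13 generations (indices 0–12).  Each selection round picks, by
truncation on the criterion in force, the 10 sires of males, 50 dams of
males and 20 sires of females; all cows are dams of females (no selection
on the dam-to-dam path).  The two sire lists are drawn independently from
the same 100-bull cohort, so the 10 sires of males are also among the 20
sires of females whenever one criterion ranks both lists — the natural
reading of a scheme whose elite bulls serve both paths.  Ties in truncation
are broken by ascending animal id; with continuous EBVs this is a
measure-zero event, handled only so that fixed seeds give bit-identical
runs.  Each newborn draws its sire and dam independently and uniformly from
the relevant lists, so progeny counts per parent are multinomial; the
across-sire dispersion of counts is reported as a population (ddof = 0)
standard deviation because the count mean is fixed by the cohort size
(theory: √(100·0.1·0.9) ≈ 2.85 on the male path, √(10000·0.05·0.95) ≈ 21.8
on the female path).

## Genetic model

Traits A (production) and B (functional) follow a bivariate additive
infinitesimal model, expressed throughout in units of the founder genetic
standard deviation.  Parameters that matter:

| parameter | default | meaning |
|---|---|---|
| ρ | −0.3 | genetic correlation between A and B (antagonistic) |
| σ_A, σ_B | 1 | founder genetic s.d. (the unit of all trait values) |
| CD (bulls / cows) | 0.6 / 0.4 | EBV accuracy, squared correlation with the true value |
| w_B | 0.5 | weight of trait B in the total merit index (1 − w_A) |

Founder values are A ~ N(0,1), B = ρA + √(1−ρ²)β.  Offspring receive the
mid-parent value plus a Mendelian deviation with s.d.
√(½[1 − (F_s + F_d)/2]) per trait; the (γ, δ) deviations for A and B are a
standard bivariate normal pair with correlation ρ, generated by the same
Cholesky construction as the founders (any construction with these moments
is equivalent).  EBVs are *imposed*, not estimated: EBV = CD·g +
ε√(CD(1−CD)) once per animal at birth, applied verbatim to the realized
genetic values.  This makes corr(EBV, g)² = CD exactly in expectation, but
shrinks each cohort's EBV mean by CD relative to its true mean.  Within a
cohort (where all selection operates) this is irrelevant; the only
cross-generation use of EBVs is the total-merit ranking of stored cryobank
bulls, and a generation-mean-corrected variant of that ranking was found to
change the chosen bulls and all downstream results negligibly, so the
verbatim form is kept.  All genetic values are stored in double precision.

## Pedigree, inbreeding and kinship

Inbreeding and coancestry are exact pedigree quantities.  Two code paths
exist: a memoised pair recursion (the oracle, used in tests and for small
pedigrees) and a vectorised cohort-matrix update used by the engine —
Φ(o₁,o₂) = ¼ΣΦ(parents), diagonal ½(1 + Φ(sire, dam)) — since whole
10,100-animal generations must be averaged.  The cohort matrix is stored in
single precision (10,100² entries per generation); the test suite verifies
it against the double-precision recursion entrywise (tolerance 1e-12 on
small pedigrees; F values agree to 1e-6 at full scale).  A full
all-generations relationship matrix (~131k animals) is never formed; the
scheme only ever mates within the previous cohort plus tracked cryobank
bulls, whose cross-rows are propagated explicitly.  Average kinship is the
mean over unordered *distinct* pairs — self-kinship is excluded so that Φ
and F remain separate statistics.  The inner propagation loop is a numba
kernel (upper triangle, mirrored); a pure-numpy fallback produces identical
results.

Genetic contributions of the reused bulls are computed by the exact
recursion p(i) = ½σ_sire + ½σ_dam (σ = 1 across a labelled generation-9
mating, the parent's p otherwise), which is the infinite-run limit of
single-locus gene dropping; the Monte-Carlo gene dropper is retained and
tested against it, but the exact path removes sampling noise from reported
tables.

## Cryobank rules and reuse

During stage 1, a young bull enters the bank if its EBVA is beyond ±3
within-cohort standard deviations (both tails), its EBVB above +2 s.d.
(functional trait: upper tail only), or if, one generation later, it is a
sire of sires none of whose sons was selected as a sire of males *or* of
females.  Thresholds use the empirical mean and s.d. of the 100-bull
cohort with strict inequalities.  Rules i–ii run on cohorts 0–7 and rule
iii on sires of sires born 0–6, so that the lagged assessment still falls
inside stage 1; these ranges reproduce the observed mean birth generations
of sampled bulls (~3.5 for the EBV rules, ~3.0 for rule iii).  A bull
satisfying several rules is stored once with merged reasons and credited to
each rule in composition tables.  A store-everything variant (all young
bulls banked) is provided; at matched scale it leaves the scenario
endpoints statistically indistinguishable.

At generation 9 the four reused bulls are the bank's best by TMI (with the
scenario's w_B) or its lowest by mean coancestry with the full generation-8
cohort, males and females together.  They are used once, only on the male
path, mated to the same 50 selected dams of bulls as regular matings —
mating them to random cows instead collapses the b1 contribution to ~0.2%
against a published ~2.8%, so the elite-dam reading is the consistent one.
Under male-line conservation (d2/d3) every sire of sires gets exactly 10
sons, of which the best EBVA son continues the line and the two best become
sires of dams; with cryobank use (d3) the four stored bulls *head four of
the ten conserved lines*, displacing the lowest-ranked regular sires.  The
alternative — 14 lines later truncated back to 10 — eliminates every
founder-born cryobank line at the first cross-line selection and drives the
d3 contribution to zero, contradicting the sustained ~7% the combined
strategy is meant to achieve.

## Replicates, seeds and scale

A master seed spawns one `numpy` substream per replicate and, within a
replicate, one per stage/branch.  Because stage 1 is identical in
distribution across scenarios, branch comparisons share each replicate's
stage-1 run (a paired design that removes common stage-1 noise from
contrasts); fully independent replicates are also available.  Scenario
contrasts use Welch's two-sample t on replicate-level metrics.  Reference
results in the tests use 10 full-size replicates, and
`scripts/acceptance.py` uses 20 — means over 10,100 animals are stable at
these counts (across-replicate s.d. ~0.3 genetic s.d. on trait means,
~0.7pp on kinship); the gene-contribution of reused bulls is the noisiest
statistic (per-replicate s.d. ~3–5pp under the b scenarios, where selection
of their sons is a near-threshold event).  A `scaled()` configuration
shrinks cohorts proportionally for fast structural tests; it deliberately
does **not** reproduce full-size magnitudes, because selection intensities
change with list sizes.

## Known behaviour and limitations

* The realized rate of inbreeding needs its stabilized regime: founders are
  unrelated, so ΔF is ~0 at generation 1 and ramps up; averaged over
  generations 5–8 it is ~1.1%/generation (four-path theory for this
  structure predicts ~1.06%), while averaging from generation 1 gives
  ~0.95%.  Headline rates are therefore quoted on generations 5–8.
* Generation-8 average kinship runs ~1 percentage point above the
  published trajectory for this scheme (young bulls ~9.2% vs 8.1; whole
  population ~8.0% vs 6.9) even though the selection response, bank
  composition, progeny dispersions and all generation-12 kinship endpoints
  match; structural variants that lower it (disjoint sire lists) break the
  selection response badly and were rejected.  The corresponding
  acceptance check is left failing rather than re-tuned.
* Under scenario b3 the reused bulls' descendants are slightly more
  competitive here than in the published account (gene contribution ~8% vs
  6.5% at generation 12, within ~1 across-replicate s.d.), and the best-TMI
  choice picks marginally older bulls (mean birth generation ~5.4–6.3 vs
  6.6); the qualitative contrast — TMI picks recent bulls, minimum-kinship
  picks founders — is unaffected.
* No marker or QTL genetics, no BLUP (accuracy is imposed), no overlapping
  generations, no semen-dose accounting, no female-path cryopreservation,
  and no optimal-contribution selection — the scheme is deliberately the
  classical four-path truncation design.
* The synthetic breed omits features of real populations (unbalanced
  reproducer use, preferential matings, selection on pedigree
  information), so passing tests demonstrate internal consistency of the
  model and faithfulness to the reference scheme, not predictions for any
  actual breed.
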