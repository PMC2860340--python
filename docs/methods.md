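# Methods

## Model and statistics

For one biallelic SNP in a case–control sample of N individuals
(N_ca cases, N_co controls), each individual is assigned the symbol
(genotype, status).  Write n(X, t) for the count of symbol (X, t),
X ∈ {AA, Aa, aa}, t ∈ {ca, co}.  Four Shannon entropies (natural log,
`0 ln 0 = 0`) are formed from the *joint* symbol frequencies n(X, t)/N:

* `h(C, Cᶜ)` — entropy of (N_ca/N, N_co/N);
* `h(S)` — entropy of the pooled genotype frequencies (column totals / N);
* `h(S, ca)`, `h(S, co)` — partial entropies `−Σ_X (n(X,t)/N) ln(n(X,t)/N)`.

Their combination `H = h(C,Cᶜ) + h(S) − h(S,ca) − h(S,co)` is the
mutual information between genotype and status: non-negative, and zero
exactly when the genotype distribution is identical in cases and
controls.  The genotypic statistic is `GE = 2N·H`, which is the exact
multinomial likelihood-ratio statistic (the G-statistic
`2 Σ O ln(O/E)`) of the 2×3 table; its null distribution is
asymptotically χ² with 2 df.  The allelic statistic uses the 2×2
allele table (each individual contributes two alleles) with multiplier
M, the total allele count: `AL = 2M·H_allele`, asymptotically χ²(1).
Using the joint rather than within-group frequencies in the partial
entropies is what makes the decomposition a mutual information and the
statistic the exact LRT; a within-group reading would not reproduce
either identity.

Because H is fixed by the cell frequencies, scaling all counts by k
scales the statistic by k, so the statistic diverges under any fixed
alternative — the tests are consistent.

### Numerical conventions

* Natural logarithms throughout: the χ² asymptotics of −2 ln λ require
  nats.
* `0 · ln 0 = 0` (via `scipy.special.xlogy`), so empty symbol classes
  are harmless — no grouping or pseudo-counts are ever needed.
* Tiny negative rounding residue in H (order 1e-16) is clipped to 0.
* Degrees of freedom are fixed at 2 (genotypic) and 1 (allelic) even
  when genotype/allele classes are empty in the pooled sample.  This
  deliberately makes the tests conservative at very low MAF; adapting
  df would destroy that behaviour and the comparability with the
  Pearson comparators, whose empty cells likewise contribute 0 with df
  held fixed.
* A SNP whose pooled sample has a single genotype (or allele) class is
  reported as statistic 0, p = 1 with a `degenerate` flag, never as an
  error; degenerate SNPs stay in every denominator so empirical sizes
  are unconditional.
* p-values are upper-tail χ² probabilities (`scipy.stats.chi2.sf`).

## Exact comparator tests

The two-sided Fisher tests condition on all margins.  The 2×2 test and
its 2×3 (Freeman–Halton) extension share one enumeration: the top-row
entries of the k−1 smallest column margins are enumerated on a grid,
the last column and bottom row follow from the margins, and point
probabilities `Π_j C(c_j, a_j) / C(N, r₁)` are evaluated with
log-gamma arithmetic.  The two-sided p-value sums the probabilities of
all tables no more probable than the observed one, with a relative tie
tolerance of 1e-12.  The enumeration is exact by construction; if the
grid would exceed the capacity cap (default 1e8 tables) the test
raises a capacity error rather than approximating.  Enumerating the
smallest margins makes low-MAF tables — the regime where Fisher is
actually used — cheap: at MAF 0.03 with 5,000/5,000 a 2×3 test visits
a few thousand tables.

Pearson X² uses `Σ (O−E)²/E` over cells with E > 0.  Both comparator
families are implemented in-package because library routines either
adapt df / reject empty classes (`scipy.stats.chi2_contingency`) or
use a different tie tolerance and lack a 2×3 form
(`scipy.stats.fisher_exact`); both scipy routines serve as independent
oracles in the test suite instead.

## Simulator

The generator emulates the study conditions of the evaluation design:
unrelated individuals, one biallelic SNP at a time, Hardy–Weinberg
equilibrium within each status group, no LD, no genotyping error, and
an effect expressed purely as an allele-frequency shift.  Given the
control minor-allele frequency p_co and an allelic odds ratio OR, the
case frequency is the closed-form solution of
`odds(p_ca) = OR · odds(p_co)`:

    p_ca = OR·p_co / (1 − p_co + OR·p_co).

Genotypes are drawn per group as one multinomial over the HWE
probabilities (q², 2pq, p²) — distributionally identical to i.i.d.
individual draws — and expanded to individual codes in a fixed order.
Null scenarios draw p_co ~ Uniform(1e-6, 0.5) per SNP (open lower
bound implemented as 1e-6; monomorphic draws are kept as degenerate
tests to preserve the unconditional size interpretation).  Each SNP
has its own `SeedSequence(seed, spawn_key=(snp,))` substream, so
enlarging `n_snps` never perturbs earlier SNPs and every dataset is
bit-reproducible from its config.

Default scenario grids (the `evaluate` presets) follow the original
evaluation design: 10,000 null SNPs at 500/500 for calibration;
100-SNP cells at 500/500 over OR ∈ {1.25, 1.5, 2} × MAF ∈
{0.05, 0.2, 0.4} for common-variant power; 1,000-SNP cells at
5,000/5,000 over OR ∈ {1, 1.5, 1.8} × MAF ∈ {0.01, 0.03, 0.06} for
the low-frequency regime.

What passing these simulations does *not* show: behaviour under
population structure, LD between markers, differential missingness or
genotyping error — none of which the generator models.  Real-data
pathologies such as low call rates (which can make the entropy and
Pearson statistics disagree in either direction) must be handled by
upstream QC; the package's only missing-data policy is per-SNP
listwise exclusion, a choice the evaluation design never exercises.

## Evaluation harness

Rejection is `p < α` (strict; this matters only for the discrete
Fisher p-values).  Empirical rates are binomial proportions over the
SNPs of a cell and are reported with their standard error
`sqrt(r(1−r)/n)`.  The gain summary reports, per cell, the mean of
`(entropy − Pearson)` statistic differences and the mean of the
per-SNP proportional gain `(entropy − Pearson)/Pearson`; SNPs with a
zero Pearson statistic are excluded from the proportional mean only
(their count is reported).  The proportional mean is taken over **all**
SNPs of a cell, not only rejected ones — the definition leaves this
open and the all-SNP mean is the variance-minimising choice.
Per-config sub-seeds derive from a master seed plus a hash of the
config, so cells are independent and individually reproducible.

## Problem sizes and tolerances in the shipped checks

The acceptance script and the full-scale tests use the original cell
sizes (10,000 / 1,000 / 100 SNPs as above); everything else in the
suite runs at reduced n chosen to keep Monte-Carlo error well inside
the asserted tolerances.  Monte-Carlo comparisons against reference
rates use three standard errors; where the reference is itself a
simulation estimate of the same size, the SE of the *difference* of
two independent binomial estimates is used.  Algebraic identities
(entropy statistic ≡ G-statistic, exact p ≡ enumeration oracle) are
asserted to 1e-9.

## Known limitations

* Asymptotic p-values only for the entropy and Pearson tests; no
  permutation option.
* Biallelic autosomal markers only; no X-chromosome, multi-allelic or
  quantitative-trait support; no covariates, trend test, or epistasis.
* At MAF < 1% all four tests are conservative; the entropy tests more
  so than Fisher, hence less powerful there.
* The Fisher capacity cap refuses balanced tables with three large
  column margins (all ≫ 10⁴); such tables are precisely where the χ²
  approximation is excellent and Fisher is unnecessary.
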