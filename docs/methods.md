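# Methods

## Data model

A study is a collection of independent pedigrees typed at one diallelic
marker (alleles M₁/M₂; genotype score X = number of M₁ alleles).  Affection
is dichotomous.  Individuals with unknown affection status are treated as
unaffected by default (`unknown_affection="unaffected"`), mirroring common
practice in consortium data; a strict mode (`"exclude"`) removes them from
all discordant-pair sums instead.  Genotypes are either fully observed or
fully missing; half-typed genotypes are rejected at parse time.  Pedigrees
without at least one affected and one unaffected member contain no
discordant pair and are skipped by every statistic (the skip count is
reported in the results object).

## GDT-ME and GDT

The pedigree score S_i = (1/N_i) Σ_{j affected} Σ_{k unaffected}
(X_ij − X_ik) sums genotype differences over all discordant relative pairs,
including pairs beyond first degree.  GDT-ME studentises ΣS_i by the moment
estimate √(ΣS_i²) and is referred to the standard normal; p-values are
two-sided because the statistic is signed.  The GDT comparator replaces the
moment denominator with a kinship-based variance V_i = (1/N_i²) aᵀCa where
a_j = U_i for affected and −A_i for unaffected members and
C_jk = 4 φ_jk p(1−p) under Hardy–Weinberg equilibrium, with φ the standard
recursive kinship coefficient (founders unrelated and non-inbred).  This
variance is a reconstruction from kinship coefficients rather than from
observed identity-by-descent sharing, and we treat GDT as a comparator
only.  On incomplete data both tests simply drop untyped individuals; the
1/N_i scaling then uses the number of typed members, which leaves the
statistic's null calibration intact (the scaling is per-pedigree arbitrary)
while keeping the moment variance consistent with the scores actually
summed.

## GDTI: the imprinting-aware score test

Each genotype score is decomposed as X = X⁽ᵖ⁾ + X⁽ᵐ⁾.  A homozygote
contributes (0,0) or (1,1).  A heterozygote contributes (1,0) or (0,1)
when the parental origin of its M₁ allele is forced by the parents'
genotypes, and (0.5, 0.5) when it is not — heterozygous founders, and
heterozygous nonfounders with two heterozygous parents.  Phase is resolved
from the parents' genotypes *only*: sibling, grandparental or offspring
information is deliberately not used, because the statistic's information
matrix is derived for exactly this three-case coding; deeper phasing would
change the statistic.  A property test asserts the only ambiguous
nonfounder case is the double-heterozygous-parent one.

Modelling affection by a logistic model with separate coefficients β_p, β_m
on the two allele scores, and conditioning on the number of affected
members per pedigree, gives a conditional likelihood whose score vector at
β_p = β_m = 0 has per-pedigree components

D_i1 = (1/N_i) Σ_{j aff} Σ_{k unaff} (X⁽ᵖ⁾_ij − X⁽ᵖ⁾_ik),

and D_i2 its maternal analogue (so D_i1 + D_i2 = S_i exactly).  The
observed information is an average over all C(N_i, A_i) relabelings of
which members are affected: with c_j = Σ_{k unaff}(x_j − x_k) the
per-member contrast sum, the leading term of I_i11 is
(1/U_i²)·E[(Σ_{j∈s} c_j)²] over uniformly random size-A_i subsets s.  Two
evaluation routes are implemented:

* **enumeration** — literally iterating the subsets (the reference route;
  capped at C(N_i, A_i) ≤ 10⁶);
* **closed form** — E[T²] = Var(T) + (E T)² with the exact
  sampling-without-replacement variance
  Var(T) = A(N−A)/(N−1) · (1/N)Σ(c_j − c̄)², and the covariance analogue
  for the cross term (the production route, O(N)).

The two agree to ≤ 1e−12 absolute on every pedigree (tested property).

GDTI is the quadratic form of the summed score vector in the inverse of
the summed 2×2 information, referred to χ² with 2 degrees of freedom.  If
the summed information is singular (e.g. no phase is resolvable anywhere,
making the paternal and maternal score vectors identical), the
Moore–Penrose pseudo-inverse is used and the degrees of freedom drop to
the matrix rank — a conservative, well-defined boundary convention; rank 0
returns statistic 0 with p-value 1.  Rank is decided at a relative
eigenvalue tolerance of 1e−10.  The statistic is invariant under
relabelling M₁ ↔ M₂ (both score sums negate; the information is
unchanged).

## Missing genotypes: MCGDTI and MCGDT-ME

Missing genotypes are imputed by sampling from the exact conditional
P(G_m | G_o) under founders in Hardy–Weinberg equilibrium at M₁ frequency
p, Mendelian transmission, and genotype–phenotype independence.
Conditioning is on genotypes only, not phenotypes; under the null this is
the correct conditional, under ascertained alternatives it is an
approximation (adopted deliberately — the sampling model is a null model).

The pedigree likelihood is computed by variable elimination over the
genotype factor graph (founder HWE priors, one transmission factor per
trio, evidence applied by slicing), i.e. Elston–Stewart peeling in its
graph form.  Variable elimination is exact on looped pedigrees as well —
the greedy elimination order just produces larger intermediate factors —
so no zero-loop restriction is imposed.  Sampling uses an exact-enumeration
fast path whenever 3^(#missing) ≤ 3⁸: the joint weight of every completion
is evaluated vectorially, and K draws are a single multinomial.  Beyond
that, exact chain-rule sampling draws each missing genotype in turn from
its peeled conditional.  Both routes are checked against an independent
brute-force enumeration oracle in the tests (likelihoods to 1e−12
relative; sampled distributions by chi-square goodness-of-fit at
α = 0.001 with K = 50,000).

Each pedigree's components (S_i, D_i1, D_i2, I_i11, I_i22, I_i12) are
averaged over K completions (default K = 50); MCGDTI and MCGDT-ME then
assemble the same quadratic form / ratio as their complete-data
counterparts.  With no missing genotypes the conditional is degenerate and
both tests reduce bit-for-bit to GDTI / GDT-ME.  The sampler's M₁
frequency comes from one of three modes: `true` (supplied), `founders`
(gene counting over typed founders, the default) or `all_individuals`
(all typed members, for data with heavy founder missingness).  Each
pedigree uses an RNG substream keyed by (master seed, CRC32 of the family
id), so results do not depend on pedigree processing order.

## The simulator

Gene dropping at two completely linked loci: founders draw two haplotypes
i.i.d. from the population frequencies of DM₁, dM₁, DM₂, dM₂; each
nonfounder inherits one haplotype from each parent uniformly (no
recombination).  Affection is Bernoulli with penetrance indexed by the
*ordered* disease-locus genotype (f₂, f₁₀, f₀₁, f₀ for D/D, D/d, d/D,
d/d, paternal allele first), so imprinting is f₁₀ ≠ f₀₁.  LD is
P(DM₁) − P_D·P_M₁.

Built-in study settings: three LD scenarios with P_D = 0.25 and
P_M₁ ∈ {0.15, 0.35, 0.25} (LD = 0.0925, 0.1425, 0.1575); homozygote
penetrance pairs (0.390, 0.260), (0.440, 0.240), (0.480, 0.220) giving
relative risks 1.500, 1.833, 2.182; no/incomplete/complete imprinting
models per pair (no imprinting sets f₁ = (f₂+f₀)/2; complete imprinting
silences the maternal copy, f₁₀ = f₂, f₀₁ = f₀).  Null designs use
product haplotype frequencies (LD = 0).  The stratification designs mix
two subpopulations with P_D = P_M₁ = 0.1 and 0.5 at linkage equilibrium
and shared penetrances (0.45, 0.30, 0.30, 0.20), either balanced across
the three structures or confounding subpopulation with structure.

Three pedigree structures are built in — a two-generation family of 5, a
three-generation pedigree of 10 and a four-generation pedigree of 12 —
with fixed missing-data masks (member 1; members 1, 4, 5; members 1 and 3
respectively, all founders or married-in spouses).  The exact topologies
beyond member counts, generation depth and the masked identifiers are a
design choice of this package: null calibration and qualitative power
orderings are driven by the discordant-pair counts and the per-structure
missingness burden, not by fine topology, and templates are
config-overridable.  Ascertainment requires at least one affected
nonfounder, implemented by rejection sampling with a configurable attempt
cap (10⁶).

What the simulator does *not* emulate: genotyping error, multi-marker LD
structure, inbreeding or marriage loops, variable family sizes,
ascertainment through probands, or covariates.  Passing tests therefore
certify the statistics' calibration and ordering under clean Mendelian
data, not robustness to those real-data complications.

## Experiments and reproducibility

`run_experiment` simulates replicates of a design and reports per-test
rejection proportions at a chosen level (rejection is p ≤ α).  Replicate r
uses the substream `SeedSequence(seed, spawn_key=(r,))`, making runs
reproducible and trivially partitionable.  Internally the experiments use
vectorised array kernels (one batch per pedigree template) that share the
closed-form component code with the object-level API; the test suite
asserts the two paths produce identical statistics on the same data.  An
option simulates a fraction of unknown affection statuses to check the
treat-as-unaffected policy; it is off by default.

Problem sizes: unit and property tests use small replicates (tens of
pedigrees); the size checks in the test suite use 2,000 replicates (500
for Monte-Carlo tests at K = 50) and compare empirical rates within three
binomial standard errors of their references; the acceptance script runs
the complete-data cells at 10,000 replicates and the Monte-Carlo /
stratification cells at 2,000–5,000.

## Known limitations

* No covariate adjustment; within-family dependence induced by shared
  covariates is not modelled.
* The GDT kinship variance assumes HWE and non-inbred founders and is a
  comparator approximation, not a primary output.
* Asymptotic reference distributions only (normal, χ²); no exact
  small-sample or permutation p-values.
* One diallelic autosomal marker per test; no X-linked markers,
  multi-allelic markers or haplotype tests.
* The Monte-Carlo sampler ignores linkage with other typed markers when
  imputing missing genotypes.
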