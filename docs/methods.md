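# Methods

## Model

The evaluations solve Henderson's mixed-model equations (MME) for a
single trait with one additive-genetic effect per animal:

    y = Xb + Zu + e,   u ~ N(0, K σ_a²),   e ~ N(0, R)

with `X` the fixed-effect incidence (intercept plus reference-coded
categorical dummies; the first-seen level of each factor is the
reference), `Z` the 0/1 record-by-animal incidence, and `R` diagonal
(σ_e², overridable per record).  For pedigree BLUP, `K = A`, the
numerator relationship matrix; for single-step GBLUP,
`K⁻¹ = H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]` where `G` is the genomic
relationship matrix among genotyped animals and `A22` the corresponding
pedigree block.  No blending or scaling of `G` toward `A22` is applied;
a non-positive-definite `G` is reported as an error rather than
repaired.

### Pedigree machinery

* `A⁻¹` is assembled directly by Henderson's rules from the
  Mendelian-sampling variance ratios `D_i` (1, 0.75 − 0.25F_p, or
  0.5 − 0.25(F_s + F_d) for 0/1/2 known parents).  Inbreeding
  coefficients come from a Meuwissen–Luo style recursion (each animal's
  diagonal `a_ii = Σ_j L_ij² d_j` accumulated over its ancestor list);
  inbreeding is ON by default everywhere.
* The tabular (recursive) `A` is kept as the transparent oracle; every
  inverse routine is tested against it.
* Subset inverses (`A22⁻¹`, `A_pp⁻¹`, `A_qq⁻¹`) use the Schur
  complement of the discarded block of `A⁻¹`:
  `A_SS⁻¹ = Q_SS − Q_SN Q_NN⁻¹ Q_NS`.  This is exact for *any* subset.
  The cheaper route — prune the pedigree to the subset and re-apply
  Henderson's rules — agrees only for ancestor-closed subsets (a
  regression test pins the counterexample: a kept set that severs the
  half-sib link creating an animal's inbreeding).

### Reduced animal models

Three equivalent reductions of the single-step system are implemented
(kept set, absorbed set, back-solve):

| method | kept                                     | back-solve |
|--------|------------------------------------------|------------|
| 1      | genotyped + nongenotyped parents `p`     | Mendelian regression per nonparent |
| 2      | genotyped + nongenotyped phenotyped      | `A^nn â_n = −A^np â_p` (pedigree blocks) |
| 3      | genotyped + nongenotyped parents of phenotyped nongenotyped nonparents `q` | `r` from `A_pp⁻¹` blocks, then nonparents as in 1 |

Records of absorbed phenotyped nonparents (Methods 1 and 3) enter
through a row of halves on their known parents; the Mendelian-sampling
term moves into the residual, `R̃_ii = R_ii + D_i σ_a²`, and the
back-solve regression is `B_i = D_i σ_a² / (R_ii + D_i σ_a²)`
(equivalently `(1 + R_ii D_i⁻¹ σ_a⁻²)⁻¹`), which reproduces the
regression interpretation of Mendelian sampling; an animal without a
record gets the parent average.  A missing parent contributes zero to
the parent average, so one known parent gives `â_parent/2`.  Phenotyped
animals are never absorbed into Method 3's `r` set: a phenotyped animal
owns an identity row in the reduced design and cannot be reduced away
by the linear block solve.

Back-solving uses pedigree-derived matrices only.  The genomic
correction `G⁻¹ − A22⁻¹` stays inside the kept system's genotyped block
— this is what makes the reductions computationally attractive, and it
is asserted by tests that reconstruct every back-solved value from
tabular-`A`-derived blocks.

Absorbed animals are assumed to carry at most one record; repeated
records on an absorbed animal would require a correlated-residual
absorption and are rejected with an error (kept animals may have any
number of records).

### Single-step marker model

The marker model fits marker effects α directly with imputed marker
covariates for nongenotyped animals (`M₁` solved from
`A^11 M₁ = −A^12 M₂`), per-animal imputation deviations ε (prior
precision `A^11 σ_α⁻²`, nongenotyped animals only) and a residual
polygenic effect δ (prior `A⁻¹ σ_δ⁻²`).  Total merit is `M₂α̂ + δ̂` for
genotyped and `M₁α̂ + ε̂ + δ̂` for nongenotyped animals.

Centered genotypes are scaled by `1/sqrt(2Σp_j(1−p_j))` by default so
`MM′` sits on the relationship scale; this is what lets the single
variance σ_α² serve coherently as both the marker-effect prior and the
ε prior, and yields the numerical equivalence with ssGBLUP run on
`G_eq = (M₂M₂′σ_α² + A22σ_δ²)/(σ_α² + σ_δ²)` (verified to 1e-6 on
simulated data; a raw mode accepts user-scaled genotypes as-is).  With
zero markers the α and ε blocks vanish and the model collapses to
pedigree BLUP on δ.

The three reductions apply verbatim: δ equations shrink to the kept
set with subset-inverse priors, ε equations to the nongenotyped kept
animals, absorbed records get the same `R̃` inflation with
`σ_a² = σ_α² + σ_δ²`.  Back-solving recovers δ and ε jointly.  For an
absorbed phenotyped nonparent the common residual
`r_i = y_i − x_i'b̂ − m_i'α̂ − PA_ε − PA_δ` (with `m_i` the
parent-average marker row) is regressed with the component-specific
coefficients `D_iσ_δ²/(R_ii + D_iσ_a²)` and `D_iσ_α²/(R_ii + D_iσ_a²)`;
their sum equals the animal-model `B_i`, so total merit obeys exactly
the Method-1 regression.  A genotyped parent contributes zero to the ε
parent average.  This joint form is the one that reproduces the full
marker-model solutions to machine precision; simpler variants that skip
the `m_i'α̂` adjustment do not, and are not used.

## Numerical choices

* Direct dense factorisation is the default below 10,000 equations;
  above that, Jacobi-preconditioned conjugate gradients (tolerance
  1e-12 on the relative residual; non-convergence is an error carrying
  the residual trace).  All systems are symmetrised after assembly.
* `A⁻¹` is stored dense below 2,000 animals and as compressed sparse
  rows above; the Schur-complement subset inverse switches to a sparse
  LU of the discarded block when that block is large.
* Symmetry of labelled matrices is enforced at construction within
  1e-12 (relative); positive-definiteness of `G` is checked by the
  smallest eigenvalue (tolerance 1e-8).
* Every matrix is label-keyed: animal order in files, in `G`, and in
  the equation systems is immaterial, and tests shuffle inputs to
  assert it.

## Synthetic-data generator

`simulate()` produces pedigree, genotypes, phenotypes and the true
breeding values with exactly the structure the models assume:

* discrete generations, random matings within the previous generation,
  configurable missing-parent rates (defaults 10%);
* genotypes by founder allele draws at Uniform(0.1, 0.9) frequencies
  followed by gene dropping of independent loci;
* true breeding values `u = Mα + δ`: a marker-determined component
  (default half of σ_a², configurable via `marker_variance_fraction`)
  plus a residual polygenic part drawn through the pedigree recursion
  `δ_i = (δ_s + δ_d)/2 + N(0, D_iσ_δ²)` — so `Var(u) = Aσ_a²`
  marginally while the markers genuinely carry information about
  realised merit;
* phenotypes `y = Xb + u + e` with an intercept-plus-sex fixed
  structure and σ_e² = 2 against σ_a² = 1 (heritability 1/3) by
  default.

The simulator attaches the true founder allele frequencies to its
genotype container: centering at *observed* frequencies leaves the ones
vector in the null space of `M_cM_c′`, i.e. a VanRaden `G` built from
observed frequencies is always singular (the practical reason blending
exists).  File-based genotype data default to observed frequencies, and
a frequency file can be supplied.

What the generator does **not** emulate: linkage and LD between
markers, selection, non-random mating, genotyping biased toward
selection candidates, QTL effect-size architecture, missing genotypes.
Passing equivalence tests therefore certifies the algebra of the
reductions on data with the assumed covariance structure, not
robustness to real-data artefacts.

Problem sizes used by the test-suite studies were chosen to keep the
whole suite fast while leaving no algebraic case untested: equivalence
runs use ~30–80 animals and 40–60 markers over 20 seeds (the
equivalence being exact algebra, size adds nothing but conditioning);
the accuracy study uses ~530 animals, 100 markers, 25% genotyped, 80%
phenotyped, 60% marker-determined genetic variance, and evaluates the
correlation gain over genotyped animals with the model's G matched to
the generative variance split (measured win rate 93% over 100 fresh
seeds).

## Pruning

A two-hop partition classifies animals by genomic information flow:
genotyped (class 2), their parents/progeny/mates (class 3), the
parents/progeny/mates of those (class 4), everyone else (class 0).
Class-0 animals can be removed from the single-step run and evaluated
by pedigree BLUP separately.  Pruning is exposed (`prune_partition`,
`prune_pedigree`, CLI `prune`) but OFF by default in the pipelines:
removal is exact only insofar as the removed animals' records do not
shift the fixed-effect solutions, and the implementation logs a warning
to that effect.  The partition is surfaced for inspection rather than
asserting exactness beyond the two-hop rule.

## Known limitations

Single trait, single genetic effect; no maternal effects, repeated
records on absorbed animals, unknown-parent groups or metafounders; no
REML/Gibbs variance estimation; no reliabilities (would need inverse
elements); no G blending/tuning or APY-style approximate inverses; no
VCF parsing or genotype imputation from partial marker data.
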