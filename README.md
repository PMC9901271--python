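# ssram — single-step genetic evaluation with reduced animal models

`ssram` solves Henderson's mixed-model equations for the genetic
evaluation of pedigreed populations, combining pedigree and genomic
information in a single step (ssGBLUP and the single-step marker model),
and implements three **reduced animal models**: equivalent reformulations
that set up equations for only a subset of animals and recover everyone
else's breeding value exactly by back-solving.  It is aimed at animal
breeders and quantitative geneticists who want a transparent, fully
tested reference implementation of these reductions at desk scale.

## The models

The full single-step animal model solves

```
[ X'R⁻¹X            X'R⁻¹Z          ] [b̂]   [X'R⁻¹y]
[ Z'R⁻¹X   Z'R⁻¹Z + H⁻¹ σₐ⁻²        ] [â] = [Z'R⁻¹y]
```

where `H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]` augments the sparse pedigree
inverse (Henderson's rules, inbreeding included) with a genomic
correction in the genotyped block.  The three reductions keep:

1. **Method 1** — genotyped animals + nongenotyped parents (`p`).
   Records of absorbed phenotyped nonparents enter through incidence
   rows of halves on their parents, with the Mendelian-sampling variance
   folded into the residual (`R̃ᵢᵢ = Rᵢᵢ + Dᵢσₐ²`).  Nonparents are
   back-solved by `âᵢ = Bᵢ(yᵢ − xᵢ'b̂ − PAᵢ) + PAᵢ`,
   `Bᵢ = Dᵢσₐ²/(Rᵢᵢ + Dᵢσₐ²)`, with `PA` the parent average.
2. **Method 2** — genotyped + nongenotyped phenotyped animals; absorbed
   animals carry no records and are recovered from pedigree-inverse
   blocks: `A^nn â_n = −A^np â_p`.
3. **Method 3** — genotyped animals + nongenotyped parents of phenotyped
   nongenotyped nonparents (`q`); the remaining nongenotyped parents
   (`r`) come from `A_pp⁻¹` blocks, then nonparents by the Mendelian
   regression.

All kept-set priors are exact subset inverses computed by the Schur
complement of the discarded block of `A⁻¹`, so every reduction
reproduces the full model to machine precision.  The single-step marker
model fits marker effects directly (imputed covariates, imputation
deviations ε and a residual polygenic effect δ) and admits the same
three reductions.

## Worked example

The package ships a 12-animal example (two genotyped animals with a
given 2×2 `G`, six phenotypes, σₐ² = 1, σₑ² = 2) for which every
intermediate matrix and solution is known.  `examples/01_full_single_step.py`:

```
system order: 14 (2 fixed effects + 12 animals)
fixed effects (mu, female vs male):
  mu             5.1938
  sex:female     0.3287
estimated breeding values:
  animal  1   -0.0476
  animal  2   -0.0414
  animal  3    0.1040
  ...
  animal 11    0.6534
  animal 12   -0.1217
```

`examples/02_reduced_models.py` shows the reductions shrinking the
system from 14 to 10, 8 and 7 equations while agreeing with the full
solutions to ~1e-15; `examples/03_marker_model.py` demonstrates the
marker-model equivalence, `04` the two-hop pruning partition, and `05` a
simulated accuracy comparison against pedigree BLUP.

The same computations are available from a shell:

```
ssram solve-ram --method 1 --pedigree ped.csv --phenotypes phe.csv \
      --g-matrix g.txt --fixed sex --sigma-a 1 --sigma-e 2 -o out/
```

with subcommands `solve-full`, `solve-ram`, `solve-ssmm`, `classify`,
`prune`, `simulate` and `validate`.

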