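"""Single-step marker model vs single-step GBLUP on simulated data.

The marker model fits marker effects directly, imputes marker covariates
for nongenotyped animals, and carries imputation deviations (epsilon) and
a residual polygenic effect (delta).  With centered genotypes scaled to
the relationship scale and sigma_a2 = sigma_alpha2 + sigma_delta2, its
total merit equals single-step GBLUP run on the blended genomic matrix
G_eq = (M2 M2' sigma_alpha2 + A22 sigma_delta2) / sigma_a2.
"""

import numpy as np

from ssram import (SimConfig, VarianceComponents, equivalent_g, run_ssmm,
                   simulate, solve_full, tabular_a)

d = simulate(SimConfig(seed=7, n_founders=12, n_generations=3, n_markers=50))
vc = VarianceComponents(sigma_a2=1.0, sigma_e2=2.0,
                        sigma_alpha2=0.6, sigma_delta2=0.4)
geno = [a for a in d.ped.labels if a in d.genotyped]
print(f"simulated {d.ped.n} animals, {len(geno)} genotyped, "
      f"{len(d.records)} phenotyped, {d.markers.n_markers} markers")

g_eq = equivalent_g(d.markers, tabular_a(d.ped, geno), vc)
ssgblup = solve_full(d.records, d.ped, vc, fixed=("sex",),
                     genotyped=geno, g=g_eq)
mm = run_ssmm(d.records, d.ped, d.genotyped, d.markers, vc,
              method="full", fixed=("sex",))
print(f"ssMM order {mm.diagnostics['order']} "
      f"(fixed + markers + epsilon + delta equations)")
print(f"max |ssMM total merit - ssGBLUP a_hat| = "
      f"{np.abs(mm.animal - ssgblup.animal).max():.2e}")

for m in (1, 2, 3):
    red = run_ssmm(d.records, d.ped, d.genotyped, d.markers, vc,
                   method=m, fixed=("sex",))
    print(f"reduced ssMM method {m}: order {red.diagnostics['order']}, "
          f"max |merit - full ssMM| = "
          f"{np.abs(red.animal - mm.animal).max():.2e}")

print("\nDifferences at machine precision confirm the model equivalences;")
print("the reductions only shrink the equation system, not the answer.")
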