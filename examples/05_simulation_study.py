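"""Accuracy gain from genomic information on one simulated herd.

Simulates a multi-generation pedigree whose true breeding values have a
marker-determined component, then compares pedigree BLUP with single-step
GBLUP (G matched to the generative variance split) by their correlation
with the simulated truth over the genotyped animals.
"""

import numpy as np

from ssram import (SimConfig, VarianceComponents, equivalent_g, simulate,
                   solve_full, tabular_a)

cfg = SimConfig(seed=3, n_founders=40, n_generations=5, progeny_per_mating=3,
                n_markers=100, genotyped_fraction=0.25,
                phenotyped_fraction=0.8, marker_variance_fraction=0.6)
d = simulate(cfg)
vc = VarianceComponents(sigma_a2=1.0, sigma_e2=2.0,
                        sigma_alpha2=0.6, sigma_delta2=0.4)
geno = [a for a in d.ped.labels if a in d.genotyped]
print(f"{d.ped.n} animals, {len(geno)} genotyped, {len(d.records)} records")

g = equivalent_g(d.markers, tabular_a(d.ped, geno), vc)
ss = solve_full(d.records, d.ped, vc, fixed=("sex",), genotyped=geno, g=g)
blup = solve_full(d.records, d.ped, vc, fixed=("sex",))

r_ss = np.corrcoef(ss.animal[geno], d.true_u[geno])[0, 1]
r_blup = np.corrcoef(blup.animal[geno], d.true_u[geno])[0, 1]
print(f"accuracy over genotyped animals (corr with true breeding values):")
print(f"  pedigree BLUP     {r_blup:.3f}")
print(f"  single-step GBLUP {r_ss:.3f}")
print("\nThe gap is the information added by the genotypes: realised")
print("marker sharing replaces expected pedigree relationships.")
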