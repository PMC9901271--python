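"""Synthetic pedigree/genotype/phenotype generator.

Generates data with exactly the statistical structure the models assume:
breeding values follow the pedigree recursion u_i = (u_s + u_d)/2 + m_i
with Mendelian-sampling deviations m_i ~ N(0, D_i σ_a²) (D_i accounting
for parental inbreeding, missing parents contributing zero), genotypes by
founder allele draws at frequency p_j followed by gene dropping of
independent loci (no linkage), and phenotypes y = Xb + u + e with
e ~ N(0, σ_e²).  Intended for equivalence and recovery testing, not for
biological realism: there is no LD, no selection and no QTL architecture
(markers are independent of u).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SsramError
from .genomic import MarkerData
from .pedigree import Pedigree
from .relationship import MendelianVariances, inbreeding


@dataclass
class SimConfig:
    """Study-design knobs of the generator.

    Defaults describe a small multi-generation herd: 20 founders, 4
    discrete generations with 2 progeny per mating, a 10% missing-parent
    rate (immigrant-like gaps), 60% of animals phenotyped, 30% genotyped,
    100 biallelic markers with Uniform(0.1, 0.9) founder frequencies, an
    intercept-plus-sex fixed structure and heritability 1/3
    (σ_a² = 1, σ_e² = 2).
    """

    n_founders: int = 20
    n_generations: int = 4
    progeny_per_mating: int = 2
    missing_sire_prob: float = 0.1
    missing_dam_prob: float = 0.1
    phenotyped_fraction: float = 0.6
    genotyped_fraction: float = 0.3
    n_markers: int = 100
    freq_low: float = 0.1
    freq_high: float = 0.9
    #: share of sigma_a2 explained by the markers (u = M alpha + delta);
    #: 0 makes the truth purely polygenic and the markers uninformative
    marker_variance_fraction: float = 0.5
    true_b: tuple[float, float] = (5.0, 0.5)  # intercept, female effect
    sigma_a2: float = 1.0
    sigma_e2: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "missing_sire_prob", "missing_dam_prob",
            "phenotyped_fraction", "genotyped_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SsramError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise SsramError("seed is mandatory")


@dataclass
class SimData:
    """One simulated dataset plus the truth used to generate it."""

    ped: Pedigree
    records: pd.DataFrame            # animal, value, sex (phenotyped subset)
    markers: MarkerData              # genotyped subset
    genotyped: frozenset
    sex: pd.Series                   # 'male'/'female' per animal
    true_u: pd.Series
    true_b: tuple[float, float]
    config: SimConfig


def draw_breeding_values(
    ped: Pedigree,
    mv: MendelianVariances,
    sigma_a2: float,
    rng: np.random.Generator,
    n_rep: int = 1,
) -> np.ndarray:
    """Draw u ~ N(0, A σ_a²) via the pedigree recursion; shape (n_rep, N).

    Also returns only u (the Mendelian deviations are u minus the parent
    average and can be recovered by the caller).
    """
    n = ped.n
    sd = np.sqrt(mv.D.to_numpy() * sigma_a2)
    ms = rng.standard_normal((n_rep, n)) * sd
    u = np.zeros((n_rep, n))
    for i in range(n):
        pa = np.zeros(n_rep)
        if ped.sire[i] != 0:
            pa += 0.5 * u[:, ped.sire[i] - 1]
        if ped.dam[i] != 0:
            pa += 0.5 * u[:, ped.dam[i] - 1]
        u[:, i] = pa + ms[:, i]
    return u


def _gene_drop(
    ped: Pedigree, freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Allele counts (N × markers) by independent-locus gene dropping."""
    n, m = ped.n, len(freqs)
    gametes = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        for k, par in enumerate((ped.sire[i], ped.dam[i])):
            if par == 0:
                gametes[i, k] = rng.random(m) < freqs
            else:
                pick = rng.integers(0, 2, size=m)
                gametes[i, k] = gametes[par - 1, pick, np.arange(m)]
    return gametes.sum(axis=1).astype(float)


def simulate(cfg: SimConfig) -> SimData:
    """Generate one dataset, reproducible by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    # -- pedigree: discrete generations, random matings within the previous
    rows: list[tuple[int, int | None, int | None]] = []
    sex: dict[int, str] = {}
    next_id = 1
    prev: list[int] = []
    for _ in range(cfg.n_founders):
        rows.append((next_id, None, None))
        sex[next_id] = "male" if next_id % 2 == 0 else "female"
        prev.append(next_id)
        next_id += 1
    for _ in range(cfg.n_generations - 1):
        males = [a for a in prev if sex[a] == "male"]
        females = [a for a in prev if sex[a] == "female"]
        if not males or not females:
            raise SsramError("cannot mate: a generation lacks one sex")
        gen: list[int] = []
        for dam in females:
            sire = int(rng.choice(males))
            for _ in range(cfg.progeny_per_mating):
                s = None if rng.random() < cfg.missing_sire_prob else sire
                d = None if rng.random() < cfg.missing_dam_prob else dam
                rows.append((next_id, s, d))
                sex[next_id] = "male" if next_id % 2 == 0 else "female"
                gen.append(next_id)
                next_id += 1
        prev = gen
    ped = Pedigree.from_records(rows)
    sex_s = pd.Series({a: sex[a] for a in ped.labels})

    # -- genotypes for every animal (a subset is observed later)
    freqs = rng.uniform(cfg.freq_low, cfg.freq_high, size=cfg.n_markers)
    counts = _gene_drop(ped, freqs, rng)

    # -- true breeding values: marker component plus residual polygenic,
    # u = M alpha + delta, so Var(u) = A sigma_a2 marginally while the
    # markers actually carry signal about realised genetic merit
    mv = inbreeding(ped)
    frac = cfg.marker_variance_fraction
    if not 0.0 <= frac <= 1.0:
        raise SsramError("marker_variance_fraction must be in [0, 1]")
    u = np.zeros(ped.n)
    if frac > 0 and cfg.n_markers > 0:
        k = 2.0 * np.sum(freqs * (1.0 - freqs))
        mc = (counts - 2.0 * freqs) / np.sqrt(k)
        alpha = rng.normal(0.0, np.sqrt(frac * cfg.sigma_a2), size=cfg.n_markers)
        u += mc @ alpha
    if frac < 1.0:
        u += draw_breeding_values(ped, mv, (1.0 - frac) * cfg.sigma_a2, rng)[0]
    true_u = pd.Series(u, index=list(ped.labels))

    n_pheno = max(1, int(round(cfg.phenotyped_fraction * ped.n)))
    pheno = sorted(rng.choice(ped.n, size=n_pheno, replace=False))
    if not pheno:
        raise SsramError("degenerate config: no phenotyped animals")
    mu, b_sex = cfg.true_b
    rec = []
    for i in pheno:
        a = ped.labels[i]
        xb = mu + (b_sex if sex_s[a] == "female" else 0.0)
        y = xb + u[i] + rng.normal(0.0, np.sqrt(cfg.sigma_e2))
        rec.append({"animal": a, "value": y, "sex": sex_s[a]})
    records = pd.DataFrame(rec)

    # -- observed genotype subset
    n_geno = max(1, int(round(cfg.genotyped_fraction * ped.n)))
    geno_idx = sorted(rng.choice(ped.n, size=n_geno, replace=False))
    geno_labels = [ped.labels[i] for i in geno_idx]
    cols = [f"m{j+1}" for j in range(cfg.n_markers)]
    # center at the true founder frequencies: keeps G full-rank for
    # n_genotyped < n_markers (observed-frequency centering always leaves
    # the ones-vector in the null space of M_c M_c')
    markers = MarkerData(
        pd.DataFrame(counts[geno_idx], index=geno_labels, columns=cols),
        allele_freq=pd.Series(freqs, index=cols),
    )
    return SimData(
        ped=ped,
        records=records,
        markers=markers,
        genotyped=frozenset(geno_labels),
        sex=sex_s,
        true_u=true_u,
        true_b=cfg.true_b,
        config=cfg,
    )
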