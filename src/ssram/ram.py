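"""Reduced animal models for single-step evaluation, with exact back-solving.

Three equivalent reductions of the full single-step system are provided.
Each solves a smaller symmetric system for a kept subset of animals and
recovers the remaining breeding values exactly afterwards:

* Method 1 keeps genotyped animals and nongenotyped parents (``p``).
  Records of absorbed phenotyped nonparents enter through an incidence
  row of halves on their known parents (W), with the Mendelian-sampling
  variance folded into the record's residual, R̃_ii = R_ii + D_i σ_a².
  Nonparents are back-solved by the Mendelian-sampling regression
  â_i = B_i (y_i − x_i′b̂ − PA_i) + PA_i with B_i = D_i σ_a² / (R_ii + D_i σ_a²)
  and PA the parent average (a missing parent contributes zero).
* Method 2 keeps genotyped animals and nongenotyped phenotyped animals;
  absorbed animals carry no records, so the design is untouched and the
  kept-block prior is the subset inverse A_pp⁻¹ (plus the genomic
  correction).  Absorbed animals are back-solved from the pedigree-only
  inverse blocks:  A^nn â_n = −A^np â_p.
* Method 3 reduces Method 1 further to genotyped animals and nongenotyped
  parents of phenotyped nongenotyped nonparents (``q``).  The remaining
  nongenotyped parents (``r``) are back-solved first from A_pp⁻¹ blocks,
  then nonparents by the Mendelian regression with parents drawn from
  q ∪ r.

All back-solving uses pedigree-derived matrices only; the genomic
correction G⁻¹ − A22⁻¹ never leaves the reduced system's genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, SolverError
from .evaluation import (
    Design,
    EquationSystem,
    SolutionSet,
    VarianceComponents,
    assemble_blocks,
    build_design,
    solve,
)
from .genomic import MarkerData, build_g, h_inverse, invert_g
from .lmatrix import Label, LabeledSymMatrix
from .pedigree import AnimalSets, Pedigree, classify_animals
from .relationship import MendelianVariances, a_inverse, inbreeding, subset_inverse


@dataclass(frozen=True)
class MendelianEntry:
    """Back-solve bookkeeping for one absorbed nonparent."""

    animal: Label
    sire: Label | None
    dam: Label | None
    B: float
    y: float | None  # None: no record; back-solve reduces to parent average
    xrow: np.ndarray | None


@dataclass
class BacksolvePlan:
    """Mendelian-sampling back-solve entries plus fixed-effect layout."""

    entries: list[MendelianEntry]
    fixed_names: tuple[str, ...]


@dataclass
class ReducedDesign:
    """Record-level design of a reduced system.

    ``W`` has identity rows for records of kept animals and rows of halves
    (on the known parents) for records of absorbed phenotyped nonparents;
    ``r_tilde_inv`` is the corresponding diagonal of R̃⁻¹, inflated by the
    Mendelian-sampling variance D_i σ_a² on absorbed-animal records only.
    """

    method: int
    kept: tuple[Label, ...]
    W: np.ndarray
    X: np.ndarray
    y: np.ndarray
    r_tilde_inv: np.ndarray
    fixed_names: tuple[str, ...]
    record_animals: tuple[Label, ...]
    absorbed_n: tuple[Label, ...]
    plan: BacksolvePlan = field(repr=False, default=None)


def _pedigree_order(ped: Pedigree, labels: Iterable[Label]) -> tuple[Label, ...]:
    s = set(labels)
    return tuple(l for l in ped.labels if l in s)


def build_reduced_design(
    records: pd.DataFrame,
    ped: Pedigree,
    sets: AnimalSets,
    mv: MendelianVariances,
    vc: VarianceComponents,
    method: int,
    fixed: Sequence[str] = (),
) -> ReducedDesign:
    """Build W, X and R̃⁻¹ for the requested reduction."""
    if method not in (1, 2, 3):
        raise ValueError("method must be 1, 2 or 3")
    kept = _pedigree_order(ped, sets.kept(method))
    kept_pos = {lab: i for i, lab in enumerate(kept)}
    base = build_design(records, ped, fixed=fixed, sigma_e2=vc.sigma_e2)

    n_rec = len(base.y)
    W = np.zeros((n_rec, len(kept)))
    r_tilde_inv = np.empty(n_rec)
    entries: dict[Label, MendelianEntry] = {}
    seen_absorbed: set[Label] = set()
    for r, a in enumerate(base.record_animals):
        if a in kept_pos:
            W[r, kept_pos[a]] = 1.0
            r_tilde_inv[r] = base.r_inv[r]
            continue
        if method == 2:
            # absorbed animals are nonphenotyped by classification
            raise DesignError(
                f"Method 2 absorbed animal {a!r} has a record; classification bug"
            )
        if a in seen_absorbed:
            raise DesignError(
                f"absorbed animal {a!r} has multiple records; the Mendelian-sampling "
                "absorption assumes a single record per absorbed animal"
            )
        seen_absorbed.add(a)
        s, d = ped.parents_of(a)
        for par in (s, d):
            if par is not None:
                if par not in kept_pos:
                    raise DesignError(
                        f"parent {par!r} of absorbed phenotyped animal {a!r} is not kept; "
                        "classification bug"
                    )
                W[r, kept_pos[par]] += 0.5
        d_i = mv.d_of(a)
        r_ii = 1.0 / base.r_inv[r]
        r_tilde_inv[r] = 1.0 / (r_ii + d_i * vc.sigma_a2)
        entries[a] = MendelianEntry(
            animal=a,
            sire=s,
            dam=d,
            B=d_i * vc.sigma_a2 / (r_ii + d_i * vc.sigma_a2),
            y=float(base.y[r]),
            xrow=base.X[r].copy(),
        )

    # nonparents absorbed without records (their back-solve is the parent average)
    absorbed = {1: sets.method1_n, 2: sets.method2_n, 3: sets.method3_n}[method]
    if method in (1, 3):
        for a in _pedigree_order(ped, absorbed):
            if a in entries:
                continue
            s, d = ped.parents_of(a)
            d_i = mv.d_of(a)
            entries[a] = MendelianEntry(
                animal=a,
                sire=s,
                dam=d,
                B=d_i * vc.sigma_a2 / (vc.sigma_e2 + d_i * vc.sigma_a2),
                y=None,
                xrow=None,
            )
    ordered = [entries[a] for a in _pedigree_order(ped, entries)]
    return ReducedDesign(
        method=method,
        kept=kept,
        W=W,
        X=base.X,
        y=base.y,
        r_tilde_inv=r_tilde_inv,
        fixed_names=base.fixed_names,
        record_animals=base.record_animals,
        absorbed_n=tuple(_pedigree_order(ped, absorbed)),
        plan=BacksolvePlan(entries=ordered, fixed_names=base.fixed_names),
    )


def assemble_reduced(
    rd: ReducedDesign, h_reduced_inv: LabeledSymMatrix, vc: VarianceComponents
) -> EquationSystem:
    """Reduced MME: [X′R̃⁻¹X, X′R̃⁻¹W; W′R̃⁻¹X, W′R̃⁻¹W + H_kept⁻¹ σ_a⁻²]."""
    if set(h_reduced_inv.labels) != set(rd.kept):
        raise DesignError("reduced prior must be built on exactly the kept animals")
    prior = h_reduced_inv.reordered(rd.kept).to_dense() / vc.sigma_a2
    blocks = [
        ("fixed", rd.fixed_names, rd.X, None),
        ("animal", rd.kept, rd.W, prior),
    ]
    return assemble_blocks(blocks, rd.r_tilde_inv, rd.y)


# ---------------------------------------------------------------------------
# back-solving
# ---------------------------------------------------------------------------

def backsolve_mendelian(sol: SolutionSet, plan: BacksolvePlan) -> SolutionSet:
    """Recover absorbed nonparents by the Mendelian-sampling regression.

    â_i = B_i (y_i − x_i′b̂ − PA_i) + PA_i, with PA_i the mean of available
    parent solutions (a missing parent contributes zero, so one known
    parent gives â_parent / 2).  Animals without a record get â_i = PA_i,
    which is the same formula with the adjusted record replaced by PA_i.
    """
    b = sol.fixed.to_numpy()
    animal = sol.animal.copy()
    prov = sol.provenance.copy()
    adj = {}
    for e in plan.entries:
        pa = 0.0
        for par in (e.sire, e.dam):
            if par is not None:
                if par not in animal.index:
                    raise SolverError(
                        f"parent {par!r} of {e.animal!r} unsolved before back-solve "
                        "(ordering bug)"
                    )
                pa += 0.5 * float(animal[par])
        if e.y is None:
            a_hat = pa
            adj[e.animal] = pa
        else:
            resid = e.y - float(e.xrow @ b)
            adj[e.animal] = resid
            a_hat = e.B * (resid - pa) + pa
        animal[e.animal] = a_hat
        prov[e.animal] = "backsolved"
    sol.animal = animal
    sol.provenance = prov
    sol.diagnostics.setdefault("adjusted_record", pd.Series(dtype=float))
    sol.diagnostics["adjusted_record"] = pd.Series(adj, dtype=float)
    sol.diagnostics["B"] = pd.Series({e.animal: e.B for e in plan.entries}, dtype=float)
    return sol


def backsolve_absorbed(
    sol: SolutionSet,
    a_inv_blocks: LabeledSymMatrix,
    absorbed: Sequence[Label],
    source: Sequence[Label] | None = None,
) -> SolutionSet:
    """Recover absorbed animals from pedigree-inverse blocks.

    Solves Q_nn â_n = −Q_ns â_s with Q a pedigree-only inverse (the full
    A⁻¹ for Method 2, A_pp⁻¹ for Method 3's r animals); no genomic terms
    enter.  Q_nn is a principal submatrix of a positive-definite matrix,
    hence nonsingular.
    """
    absorbed = list(absorbed)
    if not absorbed:
        return sol
    if source is None:
        source = [l for l in a_inv_blocks.labels if l not in set(absorbed)]
    q_nn = a_inv_blocks.block(absorbed, absorbed)
    q_ns = a_inv_blocks.block(absorbed, list(source))
    a_s = sol.animal.reindex(list(source)).to_numpy()
    if np.isnan(a_s).any():
        raise SolverError("source animals unsolved before absorbed back-solve")
    a_n = np.linalg.solve(q_nn, -q_ns @ a_s)
    animal = sol.animal.copy()
    prov = sol.provenance.copy()
    for lab, v in zip(absorbed, a_n):
        animal[lab] = float(v)
        prov[lab] = "backsolved"
    sol.animal = animal
    sol.provenance = prov
    return sol


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def run_ram(
    records: pd.DataFrame,
    ped: Pedigree,
    genotyped: Iterable[Label],
    vc: VarianceComponents,
    method: int,
    fixed: Sequence[str] = (),
    g: LabeledSymMatrix | None = None,
    markers: MarkerData | None = None,
    with_inbreeding: bool = True,
    solver: str = "auto",
    tol: float = 1e-12,
) -> SolutionSet:
    """Run a reduced single-step evaluation end to end.

    Returns a complete :class:`SolutionSet`: kept animals solved directly,
    absorbed animals tagged ``backsolved``.  With neither ``g`` nor
    ``markers``, the reduction runs on plain pedigree BLUP.
    """
    genotyped = frozenset(genotyped)
    phenotyped = frozenset(records["animal"])
    sets = classify_animals(ped, genotyped, phenotyped)
    mv = inbreeding(ped, with_inbreeding=with_inbreeding)
    a_inv = a_inverse(ped, with_inbreeding=with_inbreeding)

    kept = _pedigree_order(ped, sets.kept(method))
    a_kept_inv = subset_inverse(a_inv, kept)
    if g is None and markers is not None:
        g = build_g(markers)
    if g is not None:
        geno_order = _pedigree_order(ped, genotyped)
        if set(g.labels) != set(geno_order):
            raise DesignError("G labels must be exactly the genotyped animals")
        a22_inv = subset_inverse(a_inv, geno_order)
        h_kept_inv = h_inverse(a_kept_inv, invert_g(g.reordered(geno_order)), a22_inv)
    else:
        h_kept_inv = a_kept_inv

    rd = build_reduced_design(records, ped, sets, mv, vc, method, fixed=fixed)
    sys = assemble_reduced(rd, h_kept_inv, vc)
    sol = solve(sys, method=solver, tol=tol, tag=f"ram{method}")
    sol.diagnostics["fixed_names"] = rd.fixed_names
    sol.diagnostics["kept"] = kept

    if method == 1:
        sol = backsolve_mendelian(sol, rd.plan)
    elif method == 2:
        sol = backsolve_absorbed(
            sol, a_inv, _pedigree_order(ped, sets.method2_n), source=kept
        )
    else:  # method 3: r from A_pp⁻¹ blocks, then nonparents by regression
        p_order = _pedigree_order(ped, sets.method1_p)
        r_order = _pedigree_order(ped, sets.method3_r)
        if r_order:
            a_pp_inv = subset_inverse(a_inv, p_order)
            sol = backsolve_absorbed(sol, a_pp_inv, r_order, source=kept)
        sol = backsolve_mendelian(sol, rd.plan)

    sol.animal = sol.animal.reindex(list(ped.labels))
    sol.provenance = sol.provenance.reindex(list(ped.labels))
    if sol.animal.isna().any():
        missing = list(sol.animal.index[sol.animal.isna()])
        raise SolverError(f"animals left unsolved after back-solving: {missing}")
    return sol
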