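"""Single-step marker model (ssMM) and its three reductions.

Instead of a combined relationship matrix, the marker model fits marker
effects α directly.  Nongenotyped animals receive imputed marker
covariates M₁ (solved from A⁻¹ blocks: A^11 M₁ = −A^12 M₂) plus a
per-animal imputation deviation ε with prior precision A^11 σ_α⁻²; every
animal additionally carries a residual polygenic effect δ with prior
precision A⁻¹ σ_δ⁻².  Total genetic merit is M₂α̂ + δ̂ for genotyped
animals and M₁α̂ + ε̂ + δ̂ for nongenotyped ones.

Centered genotypes are scaled by 1/sqrt(2 Σ p_j (1 − p_j)) by default so
that M M′ sits on the relationship scale; this makes the single variance
σ_α² act coherently as both the marker-effect prior and the ε prior, and
makes the model numerically equivalent to ssGBLUP run on
G_eq = (M₂M₂′ σ_α² + A22 σ_δ²) / (σ_α² + σ_δ²).  A raw mode accepts a
user-centered M as is.

The reductions mirror the animal-model ones: the δ equations shrink to
the kept animals with prior (subset inverse) blocks, the ε equations to
the nongenotyped kept animals, records of absorbed phenotyped nonparents
enter through rows of halves with the Mendelian-sampling inflation
R̃_ii = R_ii + D_i σ_a² (σ_a² = σ_α² + σ_δ²), and back-solving recovers δ
and ε for the absorbed animals from pedigree blocks or the Mendelian
regression — never touching genomic equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, SolverError
from .evaluation import (
    EquationSystem,
    SolutionSet,
    VarianceComponents,
    assemble_blocks,
    build_design,
    solve,
)
from .genomic import MarkerData
from .lmatrix import Label, LabeledSymMatrix
from .pedigree import AnimalSets, Pedigree, classify_animals
from .ram import _pedigree_order
from .relationship import MendelianVariances, a_inverse, inbreeding, subset_inverse


def impute_m1(
    a_inv_like: LabeledSymMatrix, m2: pd.DataFrame
) -> pd.DataFrame:
    """Impute marker covariates for nongenotyped animals.

    Solves Q_11 M₁ = −Q_12 M₂ where Q is any pedigree inverse
    (the full A⁻¹ or a subset inverse) whose labels include the genotyped
    animals of ``m2``; rows are returned for every other label of Q.
    A terminal nongenotyped animal's row is the average of its known
    parents' rows.
    """
    geno = [l for l in a_inv_like.labels if l in set(m2.index)]
    nongeno = [l for l in a_inv_like.labels if l not in set(m2.index)]
    if not nongeno:
        return pd.DataFrame(np.empty((0, m2.shape[1])), index=[], columns=m2.columns)
    q11 = a_inv_like.block(nongeno, nongeno)
    q12 = a_inv_like.block(nongeno, geno)
    rhs = -q12 @ m2.loc[geno].to_numpy()
    m1 = np.linalg.solve(q11, rhs)
    return pd.DataFrame(m1, index=nongeno, columns=m2.columns)


@dataclass
class SsmmSystem:
    """Assembled marker-model system plus the pieces back-solving needs."""

    eqs: EquationSystem
    kept: tuple[Label, ...]
    nongeno_kept: tuple[Label, ...]
    marker_names: tuple[str, ...]
    m_kept: pd.DataFrame  # marker covariates (observed or imputed) of kept animals
    fixed_names: tuple[str, ...]


def _sigma_a2(vc: VarianceComponents) -> float:
    if vc.sigma_alpha2 is None or vc.sigma_delta2 is None:
        raise DesignError("the marker model needs sigma_alpha2 and sigma_delta2")
    return vc.sigma_alpha2 + vc.sigma_delta2


def assemble_ssmm(
    records: pd.DataFrame,
    ped: Pedigree,
    sets: AnimalSets,
    mv: MendelianVariances,
    markers: MarkerData,
    vc: VarianceComponents,
    fixed: Sequence[str] = (),
    method: str | int = "full",
    a_inv: LabeledSymMatrix | None = None,
    scaled: bool = True,
) -> SsmmSystem:
    """Assemble the full or reduced marker-model equations.

    With zero markers the α and ε blocks vanish and the system collapses
    to (reduced) pedigree BLUP on δ.
    """
    if a_inv is None:
        a_inv = a_inverse(ped)
    sigma_a2 = _sigma_a2(vc)
    geno_set = set(markers.animals)
    if geno_set != set(sets.genotyped):
        raise DesignError("marker rows must be exactly the genotyped animals")

    if method == "full":
        kept = tuple(ped.labels)
        q = a_inv
    elif method in (1, 2, 3):
        kept = _pedigree_order(ped, sets.kept(method))
        q = subset_inverse(a_inv, kept)
    else:
        raise ValueError(f"unknown ssMM method {method!r}")
    kept_pos = {lab: i for i, lab in enumerate(kept)}
    nongeno_kept = tuple(l for l in kept if l not in geno_set)

    have_markers = markers.n_markers > 0 and markers.polymorphic().any()
    if have_markers:
        m2 = markers.centered(scaled=scaled)
        m1 = impute_m1(q, m2)
        m_kept = (pd.concat([m2, m1]) if len(m1) else m2).loc[list(kept)]
        marker_names = tuple(m2.columns)
    else:
        m_kept = pd.DataFrame(np.empty((len(kept), 0)), index=list(kept))
        marker_names = ()

    base = build_design(records, ped, fixed=fixed, sigma_e2=vc.sigma_e2)
    n_rec = len(base.y)
    n_mark = len(marker_names)
    T_alpha = np.zeros((n_rec, n_mark))
    T_eps = np.zeros((n_rec, len(nongeno_kept)))
    T_delta = np.zeros((n_rec, len(kept)))
    eps_pos = {lab: i for i, lab in enumerate(nongeno_kept)}
    r_inv = np.empty(n_rec)
    mkv = m_kept.to_numpy()
    seen_absorbed: set[Label] = set()
    for r, a in enumerate(base.record_animals):
        if a in kept_pos:
            T_delta[r, kept_pos[a]] = 1.0
            if a in eps_pos:
                T_eps[r, eps_pos[a]] = 1.0
            if n_mark:
                T_alpha[r] = mkv[kept_pos[a]]
            r_inv[r] = base.r_inv[r]
            continue
        if method == 2 or method == "full":
            raise DesignError(
                f"absorbed animal {a!r} has a record; classification bug"
            )
        if a in seen_absorbed:
            raise DesignError(
                f"absorbed animal {a!r} has multiple records; unsupported"
            )
        seen_absorbed.add(a)
        for par in ped.parents_of(a):
            if par is None:
                continue
            if par not in kept_pos:
                raise DesignError(
                    f"parent {par!r} of absorbed phenotyped animal {a!r} not kept"
                )
            T_delta[r, kept_pos[par]] += 0.5
            if n_mark:
                T_alpha[r] += 0.5 * mkv[kept_pos[par]]
            if par in eps_pos:
                T_eps[r, eps_pos[par]] += 0.5
        r_ii = 1.0 / base.r_inv[r]
        r_inv[r] = 1.0 / (r_ii + mv.d_of(a) * sigma_a2)

    blocks = [("fixed", base.fixed_names, base.X, None)]
    if n_mark:
        blocks.append(
            ("marker", marker_names, T_alpha, np.eye(n_mark) / vc.sigma_alpha2)
        )
        if nongeno_kept:
            q11 = q.block(list(nongeno_kept), list(nongeno_kept))
            blocks.append(("epsilon", nongeno_kept, T_eps, q11 / vc.sigma_alpha2))
    blocks.append(
        ("delta", kept, T_delta, q.reordered(kept).to_dense() / vc.sigma_delta2)
    )
    eqs = assemble_blocks(blocks, r_inv, base.y)
    return SsmmSystem(
        eqs=eqs,
        kept=kept,
        nongeno_kept=nongeno_kept,
        marker_names=marker_names,
        m_kept=m_kept,
        fixed_names=base.fixed_names,
    )


def total_merit(
    alpha: pd.Series | None,
    epsilon: pd.Series | None,
    delta: pd.Series,
    m_rows: pd.DataFrame,
    genotyped: Iterable[Label],
) -> pd.Series:
    """Merit per animal: M₂α̂ + δ̂ (genotyped) or M₁α̂ + ε̂ + δ̂ (nongenotyped)."""
    geno = set(genotyped)
    out = {}
    for a in delta.index:
        v = float(delta[a])
        if alpha is not None and len(alpha):
            v += float(m_rows.loc[a].to_numpy() @ alpha.to_numpy())
        if a not in geno and epsilon is not None and a in epsilon.index:
            v += float(epsilon[a])
        out[a] = v
    return pd.Series(out, dtype=float)


def run_ssmm(
    records: pd.DataFrame,
    ped: Pedigree,
    genotyped: Iterable[Label],
    markers: MarkerData,
    vc: VarianceComponents,
    method: str | int = "full",
    fixed: Sequence[str] = (),
    scaled: bool = True,
    with_inbreeding: bool = True,
    solver: str = "auto",
    tol: float = 1e-12,
) -> SolutionSet:
    """Run the (reduced) single-step marker model end to end.

    The returned ``SolutionSet`` carries α̂, ε̂ (nongenotyped animals), δ̂
    and per-animal total merit; ``animal`` holds the merit so the result
    is directly comparable with a ssGBLUP run.
    """
    genotyped = frozenset(genotyped)
    phenotyped = frozenset(records["animal"])
    sets = classify_animals(ped, genotyped, phenotyped)
    mv = inbreeding(ped, with_inbreeding=with_inbreeding)
    a_inv = a_inverse(ped, with_inbreeding=with_inbreeding)
    sigma_a2 = _sigma_a2(vc)

    sys = assemble_ssmm(
        records, ped, sets, mv, markers, vc,
        fixed=fixed, method=method, a_inv=a_inv, scaled=scaled,
    )
    sol = solve(sys.eqs, method=solver, tol=tol, tag=f"ssmm-{method}")
    sol.diagnostics["fixed_names"] = sys.fixed_names
    if sol.delta is None:
        raise SolverError("marker-model solve returned no delta block")

    alpha = sol.alpha
    eps = sol.epsilon if sol.epsilon is not None else pd.Series(dtype=float)
    delta = sol.delta
    prov = pd.Series("direct", index=list(sys.kept), dtype=object)
    m_all = sys.m_kept

    if method != "full":
        have_markers = len(sys.marker_names) > 0
        # marker covariates for every animal, for merit and parent averages
        if have_markers:
            m2 = markers.centered(scaled=scaled)
            m1_all = impute_m1(a_inv, m2)
            m_all = (pd.concat([m2, m1_all]) if len(m1_all) else m2).loc[
                list(ped.labels)]
        else:
            m_all = pd.DataFrame(np.empty((ped.n, 0)), index=list(ped.labels))

        def absorbed_linear(qmat: LabeledSymMatrix, absorbed, source):
            """δ and ε back-solves from pedigree blocks (Eq.-9 style)."""
            nonlocal delta, eps
            absorbed = list(absorbed)
            if not absorbed:
                return
            src = list(source)
            q_nn = qmat.block(absorbed, absorbed)
            d_n = np.linalg.solve(
                q_nn, -qmat.block(absorbed, src) @ delta.reindex(src).to_numpy()
            )
            delta = pd.concat([delta, pd.Series(d_n, index=absorbed)])
            src_ng = [l for l in src if l not in genotyped]
            if have_markers:
                e_src = eps.reindex(src_ng).to_numpy() if src_ng else np.zeros(0)
                e_n = np.linalg.solve(
                    q_nn,
                    -qmat.block(absorbed, src_ng) @ e_src
                    if src_ng
                    else np.zeros(len(absorbed)),
                )
                eps = pd.concat([eps, pd.Series(e_n, index=absorbed)])

        def absorbed_mendelian(absorbed, b_hat):
            """Joint δ/ε Mendelian regression for absorbed nonparents."""
            nonlocal delta, eps
            rec = records.set_index("animal", drop=False)
            base = build_design(records, ped, fixed=fixed, sigma_e2=vc.sigma_e2)
            xrows = {a: base.X[i] for i, a in enumerate(base.record_animals)}
            rvars = {a: 1.0 / base.r_inv[i] for i, a in enumerate(base.record_animals)}
            for a in _pedigree_order(ped, absorbed):
                s, d = ped.parents_of(a)
                pa_delta = sum(0.5 * float(delta[p]) for p in (s, d) if p is not None)
                pa_eps = sum(
                    0.5 * float(eps[p])
                    for p in (s, d)
                    if p is not None and p not in genotyped
                )
                if have_markers:
                    m_i = np.zeros(m_all.shape[1])
                    for p in (s, d):
                        if p is not None:
                            m_i += 0.5 * m_all.loc[p].to_numpy()
                    m_all.loc[a] = m_i
                if a in xrows:
                    d_i = mv.d_of(a)
                    denom = rvars[a] + d_i * sigma_a2
                    resid = float(rec.loc[a, "value"]) - float(xrows[a] @ b_hat)
                    resid -= pa_delta + pa_eps
                    if have_markers:
                        resid -= float(m_i @ alpha.to_numpy())
                    delta[a] = pa_delta + d_i * vc.sigma_delta2 / denom * resid
                    if have_markers:
                        eps[a] = pa_eps + d_i * vc.sigma_alpha2 / denom * resid
                else:
                    delta[a] = pa_delta
                    if have_markers:
                        eps[a] = pa_eps

        b_hat = sol.fixed.to_numpy()
        if method == 1:
            absorbed_mendelian(_pedigree_order(ped, sets.method1_n), b_hat)
            backsolved = sets.method1_n
        elif method == 2:
            absorbed_linear(
                a_inv, _pedigree_order(ped, sets.method2_n), source=sys.kept
            )
            backsolved = sets.method2_n
        else:
            p_order = _pedigree_order(ped, sets.method1_p)
            r_order = _pedigree_order(ped, sets.method3_r)
            if r_order:
                a_pp_inv = subset_inverse(a_inv, p_order)
                absorbed_linear(a_pp_inv, r_order, source=sys.kept)
            absorbed_mendelian(_pedigree_order(ped, sets.method3_n), b_hat)
            backsolved = sets.method3_n | sets.method3_r
        prov = pd.concat(
            [prov, pd.Series("backsolved", index=list(backsolved), dtype=object)]
        )

    merit = total_merit(alpha, eps, delta, m_all, genotyped)
    order = list(ped.labels)
    sol.delta = delta.reindex(order)
    sol.epsilon = eps.reindex([l for l in order if l not in genotyped]) if len(eps) else eps
    sol.merit = merit.reindex(order)
    sol.animal = sol.merit.copy()
    sol.provenance = prov.reindex(order)
    if sol.animal.isna().any():
        missing = list(sol.animal.index[sol.animal.isna()])
        raise SolverError(f"animals left unsolved after ssMM back-solving: {missing}")
    return sol


def equivalent_g(
    markers: MarkerData, a22: LabeledSymMatrix, vc: VarianceComponents
) -> LabeledSymMatrix:
    """The ssGBLUP G that makes the two single-step forms numerically equal:
    G_eq = (M₂M₂′ σ_α² + A22 σ_δ²) / (σ_α² + σ_δ²), with M₂ on the
    relationship scale."""
    sigma_a2 = _sigma_a2(vc)
    m2 = markers.centered(scaled=True)
    m2 = m2.loc[list(a22.labels)].to_numpy()
    g = (m2 @ m2.T * vc.sigma_alpha2 + a22.to_dense() * vc.sigma_delta2) / sigma_a2
    g = 0.5 * (g + g.T)
    return LabeledSymMatrix(g, a22.labels, role="G_eq")
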