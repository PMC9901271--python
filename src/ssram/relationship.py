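"""Pedigree-based numerator relationship machinery.

Provides the tabular relationship matrix A (the slow, transparent oracle),
inbreeding coefficients F and Mendelian-sampling variance ratios D via a
Meuwissen–Luo style recursion, Henderson's sparse rules for A⁻¹, and subset
inverses (A22⁻¹, A_pp⁻¹, A_qq⁻¹) through the Schur complement
A_SS⁻¹ = Q_SS − Q_SN Q_NN⁻¹ Q_NS of the full inverse Q = A⁻¹.

All matrices are returned as :class:`~ssram.lmatrix.LabeledSymMatrix` keyed
by external animal labels.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import MatrixError
from .lmatrix import Label, LabeledSymMatrix
from .pedigree import UNKNOWN, Pedigree

#: below this order A⁻¹ is kept dense; above, compressed sparse
DENSE_FALLBACK_N = 2000


@dataclass(frozen=True)
class MendelianVariances:
    """Per-animal inbreeding F and Mendelian-sampling variance ratio D.

    D_i is the diagonal of D in the decomposition A = TDT′:
    0.5 − 0.25(F_s + F_d) with both parents known, 0.75 − 0.25 F_known with
    one, and 1 with none.  The Mendelian-sampling variance itself is
    D_i σ_a².
    """

    F: pd.Series
    D: pd.Series

    def d_of(self, label: Label) -> float:
        return float(self.D[label])


def inbreeding(ped: Pedigree, with_inbreeding: bool = True) -> MendelianVariances:
    """Compute F and D for every animal.

    Uses the Meuwissen–Luo recursion: the diagonal a_ii = Σ_j L_ij² d_j is
    accumulated by walking each animal's ancestor list once, pushing halved
    path coefficients onto parents; F_i = a_ii − 1.  With
    ``with_inbreeding=False``, F is forced to zero and D depends only on
    how many parents are known (0.5 / 0.75 / 1).
    """
    n = ped.n
    sire = ped.sire
    dam = ped.dam
    F = np.zeros(n)
    d_tilde = np.empty(n)  # within-family variance given parent F

    def _d(i: int) -> float:
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            return 0.5 - 0.25 * (F[s - 1] + F[d - 1])
        if s != UNKNOWN:
            return 0.75 - 0.25 * F[s - 1]
        if d != UNKNOWN:
            return 0.75 - 0.25 * F[d - 1]
        return 1.0

    if with_inbreeding:
        for i in range(n):
            d_tilde[i] = _d(i)
            if sire[i] == UNKNOWN or dam[i] == UNKNOWN:
                F[i] = 0.0  # needs both parents to be inbred
                continue
            # accumulate a_ii = sum_j L_ij^2 d_j over ancestors j of i,
            # visiting codes in decreasing order so parents collect the
            # full halved path coefficients before being expanded
            weights: dict[int, float] = {i: 1.0}
            heap = [-i]
            aii = 0.0
            while heap:
                j = -heapq.heappop(heap)
                w = weights.pop(j, 0.0)
                if w == 0.0:
                    continue
                aii += w * w * d_tilde[j]
                for par in (sire[j], dam[j]):
                    if par != UNKNOWN:
                        p = par - 1
                        if p not in weights:
                            weights[p] = 0.5 * w
                            heapq.heappush(heap, -p)
                        else:
                            weights[p] += 0.5 * w
            F[i] = aii - 1.0
        D = np.array([_d(i) for i in range(n)])
    else:
        both = (sire != UNKNOWN) & (dam != UNKNOWN)
        one = ((sire != UNKNOWN) | (dam != UNKNOWN)) & ~both
        D = np.where(both, 0.5, np.where(one, 0.75, 1.0))
    idx = list(ped.labels)
    return MendelianVariances(F=pd.Series(F, index=idx), D=pd.Series(D, index=idx))


def tabular_a(ped: Pedigree, subset: Iterable[Label] | None = None) -> LabeledSymMatrix:
    """Relationship matrix A by the recursive tabular method.

    With ``subset`` given, the table is built over the subset's ancestor
    closure and then sliced, so the result is the exact principal submatrix
    of the full A on those animals (in the order given).
    """
    if subset is None:
        wanted = list(ped.labels)
        needed_idx = np.arange(ped.n)
    else:
        wanted = list(subset)
        for lab in wanted:
            if lab not in ped.code:
                raise MatrixError(f"animal {lab!r} not in pedigree")
        need = set()
        stack = [ped.code[lab] - 1 for lab in wanted]
        while stack:
            i = stack.pop()
            if i in need:
                continue
            need.add(i)
            for par in (ped.sire[i], ped.dam[i]):
                if par != UNKNOWN:
                    stack.append(par - 1)
        needed_idx = np.array(sorted(need), dtype=int)

    pos = {i: k for k, i in enumerate(needed_idx)}
    m = len(needed_idx)
    a = np.zeros((m, m))
    for k, i in enumerate(needed_idx):
        s = pos.get(ped.sire[i] - 1) if ped.sire[i] != UNKNOWN else None
        d = pos.get(ped.dam[i] - 1) if ped.dam[i] != UNKNOWN else None
        for j in range(k):
            val = 0.0
            if s is not None:
                val += 0.5 * a[j, s]
            if d is not None:
                val += 0.5 * a[j, d]
            a[k, j] = a[j, k] = val
        diag = 1.0
        if s is not None and d is not None:
            diag += 0.5 * a[s, d]
        a[k, k] = diag
    labels_built = [ped.labels[i] for i in needed_idx]
    full = LabeledSymMatrix(a, labels_built, role="A")
    if subset is None:
        return full
    return full.submatrix(wanted, role="A")


def a_inverse(ped: Pedigree, with_inbreeding: bool = True) -> LabeledSymMatrix:
    """Sparse A⁻¹ by Henderson's rules.

    For each animal i with Mendelian variance ratio D_i, add 1/D_i at
    (i,i), −1/(2D_i) at (i, parent) and 1/(4D_i) at every (parent, parent′)
    pair over the known parents.
    """
    mv = inbreeding(ped, with_inbreeding=with_inbreeding)
    n = ped.n
    rows, cols, vals = [], [], []
    dinv = 1.0 / mv.D.to_numpy()
    for i in range(n):
        di = dinv[i]
        pars = [p - 1 for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i)
        cols.append(i)
        vals.append(di)
        for p in pars:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * di, -0.5 * di]
        for p in pars:
            for q in pars:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * di)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if n < DENSE_FALLBACK_N:
        return LabeledSymMatrix(mat.toarray(), ped.labels, role="A_inv")
    return LabeledSymMatrix(mat, ped.labels, role="A_inv")


def subset_inverse(a_inv: LabeledSymMatrix, keep: Iterable[Label]) -> LabeledSymMatrix:
    """Inverse of the A-slice on ``keep`` without forming A.

    Schur complement of the discarded block of Q = A⁻¹:
    ``A_SS⁻¹ = Q_SS − Q_SN Q_NN⁻¹ Q_NS``.  Valid for any subset, whether or
    not it is closed under ancestry.  Q_NN is a principal submatrix of a
    positive-definite matrix and therefore nonsingular.
    """
    keep = list(keep)
    keep_set = set(keep)
    if not keep_set <= set(a_inv.labels):
        missing = sorted(keep_set - set(a_inv.labels), key=str)
        raise MatrixError(f"keep labels not in matrix: {missing}")
    drop = [l for l in a_inv.labels if l not in keep_set]
    if not drop:
        return a_inv.reordered(keep)
    q_ss = a_inv.block(keep, keep)
    q_sn = a_inv.block(keep, drop)
    q_ns = q_sn.T
    if a_inv.is_sparse() and len(drop) > 50:
        q_nn = sp.csc_matrix(
            a_inv.values[np.ix_(a_inv.positions(drop), a_inv.positions(drop))]
        )
        lu = spla.splu(q_nn)
        sol = lu.solve(q_ns)
    else:
        q_nn = a_inv.block(drop, drop)
        sol = np.linalg.solve(q_nn, q_ns)
    out = q_ss - q_sn @ sol
    out = 0.5 * (out + out.T)
    return LabeledSymMatrix(out, keep, role=f"{a_inv.role}_subset")
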