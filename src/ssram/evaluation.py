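"""Design matrices, mixed-model equation assembly, and linear solving.

The full single-step system is Henderson's MME

    [ X′R⁻¹X            X′R⁻¹Z        ] [b̂]   [X′R⁻¹y]
    [ Z′R⁻¹X   Z′R⁻¹Z + H⁻¹ σ_a⁻²     ] [â] = [Z′R⁻¹y]

with X the fixed-effect incidence (intercept plus reference-coded
dummies), Z the 0/1 record-by-animal incidence, R the diagonal residual
(co)variance and H⁻¹ the combined pedigree+genomic inverse (A⁻¹ for plain
pedigree BLUP).  The same assembler serves the reduced systems (W in
place of Z) and the marker model (extra effect blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DesignError, SolverError
from .genomic import MarkerData, build_g, h_inverse, invert_g
from .lmatrix import Label, LabeledSymMatrix
from .pedigree import Pedigree
from .relationship import a_inverse, subset_inverse

#: above this system order the default solver switches to preconditioned CG
DIRECT_SOLVE_MAX_N = 10_000


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the models.

    sigma_a2/sigma_e2 are the additive-genetic and residual variances of
    the animal models; sigma_alpha2/sigma_delta2 are the marker-part and
    residual-polygenic variances of the marker model (on the relationship
    scale, so sigma_a2 = sigma_alpha2 + sigma_delta2 for equivalence).
    """

    sigma_a2: float
    sigma_e2: float
    sigma_alpha2: float | None = None
    sigma_delta2: float | None = None

    def __post_init__(self):
        for name in ("sigma_a2", "sigma_e2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("sigma_alpha2", "sigma_delta2"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when given")


@dataclass
class Design:
    """Record-level design: X, Z and the diagonal R⁻¹."""

    X: np.ndarray
    Z: np.ndarray
    r_inv: np.ndarray
    y: np.ndarray
    fixed_names: tuple[str, ...]
    animal_labels: tuple[Label, ...]
    record_animals: tuple[Label, ...]


def build_design(
    records: pd.DataFrame,
    ped: Pedigree,
    fixed: Sequence[str] = (),
    sigma_e2: float = 1.0,
    animal_labels: Sequence[Label] | None = None,
) -> Design:
    """Build X (intercept + reference-coded factors), Z and diagonal R⁻¹.

    ``records`` must carry columns ``animal`` and ``value``; each name in
    ``fixed`` is a categorical column whose first-seen level becomes the
    reference.  An optional ``residual_variance`` column overrides σ_e²
    per record.  Z columns follow ``animal_labels`` (default: pedigree
    order).
    """
    if "animal" not in records or "value" not in records:
        raise DesignError("records need 'animal' and 'value' columns")
    rec_animals = list(records["animal"])
    for a in rec_animals:
        if a not in ped.code:
            raise DesignError(f"record animal {a!r} not in pedigree")
    n_rec = len(records)

    cols = [np.ones(n_rec)]
    names = ["mu"]
    for f in fixed:
        if f not in records:
            raise DesignError(f"fixed-effect column {f!r} not in records")
        levels = list(dict.fromkeys(records[f]))
        for lev in levels[1:]:
            cols.append((records[f] == lev).to_numpy(float))
            names.append(f"{f}:{lev}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            f"fixed-effect design is rank deficient; confounded columns among {names}"
        )

    if animal_labels is None:
        animal_labels = ped.labels
    animal_labels = tuple(animal_labels)
    pos = {lab: i for i, lab in enumerate(animal_labels)}
    Z = np.zeros((n_rec, len(animal_labels)))
    for r, a in enumerate(rec_animals):
        Z[r, pos[a]] = 1.0

    if "residual_variance" in records:
        rvar = records["residual_variance"].fillna(sigma_e2).to_numpy(float)
    else:
        rvar = np.full(n_rec, float(sigma_e2))
    if np.any(rvar <= 0):
        raise DesignError("residual variances must be > 0")
    y = records["value"].to_numpy(float)
    return Design(
        X=X,
        Z=Z,
        r_inv=1.0 / rvar,
        y=y,
        fixed_names=tuple(names),
        animal_labels=animal_labels,
        record_animals=tuple(rec_animals),
    )


# ---------------------------------------------------------------------------
# equation system
# ---------------------------------------------------------------------------

@dataclass
class EquationSystem:
    """Assembled symmetric system with an effect-descriptor index.

    ``index`` entries are (kind, label) with kind in
    {"fixed", "animal", "marker", "epsilon", "delta"}.
    """

    lhs: np.ndarray
    rhs: np.ndarray
    index: tuple[tuple[str, Label], ...]

    @property
    def order(self) -> int:
        return len(self.index)


def assemble_blocks(
    blocks: Sequence[tuple[str, Sequence[Label], np.ndarray, np.ndarray | None]],
    r_inv: np.ndarray,
    y: np.ndarray,
) -> EquationSystem:
    """Generic MME assembler.

    Each block is (kind, labels, T_block, prior) where T_block is the
    record-by-effect design columns for that block and ``prior`` (may be
    None) is the symmetric matrix added to the block diagonal of the LHS.
    """
    T = np.hstack([b[2] for b in blocks])
    index: list[tuple[str, Label]] = []
    for kind, labels, tb, _ in blocks:
        if tb.shape[1] != len(labels):
            raise DesignError("block width does not match its labels")
        index.extend((kind, lab) for lab in labels)
    TR = T.T * r_inv
    lhs = TR @ T
    rhs = TR @ y
    off = 0
    for kind, labels, tb, prior in blocks:
        k = tb.shape[1]
        if prior is not None:
            p = prior.toarray() if sp.issparse(prior) else np.asarray(prior)
            if p.shape != (k, k):
                raise DesignError(f"prior shape {p.shape} for block {kind!r} of width {k}")
            lhs[off : off + k, off : off + k] += p
        off += k
    lhs = 0.5 * (lhs + lhs.T)
    return EquationSystem(lhs=lhs, rhs=rhs, index=tuple(index))


def assemble_full(
    design: Design, k_inv: LabeledSymMatrix, vc: VarianceComponents
) -> EquationSystem:
    """Full animal-model MME with genetic prior K⁻¹/σ_a² (K = H or A)."""
    if tuple(k_inv.labels) != design.animal_labels:
        k_inv = k_inv.reordered(design.animal_labels)
    prior = k_inv.to_dense() / vc.sigma_a2
    blocks = [
        ("fixed", design.fixed_names, design.X, None),
        ("animal", design.animal_labels, design.Z, prior),
    ]
    return assemble_blocks(blocks, design.r_inv, design.y)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

@dataclass
class SolutionSet:
    """Solutions keyed by effect labels, with per-animal provenance.

    ``animal`` is the additive genetic merit per animal (â for the animal
    models; marker merit plus deviations for the marker model).
    ``provenance`` records whether an animal was solved directly in the
    equation system or recovered by back-solving.
    """

    method: str
    fixed: pd.Series
    animal: pd.Series
    provenance: pd.Series
    alpha: pd.Series | None = None
    epsilon: pd.Series | None = None
    delta: pd.Series | None = None
    merit: pd.Series | None = None
    diagnostics: dict = field(default_factory=dict)

    def residual_norm(self) -> float | None:
        return self.diagnostics.get("residual_norm")


def _raw_solve(lhs: np.ndarray, rhs: np.ndarray, method: str, tol: float) -> tuple[np.ndarray, float]:
    n = lhs.shape[0]
    if method == "direct" or (method == "auto" and n <= DIRECT_SOLVE_MAX_N):
        try:
            x = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as e:
            raise SolverError(f"direct solve failed: {e}") from None
    elif method in ("pcg", "auto"):
        diag = np.diag(lhs).copy()
        if np.any(diag <= 0):
            raise SolverError("Jacobi preconditioner needs positive diagonal")
        M = sp.diags(1.0 / diag)
        A = sp.csr_matrix(lhs)
        trace: list[float] = []

        def cb(xk):
            trace.append(float(np.linalg.norm(A @ xk - rhs)))

        x, info = spla.cg(A, rhs, rtol=tol, atol=0.0, M=M, maxiter=10 * n, callback=cb)
        if info != 0:
            raise SolverError(
                f"PCG did not converge (info={info}); residual trace tail {trace[-5:]}"
            )
    else:
        raise ValueError(f"unknown solver method {method!r}")
    denom = float(np.linalg.norm(rhs))
    resid = float(np.linalg.norm(lhs @ x - rhs)) / (denom if denom > 0 else 1.0)
    if method == "direct" and not np.all(np.isfinite(x)):
        raise SolverError("direct solve produced non-finite solutions (singular system?)")
    return x, resid


def solve(sys: EquationSystem, method: str = "auto", tol: float = 1e-12,
          tag: str = "full") -> SolutionSet:
    """Solve the assembled system and map solutions back to labels."""
    x, resid = _raw_solve(np.asarray(sys.lhs), np.asarray(sys.rhs), method, tol)
    buckets: dict[str, dict[Label, float]] = {}
    for (kind, lab), v in zip(sys.index, x):
        buckets.setdefault(kind, {})[lab] = float(v)
    animal = pd.Series(buckets.get("animal", {}), dtype=float)
    sol = SolutionSet(
        method=tag,
        fixed=pd.Series(buckets.get("fixed", {}), dtype=float),
        animal=animal,
        provenance=pd.Series("direct", index=animal.index, dtype=object),
        alpha=pd.Series(buckets["marker"], dtype=float) if "marker" in buckets else None,
        epsilon=pd.Series(buckets["epsilon"], dtype=float) if "epsilon" in buckets else None,
        delta=pd.Series(buckets["delta"], dtype=float) if "delta" in buckets else None,
        diagnostics={"residual_norm": resid, "order": sys.order},
    )
    return sol


# ---------------------------------------------------------------------------
# end-to-end full models
# ---------------------------------------------------------------------------

def solve_full(
    records: pd.DataFrame,
    ped: Pedigree,
    vc: VarianceComponents,
    fixed: Sequence[str] = (),
    genotyped: Iterable[Label] | None = None,
    g: LabeledSymMatrix | None = None,
    markers: MarkerData | None = None,
    with_inbreeding: bool = True,
    solver: str = "auto",
    tol: float = 1e-12,
) -> SolutionSet:
    """Full ssGBLUP (or pedigree BLUP when no genomic input is given).

    ``g`` takes precedence over ``markers``; with neither, the genetic
    prior is the plain pedigree A⁻¹.
    """
    a_inv = a_inverse(ped, with_inbreeding=with_inbreeding)
    if g is None and markers is not None:
        g = build_g(markers)
    if g is not None:
        geno = tuple(g.labels) if genotyped is None else tuple(genotyped)
        g = g.reordered(geno)
        a22_inv = subset_inverse(a_inv, geno)
        k_inv = h_inverse(a_inv, invert_g(g), a22_inv)
        tag = "full-ssgblup"
    else:
        k_inv = a_inv
        tag = "full-blup"
    design = build_design(records, ped, fixed=fixed, sigma_e2=vc.sigma_e2)
    sys = assemble_full(design, k_inv, vc)
    sol = solve(sys, method=solver, tol=tol, tag=tag)
    sol.diagnostics["fixed_names"] = design.fixed_names
    return sol
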