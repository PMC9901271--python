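"""Labelled symmetric matrices.

Relationship-type matrices (A, A⁻¹, A22⁻¹, G, G⁻¹, H⁻¹ and their subset
counterparts) are carried around together with the animal labels indexing
their rows/columns, so that every downstream operation places entries by
label rather than by position.  The numeric payload may be a dense
``numpy.ndarray`` or any ``scipy.sparse`` matrix; symmetry is enforced at
construction.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import MatrixError

Label = Hashable

_SYM_TOL = 1e-12


class LabeledSymMatrix:
    """A symmetric matrix with an ordered animal-label index.

    Parameters
    ----------
    values
        Square symmetric matrix (dense array or scipy sparse).
    labels
        Row/column labels, unique, in matrix order.
    role
        Free-form tag describing what the matrix is (``"A_inv"``, ``"G"``,
        ...); informational only.
    """

    def __init__(self, values, labels: Sequence[Label], role: str = ""):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise MatrixError("duplicate labels in matrix index")
        if values.shape != (len(labels), len(labels)):
            raise MatrixError(
                f"matrix shape {values.shape} does not match {len(labels)} labels"
            )
        if sp.issparse(values):
            values = values.tocsr()
            asym = abs(values - values.T)
            max_asym = asym.max() if asym.nnz else 0.0
        else:
            values = np.asarray(values, dtype=float)
            max_asym = float(np.max(np.abs(values - values.T))) if values.size else 0.0
        scale = self._scale(values)
        if max_asym > _SYM_TOL * max(1.0, scale):
            raise MatrixError(f"matrix is not symmetric (max asymmetry {max_asym:g})")
        self.values = values
        self.labels = labels
        self.role = role
        self._pos = {lab: i for i, lab in enumerate(labels)}

    @staticmethod
    def _scale(values) -> float:
        if sp.issparse(values):
            return float(abs(values).max()) if values.nnz else 0.0
        return float(np.max(np.abs(values))) if values.size else 0.0

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: Label) -> int:
        try:
            return self._pos[label]
        except KeyError:
            raise MatrixError(f"label {label!r} not in matrix index") from None

    def loc(self, i: Label, j: Label) -> float:
        """Element by (row label, column label)."""
        return float(self.values[self.index_of(i), self.index_of(j)])

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    # -- slicing ---------------------------------------------------------
    def positions(self, labels: Iterable[Label]) -> np.ndarray:
        return np.array([self.index_of(l) for l in labels], dtype=int)

    def block(self, rows: Sequence[Label], cols: Sequence[Label]) -> np.ndarray:
        """Dense rectangular block addressed by labels."""
        r = self.positions(rows)
        c = self.positions(cols)
        if sp.issparse(self.values):
            return self.values[np.ix_(r, c)].toarray()
        return self.values[np.ix_(r, c)]

    def submatrix(self, labels: Sequence[Label], role: str | None = None) -> "LabeledSymMatrix":
        """Principal submatrix on ``labels`` (in the order given)."""
        labels = tuple(labels)
        vals = self.block(labels, labels)
        vals = 0.5 * (vals + vals.T)
        return LabeledSymMatrix(vals, labels, role or self.role)

    def reordered(self, labels: Sequence[Label]) -> "LabeledSymMatrix":
        labels = tuple(labels)
        if set(labels) != set(self.labels):
            raise MatrixError("reordered() requires the same label set")
        return self.submatrix(labels)

    # -- arithmetic ------------------------------------------------------
    def add_block(self, other: "LabeledSymMatrix") -> "LabeledSymMatrix":
        """Return self with ``other`` added into the equations of its labels.

        Placement is by label, independent of position; every label of
        ``other`` must exist in self.
        """
        rows = self.positions(other.labels)
        add = other.to_dense()
        if sp.issparse(self.values):
            out = self.values.tolil(copy=True)
            out[np.ix_(rows, rows)] = out[np.ix_(rows, rows)].toarray() + add
            return LabeledSymMatrix(out.tocsr(), self.labels, self.role)
        out = self.to_dense().copy()
        out[np.ix_(rows, rows)] += add
        return LabeledSymMatrix(out, self.labels, self.role)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "sparse" if self.is_sparse() else "dense"
        tag = f" role={self.role}" if self.role else ""
        return f"<LabeledSymMatrix {self.n}x{self.n} {kind}{tag}>"


def from_triplets(
    entries: Iterable[tuple[Label, Label, float]],
    labels: Sequence[Label] | None = None,
    role: str = "",
    sparse: bool = False,
) -> LabeledSymMatrix:
    """Build a symmetric matrix from (row_label, col_label, value) triplets.

    Each off-diagonal triplet is mirrored; duplicated coordinates accumulate.
    """
    entries = list(entries)
    if labels is None:
        seen: dict[Label, None] = {}
        for r, c, _ in entries:
            seen.setdefault(r)
            seen.setdefault(c)
        labels = tuple(seen)
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    rows, cols, vals = [], [], []
    for r, c, v in entries:
        i, j = pos[r], pos[c]
        rows.append(i)
        cols.append(j)
        vals.append(v)
        if i != j:
            rows.append(j)
            cols.append(i)
            vals.append(v)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    if sparse:
        return LabeledSymMatrix(mat.tocsr(), labels, role)
    return LabeledSymMatrix(mat.toarray(), labels, role)
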