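"""Genomic relationship handling and single-step H⁻¹ assembly.

The genomic relationship matrix G is built from allele counts by the
first VanRaden method, G = M_c M_c′ / k with M_c centered at twice the
allele frequency and k = 2 Σ p_j (1 − p_j).  H⁻¹ assembly adds
G⁻¹ − A22⁻¹ into the genotyped block of any pedigree inverse (the full
A⁻¹ or a subset inverse A_pp⁻¹ / A_qq⁻¹), placed by animal label.  No
blending or scaling of G toward A22 is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MatrixError
from .lmatrix import Label, LabeledSymMatrix

_PD_TOL = 1e-8


@dataclass
class MarkerData:
    """Allele-count matrix for genotyped animals with centering metadata.

    Parameters
    ----------
    counts
        DataFrame of allele counts in {0,1,2}, rows indexed by animal
        label, one column per marker.
    allele_freq
        Per-marker allele frequency p_j.  Computed from the data
        (column mean / 2) when not supplied, e.g. from a frequency file.
    """

    counts: pd.DataFrame
    allele_freq: pd.Series | None = None

    def __post_init__(self):
        counts = self.counts.astype(float)
        if not counts.index.is_unique:
            raise MatrixError("duplicate animal labels in genotype table")
        if np.isnan(counts.to_numpy()).any():
            raise MatrixError("missing genotypes are not supported")
        self.counts = counts
        if self.allele_freq is None:
            self.allele_freq = counts.mean(axis=0) / 2.0
        else:
            self.allele_freq = pd.Series(self.allele_freq, index=counts.columns, dtype=float)

    @property
    def animals(self) -> tuple[Label, ...]:
        return tuple(self.counts.index)

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    def polymorphic(self) -> np.ndarray:
        p = self.allele_freq.to_numpy()
        return (p > 0.0) & (p < 1.0)

    @property
    def scale_k(self) -> float:
        """2 Σ p_j (1 − p_j) over polymorphic markers."""
        p = self.allele_freq.to_numpy()[self.polymorphic()]
        return float(2.0 * np.sum(p * (1.0 - p)))

    def centered(self, scaled: bool = False) -> pd.DataFrame:
        """Centered allele counts M_c = counts − 2p (polymorphic markers).

        With ``scaled=True`` columns are further divided by sqrt(k) so that
        M M′ is on the relationship scale (M M′ = G).
        """
        keep = self.polymorphic()
        if not keep.any():
            raise MatrixError("all markers are monomorphic")
        counts = self.counts.loc[:, keep]
        p = self.allele_freq.to_numpy()[keep]
        m = counts - 2.0 * p
        if scaled:
            m = m / np.sqrt(self.scale_k)
        return m


def build_g(markers: MarkerData, method: str = "vanraden1") -> LabeledSymMatrix:
    """Genomic relationship matrix G = M_c M_c′ / (2 Σ p(1−p))."""
    if method != "vanraden1":
        raise ValueError(f"unknown G method {method!r}")
    mc = markers.centered().to_numpy()
    k = markers.scale_k
    if k <= 0:
        raise MatrixError("all markers are monomorphic; G undefined")
    g = mc @ mc.T / k
    g = 0.5 * (g + g.T)
    return LabeledSymMatrix(g, markers.animals, role="G")


def invert_g(g: LabeledSymMatrix) -> LabeledSymMatrix:
    """Exact inverse of a positive-definite G.

    Raises when the smallest eigenvalue is below tolerance; a singular G
    typically means too few markers relative to genotyped animals and is
    conventionally repaired by blending with A22 (not done here).
    """
    dense = g.to_dense()
    eigmin = float(np.linalg.eigvalsh(dense)[0])
    if eigmin < _PD_TOL:
        raise MatrixError(
            f"G is not positive-definite (min eigenvalue {eigmin:.3e}); "
            "consider blending with A22 before inversion"
        )
    inv = np.linalg.inv(dense)
    inv = 0.5 * (inv + inv.T)
    return LabeledSymMatrix(inv, g.labels, role="G_inv")


def h_inverse(
    a_inv: LabeledSymMatrix,
    g_inv: LabeledSymMatrix,
    a22_inv: LabeledSymMatrix,
) -> LabeledSymMatrix:
    """Single-step inverse: a pedigree inverse plus (G⁻¹ − A22⁻¹) in the
    genotyped block.

    ``a_inv`` may be the full A⁻¹ or any subset inverse whose labels
    contain the genotyped animals; the correction is placed by label, so
    the genotyped animals' position within the matrix is irrelevant.
    """
    if set(g_inv.labels) != set(a22_inv.labels):
        raise MatrixError("G⁻¹ and A22⁻¹ must index the same genotyped animals")
    if not set(g_inv.labels) <= set(a_inv.labels):
        missing = sorted(set(g_inv.labels) - set(a_inv.labels), key=str)
        raise MatrixError(f"genotyped animals missing from pedigree inverse: {missing}")
    corr = LabeledSymMatrix(
        g_inv.to_dense() - a22_inv.reordered(g_inv.labels).to_dense(),
        g_inv.labels,
        role="G_inv-A22_inv",
    )
    out = a_inv.add_block(corr)
    return LabeledSymMatrix(out.values, out.labels, role="H_inv")
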