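"""The 12-animal worked example shipped with the package.

A small pedigree of 12 animals (odd identifiers female, even male), two of
them genotyped (5 and 10, with a given 2×2 genomic relationship matrix),
six phenotyped, one categorical fixed effect (sex, male reference) and
known variances σ_a² = 1, σ_e² = 2.  Every intermediate matrix and every
solution vector of the full single-step evaluation and of the three
reduced models is known for this dataset, so it doubles as the package's
primary verification fixture: ``expected()`` returns the catalogue of
reference values the test suite asserts against.

The parentage is: 1, 2, 3 founders; 4 out of dam 1; 5 and 6 out of sire 2;
7 out of dam 3; 8 out of sire 4; 9 = 4×5; 10 = 6×5; 11 = 6×7; 12 = 4×7.
Animal 10 is inbred (F = 0.125: its parents are paternal half-sibs), which
exercises the inbreeding path of A22 while leaving A⁻¹ without parental-
inbreeding adjustments (no inbred animal has progeny).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import VarianceComponents
from .lmatrix import LabeledSymMatrix
from .pedigree import Pedigree

PEDIGREE_ROWS = [
    (1, 0, 0),
    (2, 0, 0),
    (3, 0, 0),
    (4, 0, 1),
    (5, 2, 0),
    (6, 2, 0),
    (7, 0, 3),
    (8, 4, 0),
    (9, 4, 5),
    (10, 6, 5),
    (11, 6, 7),
    (12, 4, 7),
]

GENOTYPED = (5, 10)
PHENOTYPES = {4: 5.64, 5: 4.30, 9: 4.32, 10: 5.39, 11: 7.72, 12: 4.36}
G_MATRIX = np.array([[0.96, 0.56], [0.56, 1.16]])
SIGMA_A2 = 1.0
SIGMA_E2 = 2.0


def sex_of(animal: int) -> str:
    return "female" if animal % 2 == 1 else "male"


@dataclass
class PaperExample:
    """Inputs of the worked example, ready to feed the pipelines."""

    ped: Pedigree
    records: pd.DataFrame
    genotyped: tuple[int, ...]
    g: LabeledSymMatrix
    vc: VarianceComponents
    fixed: tuple[str, ...]


def load_paper_example() -> PaperExample:
    ped = Pedigree.from_records(PEDIGREE_ROWS)
    records = pd.DataFrame(
        [
            {"animal": a, "value": y, "sex": sex_of(a)}
            for a, y in PHENOTYPES.items()
        ]
    )
    g = LabeledSymMatrix(G_MATRIX, GENOTYPED, role="G")
    vc = VarianceComponents(sigma_a2=SIGMA_A2, sigma_e2=SIGMA_E2)
    return PaperExample(
        ped=ped, records=records, genotyped=GENOTYPED, g=g, vc=vc, fixed=("sex",)
    )


def expected() -> dict:
    """Reference catalogue for the worked example (4-dp decimals, exact
    rationals where the quantity is a small integer over 6 or 3)."""
    a_inv_6 = np.array(
        [
            [8, 0, 0, -4, 0, 0, 0, 0, 0, 0, 0, 0],
            [0, 10, 0, 0, -4, -4, 0, 0, 0, 0, 0, 0],
            [0, 0, 8, 0, 0, 0, -4, 0, 0, 0, 0, 0],
            [-4, 0, 0, 16, 3, 0, 3, -4, -6, 0, 0, -6],
            [0, -4, 0, 3, 14, 3, 0, 0, -6, -6, 0, 0],
            [0, -4, 0, 0, 3, 14, 3, 0, 0, -6, -6, 0],
            [0, 0, -4, 3, 0, 3, 14, 0, 0, 0, -6, -6],
            [0, 0, 0, -4, 0, 0, 0, 8, 0, 0, 0, 0],
            [0, 0, 0, -6, -6, 0, 0, 0, 12, 0, 0, 0],
            [0, 0, 0, 0, -6, -6, 0, 0, 0, 12, 0, 0],
            [0, 0, 0, 0, 0, -6, -6, 0, 0, 0, 12, 0],
            [0, 0, 0, -6, 0, 0, -6, 0, 0, 0, 0, 12],
        ],
        dtype=float,
    )
    a_pp_inv_6 = np.array(  # Method 1 kept set (1..7, 10)
        [
            [8, 0, 0, -4, 0, 0, 0, 0],
            [0, 10, 0, 0, -4, -4, 0, 0],
            [0, 0, 8, 0, 0, 0, -4, 0],
            [-4, 0, 0, 8, 0, 0, 0, 0],
            [0, -4, 0, 0, 11, 3, 0, -6],
            [0, -4, 0, 0, 3, 11, 0, -6],
            [0, 0, -4, 0, 0, 0, 8, 0],
            [0, 0, 0, 0, -6, -6, 0, 12],
        ],
        dtype=float,
    )
    a_pp_inv_m2 = np.array(  # Method 2 kept set (4, 5, 9, 10, 11, 12)
        [
            [1.8670, 0.5150, -1.0, -0.0644, 0.2017, -0.7339],
            [0.5150, 2.0386, -1.0, -0.8798, 0.0901, -0.0300],
            [-1.0, -1.0, 2.0, 0.0, 0.0, 0.0],
            [-0.0644, -0.8798, 0.0, 1.4850, -0.3863, 0.1288],
            [0.2017, 0.0901, 0.0, -0.3863, 1.2103, -0.4034],
            [-0.7339, -0.0300, 0.0, 0.1288, -0.4034, 1.4678],
        ]
    )
    a_qq_inv_3 = np.array(  # Method 3 kept set (4, 5, 6, 7, 10)
        [
            [3, 0, 0, 0, 0],
            [0, 4.7, 0.7, 0, -3],
            [0, 0.7, 4.7, 0, -3],
            [0, 0, 0, 3, 0],
            [0, -3, -3, 0, 6],
        ],
        dtype=float,
    )
    w_m1 = np.array(  # records (4,5,9,10,11,12) × kept (1..7,10)
        [
            [0, 0, 0, 1, 0, 0, 0, 0],
            [0, 0, 0, 0, 1, 0, 0, 0],
            [0, 0, 0, 0.5, 0.5, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0, 1],
            [0, 0, 0, 0, 0, 0.5, 0.5, 0],
            [0, 0, 0, 0.5, 0, 0, 0.5, 0],
        ]
    )
    w_q_m3 = np.array(  # records (4,5,9,10,11,12) × kept (4,5,6,7,10)
        [
            [1, 0, 0, 0, 0],
            [0, 1, 0, 0, 0],
            [0.5, 0.5, 0, 0, 0],
            [0, 0, 0, 0, 1],
            [0, 0, 0.5, 0.5, 0],
            [0.5, 0, 0, 0.5, 0],
        ]
    )
    a_hat = {
        1: -0.0476, 2: -0.0414, 3: 0.1040, 4: -0.0953, 5: -0.4302, 6: 0.3268,
        7: 0.2080, 8: -0.0476, 9: -0.4507, 10: 0.0255, 11: 0.6534, 12: -0.1217,
    }
    return {
        "b_hat": {"mu": 5.1938, "sex:female": 0.3287},
        "a_hat": a_hat,
        "x_sex_column": {4: 0, 5: 1, 9: 1, 10: 0, 11: 1, 12: 0},
        "g_inv": np.array([[1.45, -0.7], [-0.7, 1.2]]),
        "a22_inv": np.array([[1.5319, -0.8511], [-0.8511, 1.3617]]),
        "a_inv_x6": a_inv_6,
        "a_pp_inv_x6_order": (1, 2, 3, 4, 5, 6, 7, 10),
        "a_pp_inv_x6": a_pp_inv_6,
        "a_pp_inv_m2_order": (4, 5, 9, 10, 11, 12),
        "a_pp_inv_m2": a_pp_inv_m2,
        "a_qq_inv_x3_order": (4, 5, 6, 7, 10),
        "a_qq_inv_x3": a_qq_inv_3,
        "d_nn": {9: 0.5, 11: 0.5, 12: 0.5},
        "r_tilde_nn": {9: 0.4, 11: 0.4, 12: 0.4},
        "w_m1_records": (4, 5, 9, 10, 11, 12),
        "w_m1": w_m1,
        "w_q_m3": w_q_m3,
        "b_diag": {8: 3.0 / 11.0, 9: 0.2, 11: 0.2, 12: 0.2},
        "m1_kept": (1, 2, 3, 4, 5, 6, 7, 10),
        "m1_a_p": {1: -0.0476, 2: -0.0414, 3: 0.1040, 4: -0.0953,
                   5: -0.4302, 6: 0.3268, 7: 0.2080, 10: 0.0255},
        "m1_adjusted": {9: -1.2025, 11: 2.1975, 12: -0.8338},
        "m1_a_n": {8: -0.0476, 9: -0.4507, 11: 0.6534, 12: -0.1217},
        "m2_kept": (4, 5, 9, 10, 11, 12),
        "m2_a_p": {4: -0.0953, 5: -0.4302, 9: -0.4507, 10: 0.0255,
                   11: 0.6534, 12: -0.1217},
        "m2_a_n": {1: -0.0476, 2: -0.0414, 3: 0.1040, 6: 0.3268,
                   7: 0.2080, 8: -0.0476},
        "m3_kept": (4, 5, 6, 7, 10),
        # animal 6 omitted: its kept-set value equals the full-model 0.3268
        "m3_a_q": {4: -0.0953, 5: -0.4302, 7: 0.2080, 10: 0.0255},
        "m3_a_n": {8: -0.0476, 9: -0.4507, 11: 0.6534, 12: -0.1217},
        "m3_a_r": {1: -0.0476, 2: -0.0414, 3: 0.1040},
        "prune_class0": (3,),
        "f_10": 0.125,
        "a_5_10": 0.625,
        "a_10_10": 1.125,
    }
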