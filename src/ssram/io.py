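"""File formats and run configuration.

Plain-text exchange formats only: pedigree and phenotype CSV/TSV, a
whitespace genotype table (animal label followed by 0/1/2 allele counts),
the lower-triangle "row_label col_label value" triplet format customary
for relationship matrices in breeding software, and a solutions CSV with
a provenance column.  Floats are written with 12 significant digits so a
write/read cycle reproduces the numbers to that precision.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError
from .evaluation import SolutionSet, VarianceComponents
from .genomic import MarkerData
from .lmatrix import LabeledSymMatrix, from_triplets
from .pedigree import Pedigree

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# phenotypes & genotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Phenotype table: columns ``animal``, ``value`` plus fixed-effect
    columns; header required."""
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    for col in ("animal", "value"):
        if col not in df.columns:
            raise FormatError(f"phenotype file {path} lacks column {col!r}")
    df["animal"] = [int(a) if str(a).lstrip("-").isdigit() else a for a in df["animal"]]
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return df


def read_genotypes(path, allele_freq: pd.Series | None = None) -> MarkerData:
    """Whitespace table: first column animal label, remaining columns allele
    counts 0/1/2 (no missing values)."""
    rows = []
    labels = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            lab = parts[0]
            labels.append(int(lab) if lab.lstrip("-").isdigit() else lab)
            try:
                counts = [float(x) for x in parts[1:]]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: bad genotype value ({e})") from None
            if any(c not in (0.0, 1.0, 2.0) for c in counts):
                raise FormatError(f"{path}:{ln}: allele counts must be 0/1/2")
            rows.append(counts)
    if not rows:
        raise FormatError(f"genotype file {path} is empty")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"genotype file {path} has ragged rows")
    df = pd.DataFrame(rows, index=labels,
                      columns=[f"m{j+1}" for j in range(widths.pop())])
    return MarkerData(df, allele_freq=allele_freq)


# ---------------------------------------------------------------------------
# triplet matrices
# ---------------------------------------------------------------------------

def read_matrix_triplets(path) -> LabeledSymMatrix:
    """Read a labelled symmetric matrix from 'row col value' lines
    (lower triangle; either triangle accepted)."""
    entries = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 'row col value'")
            r, c, v = parts
            r = int(r) if r.lstrip("-").isdigit() else r
            c = int(c) if c.lstrip("-").isdigit() else c
            key = (r, c) if str(r) <= str(c) else (c, r)
            if key in seen:
                raise FormatError(f"{path}:{ln}: duplicate entry for {r}, {c}")
            seen.add(key)
            try:
                entries.append((r, c, float(v)))
            except ValueError:
                raise FormatError(f"{path}:{ln}: bad value {v!r}") from None
    if not entries:
        raise FormatError(f"matrix file {path} is empty")
    return from_triplets(entries)


def write_matrix_triplets(mat: LabeledSymMatrix, path) -> None:
    """Write the lower triangle (including zeros on the diagonal) as
    'row_label col_label value'."""
    dense = mat.to_dense()
    with open(path, "w") as fh:
        for i, ri in enumerate(mat.labels):
            for j in range(i + 1):
                v = dense[i, j]
                if v != 0.0 or i == j:
                    fh.write(f"{ri} {mat.labels[j]} {FLOAT_FMT % v}\n")


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------

def write_solutions(sol: SolutionSet, path) -> None:
    rows = []
    for name, v in sol.fixed.items():
        rows.append(("fixed", name, v, "direct"))
    for lab, v in sol.animal.items():
        rows.append(("animal", lab, v, sol.provenance.get(lab, "direct")))
    for attr, kind in (("alpha", "marker"), ("epsilon", "epsilon"), ("delta", "delta")):
        series = getattr(sol, attr)
        if series is not None:
            for lab, v in series.items():
                rows.append((kind, lab, v, sol.provenance.get(lab, "direct")))
    df = pd.DataFrame(rows, columns=["effect_type", "label", "solution", "provenance"])
    df["method"] = sol.method
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_solutions(path) -> SolutionSet:
    df = pd.read_csv(path)
    df["label"] = [int(l) if str(l).lstrip("-").isdigit() else l for l in df["label"]]

    def series(kind):
        sub = df[df.effect_type == kind]
        return pd.Series(sub.solution.to_numpy(float), index=list(sub.label))

    animal_df = df[df.effect_type == "animal"]
    animal = series("animal")
    return SolutionSet(
        method=str(df["method"].iloc[0]) if "method" in df else "unknown",
        fixed=series("fixed"),
        animal=animal,
        provenance=pd.Series(
            animal_df.provenance.to_numpy(object), index=list(animal_df.label)
        ),
        alpha=series("marker") if (df.effect_type == "marker").any() else None,
        epsilon=series("epsilon") if (df.effect_type == "epsilon").any() else None,
        delta=series("delta") if (df.effect_type == "delta").any() else None,
    )


def write_pedigree(ped: Pedigree, path, partition: dict | None = None) -> None:
    df = ped.to_frame()
    if partition is not None:
        df["partition"] = [partition[a] for a in df["animal"]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured run configuration; keys mirror the CLI flags 1:1."""

    pedigree: str = ""
    phenotypes: str = ""
    genotypes: str = ""
    g_matrix: str = ""
    genotyped: str = ""  # comma-separated labels (when G is given directly)
    fixed: str = ""      # comma-separated fixed-effect column names
    sigma_a: float = 1.0
    sigma_e: float = 1.0
    sigma_alpha: float | None = None
    sigma_delta: float | None = None
    method: str = "full"
    prune: bool = False
    solver: str = "auto"
    tol: float = 1e-12
    out: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]
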