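"""Pedigree reading, validation, ordering and animal classification.

A pedigree is a table of (animal, sire, dam) records with unknown parents
coded 0 (the readers also accept empty fields and NA).  Internally animals
get contiguous integer codes 1..N in a topological order (parents precede
progeny), regardless of the order of the input file, so every downstream
matrix is invariant to row shuffling of the source table.

The classification routines produce the animal subsets each reduced-model
variant keeps in its equation system:

* Method 1 keeps genotyped animals plus nongenotyped parents (``p``) and
  absorbs everything else (``n``: nongenotyped nonparents).
* Method 2 keeps genotyped animals plus nongenotyped phenotyped animals and
  absorbs nongenotyped nonphenotyped animals.
* Method 3 keeps genotyped animals plus nongenotyped parents of phenotyped
  nongenotyped nonparents (``q``); the remaining nongenotyped parents
  (``r``) and the nonparents (``n``) are absorbed.

A separate two-hop partition marks animals whose equations carry no genomic
information flow at all (class 0) and which may be pruned and evaluated by
pedigree BLUP on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import PedigreeError

Label = Hashable
UNKNOWN = 0

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "0", "NA", "NaN", "nan", ".", "None", "na"}


def _normalise_label(x) -> Label | None:
    """Map raw cell content to a label, or None for an unknown parent."""
    if x is None:
        return None
    if isinstance(x, float):
        if np.isnan(x):
            return None
        if x == int(x):
            x = int(x)
    if isinstance(x, (int, np.integer)):
        return None if int(x) == UNKNOWN else int(x)
    s = str(x).strip()
    if s in _NA_TOKENS:
        return None
    # keep integer-looking labels as ints so files and literals agree
    try:
        return int(s)
    except ValueError:
        return s


class Pedigree:
    """Validated, topologically ordered pedigree.

    Attributes
    ----------
    labels : tuple
        External animal labels in topological order (parents first).
    sire, dam : ndarray of int
        Internal parent codes per animal (1-based, 0 = unknown), aligned
        with ``labels``.
    """

    def __init__(self, labels: Sequence[Label], sire: np.ndarray, dam: np.ndarray):
        self.labels = tuple(labels)
        self.sire = np.asarray(sire, dtype=int)
        self.dam = np.asarray(dam, dtype=int)
        self.code = {lab: i + 1 for i, lab in enumerate(self.labels)}

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        add_missing_parents: bool = False,
    ) -> "Pedigree":
        """Build from (animal, sire, dam) tuples.

        Unknown parents may be given as 0, None, "", "NA" or NaN.  Parent
        labels absent from the animal column are an error unless
        ``add_missing_parents`` is set, in which case they are added as
        founders.
        """
        rows = []
        for rec in records:
            if len(rec) != 3:
                raise PedigreeError(f"pedigree record must have 3 fields, got {rec!r}")
            a, s, d = (_normalise_label(x) for x in rec)
            if a is None:
                raise PedigreeError("animal label missing/unknown in pedigree record")
            rows.append((a, s, d))
        animals = [a for a, _, _ in rows]
        if len(set(animals)) != len(animals):
            dup = pd.Series(animals)
            dup = sorted(dup[dup.duplicated()].unique().tolist())
            raise PedigreeError(f"duplicate animal records: {dup}")
        known = set(animals)
        missing = []
        for _, s, d in rows:
            for par in (s, d):
                if par is not None and par not in known:
                    missing.append(par)
        if missing:
            if not add_missing_parents:
                raise PedigreeError(
                    f"parent labels with no animal record: {sorted(set(missing), key=str)} "
                    "(pass add_missing_parents=True to add them as founders)"
                )
            for par in dict.fromkeys(missing):
                rows.append((par, None, None))
                known.add(par)

        # Topological order via the parent->progeny DAG.
        g = nx.DiGraph()
        g.add_nodes_from(a for a, _, _ in rows)
        for a, s, d in rows:
            if s is not None:
                g.add_edge(s, a)
            if d is not None and d != s:
                g.add_edge(d, a)
        try:
            order = list(nx.lexicographical_topological_sort(g, key=str))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise PedigreeError(f"pedigree contains a cycle: {path}") from None

        parent_of = {a: (s, d) for a, s, d in rows}
        code = {lab: i + 1 for i, lab in enumerate(order)}
        sire = np.array(
            [code[parent_of[a][0]] if parent_of[a][0] is not None else UNKNOWN for a in order]
        )
        dam = np.array(
            [code[parent_of[a][1]] if parent_of[a][1] is not None else UNKNOWN for a in order]
        )
        return cls(order, sire, dam)

    # -- basic properties ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def parents_of(self, label: Label) -> tuple[Label | None, Label | None]:
        i = self.code[label] - 1
        s = self.labels[self.sire[i] - 1] if self.sire[i] != UNKNOWN else None
        d = self.labels[self.dam[i] - 1] if self.dam[i] != UNKNOWN else None
        return s, d

    def parent_labels(self) -> set[Label]:
        """Labels of animals with at least one progeny."""
        idx = set(self.sire[self.sire != UNKNOWN]) | set(self.dam[self.dam != UNKNOWN])
        return {self.labels[i - 1] for i in idx}

    def founders(self) -> set[Label]:
        mask = (self.sire == UNKNOWN) & (self.dam == UNKNOWN)
        return {lab for lab, m in zip(self.labels, mask) if m}

    def to_frame(self) -> pd.DataFrame:
        s = [self.labels[c - 1] if c != UNKNOWN else 0 for c in self.sire]
        d = [self.labels[c - 1] if c != UNKNOWN else 0 for c in self.dam]
        return pd.DataFrame({"animal": list(self.labels), "sire": s, "dam": d})

    def __contains__(self, label: Label) -> bool:
        return label in self.code

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Pedigree n={self.n}>"


def read_pedigree(
    path,
    sep: str | None = None,
    columns: Sequence[str] = ("animal", "sire", "dam"),
    add_missing_parents: bool = False,
) -> Pedigree:
    """Read a pedigree CSV/TSV with columns animal,sire,dam.

    The header is optional: if the first row does not contain the expected
    column names the first three columns are used positionally.  ``sep=None``
    sniffs comma vs whitespace.
    """
    df = pd.read_csv(path, sep=sep, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError(f"pedigree file {path} needs >=3 columns, found {df.shape[1]}")
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if set(columns) <= set(first):
        df.columns = first
        df = df.iloc[1:]
        df = df[[*columns]]
    else:
        df = df.iloc[:, :3]
        df.columns = list(columns)
    return Pedigree.from_records(
        df.itertuples(index=False, name=None), add_missing_parents=add_missing_parents
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnimalSets:
    """Animal subsets used by the reduced-model variants."""

    genotyped: frozenset
    phenotyped: frozenset
    parents: frozenset
    method1_p: frozenset
    method1_n: frozenset
    method2_p: frozenset
    method2_n: frozenset
    method3_q: frozenset
    method3_r: frozenset
    method3_n: frozenset

    def kept(self, method: int) -> frozenset:
        return {1: self.method1_p, 2: self.method2_p, 3: self.method3_q}[method]


def classify_animals(
    ped: Pedigree, genotyped: Iterable[Label], phenotyped: Iterable[Label]
) -> AnimalSets:
    """Classify animals into the kept/absorbed sets of the three reductions.

    ``q`` (Method 3) contains genotyped animals plus the nongenotyped parents
    of phenotyped nongenotyped nonparents; nongenotyped *phenotyped* parents
    are also kept in ``q`` because a phenotyped animal owns an identity row
    in the reduced design and cannot be absorbed into ``r``.
    """
    genotyped = frozenset(genotyped)
    phenotyped = frozenset(phenotyped)
    all_animals = frozenset(ped.labels)
    for name, s in (("genotyped", genotyped), ("phenotyped", phenotyped)):
        extra = s - all_animals
        if extra:
            raise PedigreeError(f"{name} animals not in pedigree: {sorted(extra, key=str)}")
    parents = frozenset(ped.parent_labels())

    m1_p = genotyped | (parents - genotyped)
    m1_n = all_animals - m1_p

    m2_p = genotyped | (phenotyped - genotyped)
    m2_n = all_animals - m2_p

    # phenotyped nongenotyped nonparents and their known parents
    pheno_n = (phenotyped - genotyped) - parents
    q_parents: set[Label] = set()
    for a in pheno_n:
        for par in ped.parents_of(a):
            if par is not None:
                q_parents.add(par)
    m3_q = genotyped | (q_parents - genotyped) | ((parents & phenotyped) - genotyped)
    m3_r = m1_p - m3_q
    m3_n = all_animals - m3_q - m3_r
    return AnimalSets(
        genotyped=genotyped,
        phenotyped=phenotyped,
        parents=parents,
        method1_p=frozenset(m1_p),
        method1_n=frozenset(m1_n),
        method2_p=frozenset(m2_p),
        method2_n=frozenset(m2_n),
        method3_q=frozenset(m3_q),
        method3_r=frozenset(m3_r),
        method3_n=frozenset(m3_n),
    )


# ---------------------------------------------------------------------------
# pruning partition (two-hop rule)
# ---------------------------------------------------------------------------

def _adjacency(ped: Pedigree) -> dict[Label, set[Label]]:
    """Parent/progeny/mate adjacency between animals."""
    adj: dict[Label, set[Label]] = {lab: set() for lab in ped.labels}
    for i, lab in enumerate(ped.labels):
        s = ped.labels[ped.sire[i] - 1] if ped.sire[i] != UNKNOWN else None
        d = ped.labels[ped.dam[i] - 1] if ped.dam[i] != UNKNOWN else None
        for par in (s, d):
            if par is not None:
                adj[lab].add(par)
                adj[par].add(lab)
        if s is not None and d is not None:
            adj[s].add(d)
            adj[d].add(s)
    return adj


def prune_partition(ped: Pedigree, genotyped: Iterable[Label]) -> dict[Label, int]:
    """Assign every animal to class 2, 3, 4 or 0.

    Class 2 = genotyped; class 3 = nongenotyped animals that are parent,
    progeny or mate of a genotyped animal; class 4 = nongenotyped animals
    that are parent, progeny or mate of a class-3 animal; class 0 = the
    remainder, whose equations exchange no genomic information within two
    hops and are candidates for removal.
    """
    genotyped = set(genotyped)
    extra = genotyped - set(ped.labels)
    if extra:
        raise PedigreeError(f"genotyped animals not in pedigree: {sorted(extra, key=str)}")
    adj = _adjacency(ped)
    class3 = set().union(*(adj[g] for g in genotyped)) - genotyped if genotyped else set()
    class4 = (
        set().union(*(adj[a] for a in class3)) - genotyped - class3 if class3 else set()
    )
    part: dict[Label, int] = {}
    for lab in ped.labels:
        if lab in genotyped:
            part[lab] = 2
        elif lab in class3:
            part[lab] = 3
        elif lab in class4:
            part[lab] = 4
        else:
            part[lab] = 0
    return part


def prune_pedigree(
    ped: Pedigree, partition: Mapping[Label, int]
) -> tuple[Pedigree, list[Label]]:
    """Drop class-0 animals; returns (pruned pedigree, removed labels).

    References to removed parents become unknown.  Removal is exact for
    class-0 animals absorbed as leaves/founders; for phenotyped class-0
    animals the fixed-effect solutions may shift slightly, hence the
    warning.  Refuses to run when nothing is genotyped ("nothing to
    anchor" a genomic partition).
    """
    if not any(v == 2 for v in partition.values()):
        raise PedigreeError("pruning refused: no genotyped animals, nothing to anchor")
    removed = [lab for lab in ped.labels if partition.get(lab, 0) == 0]
    if not removed:
        return ped, []
    logger.warning(
        "pruning removes %d animals; exact only if their records do not move "
        "the fixed-effect solutions", len(removed),
    )
    removed_set = set(removed)
    rows = []
    for lab in ped.labels:
        if lab in removed_set:
            continue
        s, d = ped.parents_of(lab)
        rows.append(
            (lab, s if s not in removed_set else None, d if d not in removed_set else None)
        )
    return Pedigree.from_records(rows), removed
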