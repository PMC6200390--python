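"""Pedigree parsing and the pedigree numerator relationship matrix.

The numerator relationship matrix **A** holds expected additive-genetic
relationships: the diagonal is 1 + F (F the inbreeding coefficient of the
animal) and off-diagonal entries are twice the coefficient of kinship.  A is
the covariance structure of the random animal effect in the animal model,
``a ~ N(0, A * sigma2_a)``, and is built with the tabular method: animals are
processed parents-first, each new row averaging its parents' rows.

Ids are opaque strings.  Unknown parents may be coded as empty fields or
``0`` in input files and contribute nothing to the recursion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import Kernel

_UNKNOWN_CODES = {"", "0", "0.0", "nan", "none", "na", ".", "unknown"}


def _norm_id(x) -> str | None:
    if x is None:
        return None
    s = str(x).strip()
    if s.lower() in _UNKNOWN_CODES:
        return None
    return s


@dataclass
class Pedigree:
    """Validated, topologically sorted pedigree.

    ``sire[i]`` / ``dam[i]`` are integer indices into ``ids`` (always smaller
    than ``i``) or -1 when the parent is unknown.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from (animal, sire, dam) triples in any order.

        Duplicate animal ids and parentage cycles raise ``ValueError``;
        parents that never appear as animals are auto-inserted as founders
        with a warning.
        """
        rows = [(_norm_id(a), _norm_id(s), _norm_id(d)) for a, s, d in records]
        if any(a is None for a, _, _ in rows):
            raise ValueError("pedigree contains a missing animal id")
        seen: set[str] = set()
        for a, _, _ in rows:
            if a in seen:
                raise ValueError(f"duplicate animal id {a!r} in pedigree")
            seen.add(a)
        undeclared: list[str] = []
        for _, s, d in rows:
            for p in (s, d):
                if p is not None and p not in seen and p not in undeclared:
                    undeclared.append(p)
        if undeclared:
            warnings.warn(
                f"{len(undeclared)} parent(s) never declared as animals; "
                "inserted as founders", stacklevel=2)
            rows = [(p, None, None) for p in undeclared] + rows
        # Kahn topological sort, stable in input order.
        index = {a: i for i, (a, _, _) in enumerate(rows)}
        indeg = np.zeros(len(rows), dtype=int)
        children: dict[int, list[int]] = {}
        for i, (_, s, d) in enumerate(rows):
            for p in (s, d):
                if p is not None:
                    indeg[i] += 1
                    children.setdefault(index[p], []).append(i)
        from collections import deque
        queue = deque(i for i in range(len(rows)) if indeg[i] == 0)
        order: list[int] = []
        while queue:
            i = queue.popleft()
            order.append(i)
            for c in children.get(i, ()):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) < len(rows):
            stuck = [rows[i][0] for i in range(len(rows)) if indeg[i] > 0]
            raise ValueError(
                f"pedigree contains a cycle involving {stuck[:5]}")
        ids = [rows[i][0] for i in order]
        newpos = {a: k for k, a in enumerate(ids)}
        sire = np.array(
            [newpos[rows[i][1]] if rows[i][1] is not None else -1
             for i in order], dtype=int)
        dam = np.array(
            [newpos[rows[i][2]] if rows[i][2] is not None else -1
             for i in order], dtype=int)
        return cls(ids, sire, dam)

    def records(self) -> list[tuple[str, str | None, str | None]]:
        return [
            (a,
             self.ids[self.sire[i]] if self.sire[i] >= 0 else None,
             self.ids[self.dam[i]] if self.dam[i] >= 0 else None)
            for i, a in enumerate(self.ids)
        ]

    def founder_mask(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def to_frame(self) -> pd.DataFrame:
        recs = self.records()
        return pd.DataFrame(
            {"animal": [r[0] for r in recs],
             "sire": [r[1] or "0" for r in recs],
             "dam": [r[2] or "0" for r in recs]})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    """Read a CSV/TSV pedigree with animal, sire and dam columns.

    The delimiter is sniffed; column matching is case-insensitive and accepts
    common synonyms (id/animal, father/sire, mother/dam).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(
            f"pedigree file needs one of columns {names}, found {list(df.columns)}")
    a = pick("animal", "id", "animal_id")
    s = pick("sire", "father", "sire_id")
    d = pick("dam", "mother", "dam_id")
    records = list(zip(df[a], df[s], df[d]))
    if not records:
        raise ValueError("pedigree file is empty")
    return Pedigree.from_records(records)


def build_A(ped: Pedigree, subset=None) -> Kernel:
    """Numerator relationship matrix by the tabular method.

    ``A[i, i] = 1 + 0.5 * A[sire, dam]`` and, for earlier animals j,
    ``A[i, j] = 0.5 * (A[sire, j] + A[dam, j])``; unknown parents contribute
    zero.  If ``subset`` is given the full recursion is run first and the
    matrix then restricted to those ids (in that order).
    """
    n = ped.n
    if n == 0:
        raise ValueError("cannot build A for an empty pedigree")
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    kern = Kernel(list(ped.ids), A, name="A")
    if subset is not None:
        kern = kern.subset(subset)
        kern.name = "A"
    return kern


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F (diagonal of A minus one), in pedigree order."""
    return build_A(ped).values.diagonal() - 1.0


def prune_to_ancestors(ped: Pedigree, keep_ids) -> Pedigree:
    """Retain the given animals and all their ancestors.

    The A-submatrix over ``keep_ids`` is unchanged by pruning, because the
    tabular recursion for any animal involves only its ancestors.
    """
    pos = {a: i for i, a in enumerate(ped.ids)}
    stack = []
    for k in keep_ids:
        k = str(k)
        if k not in pos:
            raise KeyError(f"id {k!r} not present in pedigree")
        stack.append(pos[k])
    keep: set[int] = set()
    while stack:
        i = stack.pop()
        if i in keep:
            continue
        keep.add(i)
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                stack.append(p)
    recs = [r for i, r in enumerate(ped.records()) if i in keep]
    return Pedigree.from_records(recs)
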