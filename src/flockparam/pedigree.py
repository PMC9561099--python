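"""Pedigrees and the numerator relationship matrix A.

The additive genetic covariance between animals in the animal model is
``A * sigma2_a``, where A is the numerator relationship matrix: twice the
kinship matrix, with diagonal ``1 + F_i`` (F the inbreeding coefficient).
This module reads and validates pedigree files, orders them parents-first,
and builds A (dense, tabular method), arbitrary principal submatrices of A
(gene-flow T-row recursion, so full A is never formed for large pedigrees),
inbreeding coefficients, and the sparse inverse of A by Henderson's rules
with full accounting for inbreeding.

Unknown parents are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse

UNKNOWN = -1

_HEADER_TOKENS = {"animal", "id", "tag", "sire", "father", "dam", "mother"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree: cycles, duplicates, self-parenting."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree triple; parents are ``None`` when unknown."""

    animal: str
    sire: str | None
    dam: str | None


@dataclass
class Pedigree:
    """Topologically ordered pedigree with inbreeding coefficients.

    ``sire``/``dam`` hold positional indices into ``ids`` (-1 = unknown
    parent); every parent index is smaller than its offspring's position.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(repr=False)
    f: np.ndarray = field(repr=False)
    _trows: list[dict[int, float]] = field(repr=False)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def inbreeding(self) -> np.ndarray:
        return self.f

    def records(self) -> list[PedigreeRecord]:
        return [
            PedigreeRecord(
                self.ids[i],
                self.ids[self.sire[i]] if self.sire[i] >= 0 else None,
                self.ids[self.dam[i]] if self.dam[i] >= 0 else None,
            )
            for i in range(len(self.ids))
        ]

    @classmethod
    def from_triples(
        cls, triples: Sequence[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Validate, promote parents to founders, topologically sort.

        Input order is irrelevant: rows are re-ordered parents-first
        (Kahn's algorithm with first-appearance tie-break).
        """
        seen: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for animal, s, d in triples:
            animal = str(animal)
            if animal in seen:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            s = None if s is None else str(s)
            d = None if d is None else str(d)
            if s == animal or d == animal:
                raise PedigreeError(f"animal {animal!r} is its own parent")
            seen[animal] = (s, d)
            order.append(animal)
        # promote parents that never appear as animals to founders
        for animal in list(order):
            for p in seen[animal]:
                if p is not None and p not in seen:
                    seen[p] = (None, None)
                    order.append(p)

        # Kahn topological sort, parents before offspring
        n_children: dict[str, list[str]] = {a: [] for a in order}
        n_pending = {a: 0 for a in order}
        for a in order:
            for p in set(p for p in seen[a] if p is not None):
                n_children[p].append(a)
                n_pending[a] += 1
        queue = [a for a in order if n_pending[a] == 0]
        sorted_ids: list[str] = []
        head = 0
        while head < len(queue):
            a = queue[head]
            head += 1
            sorted_ids.append(a)
            for c in n_children[a]:
                n_pending[c] -= 1
                if n_pending[c] == 0:
                    queue.append(c)
        if len(sorted_ids) != len(order):
            stuck = next(a for a in order if n_pending[a] > 0)
            raise PedigreeError(
                f"pedigree contains a cycle involving animal {stuck!r}"
            )

        index = {a: i for i, a in enumerate(sorted_ids)}
        sire = np.full(len(sorted_ids), UNKNOWN, dtype=np.int64)
        dam = np.full(len(sorted_ids), UNKNOWN, dtype=np.int64)
        for a, (s, d) in seen.items():
            i = index[a]
            if s is not None:
                sire[i] = index[s]
            if d is not None:
                dam[i] = index[d]
        f, trows = _inbreeding_and_trows(sire, dam)
        return cls(sorted_ids, sire, dam, index, f, trows)

    def positions(self, animal_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.index[str(a)] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None


def _mendelian_variance(i: int, sire: np.ndarray, dam: np.ndarray, f: np.ndarray) -> float:
    """Variance of the Mendelian-sampling deviation, as a fraction of sigma2_a."""
    s, d = sire[i], dam[i]
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (f[s] + f[d])
    if s >= 0:
        return 0.75 - 0.25 * f[s]
    if d >= 0:
        return 0.75 - 0.25 * f[d]
    return 1.0


def _inbreeding_and_trows(
    sire: np.ndarray, dam: np.ndarray
) -> tuple[np.ndarray, list[dict[int, float]]]:
    """One forward pass computing F and the gene-flow rows of T.

    A = T D T' with T the lower-triangular gene-flow matrix (row i holds the
    expected fraction of genes animal i derives from each ancestor) and D the
    diagonal of Mendelian-sampling variances.  F_i = 0.5 * a_{sire,dam},
    evaluated through the D-weighted dot product of the parents' T rows.
    """
    n = len(sire)
    f = np.zeros(n)
    dvec = np.zeros(n)
    trows: list[dict[int, float]] = []
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            rs, rd = trows[s], trows[d]
            if len(rd) < len(rs):
                rs, rd = rd, rs
            a_sd = sum(w * rd.get(j, 0.0) * dvec[j] for j, w in rs.items())
            f[i] = 0.5 * a_sd
        dvec[i] = _mendelian_variance(i, sire, dam, f)
        row = {i: 1.0}
        for p in (s, d):
            if p >= 0:
                for j, w in trows[p].items():
                    row[j] = row.get(j, 0.0) + 0.5 * w
        trows.append(row)
    return f, trows


def read_pedigree(
    path: str | Path | io.TextIOBase,
    unknown_code: str = "0",
    header: bool | str = "auto",
) -> Pedigree:
    """Read a delimited pedigree file (animal, sire, dam in the first columns).

    Whitespace- or comma-delimited; ``unknown_code`` (default "0") marks an
    unknown parent; with ``header="auto"`` a first row containing tokens like
    "animal"/"sire"/"dam" is skipped. Animals appearing only as parents are
    inserted as founders, and rows are topologically sorted.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    rows: list[list[str]] = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) < 3:
            raise PedigreeError(f"pedigree row has fewer than 3 columns: {line!r}")
        rows.append(parts[:3])
    if not rows:
        raise PedigreeError("empty pedigree file")
    if header == "auto":
        header = any(tok.lower() in _HEADER_TOKENS for tok in rows[0])
    if header:
        rows = rows[1:]
    triples = [
        (a, None if s == unknown_code else s, None if d == unknown_code else d)
        for a, s, d in rows
    ]
    return Pedigree.from_triples(triples)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F (founders 0), aligned with ``ped.ids``."""
    return ped.f.copy()


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    a_ii = 1 + F_i; a_ij = mean of a_{i,sire(j)} and a_{i,dam(j)}, an unknown
    parent contributing 0. A is structurally dense for related pedigrees, so a
    dense array is the honest representation; use
    :func:`relationship_submatrix` when only a subset of animals is needed.
    """
    n = len(ped)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if i > 0:
            above = 0.5 * ((a[:i, s] if s >= 0 else 0.0) + (a[:i, d] if d >= 0 else 0.0))
            if np.isscalar(above):
                above = np.zeros(i)
            a[:i, i] = above
            a[i, :i] = above
        a[i, i] = 1.0 + ped.f[i]
    return a


def relationship_submatrix(ped: Pedigree, animal_ids: Sequence[str]) -> np.ndarray:
    """A restricted to ``animal_ids``, without forming the full matrix.

    Uses A = T D T': the requested block is M D M' where M stacks the sparse
    gene-flow rows of the selected animals. Exact under inbreeding.
    """
    pos = ped.positions(animal_ids)
    dvec = np.array(
        [_mendelian_variance(i, ped.sire, ped.dam, ped.f) for i in range(len(ped))]
    )
    rows, cols, vals = [], [], []
    for r, i in enumerate(pos):
        for j, w in ped._trows[i].items():
            rows.append(r)
            cols.append(j)
            vals.append(w)
    m = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(pos), len(ped))
    )
    return np.asarray((m.multiply(dvec) @ m.T).todense())


def relationship_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's recursive rules, accounting for inbreeding.

    Each animal contributes alpha = 1/d_i (d_i the Mendelian-sampling
    variance) to its own diagonal, -alpha/2 to animal-parent entries and
    alpha/4 to parent-parent entries.
    """
    n = len(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / _mendelian_variance(i, ped.sire, ped.dam, ped.f)
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * alpha)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def write_pedigree(ped: Pedigree, path: str | Path, unknown_code: str = "0") -> None:
    """Write animal/sire/dam rows (topological order, header line included)."""
    with open(path, "w") as fh:
        fh.write("animal sire dam\n")
        for i, a in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else unknown_code
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else unknown_code
            fh.write(f"{a} {s} {d}\n")


def export_relationship_triplets(ped: Pedigree, path: str | Path) -> None:
    """Write the lower triangle of A as text triplets ``i j value`` (1-based)."""
    a = relationship_matrix(ped)
    with open(path, "w") as fh:
        fh.write("# i j a_ij (lower triangle, 1-based, ids in topological order)\n")
        for i in range(len(ped)):
            for j in range(i + 1):
                if a[i, j] != 0.0:
                    fh.write(f"{i + 1} {j + 1} {a[i, j]:.12g}\n")
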