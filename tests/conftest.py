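"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written differently from the package
implementations: recursive memoized kinship instead of the iterative
tabular sweep, and a dense projection-matrix REML likelihood instead of
the mixed-model-equations / block factorizations.
"""

from __future__ import annotations

import numpy as np
import pytest

from flockparam.model_design import DesignSet
from flockparam.pedigree import Pedigree, relationship_submatrix


@pytest.fixture
def trio_ped() -> Pedigree:
    return Pedigree.from_triples(
        [("A", None, None), ("B", None, None), ("C", "A", "B")]
    )


@pytest.fixture
def fullsib_ped() -> Pedigree:
    """Unrelated P1 x P2, full sibs O1/O2, C from the full-sib mating."""
    return Pedigree.from_triples(
        [
            ("P1", None, None),
            ("P2", None, None),
            ("O1", "P1", "P2"),
            ("O2", "P1", "P2"),
            ("C", "O1", "O2"),
        ]
    )


def random_pedigree_triples(
    rng: np.random.Generator, n: int, p_founder: float = 0.3
) -> list[tuple[str, str | None, str | None]]:
    """Random acyclic pedigree; returned in shuffled row order."""
    triples: list[tuple[str, str | None, str | None]] = []
    for i in range(n):
        if i < 2 or rng.random() < p_founder:
            triples.append((f"A{i}", None, None))
            continue
        s = f"A{rng.integers(0, i)}"
        d = f"A{rng.integers(0, i)}"
        if d == s:
            d = None
        if rng.random() < 0.1:
            s = None
        triples.append((f"A{i}", s, d))
    order = rng.permutation(len(triples))
    return [triples[k] for k in order]


def recursive_relationship(
    triples: list[tuple[str, str | None, str | None]]
) -> tuple[list[str], np.ndarray]:
    """Brute-force numerator relationships by memoized recursion.

    a(i, i) = 1 + 0.5 a(s_i, d_i); for i younger than j,
    a(i, j) = 0.5 (a(j, s_i) + a(j, d_i)); unknown parents contribute 0.
    """
    parents = {a: (s, d) for a, s, d in triples}
    for a, s, d in list(triples):
        for p in (s, d):
            if p is not None and p not in parents:
                parents[p] = (None, None)
    # age order: founders first (depth of ancestry)
    depth: dict[str, int] = {}

    def _depth(x: str) -> int:
        if x not in depth:
            s, d = parents[x]
            depth[x] = 1 + max(
                _depth(s) if s else 0, _depth(d) if d else 0
            )
        return depth[x]

    ids = sorted(parents, key=lambda x: (_depth(x), x))
    pos = {a: i for i, a in enumerate(ids)}
    memo: dict[tuple[str, str], float] = {}

    def a_of(x: str | None, y: str | None) -> float:
        if x is None or y is None:
            return 0.0
        if pos[x] > pos[y]:
            x, y = y, x
        key = (x, y)
        if key in memo:
            return memo[key]
        sy, dy = parents[y]
        if x == y:
            val = 1.0 + 0.5 * a_of(sy, dy)
        else:
            val = 0.5 * (a_of(x, sy) + a_of(x, dy))
        memo[key] = val
        return val

    n = len(ids)
    a = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            a[i, j] = a[j, i] = a_of(ids[i], ids[j])
    return ids, a


def dense_projection_loglik(design: DesignSet, components, ped=None) -> float:
    """REML log-likelihood by explicit dense V and projection matrix P."""
    n, p = design.X.shape
    v = np.eye(n) * float(components.residual)
    for blk in design.random_blocks:
        s2 = float(components.terms[blk.name])
        z = np.zeros((n, blk.n_levels))
        z[np.arange(n), blk.codes] = 1.0
        if blk.covariance == "pedigree":
            k = relationship_submatrix(ped, [str(a) for a in blk.levels])
        else:
            k = np.eye(blk.n_levels)
        v += s2 * z @ k @ z.T
    vi = np.linalg.inv(v)
    x, y = design.X, design.y
    b = x.T @ vi @ x
    proj = vi - vi @ x @ np.linalg.inv(b) @ x.T @ vi
    return -0.5 * (
        np.linalg.slogdet(v)[1]
        + np.linalg.slogdet(b)[1]
        + float(y @ proj @ y)
        + (n - p) * np.log(2 * np.pi)
    )
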