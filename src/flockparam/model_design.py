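"""Declarative model specification and design-structure construction.

A :class:`ModelSpec` names, for one response trait, the fixed interaction
terms (contemporary groups such as birth-year x flock x sex), numeric
covariates, and random terms — each random term being a grouping of records
(e.g. the animal itself, or animal x measurement round) with either an
identity covariance (permanent environment) or the pedigree numerator
relationship matrix (additive genetic effect).  :func:`build_design` turns a
phenotype table plus a spec into the concrete structures the REML fitter
consumes: a response vector, a full-column-rank fixed design, and per-term
incidence codes.

Fixed-effect aliasing is resolved deterministically: columns are scanned in
spec order and a column linearly dependent on earlier ones is dropped
(sequential Gram-Schmidt).  Estimable quantities — variance components and
their ratios — are invariant to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .pedigree import Pedigree

IDENTITY = "identity"
PEDIGREE = "pedigree"


class ConfigError(ValueError):
    """Model specification inconsistent with the data or pedigree."""


@dataclass(frozen=True)
class RandomTerm:
    """One random term: a name, grouping columns, and covariance kind."""

    name: str
    group_by: tuple[str, ...]
    covariance: str = IDENTITY

    def __post_init__(self) -> None:
        if self.covariance not in (IDENTITY, PEDIGREE):
            raise ConfigError(
                f"random term {self.name!r}: covariance must be "
                f"'identity' or 'pedigree', got {self.covariance!r}"
            )


@dataclass
class ModelSpec:
    """Declarative single-trait model: response, fixed terms, random terms."""

    response: str
    fixed_factors: list[tuple[str, ...]] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    random_terms: list[RandomTerm] = field(default_factory=list)
    animal_column: str = "animal"
    intercept: bool = True
    #: columns identifying the measurement occasion of a record.  Two traits
    #: are treated as co-recorded (residual-correlated in bivariate fits)
    #: only when their (animal, occasion) keys coincide; with no occasion
    #: columns, records pair only when they come from the same table row.
    occasion: list[str] | None = None

    def __post_init__(self) -> None:
        names = [t.name for t in self.random_terms]
        if len(set(names)) != len(names):
            raise ConfigError("random terms must have distinct names")
        for t in self.random_terms:
            if t.covariance == PEDIGREE and tuple(t.group_by) != (self.animal_column,):
                raise ConfigError(
                    f"pedigree covariance requires grouping by the animal column "
                    f"({self.animal_column!r}); term {t.name!r} groups by {t.group_by}"
                )
        if not self.intercept and not self.fixed_factors:
            raise ConfigError("model needs an intercept or at least one fixed term")

    @classmethod
    def from_dict(cls, cfg: dict) -> "ModelSpec":
        """Parse a config mapping; interactions are dot-joined column names.

        Example::

            response: ch4_gpd
            fixed: [byr.flk.sex, ryr.lot.group.round, brr]
            covariates: [bdev]
            random:
              animal: {group_by: [animal], covariance: pedigree}
              wgpe:   {group_by: [animal, round], covariance: identity}
        """
        fixed = [tuple(term.split(".")) for term in cfg.get("fixed", [])]
        random_terms = [
            RandomTerm(
                name,
                tuple(spec_.get("group_by", [name])),
                spec_.get("covariance", IDENTITY),
            )
            for name, spec_ in cfg.get("random", {}).items()
        ]
        return cls(
            response=cfg["response"],
            fixed_factors=fixed,
            covariates=list(cfg.get("covariates", [])),
            random_terms=random_terms,
            animal_column=cfg.get("animal_column", "animal"),
            intercept=cfg.get("intercept", True),
            occasion=cfg.get("occasion"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RandomBlock:
    """Incidence of records onto the levels of one random term."""

    name: str
    covariance: str
    codes: np.ndarray  # level index per record
    levels: list  # level labels; for pedigree terms these are animal ids

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class DesignSet:
    """Concrete design structures for one trait, ready for REML."""

    response: str
    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    random_blocks: list[RandomBlock]
    animals: np.ndarray  # animal id per record
    record_ids: np.ndarray  # source row labels, for cross-trait residual pairing
    n_dropped: int = 0

    @property
    def n_records(self) -> int:
        return len(self.y)


def build_contemporary_groups(
    table: pd.DataFrame, columns: Sequence[str]
) -> pd.Series:
    """Concatenate factor columns into one contemporary-group factor.

    One level per observed combination, levels ordered lexicographically;
    a record missing any component gets NaN (flagged, to be excluded from
    models using this grouping).
    """
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ConfigError(f"factor columns not in table: {missing}")
    parts = [table[c] for c in columns]
    any_na = np.logical_or.reduce([p.isna().to_numpy() for p in parts])
    joined = parts[0].astype(str)
    for p in parts[1:]:
        joined = joined + ":" + p.astype(str)
    joined = joined.where(~any_na)
    cats = sorted(joined.dropna().unique())
    return pd.Series(
        pd.Categorical(joined, categories=cats), index=table.index, name=":".join(columns)
    )


def _dummies(groups: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    codes = groups.cat.codes.to_numpy()
    k = len(groups.cat.categories)
    mat = (codes[:, None] == np.arange(k)[None, :]).astype(float)
    names = [f"{prefix}[{lvl}]" for lvl in groups.cat.categories]
    return mat, names


def _rank_reduce(
    X: np.ndarray, names: list[str], tol: float = 1e-8
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Keep a maximal independent column subset, preferring earlier columns.

    Returns (reduced X, kept names, orthonormal basis of the kept columns).
    """
    n, p = X.shape
    basis = np.empty((n, 0))
    keep: list[int] = []
    for j in range(p):
        c = X[:, j]
        r = c - basis @ (basis.T @ c)
        r = r - basis @ (basis.T @ r)  # second pass for numerical safety
        nr = np.linalg.norm(r)
        if nr > tol * max(1.0, np.linalg.norm(c)):
            basis = np.hstack([basis, (r / nr)[:, None]])
            keep.append(j)
    return X[:, keep], [names[j] for j in keep], basis


def build_design(
    table: pd.DataFrame, spec: ModelSpec, ped: Pedigree | None = None
) -> DesignSet:
    """Assemble response, full-rank fixed design and random incidences.

    Records missing the response, any model factor or covariate are dropped
    for this trait only.  Covariates are centered (on the retained records).
    Animal ids must exist in the pedigree when any pedigree-covariance term
    is present.
    """
    if spec.response not in table.columns:
        raise ConfigError(f"response column {spec.response!r} not in table")
    needed = {spec.response, spec.animal_column}
    for term in spec.fixed_factors:
        needed.update(term)
    needed.update(spec.covariates)
    for t in spec.random_terms:
        needed.update(t.group_by)
    missing_cols = sorted(c for c in needed if c not in table.columns)
    if missing_cols:
        raise ConfigError(f"model references absent columns: {missing_cols}")

    usable = table[sorted(needed)].notna().all(axis=1)
    df = table.loc[usable]
    n_dropped = int((~usable).sum())
    if len(df) == 0:
        raise ConfigError(f"no usable records for response {spec.response!r}")

    has_pedigree_term = any(t.covariance == PEDIGREE for t in spec.random_terms)
    if has_pedigree_term:
        if ped is None:
            raise ConfigError("pedigree-covariance term present but no pedigree given")
        ped.positions(df[spec.animal_column].astype(str))  # raises if absent

    y = pd.to_numeric(df[spec.response], errors="raise").to_numpy(dtype=float)

    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.intercept:
        cols.append(np.ones((len(df), 1)))
        names.append("intercept")
    for term in spec.fixed_factors:
        groups = build_contemporary_groups(df, list(term))
        mat, nm = _dummies(groups, ".".join(term))
        cols.append(mat)
        names.extend(nm)
    for cov in spec.covariates:
        v = pd.to_numeric(df[cov], errors="raise").to_numpy(dtype=float)
        cols.append((v - v.mean())[:, None])
        names.append(cov)
    X = np.hstack(cols) if cols else np.empty((len(df), 0))
    X, names, _ = _rank_reduce(X, names)

    blocks: list[RandomBlock] = []
    for t in spec.random_terms:
        groups = build_contemporary_groups(df, list(t.group_by))
        codes = groups.cat.codes.to_numpy().astype(np.int64)
        blocks.append(
            RandomBlock(t.name, t.covariance, codes, list(groups.cat.categories))
        )

    animals_arr = df[spec.animal_column].astype(str).to_numpy()
    if spec.occasion:
        miss = [c for c in spec.occasion if c not in df.columns]
        if miss:
            raise ConfigError(f"occasion references absent columns: {miss}")
        keys = [
            ("occ", a, *vals)
            for a, vals in zip(
                animals_arr, df[list(spec.occasion)].astype(str).itertuples(index=False)
            )
        ]
    else:
        # same-table-row identity: pairs only designs built from one table
        token = id(table)
        keys = [("row", token, lbl, a) for lbl, a in zip(df.index, animals_arr)]
    record_ids = np.empty(len(keys), dtype=object)
    record_ids[:] = keys

    return DesignSet(
        response=spec.response,
        y=y,
        X=X,
        x_names=names,
        random_blocks=blocks,
        animals=animals_arr,
        record_ids=record_ids,
        n_dropped=n_dropped,
    )


def screen_fixed_effects(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[Sequence[str] | str],
    alpha: float = 0.05,
    animal_column: str = "animal",
) -> pd.DataFrame:
    """Sequential (type-I) F tests of candidate fixed terms by ordinary OLS.

    Each term is either a factor interaction (sequence of column names, or a
    dot-joined string naming non-numeric columns) or a single numeric column
    treated as a covariate.  Terms are added to a fixed-effects-only model in
    the given order; each F statistic compares the fit before and after the
    term, against the residual mean square of the full model.  Terms with
    p < alpha are marked ``keep``.
    """
    parsed: list[tuple[str, list[str], bool]] = []
    for term in terms:
        cols = term.split(".") if isinstance(term, str) else list(term)
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ConfigError(f"screen term references absent columns: {missing}")
        is_cov = len(cols) == 1 and pd.api.types.is_numeric_dtype(table[cols[0]])
        parsed.append((".".join(cols), cols, is_cov))
    if len(parsed) < 2:
        raise ConfigError("screening needs at least 2 candidate terms")

    needed = {response} | {c for _, cols, _ in parsed for c in cols}
    df = table.loc[table[sorted(needed)].notna().all(axis=1)]
    y = pd.to_numeric(df[response]).to_numpy(dtype=float)
    n = len(df)

    # incremental Gram-Schmidt: track residual sum of squares after each term
    basis = np.ones((n, 1)) / np.sqrt(n)
    rank = 1
    sse = float(y @ y - np.sum((basis.T @ y) ** 2))
    rows = []
    for label, cols, is_cov in parsed:
        if is_cov:
            v = pd.to_numeric(df[cols[0]]).to_numpy(dtype=float)
            mat = (v - v.mean())[:, None]
        else:
            groups = build_contemporary_groups(df, cols)
            mat, _ = _dummies(groups, label)
        df_term = 0
        for j in range(mat.shape[1]):
            c = mat[:, j]
            r = c - basis @ (basis.T @ c)
            r = r - basis @ (basis.T @ r)
            nr = np.linalg.norm(r)
            if nr > 1e-8 * max(1.0, np.linalg.norm(c)):
                basis = np.hstack([basis, (r / nr)[:, None]])
                rank += 1
                df_term += 1
        proj = basis.T @ y
        sse_new = float(y @ y - proj @ proj)
        rows.append((label, df_term, sse - sse_new))
        sse = sse_new

    df_resid = n - rank
    if df_resid <= 0:
        raise ConfigError("saturated model: no residual degrees of freedom")
    mse = sse / df_resid
    out = []
    for label, df_term, ss in rows:
        if df_term == 0:
            out.append((label, 0, np.nan, np.nan, False))
            continue
        fstat = (ss / df_term) / mse if mse > 0 else np.inf
        pval = float(stats.f.sf(fstat, df_term, df_resid)) if np.isfinite(fstat) else 0.0
        out.append((label, df_term, fstat, pval, pval < alpha))
    return pd.DataFrame(out, columns=["term", "df", "F", "p_value", "keep"])
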