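"""REML estimation of variance components for the repeatability animal model.

The model for a trait y is

    y = Xb + Za + sum_k W_k pe_k + e,

with a ~ N(0, A sigma2_a) the additive genetic effects (A the numerator
relationship matrix), pe_k ~ N(0, I sigma2_pe_k) permanent-environment
effects on animal-level groupings (e.g. within and across measurement
rounds), and e ~ N(0, I sigma2_e).  Heritability is h2 = sigma2_a/sigma2_p
and repeatability (the intraclass correlation of repeated records) is
(sigma2_a + sum_k sigma2_pe_k)/sigma2_p, with sigma2_p the sum of all
components.  Bivariate fits replace each variance with a 2x2 covariance
matrix; the genetic correlation r_g = sigma_a12/sqrt(sigma_a11 sigma_a22)
is estimable through pedigree links even when the two traits are recorded
on disjoint sets of animals, in which case the residual covariance is not
estimable and is fixed at zero.

Estimation maximises the restricted likelihood by average-information (AI)
updates with expectation-maximisation fallback steps, on an unconstrained
scale (log variances; log-Cholesky factors for 2x2 matrices) so estimates
stay in the parameter space.  Standard errors of variance ratios and
correlations come from the inverse AI matrix by the delta method.

Two likelihood code paths exist deliberately.  ``restricted_loglik``
factorises the mixed-model equations sparsely (the route that scales to
deep pedigrees); the iterative fitter evaluates the equivalent marginal
form V = sum_k Z_k K_k Z_k' Sigma_k + ... densely, but only within the
independent record blocks found from the sparsity pattern of V, which for
family-structured data are small.  The two agree to numerical precision
and are cross-checked in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .model_design import PEDIGREE, ConfigError, DesignSet
from .pedigree import Pedigree, relationship_inverse, relationship_submatrix

LOG2PI = math.log(2.0 * math.pi)


class RemlError(RuntimeError):
    """Numerical failure in a REML fit (singular system, no variance)."""


# ---------------------------------------------------------------------------
# components and results
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Variance components by random-term name, plus the residual.

    Univariate: floats.  Bivariate: symmetric 2x2 arrays (between-trait
    covariance matrices).
    """

    terms: dict[str, float | np.ndarray]
    residual: float | np.ndarray

    def phenotypic(self) -> float | np.ndarray:
        total = self.residual
        for v in self.terms.values():
            total = total + v
        return total

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(dict(self.terms), self.residual)


@dataclass
class FitResult:
    """Converged (or flagged) REML fit with derived genetic parameters."""

    components: VarianceComponents
    loglik: float
    converged: bool
    n_iter: int
    n_records: int
    boundary: bool = False
    h2: float | None = None
    h2_se: float | None = None
    repeatability: float | None = None
    repeatability_se: float | None = None
    r_g: float | None = None
    r_g_se: float | None = None
    r_p: float | None = None
    r_p_se: float | None = None
    r_e: float | None = None
    r_e_se: float | None = None
    info_matrix: np.ndarray | None = field(default=None, repr=False)
    param_cov: np.ndarray | None = field(default=None, repr=False)
    param_labels: list[str] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        def _num(v):
            if v is None:
                return None
            if isinstance(v, np.ndarray):
                return v.tolist()
            return float(v)

        return {
            "components": {k: _num(v) for k, v in self.components.terms.items()},
            "residual": _num(self.components.residual),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "n_iter": int(self.n_iter),
            "n_records": int(self.n_records),
            "h2": _num(self.h2),
            "h2_se": _num(self.h2_se),
            "repeatability": _num(self.repeatability),
            "repeatability_se": _num(self.repeatability_se),
            "r_g": _num(self.r_g),
            "r_g_se": _num(self.r_g_se),
            "r_p": _num(self.r_p),
            "r_p_se": _num(self.r_p_se),
            "r_e": _num(self.r_e),
            "r_e_se": _num(self.r_e_se),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def significance(estimate: float, se: float, alpha: float = 0.05) -> bool:
    """Two-sided Wald z-test flag: True when |estimate/se| exceeds z_{1-a/2}."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0:
        return estimate != 0.0
    z = abs(estimate) / se
    return bool(z > stats.norm.ppf(1.0 - alpha / 2.0))


# ---------------------------------------------------------------------------
# unconstrained covariance parameterizations
# ---------------------------------------------------------------------------


class _CovParam:
    """Maps an unconstrained theta to a (nt x nt) covariance contribution.

    Exposes the constant symmetric basis matrices E_j such that
    dSigma = sum_j dv_j E_j over the distinct ("vech") elements v, and the
    Jacobian dv/dtheta, so the evaluator can work on the vech scale and the
    optimizer on the unconstrained scale.
    """

    n_theta: int
    n_vech: int
    labels: list[str]

    def sigma(self, th: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def e_mats(self) -> list[np.ndarray]:
        raise NotImplementedError

    def jac(self, th: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def theta_from_sigma(self, s: np.ndarray, floor: float) -> np.ndarray:
        raise NotImplementedError

    def clip(self, th: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
        raise NotImplementedError

    def em_sigma(self, s: np.ndarray, grad_v: np.ndarray, q: int) -> np.ndarray:
        """EM-REML update expressed through the vech-scale gradient."""
        raise NotImplementedError


class _ScalarCov(_CovParam):
    """One variance, possibly embedded on a single trait's diagonal."""

    def __init__(self, nt: int, trait: int = 0, label: str = "s2"):
        self.nt = nt
        self.trait = trait
        self.n_theta = 1
        self.n_vech = 1
        self.labels = [label]

    def sigma(self, th):
        s = np.zeros((self.nt, self.nt))
        s[self.trait, self.trait] = math.exp(th[0])
        return s

    def e_mats(self):
        e = np.zeros((self.nt, self.nt))
        e[self.trait, self.trait] = 1.0
        return [e]

    def jac(self, th):
        return np.array([[math.exp(th[0])]])

    def theta_from_sigma(self, s, floor):
        v = max(float(np.atleast_2d(s)[self.trait, self.trait]), floor)
        return np.array([math.log(v)])

    def clip(self, th, floor):
        lo = math.log(floor)
        clipped = th[0] < lo
        return np.array([max(th[0], lo)]), bool(clipped)

    def em_sigma(self, s, grad_v, q):
        v = float(np.atleast_2d(s)[self.trait, self.trait])
        out = np.array(s, dtype=float, copy=True)
        out[self.trait, self.trait] = v + 2.0 * v * v * grad_v[0] / q
        return out


class _DiagCov(_CovParam):
    """Two trait variances, zero covariance (e.g. residual of disjoint traits)."""

    def __init__(self, label: str = "s2"):
        self.nt = 2
        self.n_theta = 2
        self.n_vech = 2
        self.labels = [f"{label}[1,1]", f"{label}[2,2]"]

    def sigma(self, th):
        return np.diag(np.exp(2.0 * th))

    def e_mats(self):
        return [np.diag([1.0, 0.0]), np.diag([0.0, 1.0])]

    def jac(self, th):
        return np.diag(2.0 * np.exp(2.0 * th))

    def theta_from_sigma(self, s, floor):
        d = np.maximum(np.diag(np.atleast_2d(s)), floor)
        return 0.5 * np.log(d)

    def clip(self, th, floor):
        lo = 0.5 * math.log(floor)
        out = np.maximum(th, lo)
        return out, bool(np.any(th < lo))

    def em_sigma(self, s, grad_v, q):
        d = np.diag(np.atleast_2d(s)).copy()
        d = d + 2.0 * d * d * grad_v / q
        return np.diag(d)


class _FullCov(_CovParam):
    """Full 2x2 covariance via log-Cholesky: L = [[e^l11, 0], [a21, e^l22]]."""

    def __init__(self, label: str = "s2"):
        self.nt = 2
        self.n_theta = 3
        self.n_vech = 3
        self.labels = [f"{label}[1,1]", f"{label}[1,2]", f"{label}[2,2]"]

    def sigma(self, th):
        l11, a21, l22 = math.exp(th[0]), th[1], math.exp(th[2])
        return np.array(
            [[l11 * l11, a21 * l11], [a21 * l11, a21 * a21 + l22 * l22]]
        )

    def e_mats(self):
        return [
            np.array([[1.0, 0.0], [0.0, 0.0]]),
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.array([[0.0, 0.0], [0.0, 1.0]]),
        ]

    def jac(self, th):
        l11, a21, l22 = math.exp(th[0]), th[1], math.exp(th[2])
        # rows: d(s11, s12, s22) / d(th0=log l11, th1=a21, th2=log l22)
        return np.array(
            [
                [2.0 * l11 * l11, 0.0, 0.0],
                [a21 * l11, l11, 0.0],
                [0.0, 2.0 * a21, 2.0 * l22 * l22],
            ]
        )

    def theta_from_sigma(self, s, floor):
        s = np.atleast_2d(np.asarray(s, dtype=float))
        s11 = max(s[0, 0], floor)
        l11 = math.sqrt(s11)
        a21 = s[0, 1] / l11
        rem = max(s[1, 1] - a21 * a21, floor)
        return np.array([math.log(l11), a21, 0.5 * math.log(rem)])

    def clip(self, th, floor):
        lo = 0.5 * math.log(floor)
        out = th.copy()
        clipped = False
        for j in (0, 2):
            if out[j] < lo:
                out[j] = lo
                clipped = True
        return out, clipped

    def em_sigma(self, s, grad_v, q):
        g_full = np.array(
            [[grad_v[0], 0.5 * grad_v[1]], [0.5 * grad_v[1], grad_v[2]]]
        )
        return s + (2.0 / q) * (s @ g_full @ s)


# ---------------------------------------------------------------------------
# marginal (V-side) evaluator over independent record blocks
# ---------------------------------------------------------------------------


@dataclass
class _Term:
    """One covariance term of V (random effects or residual)."""

    name: str
    kind: str  # "identity" | "pedigree" | "residual"
    codes: np.ndarray  # level code per record, -1 = not in term
    n_levels: int
    param: _CovParam
    K: np.ndarray | None = None  # dense relationship submatrix for pedigree terms


class _Evaluator:
    """Restricted likelihood, gradient and AI matrix on the marginal form.

    V is block-diagonal over connected components of its sparsity pattern
    (records linked by shared random-effect levels, nonzero relationship,
    or residual pairing); each component is handled densely.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        trait_of: np.ndarray,
        terms: list[_Term],
        n_traits: int,
    ):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.trait_of = trait_of
        self.terms = terms
        self.n_traits = n_traits
        self.offsets: list[int] = []
        off = 0
        for t in terms:
            self.offsets.append(off)
            off += t.param.n_vech
        self.n_vech = off
        self._build_blocks()

    # -- structure ----------------------------------------------------------

    def _build_blocks(self) -> None:
        n = self.n
        adj = sparse.csr_matrix((n, n))
        rows = np.arange(n)
        for t in self.terms:
            mask = t.codes >= 0
            z = sparse.csr_matrix(
                (np.ones(mask.sum()), (rows[mask], t.codes[mask])),
                shape=(n, max(t.n_levels, 1)),
            )
            if t.K is None:
                pat = z @ z.T
            else:
                kp = sparse.csr_matrix((np.abs(t.K) > 1e-12).astype(float))
                pat = z @ kp @ z.T
            adj = adj + pat
        _, labels = csgraph.connected_components(adj, directed=False)
        order = np.argsort(labels, kind="stable")
        self.blocks: list[np.ndarray] = [
            order[labels[order] == b] for b in np.unique(labels[order])
        ]
        # per block, per term: theta-independent structure matrix M
        self._m: list[list[np.ndarray]] = []
        self._tr_ix = []
        for idx in self.blocks:
            ms = []
            for t in self.terms:
                lev = t.codes[idx]
                if t.K is None:
                    m = (lev[:, None] == lev[None, :]) & (lev[:, None] >= 0)
                    m = m.astype(float)
                else:
                    safe = np.where(lev >= 0, lev, 0)
                    m = t.K[np.ix_(safe, safe)].copy()
                    m[lev < 0, :] = 0.0
                    m[:, lev < 0] = 0.0
                ms.append(m)
            self._m.append(ms)
            tr = self.trait_of[idx]
            self._tr_ix.append(np.ix_(tr, tr))

    # -- likelihood ---------------------------------------------------------

    def _split(self, theta: np.ndarray) -> list[np.ndarray]:
        out, j = [], 0
        for t in self.terms:
            out.append(theta[j : j + t.param.n_theta])
            j += t.param.n_theta
        return out

    def sigmas(self, theta: np.ndarray) -> list[np.ndarray]:
        return [t.param.sigma(th) for t, th in zip(self.terms, self._split(theta))]

    def _v_block(self, b: int, sig: list[np.ndarray]) -> np.ndarray:
        ix = self._tr_ix[b]
        v = np.zeros_like(self._m[b][0])
        for m, s in zip(self._m[b], sig):
            if self.n_traits == 1:
                v += s[0, 0] * m
            else:
                v += m * s[ix]
        return v

    def loglik(self, theta: np.ndarray) -> float:
        sig = self.sigmas(theta)
        logdet_v = 0.0
        bmat = np.zeros((self.p, self.p))
        xty = np.zeros(self.p)
        yty = 0.0
        for b, idx in enumerate(self.blocks):
            v = self._v_block(b, sig)
            try:
                c = cho_factor(v, lower=True)
            except np.linalg.LinAlgError:
                return -np.inf
            logdet_v += 2.0 * np.sum(np.log(np.diag(c[0])))
            xb, yb = self.X[idx], self.y[idx]
            vix = cho_solve(c, xb)
            viy = cho_solve(c, yb)
            bmat += xb.T @ vix
            xty += xb.T @ viy
            yty += yb @ viy
        try:
            cb = cho_factor(bmat, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_b = 2.0 * np.sum(np.log(np.diag(cb[0])))
        bhat = cho_solve(cb, xty)
        ypy = yty - xty @ bhat
        return -0.5 * (logdet_v + logdet_b + ypy + (self.n - self.p) * LOG2PI)

    def loglik_grad_ai(
        self, theta: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Restricted log-likelihood with exact gradient and AI matrix.

        Both are on the vech scale (distinct covariance elements of every
        term, in term order); callers chain through each parameterization's
        Jacobian.
        """
        sig = self.sigmas(theta)
        emats = [t.param.e_mats() for t in self.terms]
        nv = self.n_vech
        p = self.p

        chols, vixs = [], []
        bmat = np.zeros((p, p))
        xty = np.zeros(p)
        yty = 0.0
        logdet_v = 0.0
        vs = []
        for b, idx in enumerate(self.blocks):
            v = self._v_block(b, sig)
            try:
                c = cho_factor(v, lower=True)
            except np.linalg.LinAlgError as exc:
                raise RemlError("V not positive definite at current parameters") from exc
            logdet_v += 2.0 * np.sum(np.log(np.diag(c[0])))
            xb, yb = self.X[idx], self.y[idx]
            vix = cho_solve(c, xb)
            bmat += xb.T @ vix
            xty += xb.T @ cho_solve(c, yb)
            yty += yb @ cho_solve(c, yb)
            chols.append(c)
            vixs.append(vix)
            vs.append(v)
        try:
            cb = cho_factor(bmat, lower=True)
        except np.linalg.LinAlgError as exc:
            raise RemlError("X'V^-1X singular (fixed effects not estimable)") from exc
        logdet_b = 2.0 * np.sum(np.log(np.diag(cb[0])))
        bhat = cho_solve(cb, xty)
        ypy = yty - xty @ bhat
        ll = -0.5 * (logdet_v + logdet_b + ypy + (self.n - self.p) * LOG2PI)

        tr1 = np.zeros(nv)  # tr(V^-1 Vdot)
        qmats = [np.zeros((p, p)) for _ in range(nv)]  # X'V^-1 Vdot V^-1 X
        upy = np.zeros(nv)  # y'P Vdot P y
        cvec = np.zeros((p, nv))  # X'V^-1 f_j
        fvf = np.zeros((nv, nv))  # f_i' V^-1 f_j
        for b, idx in enumerate(self.blocks):
            c, vix = chols[b], vixs[b]
            nb = len(idx)
            vinv = cho_solve(c, np.eye(nb))
            py = cho_solve(c, self.y[idx] - self.X[idx] @ bhat)
            fs = np.empty((nb, nv))
            j = 0
            for k, t in enumerate(self.terms):
                m = self._m[b][k]
                for e in emats[k]:
                    if self.n_traits == 1:
                        vd = e[0, 0] * m
                    else:
                        vd = m * e[self._tr_ix[b]]
                    tr1[j] += np.sum(vinv * vd)
                    qmats[j] += vix.T @ vd @ vix
                    fs[:, j] = vd @ py
                    j += 1
            upy += fs.T @ py
            vif = cho_solve(c, fs)
            cvec += self.X[idx].T @ vif
            fvf += fs.T @ vif

        binv_c = cho_solve(cb, cvec)
        grad = np.empty(nv)
        for j in range(nv):
            tr_p = tr1[j] - np.trace(cho_solve(cb, qmats[j]))
            grad[j] = -0.5 * (tr_p - upy[j])
        ai = 0.5 * (fvf - cvec.T @ binv_c)
        return ll, grad, ai


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


def _effectively_identity(term: _Term) -> bool:
    if term.K is None:
        return True
    return bool(np.allclose(term.K, np.eye(term.K.shape[0]), atol=1e-12))


def _check_identifiability(terms: list[_Term], n_records: int) -> None:
    """Refuse specifications where two terms induce identical covariance.

    With identity kinship (unrelated recorded animals), an animal genetic
    term and an animal permanent-environment term are indistinguishable and
    AI-REML would return an arbitrary ridge solution; similarly a term with
    one record per level duplicates the residual.
    """
    partitions = []
    for t in terms:
        if t.kind == "residual":
            continue
        ident = _effectively_identity(t)
        partitions.append((t, ident))
        if ident and t.n_levels == n_records and np.all(t.codes >= 0):
            raise ConfigError(
                f"random term {t.name!r} has one record per level and identity "
                "covariance: confounded with the residual"
            )
    for i in range(len(partitions)):
        for j in range(i + 1, len(partitions)):
            (ta, ia), (tb, ib) = partitions[i], partitions[j]
            if not (ia and ib):
                continue
            if _same_partition(ta.codes, tb.codes):
                raise ConfigError(
                    f"random terms {ta.name!r} and {tb.name!r} group records "
                    "identically and both have (effectively) identity covariance: "
                    "variances are not separable. Genetic and permanent-"
                    "environment effects need pedigree relationships to split."
                )


def _same_partition(c1: np.ndarray, c2: np.ndarray) -> bool:
    if np.any((c1 < 0) != (c2 < 0)):
        return False
    m = c1 >= 0
    pairs = set(zip(c1[m].tolist(), c2[m].tolist()))
    return len(pairs) == len(set(a for a, _ in pairs)) == len(
        set(b for _, b in pairs)
    )


def _terms_univariate(design: DesignSet, ped: Pedigree | None) -> list[_Term]:
    terms = []
    for blk in design.random_blocks:
        if blk.covariance == PEDIGREE:
            if ped is None:
                raise ConfigError("pedigree term present but no pedigree given")
            k = relationship_submatrix(ped, [str(a) for a in blk.levels])
            terms.append(_Term(blk.name, PEDIGREE, blk.codes, blk.n_levels, _ScalarCov(1), k))
        else:
            terms.append(_Term(blk.name, "identity", blk.codes, blk.n_levels, _ScalarCov(1)))
    n = design.n_records
    terms.append(
        _Term("residual", "residual", np.arange(n, dtype=np.int64), n, _ScalarCov(1))
    )
    return terms


def _ols_residual_variance(design: DesignSet) -> float:
    x, y = design.X, design.y
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = max(len(y) - x.shape[1], 1)
    s2 = float(resid @ resid / dof)
    if s2 <= 0:
        raise RemlError(f"response {design.response!r} has no residual variance")
    return s2


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


@dataclass
class _FitState:
    theta: np.ndarray
    loglik: float
    grad: np.ndarray
    ai: np.ndarray
    converged: bool
    n_iter: int
    boundary: bool


def _maximize(
    ev: _Evaluator,
    theta0: np.ndarray,
    floor: float,
    max_iter: int = 100,
    ll_tol: float = 1e-8,
    g_tol: float = 1e-4,
) -> _FitState:
    """AI updates with step halving and EM fallback; likelihood never decreases."""
    theta = theta0.copy()
    ll, grad_v, ai_v = ev.loglik_grad_ai(theta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        jacs = [t.param.jac(th) for t, th in zip(ev.terms, ev._split(theta))]
        jall = _block_diag(jacs)
        grad_t = jall.T @ grad_v
        ai_t = jall.T @ ai_v @ jall
        gnorm = float(np.max(np.abs(grad_t)))

        ridge = 1e-8 * (1.0 + np.trace(ai_t) / max(len(theta), 1))
        try:
            step = np.linalg.solve(ai_t + ridge * np.eye(len(theta)), grad_t)
        except np.linalg.LinAlgError:
            step = grad_t / (np.abs(np.diag(ai_t)) + 1.0)
        nstep = float(np.max(np.abs(step)))
        if nstep > 5.0:  # cap: log-scale moves beyond e^5 are never sensible
            step *= 5.0 / nstep

        ll_new, theta_new = -np.inf, theta
        s = 1.0
        while s >= 1.0 / 1024.0:
            cand = _clip_theta(ev, theta + s * step, floor)[0]
            cand_ll = ev.loglik(cand)
            if cand_ll > ll + 1e-14:
                ll_new, theta_new = cand_ll, cand
                break
            s *= 0.5
        if not np.isfinite(ll_new):
            # EM fallback: guaranteed uphill (or stationary) step
            cand = _em_step(ev, theta, grad_v, floor)
            cand_ll = ev.loglik(cand)
            if cand_ll > ll + 1e-14:
                ll_new, theta_new = cand_ll, cand

        if not np.isfinite(ll_new):  # no uphill direction found
            converged = gnorm < 10.0 * g_tol
            break
        rel = abs(ll_new - ll) / (1.0 + abs(ll_new))
        theta, ll = theta_new, ll_new
        ll, grad_v, ai_v = ev.loglik_grad_ai(theta)
        jall = _block_diag(
            [t.param.jac(th) for t, th in zip(ev.terms, ev._split(theta))]
        )
        gnorm = float(np.max(np.abs(jall.T @ grad_v)))
        if rel < ll_tol and gnorm < g_tol:
            converged = True
            break

    theta, boundary = _clip_theta(ev, theta, floor)
    # flag near-zero components too: flat likelihood regions let the
    # optimizer converge slightly above the hard floor
    total = sum(float(np.trace(np.atleast_2d(s))) for s in ev.sigmas(theta))
    for t, s in zip(ev.terms, ev.sigmas(theta)):
        diag = np.diag(np.atleast_2d(s))
        if np.any(diag[diag > 0] < 1e-5 * total):
            boundary = True
    jacs = [t.param.jac(th) for t, th in zip(ev.terms, ev._split(theta))]
    jall = _block_diag(jacs)
    return _FitState(
        theta=theta,
        loglik=ll,
        grad=jall.T @ grad_v,
        ai=jall.T @ ai_v @ jall,
        converged=converged,
        n_iter=n_iter,
        boundary=boundary,
    )


def _clip_theta(ev: _Evaluator, theta: np.ndarray, floor: float):
    out, j, any_clip = theta.copy(), 0, False
    for t in ev.terms:
        th = out[j : j + t.param.n_theta]
        clipped_th, c = t.param.clip(th, floor)
        out[j : j + t.param.n_theta] = clipped_th
        any_clip |= c
        j += t.param.n_theta
    return out, any_clip


def _em_step(ev: _Evaluator, theta: np.ndarray, grad_v: np.ndarray, floor: float):
    out, j, jv = theta.copy(), 0, 0
    for t in ev.terms:
        th = theta[j : j + t.param.n_theta]
        gv = grad_v[jv : jv + t.param.n_vech]
        s_new = t.param.em_sigma(t.param.sigma(th), gv, t.n_levels)
        out[j : j + t.param.n_theta] = t.param.theta_from_sigma(s_new, floor)
        j += t.param.n_theta
        jv += t.param.n_vech
    return _clip_theta(ev, out, floor)[0]


def _block_diag(mats: Sequence[np.ndarray]) -> np.ndarray:
    rows = sum(m.shape[0] for m in mats)
    cols = sum(m.shape[1] for m in mats)
    out = np.zeros((rows, cols))
    r = c = 0
    for m in mats:
        out[r : r + m.shape[0], c : c + m.shape[1]] = m
        r += m.shape[0]
        c += m.shape[1]
    return out


def _param_cov(state: _FitState, ev: _Evaluator) -> tuple[np.ndarray, np.ndarray]:
    """Covariance of the vech-scale parameters from the inverse AI matrix."""
    jall = _block_diag(
        [t.param.jac(th) for t, th in zip(ev.terms, ev._split(state.theta))]
    )
    ai_t = state.ai
    try:
        cov_t = np.linalg.inv(ai_t + 1e-12 * np.eye(len(ai_t)))
    except np.linalg.LinAlgError:
        cov_t = np.linalg.pinv(ai_t)
    return jall @ cov_t @ jall.T, jall


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def restricted_loglik(
    design: DesignSet,
    components: VarianceComponents,
    ped: Pedigree | None = None,
) -> float:
    """Restricted log-likelihood via sparse mixed-model-equations factorization.

    Evaluates the REML likelihood of y under
    V = sum_k Z_k G_k Z_k' + I sigma2_e, with G = A sigma2_a for the
    pedigree term (over all pedigree animals, using the sparse A inverse)
    and G = I sigma2_pe for permanent-environment terms.  Includes the
    -(n-p)/2 log(2 pi) constant, so it is directly comparable with a dense
    projection-form evaluation.
    """
    x, y = design.X, design.y
    n, p = x.shape
    s2e = float(components.residual)
    if s2e <= 0:
        raise RemlError("residual variance must be positive")

    z_blocks: list[sparse.csr_matrix] = []
    ginv_blocks: list[sparse.csr_matrix] = []
    logdet_g = 0.0
    rows = np.arange(n)
    for blk in design.random_blocks:
        if blk.name not in components.terms:
            raise ConfigError(f"no variance supplied for random term {blk.name!r}")
        s2k = float(components.terms[blk.name])
        if s2k <= 0:
            raise RemlError(f"variance for term {blk.name!r} must be positive")
        if blk.covariance == PEDIGREE:
            if ped is None:
                raise ConfigError("pedigree term present but no pedigree given")
            q = len(ped)
            pos = ped.positions([str(a) for a in blk.levels])
            cols = pos[blk.codes]
            ainv = relationship_inverse(ped)
            ginv_blocks.append((ainv / s2k).tocsr())
            # log|A| = sum log of Mendelian-sampling variances (A = T D T')
            from .pedigree import _mendelian_variance

            logdet_a = float(
                sum(
                    math.log(_mendelian_variance(i, ped.sire, ped.dam, ped.f))
                    for i in range(q)
                )
            )
            logdet_g += q * math.log(s2k) + logdet_a
        else:
            q = blk.n_levels
            cols = blk.codes
            ginv_blocks.append(sparse.identity(q, format="csr") / s2k)
            logdet_g += q * math.log(s2k)
        z_blocks.append(
            sparse.csr_matrix((np.ones(n), (rows, cols)), shape=(n, q))
        )

    if z_blocks:
        z = sparse.hstack(z_blocks, format="csr")
        ginv = sparse.block_diag(ginv_blocks, format="csr")
        xs = sparse.csr_matrix(x)
        w = sparse.hstack([xs, z], format="csr")
        c = (w.T @ w) / s2e + sparse.block_diag(
            [sparse.csr_matrix((p, p)), ginv], format="csr"
        )
        rhs = np.asarray((w.T @ y) / s2e).ravel()
    else:
        c = sparse.csr_matrix(x.T @ x / s2e)
        rhs = x.T @ y / s2e

    try:
        lu = splu(c.tocsc())
    except RuntimeError as exc:
        raise RemlError(f"singular mixed-model equations: {exc}") from exc
    udiag = lu.U.diagonal()
    if np.any(np.abs(udiag) < 1e-300):
        raise RemlError(
            "singular mixed-model equations (zero pivot); check that the "
            "model is identifiable and variances are not degenerate"
        )
    logdet_c = float(np.sum(np.log(np.abs(udiag))))
    sol = lu.solve(rhs)
    ypy = float(y @ y / s2e - rhs @ sol)
    logdet_r = n * math.log(s2e)
    return -0.5 * (logdet_r + logdet_g + logdet_c + ypy + (n - p) * LOG2PI)


def _initial_theta(
    ev: _Evaluator, terms: list[_Term], s2p: float, init: VarianceComponents | None,
    floor: float,
) -> np.ndarray:
    pieces = []
    n_random = sum(1 for t in terms if t.kind != "residual")
    for t in terms:
        if init is not None:
            if t.kind == "residual":
                s0 = np.atleast_2d(np.asarray(init.residual, dtype=float))
            elif t.name in init.terms:
                s0 = np.atleast_2d(np.asarray(init.terms[t.name], dtype=float))
            else:
                s0 = None
        else:
            s0 = None
        if s0 is None:
            # split 40% of the OLS residual variance evenly over random terms
            share = 0.6 if t.kind == "residual" else 0.4 / max(n_random, 1)
            s0 = np.array([[share * s2p]])
        pieces.append(t.param.theta_from_sigma(np.atleast_2d(s0), floor))
    return np.concatenate(pieces)


def fit_univariate(
    design: DesignSet,
    ped: Pedigree | None = None,
    init: VarianceComponents | None = None,
    max_iter: int = 100,
    ll_tol: float = 1e-8,
    g_tol: float = 1e-4,
) -> FitResult:
    """Fit the repeatability animal model to one trait by AI-REML.

    Returns estimates of every variance component, heritability
    h2 = sigma2_a / sigma2_p and repeatability
    (sigma2_a + sum of PE variances) / sigma2_p with delta-method standard
    errors from the inverse average-information matrix.  Non-convergence and
    boundary solutions are flagged on the result, never silent.
    """
    terms = _terms_univariate(design, ped)
    _check_identifiability(terms, design.n_records)
    ev = _Evaluator(design.y, design.X, np.zeros(design.n_records, dtype=np.int64), terms, 1)
    s2p = _ols_residual_variance(design)
    floor = 1e-10 * s2p
    theta0 = _initial_theta(ev, terms, s2p, init, floor)
    state = _maximize(ev, theta0, floor, max_iter, ll_tol, g_tol)

    sig = ev.sigmas(state.theta)
    comp = VarianceComponents(
        {t.name: float(s[0, 0]) for t, s in zip(terms, sig) if t.kind != "residual"},
        float(sig[-1][0, 0]),
    )
    cov_v, _ = _param_cov(state, ev)

    names = [t.name for t in terms]  # vech order == term order (scalars)
    is_genetic = np.array([t.kind == PEDIGREE for t in terms], dtype=float)
    is_individual = np.array([t.kind != "residual" for t in terms], dtype=float)
    v = np.array([float(s[0, 0]) for s in sig])
    s2_tot = float(v.sum())
    s2_a = float((v * is_genetic).sum())
    s2_ind = float((v * is_individual).sum())

    h2 = s2_a / s2_tot
    rep = s2_ind / s2_tot
    dh2 = (is_genetic - h2) / s2_tot
    drep = (is_individual - rep) / s2_tot
    h2_se = float(np.sqrt(max(dh2 @ cov_v @ dh2, 0.0)))
    rep_se = float(np.sqrt(max(drep @ cov_v @ drep, 0.0)))

    has_repeats = any(
        t.kind != "residual" and t.n_levels < design.n_records for t in terms
    )
    return FitResult(
        components=comp,
        loglik=state.loglik,
        converged=state.converged,
        n_iter=state.n_iter,
        n_records=design.n_records,
        boundary=state.boundary,
        h2=h2 if s2_a > 0 or any(is_genetic) else None,
        h2_se=h2_se if any(is_genetic) else None,
        repeatability=rep if has_repeats else None,
        repeatability_se=rep_se if has_repeats else None,
        info_matrix=state.ai,
        param_cov=cov_v,
        param_labels=names,
    )


def _terms_bivariate(
    d1: DesignSet, d2: DesignSet, ped: Pedigree | None
) -> tuple[list[_Term], np.ndarray, np.ndarray, np.ndarray]:
    """Stack two designs and build shared/trait-specific covariance terms."""
    n1, n2 = d1.n_records, d2.n_records
    y = np.concatenate([d1.y, d2.y])
    x = _block_diag([d1.X, d2.X])
    trait_of = np.concatenate(
        [np.zeros(n1, dtype=np.int64), np.ones(n2, dtype=np.int64)]
    )

    blocks1 = {b.name: b for b in d1.random_blocks}
    blocks2 = {b.name: b for b in d2.random_blocks}
    names = list(blocks1) + [nm for nm in blocks2 if nm not in blocks1]
    terms: list[_Term] = []
    for nm in names:
        b1, b2 = blocks1.get(nm), blocks2.get(nm)
        if b1 is not None and b2 is not None:
            if b1.covariance != b2.covariance:
                raise ConfigError(
                    f"term {nm!r} has different covariance kinds across traits"
                )
            levels = list(dict.fromkeys([*b1.levels, *b2.levels]))
            lev_ix = {lv: i for i, lv in enumerate(levels)}
            codes = np.concatenate(
                [
                    np.array([lev_ix[b1.levels[c]] for c in b1.codes]),
                    np.array([lev_ix[b2.levels[c]] for c in b2.codes]),
                ]
            ).astype(np.int64)
            if b1.covariance == PEDIGREE:
                k = relationship_submatrix(ped, [str(a) for a in levels])
                terms.append(_Term(nm, PEDIGREE, codes, len(levels), _FullCov(nm), k))
            else:
                terms.append(_Term(nm, "identity", codes, len(levels), _FullCov(nm)))
        else:
            blk = b1 if b1 is not None else b2
            trait = 0 if b1 is not None else 1
            if trait == 0:
                codes = np.concatenate([blk.codes, np.full(n2, -1, dtype=np.int64)])
            else:
                codes = np.concatenate([np.full(n1, -1, dtype=np.int64), blk.codes])
            if blk.covariance == PEDIGREE:
                k = relationship_submatrix(ped, [str(a) for a in blk.levels])
                terms.append(
                    _Term(nm, PEDIGREE, codes, blk.n_levels, _ScalarCov(2, trait, nm), k)
                )
            else:
                terms.append(
                    _Term(nm, "identity", codes, blk.n_levels, _ScalarCov(2, trait, nm))
                )

    # residual: records of the two traits sharing a source row (same animal-
    # occasion) are residual-correlated; otherwise the covariance is fixed 0.
    ids1 = {rid: i for i, rid in enumerate(d1.record_ids)}
    occ = np.arange(n1 + n2, dtype=np.int64)
    n_shared = 0
    for j, rid in enumerate(d2.record_ids):
        i = ids1.get(rid)
        if i is not None:
            occ[n1 + j] = i
            n_shared += 1
    _, occ = np.unique(occ, return_inverse=True)
    param: _CovParam = _FullCov("residual") if n_shared > 0 else _DiagCov("residual")
    terms.append(_Term("residual", "residual", occ, int(occ.max()) + 1, param))
    return terms, y, x, trait_of


def fit_bivariate(
    design1: DesignSet,
    design2: DesignSet,
    ped: Pedigree | None = None,
    init: tuple[FitResult, FitResult] | None = None,
    max_iter: int = 200,
    ll_tol: float = 1e-8,
    g_tol: float = 1e-4,
) -> FitResult:
    """Bivariate AI-REML: 2x2 genetic/PE/residual covariance matrices.

    Traits may be recorded on overlapping or disjoint animal sets; for
    trait pairs never co-recorded on the same animal-occasion the residual
    covariance is constrained to zero and the correlation flows through the
    pedigree.  Returns r_g, r_p and r_e with delta-method standard errors;
    positive-definiteness is enforced by the log-Cholesky parameterization.
    """
    for d in (design1, design2):
        if np.var(d.y) <= 0:
            raise RemlError(f"response {d.response!r} has no variance")
    terms, y, x, trait_of = _terms_bivariate(design1, design2, ped)
    _check_identifiability(terms, len(y))
    ev = _Evaluator(y, x, trait_of, terms, 2)

    s2p1 = _ols_residual_variance(design1)
    s2p2 = _ols_residual_variance(design2)
    floor = 1e-10 * min(s2p1, s2p2)

    init_vc: VarianceComponents | None = None
    if init is not None:
        f1, f2 = init
        merged: dict[str, np.ndarray] = {}
        for t in terms:
            if t.kind == "residual":
                continue
            v1 = f1.components.terms.get(t.name)
            v2 = f2.components.terms.get(t.name)
            if isinstance(t.param, _FullCov):
                m = np.diag(
                    [v1 if v1 is not None else s2p1 * 0.1,
                     v2 if v2 is not None else s2p2 * 0.1]
                )
                # small positive seed covariance keeps the Cholesky off axis
                m[0, 1] = m[1, 0] = 0.1 * math.sqrt(max(m[0, 0] * m[1, 1], 0.0))
                merged[t.name] = m
            else:
                trait = t.param.trait
                val = v1 if trait == 0 else v2
                m = np.zeros((2, 2))
                m[trait, trait] = val if val is not None else 0.1 * (
                    s2p1 if trait == 0 else s2p2
                )
                merged[t.name] = m
        res = np.diag([float(f1.components.residual), float(f2.components.residual)])
        init_vc = VarianceComponents(merged, res)

    s2p = 0.5 * (s2p1 + s2p2)
    theta0 = _initial_theta_bi(ev, terms, s2p1, s2p2, init_vc, floor)
    state = _maximize(ev, theta0, floor, max_iter, ll_tol, g_tol)

    sig = ev.sigmas(state.theta)
    comp = VarianceComponents(
        {t.name: s.copy() for t, s in zip(terms, sig) if t.kind != "residual"},
        sig[-1].copy(),
    )
    cov_v, _ = _param_cov(state, ev)

    # vech bookkeeping: E matrices of each term, flattened in term order
    e_all: list[tuple[int, np.ndarray]] = []
    for k, t in enumerate(terms):
        for e in t.param.e_mats():
            e_all.append((k, e))

    def _corr_and_se(mat_terms: list[int]) -> tuple[float | None, float | None]:
        s = np.zeros((2, 2))
        for k in mat_terms:
            s = s + sig[k]
        if s[0, 0] <= 0 or s[1, 1] <= 0:
            return None, None
        r = s[0, 1] / math.sqrt(s[0, 0] * s[1, 1])
        gmat = np.array(
            [
                [-r / (2.0 * s[0, 0]), 0.5 / math.sqrt(s[0, 0] * s[1, 1])],
                [0.5 / math.sqrt(s[0, 0] * s[1, 1]), -r / (2.0 * s[1, 1])],
            ]
        )
        grad = np.array(
            [np.sum(gmat * e) if k in mat_terms else 0.0 for k, e in e_all]
        )
        se = float(np.sqrt(max(grad @ cov_v @ grad, 0.0)))
        return float(r), se

    genetic_terms = [k for k, t in enumerate(terms) if t.kind == PEDIGREE]
    if not genetic_terms:
        raise ConfigError("bivariate fit needs a pedigree (genetic) term")
    r_g, r_g_se = _corr_and_se(genetic_terms)
    r_p, r_p_se = _corr_and_se(list(range(len(terms))))
    r_e, r_e_se = None, None
    if isinstance(terms[-1].param, _FullCov):
        r_e, r_e_se = _corr_and_se([len(terms) - 1])

    return FitResult(
        components=comp,
        loglik=state.loglik,
        converged=state.converged,
        n_iter=state.n_iter,
        n_records=len(y),
        boundary=state.boundary,
        r_g=r_g,
        r_g_se=r_g_se,
        r_p=r_p,
        r_p_se=r_p_se,
        r_e=r_e,
        r_e_se=r_e_se,
        info_matrix=state.ai,
        param_cov=cov_v,
        param_labels=[lb for t in terms for lb in t.param.labels],
    )


def _initial_theta_bi(
    ev: _Evaluator,
    terms: list[_Term],
    s2p1: float,
    s2p2: float,
    init: VarianceComponents | None,
    floor: float,
) -> np.ndarray:
    pieces = []
    n_random = max(sum(1 for t in terms if t.kind != "residual"), 1)
    for t in terms:
        s0 = None
        if init is not None:
            if t.kind == "residual":
                s0 = np.atleast_2d(np.asarray(init.residual, dtype=float))
            elif t.name in init.terms:
                s0 = np.atleast_2d(np.asarray(init.terms[t.name], dtype=float))
        if s0 is None:
            if t.kind == "residual":
                s0 = np.diag([0.5 * s2p1, 0.5 * s2p2])
            else:
                share = 0.4 / n_random
                s0 = np.diag([share * s2p1, share * s2p2])
                if isinstance(t.param, _FullCov):
                    s0[0, 1] = s0[1, 0] = 0.1 * math.sqrt(s0[0, 0] * s0[1, 1])
        pieces.append(t.param.theta_from_sigma(s0, floor))
    return np.concatenate(pieces)
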