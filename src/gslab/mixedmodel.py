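"""Pedigree-based linear mixed models (ABLUP) for multi-site progeny trials.

Two canonical models are provided. The full-sib model is

    y = Xb + Z1 a + Z2 sa + Z3 s(rep) + Z4 sf + Z5 f + e

with a ~ N(0, A s2_a) over the whole pedigree, site x additive sa, block
within site s(rep), site x family sf, family f, and residual e; the
open-pollinated half-sib model drops sf and f. Fixed effects are the
overall mean and site.

Variance components are estimated by EM-REML (monotone in the REML
log-likelihood, iterated on the observation-level covariance), and breeding
values by a direct solve of Henderson's mixed-model equations, which
propagate information through A to non-phenotyped pedigree members.

The site x additive term uses additive relationships within site and zero
covariance across sites (a direct sum of A blocks). With a single tree per
genotype per site — the situation in these trials — a plain identity sa
covariance is completely confounded with the residual; the structured form
is the standard, identifiable formulation (``sa_structure="iid"`` restores
the literal identity reading for experimentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotrf, dpotri

from .pedigree import PedigreeTable, RelationshipMatrix, build_numerator_relationship
from .varcomp import VarianceComponents, heritability

__all__ = [
    "ModelSpec",
    "VarianceEstimates",
    "EBVResult",
    "MMESystem",
    "build_mme",
    "solve_blup",
    "em_reml",
    "heritability",
    "ablup_cross_validate",
    "PedigreeBLUP",
    "PedigreeBLUPResults",
]

_TERM_TO_VC = {
    "additive": "sigma2_a",
    "site_additive": "sigma2_sa",
    "block": "sigma2_srep",
    "site_family": "sigma2_sf",
    "family": "sigma2_f",
}
_FULLSIB_TERMS = ("additive", "site_additive", "block", "site_family", "family")
_HALFSIB_TERMS = ("additive", "site_additive", "block")


@dataclass(frozen=True)
class ModelSpec:
    """Which random terms enter the model and how sa is structured."""

    kind: str
    terms: tuple
    sa_structure: str = "additive"

    def __post_init__(self):
        for t in self.terms:
            if t not in _TERM_TO_VC:
                raise ValueError(f"unknown random term {t!r}")
        if "additive" not in self.terms:
            raise ValueError("the additive term is mandatory")
        if self.sa_structure not in ("additive", "iid"):
            raise ValueError("sa_structure must be 'additive' or 'iid'")

    @classmethod
    def fullsib(cls, sa_structure: str = "additive") -> "ModelSpec":
        return cls("fullsib", _FULLSIB_TERMS, sa_structure)

    @classmethod
    def halfsib(cls, sa_structure: str = "additive") -> "ModelSpec":
        return cls("halfsib", _HALFSIB_TERMS, sa_structure)

    @classmethod
    def custom(cls, terms, sa_structure: str = "additive") -> "ModelSpec":
        return cls("custom", tuple(terms), sa_structure)


@dataclass(frozen=True)
class VarianceEstimates:
    """EM-REML output; ``converged=False`` marks provisional estimates."""

    vc: VarianceComponents
    converged: bool
    n_iter: int
    loglik: float
    loglik_path: np.ndarray


@dataclass
class _Term:
    name: str
    Z: np.ndarray  # n_obs x q incidence
    G: np.ndarray | None  # level covariance (None = identity)
    B: np.ndarray  # Z G Z' on observations
    q: int  # number of levels of the random vector
    level_ids: list
    G_inv: np.ndarray | None = None  # filled on demand for the MME


def _site_design(phen: pd.DataFrame):
    """Fixed-effect design: intercept plus treatment-coded site."""
    sites = sorted(phen["site"].astype(str).unique())
    n = len(phen)
    X = [np.ones(n)]
    names = ["mean"]
    for s in sites[1:]:
        X.append((phen["site"].astype(str) == s).to_numpy(float))
        names.append(f"site[{s}]")
    return np.column_stack(X), names


def _indicator(labels) -> tuple:
    levels, inv = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    Z = np.zeros((len(inv), len(levels)))
    Z[np.arange(len(inv)), inv] = 1.0
    return Z, [str(v) for v in levels]


def _build_terms(phen: pd.DataFrame, spec: ModelSpec, A: RelationshipMatrix) -> list:
    ids = phen["id"].astype(str).to_numpy()
    obs_idx = A.indices(ids)  # raises if a phenotyped id is missing from A
    n = len(phen)
    n_ped = len(A.ids)
    site = phen["site"].astype(str).to_numpy()
    terms: list = []
    for name in spec.terms:
        if name == "additive":
            Z = np.zeros((n, n_ped))
            Z[np.arange(n), obs_idx] = 1.0
            B = A.values[np.ix_(obs_idx, obs_idx)]
            terms.append(_Term(name, Z, A.values, B, n_ped, [str(i) for i in A.ids]))
        elif name == "site_additive":
            Z = np.eye(n)
            if spec.sa_structure == "additive":
                G = A.values[np.ix_(obs_idx, obs_idx)] * (site[:, None] == site[None, :])
            else:
                G = np.eye(n)
            terms.append(_Term(name, Z, G, G.copy(), n, [f"{s}:{i}" for s, i in zip(site, ids)]))
        elif name == "block":
            Z, lv = _indicator(phen["site"].astype(str) + ":" + phen["block"].astype(str))
            terms.append(_Term(name, Z, None, Z @ Z.T, Z.shape[1], lv))
        elif name == "site_family":
            Z, lv = _indicator(phen["site"].astype(str) + ":" + phen["family"].astype(str))
            terms.append(_Term(name, Z, None, Z @ Z.T, Z.shape[1], lv))
        elif name == "family":
            Z, lv = _indicator(phen["family"].astype(str))
            terms.append(_Term(name, Z, None, Z @ Z.T, Z.shape[1], lv))
    return terms


def _sym_inv_from_cholesky(V: np.ndarray):
    """(V^-1, log|V|) via LAPACK Cholesky; V must be positive definite."""
    c, info = dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("covariance matrix is not positive definite")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    iv, info = dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("covariance inversion failed")
    iv = np.tril(iv) + np.tril(iv, -1).T
    return iv, logdet


def _reml_quantities(y, X, terms, sigma2, sigma2_e):
    """P-matrix pieces and the REML log-likelihood for current components."""
    n = y.size
    V = sigma2_e * np.eye(n)
    for t, s2 in zip(terms, sigma2):
        if s2 > 0:
            V += s2 * t.B
    Vinv, logdetV = _sym_inv_from_cholesky(V)
    VX = Vinv @ X
    XVX = X.T @ VX
    cf = cho_factor(XVX)
    logdetXVX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    P = Vinv - VX @ cho_solve(cf, VX.T)
    Py = P @ y
    loglik = -0.5 * (logdetV + logdetXVX + float(y @ Py))
    return P, Py, loglik


_FLOOR = 1e-8  # guards exact-zero components during EM


class _LowRankREML:
    """Woodbury-based REML engine for diagonal + sparse-low-rank kernels.

    Every term kernel must satisfy B_k = diag(d_k) + U_k U_k' exactly; then
    V = D + U Lambda U' with D diagonal and U the horizontal stack of the
    sparse factors, and all EM-REML quantities (log-likelihood, traces
    tr(P B_k), quadratics y' P B_k P y) reduce to r x r algebra plus
    sparse matrix-vector products, r = total factor rank.
    """

    def __init__(self, y, X, factors, q_levels, names):
        from scipy import sparse

        self.y = y
        self.X = X
        self.n = y.size
        self.names = names
        self.q = q_levels
        self.d_list = [d for d, _ in factors]
        self.ranks = [U.shape[1] for _, U in factors]
        self.U = sparse.hstack([U for _, U in factors], format="csr")
        self.offsets = np.concatenate([[0], np.cumsum(self.ranks)])

    def quantities(self, sigma2, sigma2_e):
        """Return (loglik, Py, diagP, per-term (t1, t2), t1_e, t2_e)."""
        from scipy.linalg import cho_factor, cho_solve

        n = self.n
        U = self.U
        D = np.full(n, sigma2_e)
        for s2, d in zip(sigma2, self.d_list):
            D += s2 * d
        Dinv = 1.0 / D
        UtDU = (U.multiply(Dinv[:, None]).T @ U).toarray()
        lam_inv = np.concatenate(
            [np.full(r, 1.0 / s2) for r, s2 in zip(self.ranks, sigma2)]
        )
        Amat = UtDU + np.diag(lam_inv)
        cfA = cho_factor(Amat)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cfA[0]))))
        logdetV = float(np.sum(np.log(D))) + logdetA + float(
            np.sum([r * np.log(s2) for r, s2 in zip(self.ranks, sigma2)])
        )
        T = cho_solve(cfA, np.eye(Amat.shape[0]))

        def solveV(v):
            dv = Dinv[:, None] * v if v.ndim == 2 else Dinv * v
            w = U.T @ dv
            corr = U @ (T @ w)
            return dv - (Dinv[:, None] * corr if v.ndim == 2 else Dinv * corr)

        Vy = solveV(self.y)
        VX = solveV(self.X)
        XVX = self.X.T @ VX
        cfX = cho_factor(XVX)
        logdetXVX = 2.0 * float(np.sum(np.log(np.diag(cfX[0]))))
        beta_part = cho_solve(cfX, self.X.T @ Vy)
        Py = Vy - VX @ beta_part
        yPy = float(self.y @ Py)
        loglik = -0.5 * (logdetV + logdetXVX + yPy)

        # diag(V^-1) and diag(P)
        UT = U @ T  # n x r, cheap: U sparse
        quad = np.asarray(U.multiply(UT).sum(axis=1)).ravel()
        diagVinv = Dinv - Dinv * Dinv * quad
        XVXinv_VXT = cho_solve(cfX, VX.T)
        diagP = diagVinv - np.einsum("ij,ji->i", VX, XVXinv_VXT)

        # r x r blocks for tr(U_k' P U_k)
        UVU = UtDU - UtDU @ T @ UtDU
        UVX = U.T @ VX  # r x p
        UPU = UVU - UVX @ cho_solve(cfX, UVX.T)
        UtPy = U.T @ Py

        per_term = []
        for k, (d, name) in enumerate(zip(self.d_list, self.names)):
            sl = slice(self.offsets[k], self.offsets[k + 1])
            t1 = float(np.sum(d * Py * Py)) + float(UtPy[sl] @ UtPy[sl])
            t2 = float(np.sum(d * diagP)) + float(np.trace(UPU[sl, sl]))
            per_term.append((t1, t2))
        t1_e = float(Py @ Py)
        t2_e = float(diagP.sum())
        return loglik, per_term, t1_e, t2_e

    def em_map(self, theta):
        sigma2 = np.exp(theta[:-1])
        sigma2_e = float(np.exp(theta[-1]))
        loglik, per_term, t1_e, t2_e = self.quantities(sigma2, sigma2_e)
        new = np.empty_like(sigma2)
        for k, ((t1, t2), q) in enumerate(zip(per_term, self.q)):
            s2 = sigma2[k]
            new[k] = max(s2 + (s2 * s2 / q) * (t1 - t2), _FLOOR)
        new_e = max(
            sigma2_e + (sigma2_e * sigma2_e / self.n) * (t1_e - t2_e), _FLOOR
        )
        return np.log(np.append(new, new_e)), loglik


def _build_lowrank_engine(y, X, terms, phen, spec, A):
    """Try the exact sparse factorization of every term; None on failure."""
    from scipy import sparse

    ids = phen["id"].astype(str).to_numpy()
    site = phen["site"].astype(str).to_numpy()
    n = len(ids)
    ped = getattr(A, "parent_map", None)
    factors = []
    for t in terms:
        if t.G is None:  # indicator kernel Z Z'
            factors.append((np.zeros(n), sparse.csr_matrix(t.Z)))
            continue
        if t.name == "site_additive" and spec.sa_structure == "iid":
            factors.append((np.ones(n), sparse.csr_matrix((n, 0))))
            continue
        if t.name not in ("additive", "site_additive") or ped is None:
            return None
        rows, cols, vals = [], [], []
        col_index: dict = {}
        for i, iid in enumerate(ids):
            for parent in ped.get(iid, ()):
                key = (parent, site[i]) if t.name == "site_additive" else parent
                j = col_index.setdefault(key, len(col_index))
                rows.append(i)
                cols.append(j)
                vals.append(0.5)
        U = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n, len(col_index))
        )
        d = np.asarray(t.B.diagonal() - U.multiply(U).sum(axis=1).T).ravel()
        if np.any(d < -1e-12):
            return None
        approx = U @ U.T
        resid = t.B - approx.toarray()
        np.fill_diagonal(resid, 0.0)
        if np.abs(resid).max() > 1e-10:
            return None  # relatedness beyond shared founder parents
        factors.append((np.clip(d, 0.0, None), U))
    return _LowRankREML(y, X, factors, [t.q for t in terms], [t.name for t in terms])


def _make_em_map(y, X, terms, phen=None, spec=None, A=None):
    """Build the fastest available EM-update closure.

    ``theta`` stacks log variances of the random terms plus the residual.
    The closure returns (updated theta, REML log-likelihood *at the input*
    theta), the likelihood being a free by-product of the E-step
    quantities. When every term kernel factors exactly as diagonal +
    sparse-low-rank (single-generation founder-parent pedigrees), a
    Woodbury engine evaluates each iteration in r x r algebra; otherwise
    the dense path stacks the flattened kernels so the n^3 Cholesky
    inversion is the only cubic cost per iteration.
    """
    if phen is not None and A is not None:
        engine = _build_lowrank_engine(y, X, terms, phen, spec, A)
        if engine is not None:
            return engine.em_map
    n = y.size
    B_stack = np.stack([t.B.reshape(-1) for t in terms])
    q = np.array([float(t.q) for t in terms])

    def em_map(theta):
        sigma2 = np.exp(theta[:-1])
        sigma2_e = float(np.exp(theta[-1]))
        V = (sigma2 @ B_stack).reshape(n, n)
        V.flat[:: n + 1] += sigma2_e
        Vinv, logdetV = _sym_inv_from_cholesky(V)
        VX = Vinv @ X
        XVX = X.T @ VX
        cf = cho_factor(XVX)
        logdetXVX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        P = Vinv - VX @ cho_solve(cf, VX.T)
        Py = P @ y
        loglik = -0.5 * (logdetV + logdetXVX + float(y @ Py))
        t1 = B_stack @ np.outer(Py, Py).reshape(-1)
        t2 = B_stack @ P.reshape(-1)
        new = np.maximum(sigma2 + sigma2 * sigma2 / q * (t1 - t2), _FLOOR)
        new_e = max(
            sigma2_e
            + (sigma2_e * sigma2_e / n) * (float(Py @ Py) - float(np.trace(P))),
            _FLOOR,
        )
        return np.log(np.append(new, new_e)), loglik

    return em_map


def _moment_init(y, phen, spec: ModelSpec, A: RelationshipMatrix):
    """ANOVA-style starting values from pairwise covariance classes.

    Site-centred products are averaged within relationship classes
    (pedigree relationship 0.5 / 0.25, same vs different site, shared
    block) and solved for the components by the class expectations. Only a
    starting point for EM: coarse, clamped away from zero, and silently
    replaced by an equal split whenever a class has no pairs.
    """
    ids = phen["id"].astype(str).to_numpy()
    site = phen["site"].astype(str).to_numpy()
    block = (phen["site"].astype(str) + ":" + phen["block"].astype(str)).to_numpy()
    obs = A.indices(ids)
    Aoo = A.values[np.ix_(obs, obs)]
    mu = pd.Series(y).groupby(site).transform("mean").to_numpy()
    r = y - mu
    vary = float(np.var(r))
    R = np.outer(r, r)
    iu = np.triu(np.ones_like(Aoo, dtype=bool), k=1)
    ss = site[:, None] == site[None, :]
    sb = (block[:, None] == block[None, :]) & ss

    def cls_mean(mask):
        m = mask & iu
        cnt = int(m.sum())
        return (float(R[m].mean()) if cnt else None), cnt

    full_ws, n1 = cls_mean((np.abs(Aoo - 0.5) < 0.05) & ss)
    full_wd, n2 = cls_mean((np.abs(Aoo - 0.5) < 0.05) & ~ss)
    half_ws, n3 = cls_mean((np.abs(Aoo - 0.25) < 0.05) & ss)
    half_wd, n4 = cls_mean((np.abs(Aoo - 0.25) < 0.05) & ~ss)
    blk, n5 = cls_mean((Aoo < 0.05) & sb)

    out = {}
    if spec.kind == "fullsib" and all(v is not None for v in (full_ws, full_wd, half_ws, half_wd)):
        out["additive"] = 4.0 * half_wd
        out["site_additive"] = 4.0 * (half_ws - half_wd)
        out["family"] = full_wd - 0.5 * out["additive"]
        out["site_family"] = (
            full_ws - 0.5 * out["additive"] - 0.5 * out["site_additive"] - out["family"]
        )
    elif spec.kind == "halfsib" and half_ws is not None and half_wd is not None:
        out["additive"] = 4.0 * half_wd
        out["site_additive"] = 4.0 * (half_ws - half_wd)
    else:
        return None
    if blk is not None:
        out["block"] = blk
    elif "block" in spec.terms:
        out["block"] = 0.1 * vary
    lo, hi = 0.02 * vary, 2.0 * vary
    for k in out:
        out[k] = float(np.clip(out[k], lo, hi))
    resid = vary - sum(out.values())
    out["residual"] = float(np.clip(resid, lo, hi))
    return out


def em_reml(
    phen: pd.DataFrame,
    spec: ModelSpec,
    A: RelationshipMatrix,
    init: VarianceComponents | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    response: str = "y",
    accelerate: bool = True,
) -> VarianceEstimates:
    """EM-REML for the trial models.

    Iterates the classical expectation-maximization updates on the
    observation-level covariance V = sum_k s2_k B_k + s2_e I until the
    largest relative component change of one EM step falls below ``tol``.
    By default the EM fixed-point iteration is accelerated with squared
    extrapolation (SQUAREM) under a likelihood safeguard: an extrapolated
    point is only accepted when its REML log-likelihood does not fall below
    the current one, otherwise the plain EM step is taken, so the
    log-likelihood over accepted iterates is non-decreasing exactly as for
    plain EM. ``max_iter`` counts EM-map evaluations; non-convergence
    returns the last iterate flagged as provisional.
    """
    y = phen[response].to_numpy(float)
    X, _ = _site_design(phen)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient (confounded site levels)")
    terms = _build_terms(phen, spec, A)
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("response has zero variance")
    if init is None:
        start = _moment_init(y, phen, spec, A) if spec.kind in ("fullsib", "halfsib") else None
        if start is not None:
            sigma2 = np.array([start[t.name] for t in terms])
            sigma2_e = start["residual"]
        else:
            k = len(terms)
            sigma2 = np.full(k, 0.5 * vary / k)
            sigma2_e = 0.5 * vary
    else:
        sigma2 = np.array([getattr(init, _TERM_TO_VC[t.name]) for t in terms], float)
        sigma2_e = float(init.sigma2_e)
        if np.any(sigma2 <= 0) or sigma2_e <= 0:
            raise ValueError("initial variance components must be strictly positive")
    theta = np.log(np.append(sigma2, sigma2_e))
    lo, hi = np.log(1e-10), np.log(1e6 * vary)

    path: list = []
    converged = False
    evals = 0

    em_map = _make_em_map(y, X, terms, phen=phen, spec=spec, A=A)

    def em(th):
        nonlocal evals
        evals += 1
        return em_map(th)

    # components stuck at the zero boundary (below 0.1% of the phenotypic
    # variance) oscillate with large *relative* steps; measuring change
    # against a variance-scaled floor keeps them from blocking convergence
    change_floor = 1e-3 * vary

    def rel_change(a, b):
        sa, sb = np.exp(a), np.exp(b)
        return float(np.max(np.abs(sb - sa) / np.maximum(sa, change_floor)))

    while evals < max_iter and not converged:
        theta1, ll0 = em(theta)
        path.append(ll0)
        if rel_change(theta, theta1) < tol:
            theta = theta1
            converged = True
            break
        if not accelerate or evals + 2 > max_iter:
            theta = theta1
            continue
        theta2, _ = em(theta1)
        if rel_change(theta1, theta2) < tol:
            theta = theta2
            converged = True
            break
        r = theta1 - theta
        v = theta2 - theta1 - r
        vnorm = float(np.sqrt(v @ v))
        if vnorm < 1e-14:
            theta = theta2
            continue
        alpha = min(-float(np.sqrt(r @ r)) / vnorm, -1.0)
        # extrapolate; on a likelihood loss, backtrack alpha toward -1
        # (alpha = -1 reproduces the plain double EM step) so that slow
        # near-linear ridges still get large accepted jumps
        accepted = False
        while evals + 1 <= max_iter:
            theta_x = np.clip(theta - 2.0 * alpha * r + alpha * alpha * v, lo, hi)
            try:
                theta_new, ll_x = em(theta_x)
            except np.linalg.LinAlgError:
                ll_x = -np.inf
            if ll_x >= ll0:
                theta = theta_new
                accepted = True
                break
            if alpha > -1.5:
                break
            alpha = (alpha - 1.0) / 2.0
        if not accepted:
            theta = theta2
    sigma2 = np.exp(theta[:-1])
    sigma2_e = float(np.exp(theta[-1]))
    _, _, loglik = _reml_quantities(y, X, terms, sigma2, sigma2_e)
    path.append(loglik)
    it = evals

    kwargs = {"sigma2_a": 0.0, "sigma2_e": float(sigma2_e)}
    for t, s2 in zip(terms, sigma2):
        kwargs[_TERM_TO_VC[t.name]] = float(s2)
    return VarianceEstimates(
        vc=VarianceComponents(**kwargs),
        converged=converged,
        n_iter=it,
        loglik=float(loglik),
        loglik_path=np.asarray(path),
    )


@dataclass
class MMESystem:
    """Henderson's mixed-model equations, ready for a direct solve."""

    M: np.ndarray
    rhs: np.ndarray
    X_names: list
    terms: list
    slices: dict
    n_obs: int
    vc: VarianceComponents
    ids_phenotyped: list


def build_mme(
    phen: pd.DataFrame,
    spec: ModelSpec,
    A: RelationshipMatrix,
    vc: VarianceComponents,
    response: str = "y",
) -> MMESystem:
    """Assemble Henderson's MME for fixed variance components.

    The coefficient matrix is W'W with lambda_k G_k^-1 added to each random
    block, lambda_k = s2_e / s2_k. Included terms must have strictly
    positive variances; a rank-deficient fixed-effect block is rejected.
    """
    y = phen[response].to_numpy(float)
    X, x_names = _site_design(phen)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "fixed-effect design is rank deficient: site levels are confounded "
            f"(X has {X.shape[1]} columns, rank {np.linalg.matrix_rank(X)})"
        )
    if vc.sigma2_e <= 0:
        raise ValueError("residual variance must be strictly positive")
    terms = _build_terms(phen, spec, A)
    for t in terms:
        if getattr(vc, _TERM_TO_VC[t.name]) <= 0:
            raise ValueError(f"variance for included term {t.name!r} must be positive")
    blocks = [X] + [t.Z for t in terms]
    W = np.concatenate(blocks, axis=1)
    M = W.T @ W
    rhs = W.T @ y
    slices = {}
    start = X.shape[1]
    slices["fixed"] = slice(0, start)
    for t in terms:
        lam = vc.sigma2_e / getattr(vc, _TERM_TO_VC[t.name])
        sl = slice(start, start + t.q)
        if t.G is None:
            M[sl, sl] += lam * np.eye(t.q)
        else:
            if t.G_inv is None:
                t.G_inv, _ = _sym_inv_from_cholesky(
                    t.G + 1e-10 * np.eye(t.q)
                )
            M[sl, sl] += lam * t.G_inv
        slices[t.name] = sl
        start += t.q
    return MMESystem(
        M=M,
        rhs=rhs,
        X_names=x_names,
        terms=terms,
        slices=slices,
        n_obs=len(phen),
        vc=vc,
        ids_phenotyped=[str(i) for i in phen["id"]],
    )


@dataclass(frozen=True)
class EBVResult:
    """BLUP solutions: EBVs for every pedigree member plus the other effects."""

    ebv: pd.Series
    fixed_effects: pd.Series
    random_solutions: dict
    solution: np.ndarray


def solve_blup(system: MMESystem) -> EBVResult:
    """Exact direct solve of the MME (Cholesky, jittered once if needed)."""
    M = system.M
    try:
        cf = cho_factor(M)
    except np.linalg.LinAlgError:
        cond = np.linalg.cond(M)
        raise np.linalg.LinAlgError(
            f"mixed-model equations numerically singular (cond ~ {cond:.3e})"
        ) from None
    sol = cho_solve(cf, system.rhs)
    fixed = pd.Series(sol[system.slices["fixed"]], index=system.X_names, name="estimate")
    randoms = {}
    ebv = None
    for t in system.terms:
        s = pd.Series(sol[system.slices[t.name]], index=t.level_ids, name=t.name)
        randoms[t.name] = s
        if t.name == "additive":
            ebv = s.rename("EBV")
    return EBVResult(ebv=ebv, fixed_effects=fixed, random_solutions=randoms, solution=sol)


def ablup_cross_validate(
    phen: pd.DataFrame,
    spec: ModelSpec,
    A: RelationshipMatrix,
    vc: VarianceComponents,
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    response: str = "y",
    return_predictions: bool = False,
):
    """Replicated k-fold cross-validation of pedigree-predicted EBVs.

    Individuals are partitioned at random across all sites; per fold the
    validation phenotypes are masked, the MME re-solved with the variance
    components held fixed, and the masked individuals' EBVs are predicted
    purely through A. Fold accuracy is the Pearson correlation between these
    predictions and the full-data EBVs. Degenerate folds (constant vectors,
    or single-individual folds as in leave-one-out) are recorded as missing.
    With ``return_predictions`` a second frame holds every validation
    individual's predicted and full-data EBV.
    """
    n = len(phen)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError("cannot have more folds than observations")
    full = solve_blup(build_mme(phen, spec, A, vc, response))
    full_ebv = full.ebv
    rng = np.random.default_rng(seed)
    rows = []
    preds = []
    for rep in range(reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold_i, val_idx in enumerate(folds):
            train = phen.drop(phen.index[val_idx])
            val_ids = phen.iloc[val_idx]["id"].astype(str).to_numpy()
            res = solve_blup(build_mme(train, spec, A, vc, response))
            pred = res.ebv.loc[val_ids].to_numpy()
            ref = full_ebv.loc[val_ids].to_numpy()
            if return_predictions:
                for iid, p, r in zip(val_ids, pred, ref):
                    preds.append((rep, fold_i, iid, p, r))
            if pred.size < 2 or np.std(pred) == 0 or np.std(ref) == 0:
                rows.append((rep, fold_i, np.nan, len(val_idx), True))
                continue
            acc = float(np.corrcoef(pred, ref)[0, 1])
            rows.append((rep, fold_i, acc, len(val_idx), False))
    detail = pd.DataFrame(rows, columns=["rep", "fold", "accuracy", "n_validation", "missing"])
    if return_predictions:
        return detail, pd.DataFrame(
            preds, columns=["rep", "fold", "id", "predicted", "reference"]
        )
    return detail


class PedigreeBLUP:
    """ABLUP model for one trial: phenotypes + pedigree relationship matrix.

    Parameters
    ----------
    data : DataFrame
        One row per phenotyped tree with columns ``id``, ``site``, ``block``,
        ``family`` (full-sib) and the response column.
    pedigree : PedigreeTable or RelationshipMatrix
        Pedigree covering every phenotyped id; a ready-made A is accepted.
    kind : {"fullsib", "halfsib"}
        Chooses the random-term set of the corresponding trial model.

    Examples
    --------
    >>> model = PedigreeBLUP(phen, ped, kind="fullsib")   # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> res.heritability, res.ebv.head()                   # doctest: +SKIP
    """

    def __init__(
        self,
        data: pd.DataFrame,
        pedigree,
        kind: str = "fullsib",
        response: str = "y",
        sa_structure: str = "additive",
    ):
        if kind == "fullsib":
            self.spec = ModelSpec.fullsib(sa_structure)
        elif kind == "halfsib":
            self.spec = ModelSpec.halfsib(sa_structure)
        else:
            raise ValueError("kind must be 'fullsib' or 'halfsib'")
        needed = {"id", "site", "block", response}
        if kind == "fullsib":
            needed |= {"family"}
        missing = needed - set(data.columns)
        if missing:
            raise ValueError(f"data lacks required columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.response = response
        if isinstance(pedigree, RelationshipMatrix):
            self.A = pedigree
        elif isinstance(pedigree, PedigreeTable):
            self.A = build_numerator_relationship(pedigree)
        else:
            self.A = build_numerator_relationship(PedigreeTable.from_dataframe(pedigree))

    @classmethod
    def from_tables(cls, phenotype_path, pedigree_path, kind="fullsib", **kwargs):
        from .io import read_pedigree, read_phenotypes

        return cls(read_phenotypes(phenotype_path), read_pedigree(pedigree_path),
                   kind=kind, **kwargs)

    def fit(
        self,
        varcomp: VarianceComponents | None = None,
        tol: float = 1e-6,
        maxiter: int = 500,
        init: VarianceComponents | None = None,
    ) -> "PedigreeBLUPResults":
        """Estimate variance components by EM-REML (unless supplied) and
        solve the MME for breeding values."""
        if varcomp is None:
            est = em_reml(self.data, self.spec, self.A, init=init, tol=tol,
                          max_iter=maxiter, response=self.response)
            vc = est.vc
        else:
            est = None
            vc = varcomp
        system = build_mme(self.data, self.spec, self.A, vc, self.response)
        blup = solve_blup(system)
        return PedigreeBLUPResults(self, vc, est, blup)


class PedigreeBLUPResults:
    """Fitted ABLUP: variance components, heritability, EBVs, diagnostics."""

    def __init__(self, model: PedigreeBLUP, vc, reml: VarianceEstimates | None, blup: EBVResult):
        self.model = model
        self.varcomp = vc
        self.reml = reml
        self._blup = blup

    @property
    def ebv(self) -> pd.Series:
        return self._blup.ebv

    @property
    def fixed_effects(self) -> pd.Series:
        return self._blup.fixed_effects

    @property
    def random_solutions(self) -> dict:
        return self._blup.random_solutions

    @property
    def heritability(self) -> float:
        return heritability(self.varcomp, self.model.spec.kind)

    @property
    def converged(self) -> bool:
        return True if self.reml is None else self.reml.converged

    @property
    def loglike(self) -> float | None:
        return None if self.reml is None else self.reml.loglik

    def cross_validate(self, k: int = 10, reps: int = 10, seed: int = 0) -> pd.DataFrame:
        return ablup_cross_validate(
            self.model.data, self.model.spec, self.model.A, self.varcomp,
            k=k, reps=reps, seed=seed, response=self.model.response,
        )

    def summary(self) -> str:
        lines = [
            "Pedigree BLUP (ABLUP) results",
            "=" * 34,
            f"model kind        : {self.model.spec.kind}",
            f"observations      : {len(self.model.data)}",
            f"pedigree members  : {len(self.model.A.ids)}",
        ]
        if self.reml is not None:
            lines += [
                f"REML converged    : {self.reml.converged} ({self.reml.n_iter} iterations)",
                f"REML log-likelihood: {self.reml.loglik:.6f}",
            ]
        else:
            lines.append("variance components supplied by the user (no REML)")
        lines.append("-" * 34)
        for name, value in self.varcomp.as_dict().items():
            lines.append(f"{name:<12s} = {value:.6g}")
        lines.append(f"heritability  = {self.heritability:.4f}")
        lines.append("-" * 34)
        for name, value in self.fixed_effects.items():
            lines.append(f"fixed {name:<12s} = {value:.6g}")
        return "\n".join(lines)
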