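"""REML machinery for single- and multienvironment G-BLUP.

Model
-----
Stage-2 observations are per-trial adjusted genotype means (BLUEs). For
genotype ``i`` in environment ``j``::

    y_ij = mu_j + g_ij + e_ij,   g ~ N(0, G (x) Sigma_E),   e_ij ~ N(0, r_j)

``G`` is the genomic relationship matrix, ``Sigma_E`` the J×J genetic
covariance between environments, and ``R = diag(r_j)`` holds heterogeneous
environment-specific residual variances. Four nested parametrizations of
``Sigma_E`` are supported:

======== ==========================================  ==============
kind     Sigma_E                                     free parameters
======== ==========================================  ==============
ME       sigma_g^2 * (ones)                          1
CS       common variance + common covariance         2
UN_HET   per-env variances, one correlation rho      J + 1
US       fully unstructured (log-Cholesky)           J(J+1)/2
======== ==========================================  ==============

Estimation maximises the restricted log-likelihood directly (quasi-Newton on
unconstrained transformed parameters). When every genotype is observed in
every environment, the likelihood is evaluated through the eigendecomposition
of G: rotating the data by the eigenvectors turns the nJ×nJ covariance into
n independent J×J blocks ``lambda_i Sigma_E + R``, so each evaluation costs
O(n J^3) after a single O(n^3) factorization. Incomplete record patterns
fall back to a dense observed-records likelihood.

The restricted log-likelihood convention used throughout (and by the dense
fallback) is

    l_R = -1/2 [ log|V| + log|X'V^-1 X| + y'Py + (N - p) log 2pi ]

with the environment means profiled out by GLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "CovStructureSpec",
    "RemlFit",
    "FitError",
    "make_sigma_e",
    "structure_n_params",
    "reml_loglik",
    "reml_fit_se",
    "reml_fit_multienv",
    "lrt",
    "reml_variance_components",
    "pivot_blues",
]

KINDS = ("ME", "CS", "UN_HET", "US")
_NESTING = {"ME": 0, "CS": 1, "UN_HET": 2, "US": 3}
_VAR_FLOOR = 1e-10
_RHO_BOUND = 0.999


class FitError(RuntimeError):
    """Raised when a REML fit fails to converge or the data are degenerate."""


# ---------------------------------------------------------------------------
# Sigma_E parametrizations
# ---------------------------------------------------------------------------


@dataclass
class CovStructureSpec:
    """Explicit parametrization of the environment genetic covariance Sigma_E.

    ``params`` by kind:
      ME:      {"sigma_g2": float}
      CS:      {"sigma1_2": diag value, "sigma2_2": off-diagonal value}
      UN_HET:  {"variances": length-J, "rho": float}
      US:      {"sigma_e": full J×J matrix}  (or {"variances", "correlations"})
    """

    kind: str
    J: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        if self.J < 1:
            raise ValueError("J must be >= 1")


def structure_n_params(kind: str, J: int) -> int:
    """Free-parameter count of Sigma_E alone (residuals and means excluded)."""
    return {"ME": 1, "CS": 2, "UN_HET": J + 1, "US": J * (J + 1) // 2}[kind]


def make_sigma_e(spec: CovStructureSpec) -> np.ndarray:
    """Materialise Sigma_E from an explicit spec; validates PSD."""
    J, p = spec.J, spec.params
    if spec.kind == "ME":
        S = float(p["sigma_g2"]) * np.ones((J, J))
    elif spec.kind == "CS":
        s1, s2 = float(p["sigma1_2"]), float(p["sigma2_2"])
        S = np.full((J, J), s2)
        np.fill_diagonal(S, s1)
    elif spec.kind == "UN_HET":
        v = np.asarray(p["variances"], dtype=float)
        if v.shape != (J,):
            raise ValueError("UN_HET needs J variances")
        rho = float(p["rho"])
        sd = np.sqrt(v)
        S = rho * np.outer(sd, sd)
        np.fill_diagonal(S, v)
    else:  # US
        if "sigma_e" in p:
            S = np.asarray(p["sigma_e"], dtype=float)
        else:
            v = np.asarray(p["variances"], dtype=float)
            C = np.asarray(p["correlations"], dtype=float)
            sd = np.sqrt(v)
            S = C * np.outer(sd, sd)
        if S.shape != (J, J):
            raise ValueError(f"US matrix must be {J}×{J}")
        S = 0.5 * (S + S.T)
    w = np.linalg.eigvalsh(S)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(
            f"{spec.kind} parameters yield a non-PSD Sigma_E "
            f"(min eigenvalue {w.min():.3g})"
        )
    return S


# internal unconstrained parametrizations: theta -> Sigma_E


def _theta_to_sigma_e(kind: str, theta: np.ndarray, J: int) -> np.ndarray:
    if kind == "SE":
        return np.array([[np.exp(theta[0])]])
    if kind == "ME":
        return np.exp(theta[0]) * np.ones((J, J))
    if kind == "CS":
        m, i = np.exp(theta[0]), np.exp(theta[1])
        return m * np.ones((J, J)) + i * np.eye(J)
    if kind == "UN_HET":
        v = np.exp(theta[:J])
        rho = _RHO_BOUND * np.tanh(theta[J])
        sd = np.sqrt(v)
        S = rho * np.outer(sd, sd)
        np.fill_diagonal(S, v)
        return S
    # US: log-Cholesky, row-major lower triangle with log-diagonal
    L = np.zeros((J, J))
    k = 0
    for r in range(J):
        for c in range(r + 1):
            L[r, c] = np.exp(theta[k]) if r == c else theta[k]
            k += 1
    return L @ L.T


def _n_theta(kind: str, J: int) -> int:
    if kind == "SE":
        return 1
    return structure_n_params(kind, J)


def _structure_params(kind: str, S: np.ndarray) -> dict:
    """Human-readable parameter dict recovered from a fitted Sigma_E."""
    J = S.shape[0]
    if kind in ("SE", "ME"):
        return {"sigma_g2": float(S[0, 0])}
    if kind == "CS":
        off = float(S[0, 1]) if J > 1 else 0.0
        return {"sigma1_2": float(S[0, 0]), "sigma2_2": off}
    v = np.diag(S).copy()
    sd = np.sqrt(np.maximum(v, _VAR_FLOOR))
    C = S / np.outer(sd, sd)
    np.fill_diagonal(C, 1.0)
    if kind == "UN_HET":
        iu = np.triu_indices(J, 1)
        return {"variances": v, "rho": float(np.mean(C[iu])) if J > 1 else 0.0}
    return {"variances": v, "correlations": C, "sigma_e": S}


# ---------------------------------------------------------------------------
# BLUE table handling
# ---------------------------------------------------------------------------


def pivot_blues(
    blues: pd.DataFrame,
    env_col: str = "env",
    value_col: str = "value",
    id_col: str = "genotype_id",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Pivot a long BLUE table to genotype × environment; NaN marks absence.

    Row and column order follow first appearance in the table (pandas would
    otherwise sort labels, silently permuting Sigma_E relative to the
    caller's environment order). Duplicate (genotype, environment) records
    are an error: the model admits at most one adjusted mean per cell.
    """
    if blues.duplicated([id_col, env_col]).any():
        raise ValueError("duplicate (genotype, environment) records")
    wide = blues.pivot(index=id_col, columns=env_col, values=value_col)
    wide = wide.reindex(
        index=pd.unique(blues[id_col]), columns=pd.unique(blues[env_col])
    )
    return (
        wide.to_numpy(dtype=float),
        [str(g) for g in wide.index],
        [str(e) for e in wide.columns],
    )


def _align_G(
    G: np.ndarray | pd.DataFrame, g_ids_all: Sequence[str], g_ids_want: Sequence[str]
) -> np.ndarray:
    if isinstance(G, pd.DataFrame):
        g_ids_all = [str(i) for i in G.index]
        G = G.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(g_ids_all)}
    missing = [g for g in g_ids_want if g not in pos]
    if missing:
        raise ValueError(f"genotypes absent from G: {missing[:5]}")
    idx = np.array([pos[g] for g in g_ids_want])
    return G[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Likelihood evaluation
# ---------------------------------------------------------------------------


class _FastContext:
    """Complete-pattern likelihood via the eigendecomposition of G."""

    def __init__(self, Y: np.ndarray, G: np.ndarray) -> None:
        self.n, self.J = Y.shape
        lam, U = np.linalg.eigh(0.5 * (G + G.T))
        self.lam = np.maximum(lam, 0.0)
        self.U = U
        self.Yt = U.T @ Y
        self.a = U.T @ np.ones(self.n)

    def neg_loglik(self, S: np.ndarray, r: np.ndarray) -> float:
        n, J = self.n, self.J
        Vs = self.lam[:, None, None] * S[None] + np.diag(r)[None]
        try:
            L = np.linalg.cholesky(Vs)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
        W = np.linalg.inv(Vs)
        XtVX = np.einsum("i,ijk->jk", self.a**2, W)
        XtVy = np.einsum("i,ijk,ik->j", self.a, W, self.Yt)
        ytVy = float(np.einsum("ij,ijk,ik->", self.Yt, W, self.Yt))
        sign, ldX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        mu = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - float(XtVy @ mu)
        return 0.5 * (logdet + ldX + quad + (n * J - J) * np.log(2 * np.pi))

    def gls_means(self, S: np.ndarray, r: np.ndarray) -> np.ndarray:
        Vs = self.lam[:, None, None] * S[None] + np.diag(r)[None]
        W = np.linalg.inv(Vs)
        XtVX = np.einsum("i,ijk->jk", self.a**2, W)
        XtVy = np.einsum("i,ijk,ik->j", self.a, W, self.Yt)
        return np.linalg.solve(XtVX, XtVy)

    def blups(self, S: np.ndarray, r: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Conditional means of g for all training genotypes × environments."""
        Vs = self.lam[:, None, None] * S[None] + np.diag(r)[None]
        resid = self.Yt - np.outer(self.a, mu)
        sol = np.linalg.solve(Vs, resid[:, :, None])[:, :, 0]
        g_rot = self.lam[:, None] * (sol @ S.T)
        return self.U @ g_rot


class _DenseContext:
    """Observed-records likelihood for arbitrary missingness patterns."""

    def __init__(
        self, y: np.ndarray, g_idx: np.ndarray, e_idx: np.ndarray, G: np.ndarray, J: int
    ) -> None:
        self.y = y
        self.g_idx = g_idx
        self.e_idx = e_idx
        self.Gsub = G[np.ix_(g_idx, g_idx)]
        self.J = J
        self.X = np.zeros((len(y), J))
        self.X[np.arange(len(y)), e_idx] = 1.0

    def _V(self, S: np.ndarray, r: np.ndarray) -> np.ndarray:
        V = self.Gsub * S[np.ix_(self.e_idx, self.e_idx)]
        V[np.diag_indices_from(V)] += r[self.e_idx]
        return V

    def neg_loglik(self, S: np.ndarray, r: np.ndarray) -> float:
        V = self._V(S, r)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Xs = np.linalg.solve(L, self.X)
        ys = np.linalg.solve(L, self.y)
        XtVX = Xs.T @ Xs
        XtVy = Xs.T @ ys
        sign, ldX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        mu = np.linalg.solve(XtVX, XtVy)
        quad = float(ys @ ys) - float(XtVy @ mu)
        N, p = len(self.y), self.J
        return 0.5 * (logdet + ldX + quad + (N - p) * np.log(2 * np.pi))

    def gls_means(self, S: np.ndarray, r: np.ndarray) -> np.ndarray:
        V = self._V(S, r)
        Vi_X = np.linalg.solve(V, self.X)
        Vi_y = np.linalg.solve(V, self.y)
        return np.linalg.solve(self.X.T @ Vi_X, self.X.T @ Vi_y)

    def blups(self, S: np.ndarray, r: np.ndarray, mu: np.ndarray) -> np.ndarray:
        V = self._V(S, r)
        resid = self.y - self.X @ mu
        alpha = np.linalg.solve(V, resid)
        n_g = self.Gsub.shape[0]
        # unique genotypes in Gsub order correspond to g_idx values
        out = np.zeros((len(np.unique(self.g_idx)), self.J))
        uniq = np.unique(self.g_idx)
        remap = {g: k for k, g in enumerate(uniq)}
        rows = np.array([remap[g] for g in self.g_idx])
        C_g = self.Gsub  # records × records in genotype dimension
        for j in range(self.J):
            # cov(g_{., j}, y_obs) for each unique genotype
            Cj = np.zeros((len(uniq), len(self.y)))
            for k, g in enumerate(uniq):
                rec = np.where(self.g_idx == g)[0][0]
                Cj[k] = C_g[rec] * S[j, self.e_idx]
            out[:, j] = Cj @ alpha
        _ = rows, n_g
        return out


def reml_loglik(
    blues: pd.DataFrame,
    G: np.ndarray | pd.DataFrame,
    sigma_e: np.ndarray,
    residual_vars: np.ndarray,
    g_ids: Sequence[str] | None = None,
) -> float:
    """Restricted log-likelihood at given (Sigma_E, R), environment means
    profiled out. Uses the same code path as the fitting engine."""
    Y, gen_ids, env_labels = pivot_blues(blues)
    Gm = _align_G(G, g_ids or gen_ids, gen_ids)
    S = np.asarray(sigma_e, dtype=float)
    r = np.asarray(residual_vars, dtype=float)
    if not np.isnan(Y).any():
        ctx = _FastContext(Y, Gm)
        return -ctx.neg_loglik(S, r)
    obs = ~np.isnan(Y)
    gi, ei = np.where(obs)
    ctx = _DenseContext(Y[obs], gi, ei, Gm, len(env_labels))
    return -ctx.neg_loglik(S, r)


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------


@dataclass
class RemlFit:
    kind: str
    env_labels: list[str]
    genotype_ids: list[str]
    sigma_e: np.ndarray
    residual_vars: np.ndarray
    env_means: np.ndarray
    restricted_loglik: float
    n_free_params: int
    structure_params: dict
    blups: pd.DataFrame
    convergence: dict
    n_obs: int

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("converged", False))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "env_labels": self.env_labels,
            "sigma_e": self.sigma_e.tolist(),
            "residual_vars": self.residual_vars.tolist(),
            "env_means": self.env_means.tolist(),
            "restricted_loglik": self.restricted_loglik,
            "n_free_params": self.n_free_params,
            "convergence": {
                k: (v if not isinstance(v, np.generic) else v.item())
                for k, v in self.convergence.items()
            },
            "n_obs": self.n_obs,
        }


# ---------------------------------------------------------------------------
# Starting values (method of moments)
# ---------------------------------------------------------------------------


def _mom_start(Y: np.ndarray, G: np.ndarray, kind: str, J: int) -> np.ndarray:
    gbar = float(np.mean(np.diag(G)))
    gbar = gbar if gbar > 1e-8 else 1.0
    df = pd.DataFrame(Y)
    S_emp = df.cov(min_periods=2).to_numpy()
    S_emp = np.where(np.isnan(S_emp), 0.0, S_emp)
    d = np.maximum(np.diag(S_emp), 1e-4)
    S0 = 0.5 * S_emp / gbar
    v0 = np.maximum(np.diag(S0), 1e-4)
    r0 = np.maximum(0.5 * d, 1e-4)
    theta_r = np.log(r0)
    if kind == "SE":
        return np.concatenate([[np.log(v0[0])], theta_r])
    if kind == "ME":
        off = np.mean(S0[np.triu_indices(J, 1)]) if J > 1 else v0[0]
        return np.concatenate([[np.log(max(off, 1e-4))], theta_r])
    if kind == "CS":
        off = np.mean(S0[np.triu_indices(J, 1)]) if J > 1 else 0.5 * v0[0]
        m = max(off, 1e-4)
        i = max(float(np.mean(v0)) - m, 1e-4)
        return np.concatenate([np.log([m, i]), theta_r])
    if kind == "UN_HET":
        sd = np.sqrt(v0)
        C = S0 / np.outer(sd, sd)
        rho = float(np.mean(C[np.triu_indices(J, 1)])) if J > 1 else 0.0
        rho = float(np.clip(rho, -0.9, 0.9))
        z = np.arctanh(rho / _RHO_BOUND)
        return np.concatenate([np.log(v0), [z], theta_r])
    # US: log-Cholesky of a PSD-projected S0
    w, Q = np.linalg.eigh(0.5 * (S0 + S0.T))
    S_psd = (Q * np.maximum(w, 1e-4)) @ Q.T
    L = np.linalg.cholesky(S_psd + 1e-8 * np.eye(J))
    th = []
    for r_ in range(J):
        for c in range(r_ + 1):
            th.append(np.log(max(L[r_, c], 1e-6)) if r_ == c else L[r_, c])
    return np.concatenate([th, theta_r])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _fit(
    ctx,
    kind: str,
    J: int,
    starts: list[np.ndarray],
    n_restarts: int,
    max_iter: int,
    rng: np.random.Generator,
):
    k_struct = _n_theta(kind, J)

    def neg(theta: np.ndarray) -> float:
        theta = np.clip(theta, -40.0, 40.0)  # keep exp() finite off-path
        S = _theta_to_sigma_e(kind, theta[:k_struct], J)
        r = np.exp(theta[k_struct:]) + _VAR_FLOOR
        return ctx.neg_loglik(S, r)

    best = None
    all_starts = list(starts) + [
        starts[0] + rng.normal(0.0, 0.3, size=starts[0].size)
        for _ in range(n_restarts)
    ]
    for th0 in all_starts:
        res = optimize.minimize(
            neg,
            th0,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    return best, k_struct


def _embed_theta(kind: str, simpler: "RemlFit", J: int) -> np.ndarray:
    """Map a fitted simpler structure into the parameter space of ``kind``.

    Guards against local optima that would violate the nesting ordering
    ME <= CS <= UN_HET <= US of restricted log-likelihoods.
    """
    S, r = simpler.sigma_e, simpler.residual_vars
    theta_r = np.log(np.maximum(r, 1e-8))
    if kind == "CS":  # from ME
        m = max(float(S[0, 0]), 1e-6)
        return np.concatenate([np.log([m, 0.05 * m]), theta_r])
    if kind == "UN_HET":  # from CS
        v = max(float(S[0, 0]), 1e-6)
        rho = float(np.clip(S[0, 1] / v if J > 1 else 0.0, -0.99, 0.99))
        return np.concatenate(
            [np.log(np.full(J, v)), [np.arctanh(rho / _RHO_BOUND)], theta_r]
        )
    # US from UN_HET
    L = np.linalg.cholesky(S + 1e-6 * float(np.mean(np.diag(S))) * np.eye(J))
    th = []
    for row in range(J):
        for col in range(row + 1):
            th.append(np.log(max(L[row, col], 1e-8)) if row == col else L[row, col])
    return np.concatenate([th, theta_r])


def reml_fit_multienv(
    blues: pd.DataFrame,
    G: np.ndarray | pd.DataFrame,
    kind: str,
    g_ids: Sequence[str] | None = None,
    n_restarts: int = 2,
    max_iter: int = 500,
    theta_start: np.ndarray | None = None,
    seed: int = 0,
    compute_blups: bool = True,
) -> RemlFit:
    """Fit the multienvironment G-BLUP model with the given Sigma_E structure.

    ``blues`` is a long table with columns genotype_id, env, value. ``G`` may
    be a labelled DataFrame (aligned by genotype_id) or a raw array in the
    pivot's genotype order. ``theta_start`` warm-starts the optimizer (e.g.
    from a fit on the full data when cross-validating); method-of-moments
    starting values are used otherwise.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown structure kind {kind!r}; expected one of {KINDS}")
    Y, gen_ids, env_labels = pivot_blues(blues)
    J = len(env_labels)
    if J < 2:
        raise ValueError("multienvironment fit needs >= 2 environments")
    n_per_env = np.sum(~np.isnan(Y), axis=0)
    if (n_per_env < 2).any():
        lab = [env_labels[j] for j in np.where(n_per_env < 2)[0]]
        raise ValueError(f"fewer than 2 observations in environment(s) {lab}")
    Gm = _align_G(G, g_ids or gen_ids, gen_ids)
    complete = not np.isnan(Y).any()
    if complete:
        ctx = _FastContext(Y, Gm)
    else:
        obs = ~np.isnan(Y)
        gi, ei = np.where(obs)
        ctx = _DenseContext(Y[obs], gi, ei, Gm, J)
    if theta_start is not None:
        starts = [np.asarray(theta_start, float)]
    else:
        starts = [_mom_start(Y, Gm, kind, J)]
        parent = {"CS": "ME", "UN_HET": "CS", "US": "UN_HET"}.get(kind)
        if parent is not None:
            simpler = reml_fit_multienv(
                blues, Gm, parent, n_restarts=0, max_iter=max_iter,
                seed=seed, compute_blups=False,
            )
            starts.append(_embed_theta(kind, simpler, J))
    rng = np.random.default_rng(seed)
    res, k_struct = _fit(ctx, kind, J, starts, n_restarts, max_iter, rng)
    theta = np.clip(res.x, -40.0, 40.0)
    S = _theta_to_sigma_e(kind, theta[:k_struct], J)
    r = np.exp(theta[k_struct:]) + _VAR_FLOOR
    mu = ctx.gls_means(S, r)
    loglik = -float(res.fun)
    if not np.isfinite(loglik):
        raise FitError(f"{kind} fit diverged (non-finite restricted log-likelihood)")
    boundary = bool((r < 1e-8).any() or (np.diag(S) < 1e-8).any())
    conv = {
        "converged": bool(res.success),
        "iterations": int(res.nit),
        "n_evaluations": int(res.nfev),
        "gradient_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        "boundary": boundary,
        "message": str(res.message),
        "theta": theta.tolist(),
    }
    if compute_blups:
        gmat = ctx.blups(S, r, mu)
        if complete:
            blup_df = pd.DataFrame(gmat, index=gen_ids, columns=env_labels)
        else:
            uniq = np.unique(np.where(~np.isnan(Y))[0])
            blup_df = pd.DataFrame(
                gmat, index=[gen_ids[i] for i in uniq], columns=env_labels
            )
    else:
        blup_df = pd.DataFrame(index=gen_ids, columns=env_labels, dtype=float)
    return RemlFit(
        kind=kind,
        env_labels=env_labels,
        genotype_ids=gen_ids,
        sigma_e=S,
        residual_vars=r,
        env_means=mu,
        restricted_loglik=loglik,
        n_free_params=structure_n_params(kind, J) + J,
        structure_params=_structure_params(kind, S),
        blups=blup_df,
        convergence=conv,
        n_obs=int(np.sum(~np.isnan(Y))),
    )


def reml_fit_se(
    blues_one_env: pd.DataFrame,
    G: np.ndarray | pd.DataFrame,
    g_ids: Sequence[str] | None = None,
    n_restarts: int = 2,
    max_iter: int = 500,
    seed: int = 0,
) -> RemlFit:
    """Single-environment G-BLUP: y_i = mu + g_i + e_i, g ~ N(0, G sigma_g^2).

    Fits (sigma_g^2, sigma_eps^2) by REML through the eigendecomposition of G.
    """
    Y, gen_ids, env_labels = pivot_blues(blues_one_env)
    if Y.shape[1] != 1:
        raise ValueError("reml_fit_se expects exactly one environment")
    keep = ~np.isnan(Y[:, 0])
    Y = Y[keep]
    gen_ids = [g for g, k in zip(gen_ids, keep) if k]
    if len(gen_ids) < 3:
        raise ValueError("need >= 3 genotypes for a single-environment fit")
    Gm = _align_G(G, g_ids or gen_ids, gen_ids)
    ctx = _FastContext(Y, Gm)
    theta0 = _mom_start(Y, Gm, "SE", 1)
    rng = np.random.default_rng(seed)
    res, k_struct = _fit(ctx, "SE", 1, [theta0], n_restarts, max_iter, rng)
    S = _theta_to_sigma_e("SE", res.x[:k_struct], 1)
    r = np.exp(res.x[k_struct:]) + _VAR_FLOOR
    mu = ctx.gls_means(S, r)
    gmat = ctx.blups(S, r, mu)
    conv = {
        "converged": bool(res.success),
        "iterations": int(res.nit),
        "n_evaluations": int(res.nfev),
        "boundary": bool(S[0, 0] < 1e-8 or r[0] < 1e-8),
        "message": str(res.message),
        "theta": res.x.tolist(),
    }
    return RemlFit(
        kind="SE",
        env_labels=env_labels,
        genotype_ids=gen_ids,
        sigma_e=S,
        residual_vars=r,
        env_means=mu,
        restricted_loglik=-float(res.fun),
        n_free_params=2,
        structure_params={"sigma_g2": float(S[0, 0]), "sigma_eps2": float(r[0])},
        blups=pd.DataFrame(gmat, index=gen_ids, columns=env_labels),
        convergence=conv,
        n_obs=len(gen_ids),
    )


def lrt(fit_nested: RemlFit, fit_full: RemlFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between two nested Sigma_E structures.

    Returns (statistic, df, p). The statistic is 2(l_full - l_nested), df is
    the difference in free Sigma_E parameters, p the chi-square upper tail.
    Boundary nulls (e.g. ME inside CS) make the plain chi-square reference
    conservative; callers comparing at a boundary should read p as an upper
    bound.
    """
    if fit_nested.kind not in _NESTING or fit_full.kind not in _NESTING:
        raise ValueError("LRT requires two multienvironment structure fits")
    if _NESTING[fit_nested.kind] >= _NESTING[fit_full.kind]:
        raise ValueError(
            f"{fit_nested.kind} is not nested inside {fit_full.kind}"
        )
    if fit_nested.env_labels != fit_full.env_labels or fit_nested.n_obs != fit_full.n_obs:
        raise ValueError("LRT requires fits of the same data")
    stat = max(0.0, 2.0 * (fit_full.restricted_loglik - fit_nested.restricted_loglik))
    df = fit_full.n_free_params - fit_nested.n_free_params
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# Generic dense variance-components REML (used by the trial stage)
# ---------------------------------------------------------------------------


@dataclass
class VCFit:
    variances: np.ndarray  # one per component, residual last
    beta: np.ndarray
    cov_beta: np.ndarray
    restricted_loglik: float
    converged: bool
    n_iter: int


def reml_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    components: Sequence[np.ndarray],
    max_iter: int = 200,
) -> VCFit:
    """REML for y = X b + sum_k u_k + e with cov(u_k) = s_k^2 K_k, e ~ s^2 I.

    ``components`` are the n×n PSD kernels K_k (typically Z Z' for a grouping
    factor). Variances are optimized on the log scale; the GLS fixed-effect
    solution and its covariance are returned at the optimum. Small dense
    problems only (n up to a few hundred).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise FitError("singular fixed-effects design (aliased columns)")
    Ks = [np.asarray(K, float) for K in components]
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = float(np.var(y - X @ beta_ols, ddof=p)) or 1.0
    k = len(Ks)
    theta0 = np.log(np.full(k + 1, s2 / (k + 1)))

    def build_V(theta: np.ndarray) -> np.ndarray:
        V = (np.exp(theta[-1]) + _VAR_FLOOR) * np.eye(n)
        for s, K in zip(np.exp(theta[:-1]), Ks):
            V += s * K
        return V

    def neg(theta: np.ndarray) -> float:
        V = build_V(theta)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Xs = np.linalg.solve(L, X)
        ys = np.linalg.solve(L, y)
        XtVX = Xs.T @ Xs
        sign, ldX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        b = np.linalg.solve(XtVX, Xs.T @ ys)
        quad = float(ys @ ys) - float((Xs.T @ ys) @ b)
        return 0.5 * (logdet + ldX + quad + (n - p) * np.log(2 * np.pi))

    res = optimize.minimize(
        neg, theta0, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-6},
    )
    V = build_V(res.x)
    L = np.linalg.cholesky(V)
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, y)
    XtVX = Xs.T @ Xs
    cov_beta = np.linalg.inv(XtVX)
    beta = cov_beta @ (Xs.T @ ys)
    return VCFit(
        variances=np.exp(res.x),
        beta=beta,
        cov_beta=cov_beta,
        restricted_loglik=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
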