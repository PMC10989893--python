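"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tetragp.genomics import compute_grm
from tetragp.reml_core import CovStructureSpec, pivot_blues
from tetragp.synthetic_data import (
    STUDY_ENVS,
    SimConfig,
    simulate_dosages,
    simulate_multienv_blues,
    tuber_weight_config,
)

# ---------------------------------------------------------------------------
# independent oracles (no shared code with the engine beyond numpy)
# ---------------------------------------------------------------------------


def dense_reml_loglik(blues: pd.DataFrame, G: np.ndarray, S: np.ndarray, r: np.ndarray) -> float:
    """Restricted log-likelihood by direct dense construction of V = G (x) S + I (x) R,
    no eigen-rotation: the oracle for the engine's likelihood values."""
    Y, _, envs = pivot_blues(blues)
    assert not np.isnan(Y).any()
    n, J = Y.shape
    y = Y.flatten()  # genotype-major
    V = np.kron(G, S) + np.kron(np.eye(n), np.diag(r))
    X = np.kron(np.ones((n, 1)), np.eye(J))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return float(
        -0.5
        * (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtViX)[1]
            + y @ P @ y
            + (n * J - J) * np.log(2 * np.pi)
        )
    )


def bruteforce_grm(M: np.ndarray, ploidy: int) -> np.ndarray:
    """Double-loop VanRaden-style GRM, entry by entry."""
    n, m = M.shape
    p = M.mean(axis=0) / ploidy
    denom = ploidy * sum(p[k] * (1 - p[k]) for k in range(m))
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(m):
                acc += (M[i, k] - ploidy * p[k]) * (M[j, k] - ploidy * p[k])
            G[i, j] = acc / denom
    return G


def henderson_blup(
    y: np.ndarray,
    g_idx: np.ndarray,
    e_idx: np.ndarray,
    G: np.ndarray,
    S: np.ndarray,
    r: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-model-equations solution for (mu_j, g_ij): the BLUP oracle.

    Treats u = vec(g) over ALL genotypes in G × all environments with
    cov(u) = G (x) S; records index into it via (g_idx, e_idx). Returns
    (beta, u) with u reshaped to (n_genotypes, J).
    """
    n, J = G.shape[0], S.shape[0]
    N = len(y)
    X = np.zeros((N, J))
    X[np.arange(N), e_idx] = 1.0
    Z = np.zeros((N, n * J))
    Z[np.arange(N), g_idx * J + e_idx] = 1.0
    Rinv = np.diag(1.0 / r[e_idx])
    Sigma_inv = np.linalg.inv(np.kron(G, S))
    top = np.hstack([X.T @ Rinv @ X, X.T @ Rinv @ Z])
    bot = np.hstack([Z.T @ Rinv @ X, Z.T @ Rinv @ Z + Sigma_inv])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:J], sol[J:].reshape(n, J)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_us_panel():
    """30 genotypes × 3 environments with unstructured truth and half-sib
    relatedness — small enough for dense oracles."""
    S = np.array([[1.0, 0.6, 0.3], [0.6, 1.2, 0.5], [0.3, 0.5, 0.8]])
    cfg = SimConfig(
        n_genotypes=30,
        n_markers=400,
        env_labels=STUDY_ENVS[:3],
        sigma_e_spec=CovStructureSpec("US", 3, {"sigma_e": S}),
        residual_vars=np.array([0.3, 0.4, 0.2]),
        seed=5,
        family_size=5,
    )
    dosages = simulate_dosages(cfg)
    gr = compute_grm(dosages, ridge=1e-6)
    blues, true_g = simulate_multienv_blues(dosages, cfg, G=gr.G)
    return {"cfg": cfg, "dosages": dosages, "gr": gr, "blues": blues, "true_g": true_g}


@pytest.fixture(scope="session")
def study_tw_panel():
    """Study-scale tuber-weight-like panel (147 genotypes, 6 trials)."""
    cfg = tuber_weight_config(seed=42, n_markers=2000)
    dosages = simulate_dosages(cfg)
    gr = compute_grm(dosages, ridge=1e-6)
    blues, true_g = simulate_multienv_blues(dosages, cfg, G=gr.G)
    return {"cfg": cfg, "gr": gr, "blues": blues, "true_g": true_g}
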