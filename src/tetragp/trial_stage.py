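"""Stage-1 phenotypic analysis of single field trials.

Each trial is a row-column resolvable design with complete blocks. The
per-trial model is

    y = genotype + block + row + column + plot error

with genotype and block fixed and independent random row and column effects
(variances sigma_row^2, sigma_col^2) plus i.i.d. plot error sigma_eps^2.
REML variance components come from the package's generic dense engine;
genotype adjusted means ("BLUEs") are the GLS fixed-effect solution at the
fitted components, with blocks coded sum-to-zero so each genotype
coefficient is its adjusted mean directly.

Broad-sense heritability is reported on an entry-mean basis,

    H^2 = sigma_g^2 / (sigma_g^2 + sigma_eps^2 / n_rep),

from the same model with genotype random; n_rep is the number of complete
blocks. Row and column variances are design noise, not genotype-by-replicate
noise, and are excluded from the denominator (a plot-basis formula would add
them plus sigma_eps^2 undivided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml_core import FitError, reml_variance_components

__all__ = ["TrialVarianceComponents", "fit_trial_blues", "trial_heritability", "read_plots"]

REQUIRED_COLS = ("genotype_id", "block", "row", "column", "value")


@dataclass
class TrialVarianceComponents:
    sigma_g2: float
    sigma_row2: float
    sigma_col2: float
    sigma_eps2: float
    H2: float
    n_rep: int
    restricted_loglik: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.H2 <= 1.0):
            raise ValueError(f"H2 = {self.H2} outside [0, 1]")


def _check_plots(plots: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table missing columns {missing}")
    if plots.duplicated(["genotype_id", "block"]).any():
        raise ValueError("a genotype appears more than once in a block")
    if plots["genotype_id"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    return plots.reset_index(drop=True)


def _design(plots: pd.DataFrame):
    gen = pd.unique(plots["genotype_id"])
    blocks = pd.unique(plots["block"])
    n = len(plots)
    g_idx = plots["genotype_id"].map({g: i for i, g in enumerate(gen)}).to_numpy()
    Xg = np.zeros((n, len(gen)))
    Xg[np.arange(n), g_idx] = 1.0
    # sum-to-zero block contrasts: genotype coefficients are adjusted means
    Xb = np.zeros((n, len(blocks) - 1))
    b_idx = plots["block"].map({b: i for i, b in enumerate(blocks)}).to_numpy()
    for k in range(len(blocks) - 1):
        Xb[b_idx == k, k] = 1.0
        Xb[b_idx == len(blocks) - 1, k] = -1.0
    kernels = []
    for col in ("row", "column"):
        lvl = pd.unique(plots[col])
        z_idx = plots[col].map({v: i for i, v in enumerate(lvl)}).to_numpy()
        Z = np.zeros((n, len(lvl)))
        Z[np.arange(n), z_idx] = 1.0
        kernels.append(Z @ Z.T)
    return gen, blocks, Xg, Xb, kernels


def fit_trial_blues(plots: pd.DataFrame) -> pd.DataFrame:
    """Adjusted genotype means (BLUEs) with standard errors for one trial.

    Returns a DataFrame with columns genotype_id, blue, se, ordered by first
    appearance. Raises :class:`FitError` when genotypes are aliased (singular
    fixed-effects design).
    """
    plots = _check_plots(plots)
    gen, blocks, Xg, Xb, kernels = _design(plots)
    X = np.hstack([Xg, Xb])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        counts = plots.groupby("genotype_id").size()
        suspect = counts[counts < len(blocks)].index.tolist()
        raise FitError(f"singular fixed-effects design; check genotypes {suspect[:5]}")
    y = plots["value"].to_numpy(dtype=float)
    vc = reml_variance_components(y, X, kernels)
    k = len(gen)
    return pd.DataFrame(
        {
            "genotype_id": gen,
            "blue": vc.beta[:k],
            "se": np.sqrt(np.maximum(np.diag(vc.cov_beta)[:k], 0.0)),
        }
    )


def trial_heritability(plots: pd.DataFrame) -> TrialVarianceComponents:
    """Entry-mean broad-sense heritability with genotype treated as random."""
    plots = _check_plots(plots)
    gen, blocks, Xg, Xb, kernels = _design(plots)
    n_rep = len(blocks)
    X = np.hstack([np.ones((len(plots), 1)), Xb])
    Kg = Xg @ Xg.T
    vc = reml_variance_components(plots["value"].to_numpy(dtype=float), X, [Kg] + kernels)
    sg2, sr2, sc2, se2 = vc.variances
    denom = sg2 + se2 / n_rep
    if denom <= 0:
        raise FitError("zero total variance: heritability undefined")
    return TrialVarianceComponents(
        sigma_g2=float(sg2),
        sigma_row2=float(sr2),
        sigma_col2=float(sc2),
        sigma_eps2=float(se2),
        H2=float(sg2 / denom),
        n_rep=n_rep,
        restricted_loglik=vc.restricted_loglik,
    )


def read_plots(path) -> pd.DataFrame:
    """Read a plot CSV (trial, genotype_id, block, row, column, value)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
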