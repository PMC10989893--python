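"""Genotype-by-environment interaction summaries.

Two complementary views of G×E:

* the genetic correlation matrix from an unstructured (US) fit,
  rho_jk = sigma_jk / (sigma_j sigma_k) — sub-unit correlations and
  heterogeneous variances are the two signatures of G×E;
* GGE biplot scores — the singular value decomposition of the
  environment-centred genotype × environment table (genotype main effect
  plus G×E retained). Environment arrow length approximates the genetic
  standard deviation within an environment and the cosine between arrows the
  genetic correlation; with all components kept the cosine equals the
  Pearson correlation of the centred columns exactly, so both the
  2-component approximation and the full-space values are reported.

Environments are centred but not scaled (standard GGE convention), and the
singular values are split symmetrically between genotype and environment
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml_core import RemlFit, pivot_blues

__all__ = ["GeneticCorrelationMatrix", "GGEScores", "genetic_correlations", "gge_scores"]


@dataclass
class GeneticCorrelationMatrix:
    env_labels: list[str]
    rho: np.ndarray
    source_kind: str

    def __post_init__(self) -> None:
        R = self.rho
        if np.max(np.abs(R - R.T)) > 1e-10:
            raise ValueError("correlation matrix not symmetric")
        if np.max(np.abs(np.diag(R) - 1.0)) > 1e-10:
            raise ValueError("correlation matrix diagonal must be 1")
        if (np.abs(R) > 1.0 + 1e-10).any():
            raise ValueError("correlations outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.env_labels, columns=self.env_labels)


def genetic_correlations(us_fit: RemlFit) -> GeneticCorrelationMatrix:
    """Genetic correlations between environments from an unstructured fit."""
    if us_fit.kind != "US":
        raise ValueError(f"need an unstructured (US) fit, got {us_fit.kind}")
    S = us_fit.sigma_e
    v = np.diag(S)
    if (v < 1e-9).any():
        bad = [us_fit.env_labels[j] for j in np.where(v < 1e-9)[0]]
        raise ValueError(f"zero fitted genetic variance in environment(s) {bad}")
    sd = np.sqrt(v)
    R = S / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    R = np.clip(0.5 * (R + R.T), -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return GeneticCorrelationMatrix(
        env_labels=list(us_fit.env_labels), rho=R, source_kind=us_fit.kind
    )


@dataclass
class GGEScores:
    genotype_ids: list[str]
    env_labels: list[str]
    genotype_scores: np.ndarray  # n × 2
    env_scores: np.ndarray  # J × 2
    singular_values: np.ndarray  # all min(n, J) values
    variance_explained: np.ndarray  # per component
    env_cosines_2d: np.ndarray
    env_cosines_full: np.ndarray  # == Pearson correlation of centred columns
    env_lengths_full: np.ndarray  # == sqrt(centred sum of squares)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "genotype_scores": pd.DataFrame(
                self.genotype_scores, index=self.genotype_ids, columns=["PC1", "PC2"]
            ),
            "env_scores": pd.DataFrame(
                self.env_scores, index=self.env_labels, columns=["PC1", "PC2"]
            ),
            "env_cosines_2d": pd.DataFrame(
                self.env_cosines_2d, index=self.env_labels, columns=self.env_labels
            ),
            "env_cosines_full": pd.DataFrame(
                self.env_cosines_full, index=self.env_labels, columns=self.env_labels
            ),
        }


def _cosines(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1)
    norms = np.where(norms == 0.0, 1.0, norms)
    C = (M / norms[:, None]) @ (M / norms[:, None]).T
    return np.clip(C, -1.0, 1.0)


def gge_scores(blues: pd.DataFrame, fill_missing: bool = False) -> GGEScores:
    """GGE biplot coordinates from a genotype × environment BLUE table.

    ``blues`` is the long table (genotype_id, env, value). Missing cells are
    rejected unless ``fill_missing``, which mean-fills per environment (with
    an inevitable shrinkage of that environment's apparent variance).
    """
    Y, gen_ids, env_labels = pivot_blues(blues)
    if len(env_labels) < 2:
        raise ValueError("GGE needs at least 2 environments")
    if np.isnan(Y).any():
        if not fill_missing:
            raise ValueError(
                "missing genotype × environment cells; pass fill_missing=True "
                "to mean-fill"
            )
        col_means = np.nanmean(Y, axis=0)
        idx = np.where(np.isnan(Y))
        Y = Y.copy()
        Y[idx] = np.take(col_means, idx[1])
    Yc = Y - Y.mean(axis=0, keepdims=True)  # environment-centred
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    var_exp = s**2 / np.sum(s**2) if s.sum() > 0 else np.zeros_like(s)
    k = min(2, len(s))
    # symmetric singular-value partitioning
    gscores = U[:, :k] * np.sqrt(s[:k])[None, :]
    escores = Vt[:k].T * np.sqrt(s[:k])[None, :]
    if k < 2:  # degenerate single-component case
        gscores = np.pad(gscores, ((0, 0), (0, 2 - k)))
        escores = np.pad(escores, ((0, 0), (0, 2 - k)))
    env_full = Vt.T * s[None, :]  # rows: environment vectors, all components
    return GGEScores(
        genotype_ids=gen_ids,
        env_labels=env_labels,
        genotype_scores=gscores,
        env_scores=escores,
        singular_values=s,
        variance_explained=var_exp,
        env_cosines_2d=_cosines(escores),
        env_cosines_full=_cosines(env_full),
        env_lengths_full=np.linalg.norm(env_full, axis=1),
    )
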