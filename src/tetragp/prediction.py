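"""Cross-validated genomic prediction scenarios.

Three breeding applications of the multienvironment model, evaluated by
repeated training/test splits:

* **Scenario 1** — forecasting *tested* genotypes into a new year: train on
  one year's trials (environments = the three regions, J=3, or the target
  region alone for the single-environment baseline), predict the same
  sampled genotypes' genotypic effects for the target region, and correlate
  with their observed adjusted means in the target region and year.
* **Scenario 2** — *untested* genotypes under known conditions: train on the
  sampled genotypes' records in all six trials (environments = trials, J=6),
  predict the held-out genotypes in one target trial.
* **Scenario 3** — untested genotypes into a new year: scenario-1 training,
  but predictions are for the held-out genotypes.

Prediction ability is the Pearson correlation between predicted genotypic
effects and observed phenotypic values (stage-1 BLUEs) in the evaluation
set, averaged over repetitions. Repetition k of every scenario/model draws
its training partition from a generator seeded by (seed, k) only, so
comparisons between models are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GenomicRelationship
from .reml_core import KINDS, RemlFit, reml_fit_multienv, reml_fit_se

__all__ = [
    "ScenarioSpec",
    "PredictionResult",
    "prediction_ability",
    "blup_predict",
    "run_scenario1",
    "run_scenario2",
    "run_scenario3",
    "environment_dropout",
]

MODELS = ("SE",) + KINDS


@dataclass
class ScenarioSpec:
    """Configuration of one scenario run.

    ``target`` is (region, year) for scenarios 1 and 3, a trial label (e.g.
    "NL.18") for scenario 2. ``evaluate_all`` extends scenario-1 evaluation
    from the sampled training genotypes to the whole panel.
    """

    scenario: int
    target: tuple | str
    model: str = "ME"
    n_train: int = 105
    n_reps: int = 100
    seed: int = 0
    evaluate_all: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValueError(f"scenario must be 1, 2 or 3, got {self.scenario}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.n_train < 3:
            raise ValueError("n_train must be >= 3")


@dataclass
class PredictionResult:
    scenario: int
    target: str
    model: str
    abilities: np.ndarray  # one per repetition; NaN = undefined correlation
    n_test: list = field(default_factory=list)

    def __post_init__(self) -> None:
        finite = self.abilities[np.isfinite(self.abilities)]
        if finite.size and (np.abs(finite) > 1.0 + 1e-12).any():
            raise ValueError("abilities outside [-1, 1]")

    @property
    def mean_ability(self) -> float:
        finite = self.abilities[np.isfinite(self.abilities)]
        return float(finite.mean()) if finite.size else float("nan")

    @property
    def n_undefined(self) -> int:
        return int(np.sum(~np.isfinite(self.abilities)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "target": self.target,
                "model": self.model,
                "repetition": np.arange(1, len(self.abilities) + 1),
                "ability": self.abilities,
            }
        )


def prediction_ability(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation between predictions and observations.

    Returns NaN (an undefined-ability flag) when either side has zero
    variance; callers exclude NaNs from means and report their count.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(predicted) == 0.0 or np.std(observed) == 0.0:
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])


def _G_frame(G) -> pd.DataFrame:
    if isinstance(G, GenomicRelationship):
        return G.to_frame()
    if isinstance(G, pd.DataFrame):
        return G
    raise TypeError("G must be a GenomicRelationship or labelled DataFrame")


def blup_predict(
    fit: RemlFit,
    G,
    train_records: pd.DataFrame,
    test_genotypes: list[str],
    target_env: str,
) -> np.ndarray:
    """Predicted genotypic effects in ``target_env`` for ``test_genotypes``.

    Standard mixed-model conditional mean: with V the covariance of the
    training records implied by the fit and C = cov(g_test,target, y_train),
    ghat = C V^-1 (y - X mu). Test genotypes may be absent from training (their
    information then flows only through G); a genotype unrelated to all
    training genotypes is shrunk fully to zero.
    """
    if target_env not in fit.env_labels:
        raise ValueError(
            f"target environment {target_env!r} not in fitted environments {fit.env_labels}"
        )
    Gf = _G_frame(G)
    pos = {g: i for i, g in enumerate(Gf.index.astype(str))}
    e_pos = {e: j for j, e in enumerate(fit.env_labels)}
    bad = set(train_records["env"]) - set(e_pos)
    if bad:
        raise ValueError(f"training records in unfitted environments {sorted(bad)}")
    gi = np.array([pos[str(g)] for g in train_records["genotype_id"]])
    ei = np.array([e_pos[e] for e in train_records["env"]])
    ti = np.array([pos[str(g)] for g in test_genotypes])
    Gm = Gf.to_numpy(dtype=float)
    S, r, mu = fit.sigma_e, fit.residual_vars, fit.env_means
    V = Gm[np.ix_(gi, gi)] * S[np.ix_(ei, ei)]
    V[np.diag_indices_from(V)] += r[ei]
    y = train_records["value"].to_numpy(dtype=float)
    resid = y - mu[ei]
    C = Gm[np.ix_(ti, gi)] * S[e_pos[target_env], ei][None, :]
    return C @ np.linalg.solve(V, resid)


# ---------------------------------------------------------------------------
# scenario machinery
# ---------------------------------------------------------------------------


def _partition(ids: list[str], n_train: int, seed: int, rep: int):
    rng = np.random.default_rng([seed, rep])
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


def _fit_model(records: pd.DataFrame, G, model: str, theta_start=None) -> RemlFit:
    Gf = _G_frame(G)
    if model == "SE":
        return reml_fit_se(records, Gf, n_restarts=0)
    return reml_fit_multienv(
        records,
        Gf,
        model,
        n_restarts=0 if theta_start is not None else 1,
        theta_start=theta_start,
        compute_blups=False,
    )


def _warm_start(records: pd.DataFrame, G, model: str):
    """Fit once on all genotypes to warm-start per-repetition fits."""
    if model == "SE" or records.empty:
        return None
    fit = reml_fit_multienv(
        records, _G_frame(G), model, n_restarts=1, compute_blups=False
    )
    return np.asarray(fit.convergence["theta"], float)


def _year_transfer(
    blues: pd.DataFrame, G, spec: ScenarioSpec, predict_tested: bool
) -> PredictionResult:
    region, target_year = spec.target
    years = sorted(blues["year"].unique())
    if target_year not in years or len(years) < 2:
        raise ValueError(f"target year {target_year} needs a companion training year")
    train_year = [y for y in years if y != target_year][0]
    target_obs = blues[(blues["location"] == region) & (blues["year"] == target_year)]
    if target_obs.empty:
        raise ValueError(f"no records for region {region!r} in year {target_year}")
    obs_map = dict(zip(target_obs["genotype_id"], target_obs["value"]))
    ids = sorted(obs_map)
    train_pool = blues[blues["year"] == train_year].copy()
    train_pool["env"] = train_pool["location"]  # environments = regions
    if spec.model == "SE":
        train_pool = train_pool[train_pool["location"] == region]
    theta0 = (
        None
        if spec.model == "SE"
        else _warm_start(train_pool[["genotype_id", "env", "value"]], G, spec.model)
    )
    abilities, n_test = [], []
    for rep in range(spec.n_reps):
        train_ids, held_out = _partition(ids, spec.n_train, spec.seed, rep)
        recs = train_pool[train_pool["genotype_id"].isin(train_ids)]
        fit = _fit_model(recs[["genotype_id", "env", "value"]], G, spec.model, theta0)
        target_env = region if spec.model != "SE" else fit.env_labels[0]
        if predict_tested:
            eval_ids = ids if spec.evaluate_all else train_ids
        else:
            eval_ids = held_out
        ghat = blup_predict(
            fit, G, recs[["genotype_id", "env", "value"]], eval_ids, target_env
        )
        obs = np.array([obs_map[g] for g in eval_ids])
        abilities.append(prediction_ability(ghat, obs))
        n_test.append(len(eval_ids))
    return PredictionResult(
        scenario=spec.scenario,
        target=f"{region}.{str(target_year)[-2:]}",
        model=spec.model,
        abilities=np.array(abilities),
        n_test=n_test,
    )


def run_scenario1(blues: pd.DataFrame, G, spec: ScenarioSpec) -> PredictionResult:
    """Forecast tested genotypes into the target (region, year)."""
    if spec.scenario != 1:
        raise ValueError("spec.scenario must be 1")
    return _year_transfer(blues, G, spec, predict_tested=True)


def run_scenario3(blues: pd.DataFrame, G, spec: ScenarioSpec) -> PredictionResult:
    """Predict untested genotypes in the target (region, year)."""
    if spec.scenario != 3:
        raise ValueError("spec.scenario must be 3")
    return _year_transfer(blues, G, spec, predict_tested=False)


def run_scenario2(
    blues: pd.DataFrame, G, spec: ScenarioSpec, excluded_trials: list[str] | None = None
) -> PredictionResult:
    """Predict untested genotypes in a known trial from all available trials.

    Multienvironment models train on the sampled genotypes' records in every
    trial (minus ``excluded_trials``); the single-environment baseline trains
    on the target trial only. Held-out genotypes never enter training.
    """
    if spec.scenario != 2:
        raise ValueError("spec.scenario must be 2")
    target = spec.target
    if excluded_trials and target in excluded_trials:
        raise ValueError("cannot exclude the target trial from its own prediction")
    data = blues.copy()
    if "env" not in data.columns:
        data["env"] = data["location"] + "." + data["year"].astype(str).str[-2:]
    trials = list(pd.unique(data["env"]))
    if target not in trials:
        raise ValueError(f"target trial {target!r} not present (have {trials})")
    if excluded_trials:
        data = data[~data["env"].isin(excluded_trials)]
    target_obs = data[data["env"] == target]
    obs_map = dict(zip(target_obs["genotype_id"], target_obs["value"]))
    ids = sorted(obs_map)
    pool = data if spec.model != "SE" else data[data["env"] == target]
    theta0 = (
        None
        if spec.model == "SE"
        else _warm_start(pool[["genotype_id", "env", "value"]], G, spec.model)
    )
    abilities, n_test = [], []
    for rep in range(spec.n_reps):
        train_ids, test_ids = _partition(ids, spec.n_train, spec.seed, rep)
        recs = pool[pool["genotype_id"].isin(train_ids)]
        fit = _fit_model(recs[["genotype_id", "env", "value"]], G, spec.model, theta0)
        target_env = target if spec.model != "SE" else fit.env_labels[0]
        ghat = blup_predict(
            fit, G, recs[["genotype_id", "env", "value"]], test_ids, target_env
        )
        obs = np.array([obs_map[g] for g in test_ids])
        abilities.append(prediction_ability(ghat, obs))
        n_test.append(len(test_ids))
    return PredictionResult(
        scenario=2,
        target=target,
        model=spec.model,
        abilities=np.array(abilities),
        n_test=n_test,
    )


def environment_dropout(
    blues: pd.DataFrame, G, spec: ScenarioSpec, excluded_trials: list[str]
) -> PredictionResult:
    """Scenario-2 run with trials removed from training.

    Shares the genotype partitions of the matching full run (same seed), so
    the with/without comparison is paired repetition by repetition.
    """
    return run_scenario2(blues, G, spec, excluded_trials=excluded_trials)
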