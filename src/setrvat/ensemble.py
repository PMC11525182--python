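"""K-fold, multi-restart training and leakage-free impairment scoring.

Individuals are partitioned into K near-equal folds; for each fold, R
modules (random restarts) are trained on the other K-1 folds.  A training
cohort individual is scored by averaging exactly the R modules of its own
held-out fold — never a model that saw the individual — while external
individuals are scored by the full K*R ensemble.  The no-leakage property
is machine-checked by :func:`audit_no_leakage`.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortDataset, DataError
from .model import (
    ImpairmentModule,
    PhenotypeHead,
    TrainingConfig,
    score_matrix,
    train_impairment_module,
)

logger = logging.getLogger("setrvat")

DEFAULT_K = 5
DEFAULT_RESTARTS = 6


@dataclass
class CVPlan:
    """Fold bookkeeping: individual -> fold index, plus K, R and the seed."""

    K: int
    R: int
    fold_of: np.ndarray  # per-individual fold index
    rng_seed: int

    def fold_members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == k)


def make_folds(n_individuals: int, K: int = DEFAULT_K, R: int = DEFAULT_RESTARTS,
               rng_seed: int = 0) -> CVPlan:
    """Random partition into K folds whose sizes differ by at most one."""
    if K < 2:
        raise DataError("K must be at least 2")
    if n_individuals < K:
        raise DataError("fewer individuals than folds")
    rng = np.random.default_rng(rng_seed)
    fold_of = np.tile(np.arange(K), n_individuals // K + 1)[:n_individuals]
    rng.shuffle(fold_of)
    return CVPlan(K=K, R=R, fold_of=fold_of, rng_seed=rng_seed)


def _restart_seed(base: int, fold: int, restart: int) -> int:
    # deterministic per (fold, restart), reproducible from one integer
    return int((base * 1000003 + fold * 9973 + restart * 7919) % (2 ** 31 - 1))


@dataclass
class CVEnsemble:
    """K x R trained modules with their training-fold membership."""

    plan: CVPlan
    modules: dict[tuple[int, int], ImpairmentModule]  # (fold, restart) -> module
    heads: dict[tuple[int, int], dict[str, PhenotypeHead]] = field(default_factory=dict)
    logs: dict[tuple[int, int], pd.DataFrame] = field(default_factory=dict)

    def training_individuals(self, fold: int) -> np.ndarray:
        """Individuals the (fold, *) models were trained on: everyone
        outside the held-out fold."""
        return np.flatnonzero(self.plan.fold_of != fold)


def train_cv_ensemble(
    dataset: CohortDataset, seed_genes: dict[str, list[str]],
    assignment: pd.DataFrame, config: TrainingConfig | None = None,
    plan: CVPlan | None = None, linear: bool = False,
) -> CVEnsemble:
    """Train all K*R modules of the cross-validation scheme."""
    config = config or TrainingConfig()
    n = dataset.genotypes.n_individuals
    if plan is None:
        plan = make_folds(n, rng_seed=config.rng_seed)
    modules, heads, logs = {}, {}, {}
    for k in range(plan.K):
        train_ind = np.flatnonzero(plan.fold_of != k)
        for r in range(plan.R):
            cfg = TrainingConfig(**{**config.__dict__,
                                    "rng_seed": _restart_seed(config.rng_seed, k, r)})
            try:
                mod, hd, log = train_impairment_module(
                    dataset, seed_genes, assignment, cfg,
                    individuals=train_ind, linear=linear)
            except Exception as exc:  # noqa: BLE001 - annotate failure location
                raise RuntimeError(f"training failed at fold {k}, restart {r}: {exc}"
                                   ) from exc
            modules[(k, r)] = mod
            heads[(k, r)] = hd
            logs[(k, r)] = log
            logger.info("trained fold %d restart %d (%d epochs)", k, r, len(log))
    return CVEnsemble(plan=plan, modules=modules, heads=heads, logs=logs)


def _average_scores(mods: list[ImpairmentModule], dataset, assignment, genes,
                    individuals, maf_cutoff, cadd_cutoff) -> pd.DataFrame:
    acc = None
    for mod in mods:
        s = score_matrix(mod, dataset, assignment, genes=genes,
                         individuals=individuals, maf_cutoff=maf_cutoff,
                         cadd_cutoff=cadd_cutoff)
        acc = s if acc is None else acc + s
    return acc / len(mods)


def score_out_of_fold(
    ensemble: CVEnsemble, dataset: CohortDataset, assignment: pd.DataFrame,
    genes=None, maf_cutoff: float = 0.001, cadd_cutoff: float = 5.0,
) -> pd.DataFrame:
    """Leakage-free scores for the training cohort.

    Each individual is scored by the mean of psi over exactly the R models
    whose held-out fold contains the individual.
    """
    plan = ensemble.plan
    n = dataset.genotypes.n_individuals
    if plan.fold_of.size != n:
        raise DataError("fold plan does not match the cohort")
    parts = []
    for k in range(plan.K):
        members = plan.fold_members(k)
        mods = [ensemble.modules[(k, r)] for r in range(plan.R)]
        parts.append(_average_scores(mods, dataset, assignment, genes, members,
                                     maf_cutoff, cadd_cutoff))
    out = pd.concat(parts)
    ids = dataset.genotypes.individual_ids
    return out.loc[ids]


def score_external(
    ensemble: CVEnsemble, dataset: CohortDataset, assignment: pd.DataFrame,
    genes=None, maf_cutoff: float = 0.001, cadd_cutoff: float = 5.0,
) -> pd.DataFrame:
    """Scores for individuals outside the training cohort: mean of psi over
    all K*R models (schema checked per model)."""
    mods = [ensemble.modules[(k, r)] for k in range(ensemble.plan.K)
            for r in range(ensemble.plan.R)]
    return _average_scores(mods, dataset, assignment, genes, None,
                           maf_cutoff, cadd_cutoff)


def score_leaky(
    ensemble: CVEnsemble, dataset: CohortDataset, assignment: pd.DataFrame,
    genes=None, maf_cutoff: float = 0.001, cadd_cutoff: float = 5.0,
) -> pd.DataFrame:
    """Deliberately leaky counterpart of :func:`score_out_of_fold`: each
    individual is scored by the models that WERE trained on it.  Exists only
    to demonstrate the inflation the CV scheme prevents."""
    plan = ensemble.plan
    parts = []
    for k in range(plan.K):
        members = np.flatnonzero(plan.fold_of != k)  # training individuals
        mods = [ensemble.modules[(k, r)] for r in range(plan.R)]
        parts.append(_average_scores(mods, dataset, assignment, genes, members,
                                     maf_cutoff, cadd_cutoff))
    # each individual appears in K-1 training sets; average those scores
    stacked = pd.concat(parts)
    out = stacked.groupby(level=0).mean()
    ids = dataset.genotypes.individual_ids
    return out.loc[ids]


def audit_no_leakage(ensemble: CVEnsemble) -> bool:
    """Machine check: for every individual, the model set used for scoring
    is disjoint from the models trained on that individual."""
    plan = ensemble.plan
    for k in range(plan.K):
        members = set(plan.fold_members(k).tolist())
        trained_on = set(ensemble.training_individuals(k).tolist())
        if members & trained_on:
            return False
    return True


# ---------------------------------------------------------------------------
# ensemble persistence
# ---------------------------------------------------------------------------


def save_ensemble(directory: str, ensemble: CVEnsemble,
                  config: TrainingConfig | None = None) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "K": ensemble.plan.K, "R": ensemble.plan.R,
        "rng_seed": ensemble.plan.rng_seed,
        "maf_cutoff": config.maf_cutoff if config else None,
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    np.save(os.path.join(directory, "fold_of.npy"), ensemble.plan.fold_of)
    for (k, r), mod in ensemble.modules.items():
        mod.save(os.path.join(directory, f"fold{k}_restart{r}"))


def load_ensemble(directory: str) -> CVEnsemble:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    fold_of = np.load(os.path.join(directory, "fold_of.npy"))
    plan = CVPlan(K=manifest["K"], R=manifest["R"], fold_of=fold_of,
                  rng_seed=manifest["rng_seed"])
    modules = {}
    for k in range(plan.K):
        for r in range(plan.R):
            modules[(k, r)] = ImpairmentModule.load(
                os.path.join(directory, f"fold{k}_restart{r}"))
    return CVEnsemble(plan=plan, modules=modules)
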