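"""Rare-variant-augmented phenotype prediction.

Compares a common-variant-PRS-only regression baseline against models that
add per-gene rare-variant burdens — either learned impairment scores or
single-annotation burdens — for significant genes, and quantifies the gain
by relative improvement in R^2 / AUPRC and by enrichment of extreme-
phenotype individuals among those whose prediction the rare variants move
the most.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortDataset, DataError, filter_qualifying_variants
from .seedgenes import fit_null_logistic

logger = logging.getLogger("setrvat")


@dataclass
class PredictionModel:
    trait: str
    kind: str  # linear | logistic
    feature_names: list[str]
    coef: np.ndarray
    gene_set: list[str]
    flagged: bool = False
    note: str | None = None

    def predict(self, F: np.ndarray) -> np.ndarray:
        eta = np.asarray(F, dtype=float) @ self.coef
        if self.kind == "logistic":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def _design(X: np.ndarray, prs: np.ndarray, burdens: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(len(prs)), *np.asarray(X, dtype=float).T, np.asarray(prs, float)]
    if burdens is not None and burdens.size:
        cols.extend(np.asarray(burdens, dtype=float).T)
    return np.column_stack(cols)


def fit_phenotype_predictor(
    y: np.ndarray, X: np.ndarray, prs: np.ndarray,
    burdens: np.ndarray | None = None, gene_set: list[str] | None = None,
    kind: str = "linear", trait: str = "",
) -> PredictionModel:
    """OLS (quantitative) or maximum-likelihood logistic (binary extreme
    labels) fit of y ~ covariates + PRS + per-gene burdens.

    With an empty gene set the model reduces exactly to the PRS-only
    baseline.
    """
    gene_set = gene_set or []
    F = _design(X, prs, burdens)
    names = (["intercept"] + [f"cov{j}" for j in range(np.asarray(X).shape[1])]
             + ["prs"] + list(gene_set))
    y = np.asarray(y, dtype=float)
    flagged, note = False, None
    if kind == "linear":
        coef, *_ = np.linalg.lstsq(F, y, rcond=None)
    elif kind == "logistic":
        null = fit_null_logistic(y, F)
        coef = _logistic_coef(y, F)
        mu = 1.0 / (1.0 + np.exp(-(F @ coef)))
        if np.any((mu > 1 - 1e-8) & (y > 0.5)) and np.all((mu > 0.5) == (y > 0.5)):
            flagged, note = True, "possible perfect separation"
            logger.warning("logistic fit for %s: %s", trait, note)
        del null
    else:
        raise DataError(f"unknown model kind {kind!r}")
    return PredictionModel(trait=trait, kind=kind, feature_names=names,
                           coef=coef, gene_set=list(gene_set),
                           flagged=flagged, note=note)


def _logistic_coef(y: np.ndarray, F: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-10) -> np.ndarray:
    beta = np.zeros(F.shape[1])
    for _ in range(max_iter):
        eta = np.clip(F @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        wf = F * w[:, None]
        try:
            beta_new = np.linalg.solve(F.T @ wf, wf.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(F.T @ wf, wf.T @ z, rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def auprc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by step interpolation
    (precision treated as a step function of recall)."""
    labels = np.asarray(labels, float)
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    tp = np.cumsum(labels[order])
    n_pos = labels.sum()
    if n_pos == 0:
        raise DataError("no positive labels")
    precision = tp / np.arange(1, labels.size + 1)
    recall = tp / n_pos
    drecall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(precision * drecall))


def relative_improvement(m_rare: float, m_prs_only: float) -> float:
    """(M_rare - M_PRS) / M_PRS; sign preserved, undefined at M_PRS = 0."""
    if m_prs_only == 0:
        raise DataError("relative improvement undefined: baseline metric is 0")
    return (m_rare - m_prs_only) / m_prs_only


def extreme_phenotype_labels(y: np.ndarray, tail: str = "top",
                             percentile: float = 1.0) -> np.ndarray:
    """Binary labels for the top or bottom phenotype percentile (rank
    based, so invariant to monotone transforms of y)."""
    if not (0.0 < percentile < 50.0):
        raise DataError("percentile must lie in (0, 50)")
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise DataError("constant phenotype has no extremes")
    n = y.size
    k = int(round(n * percentile / 100.0))
    k = max(k, 1)
    order = np.argsort(y, kind="stable")
    labels = np.zeros(n)
    idx = order[-k:] if tail == "top" else order[:k]
    labels[idx] = 1.0
    return labels


@dataclass
class EnrichmentCurve:
    ranking: str
    ranks: np.ndarray
    cumulative_extreme: np.ndarray
    baseline: np.ndarray
    perfect: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def area_above_baseline(self) -> float:
        return float(np.mean(self.cumulative_extreme - self.baseline))


def enrichment_by_deviation(pred_prs: np.ndarray, pred_rare: np.ndarray,
                            extreme_labels: np.ndarray) -> EnrichmentCurve:
    """Rank held-out individuals by |rare-model prediction - PRS-only
    prediction| and count extreme-phenotype individuals cumulatively."""
    pred_prs = np.asarray(pred_prs, float)
    pred_rare = np.asarray(pred_rare, float)
    labels = np.asarray(extreme_labels, float)
    if not (pred_prs.size == pred_rare.size == labels.size):
        raise DataError("prediction/label length mismatch")
    dev = np.abs(pred_rare - pred_prs)
    order = np.argsort(-dev, kind="stable")
    cum = np.cumsum(labels[order])
    n = labels.size
    ranks = np.arange(1, n + 1)
    baseline = ranks * labels.mean()
    perfect = np.minimum(ranks, labels.sum())
    return EnrichmentCurve(ranking="abs_prediction_deviation", ranks=ranks,
                           cumulative_extreme=cum, baseline=baseline,
                           perfect=perfect)


def zscore_enrichment(pred_prs: np.ndarray, pred_rare: np.ndarray,
                      y: np.ndarray, z_cutoffs=(0.0, 0.5, 1.0, 1.5, 2.0)) -> pd.DataFrame:
    """Among individuals with y >= z, the proportion whose prediction
    exceeds that model's own 99% quantile, scaled by the z = 0 proportion.

    ``y`` should be on the standard-normal (quantile transformed) scale.
    """
    y = np.asarray(y, float)
    rows = []
    for name, pred in (("prs_only", np.asarray(pred_prs, float)),
                       ("rare_augmented", np.asarray(pred_rare, float))):
        q99 = np.quantile(pred, 0.99)
        above0 = y >= 0.0
        base = np.mean(pred[above0] > q99) if above0.any() else np.nan
        for z in z_cutoffs:
            stratum = y >= z
            if not stratum.any():
                rows.append({"model": name, "z": z, "enrichment": np.nan})
                continue
            prop = np.mean(pred[stratum] > q99)
            rows.append({"model": name, "z": z,
                         "enrichment": prop / base if base and base > 0 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alternative single-annotation burdens
# ---------------------------------------------------------------------------


def alternative_burdens(
    dataset: CohortDataset, assignment: pd.DataFrame, annotation: str,
    genes, maf_cutoff: float = 0.001, lower_is_worse: bool = False,
    individuals: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene burden s_ij: the max (or min, for annotations where lower
    means more damaging) of one annotation over the individual's
    qualifying variants; non-carriers get 0."""
    if annotation not in dataset.variants.columns:
        raise DataError(f"unknown annotation {annotation!r}")
    if individuals is None:
        individuals = np.arange(dataset.genotypes.n_individuals)
    individuals = np.asarray(individuals)
    qual = filter_qualifying_variants(dataset.variants, maf_cutoff)
    qual_mask = np.zeros(len(dataset.variants), dtype=bool)
    qual_mask[qual] = True
    vals = dataset.variants[annotation].to_numpy(dtype=float)
    csc = dataset.genotypes.matrix.tocsc()
    by_gene = assignment.groupby("gene_id")["variant_row"]
    out = np.zeros((individuals.size, len(genes)))
    for g, gene in enumerate(genes):
        if gene not in by_gene.groups:
            continue
        rows = by_gene.get_group(gene).to_numpy()
        rows = rows[qual_mask[rows]]
        if rows.size == 0:
            continue
        sub = csc[:, rows].tocsr()[individuals].tocoo()
        if sub.nnz == 0:
            continue
        v = vals[rows][sub.col]
        if lower_is_worse:
            np.minimum.at(out[:, g], sub.row, v)
        else:
            np.maximum.at(out[:, g], sub.row, v)
    ids = dataset.genotypes.individual_ids[individuals]
    return pd.DataFrame(out, index=pd.Index(ids, name="individual"),
                        columns=list(genes))
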