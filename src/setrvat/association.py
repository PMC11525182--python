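"""Gene-trait association testing on impairment scores.

The per-gene score is treated as a burden and tested with the same score
test used for seed-gene discovery; genes are gated by the expected allele
frequency (EAF >= 50) filter and Bonferroni-corrected across tested genes.
Conditional analysis re-tests a gene with caller-supplied common-variant
dosages appended to the covariates.  Scores can be exported as
pseudovariants — dosage d = 2 psi with genotype probabilities
(psi, 0, 1 - psi) — in BGEN v1.2 or a TSV dosage dialect, so external
single-marker frameworks can test them.

For binary traits a logistic score test is provided but known to be
anti-conservative for rare, strong-effect genes at low case counts; the
robust route is pseudodosage export to a Firth-penalised external tester.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    CohortDataset,
    DataError,
    MAF_CUTOFF_ASSOCIATION,
    compute_eaf,
    filter_qualifying_variants,
    quantile_transform_phenotype,
)
from .seedgenes import NullModel, burden_score_test, fit_null_linear, fit_null_logistic

logger = logging.getLogger("setrvat")


@dataclass
class AssociationResult:
    gene: str
    trait: str
    beta: float
    statistic: float
    p_value: float
    p_corrected: float | None = None
    eaf: float | None = None
    eaf_pass: bool = True
    p_conditional: float | None = None


def _effect_size(g: np.ndarray, null: NullModel) -> float:
    """One-degree-of-freedom effect estimate consistent with the score fit."""
    from .seedgenes import _residualize

    gt = _residualize(g, null)
    denom = float(gt @ gt) if not null.is_logistic else float(gt * null.weights @ gt)
    if denom <= 0:
        return 0.0
    return float(gt @ null.residuals) / denom


def impairment_association_test(
    scores: np.ndarray, y: np.ndarray, X: np.ndarray, trait_type: str = "quantitative",
    gene: str = "", trait: str = "",
) -> AssociationResult:
    """Score test of one gene's impairment scores against one trait.

    Quantitative traits use the linear null (y already quantile
    transformed); binary traits use the logistic null with a logged
    calibration caveat.
    """
    scores = np.asarray(scores, dtype=float)
    if trait_type == "binary":
        logger.warning("native logistic score test on binary trait %s; consider "
                       "pseudodosage export to a Firth-penalised tester", trait)
        null = fit_null_logistic(y, X)
    else:
        null = fit_null_linear(y, X)
    if np.allclose(scores, scores[0]):
        return AssociationResult(gene, trait, 0.0, 0.0, 1.0)
    res = burden_score_test(scores, null, gene=gene, trait=trait, mask="impairment")
    return AssociationResult(gene, trait, _effect_size(scores, null),
                             res.statistic, res.p_value)


def bonferroni_correct(results: list[AssociationResult] | pd.DataFrame,
                       m: int | None = None):
    """Corrected p = min(1, m * p); m defaults to the number of results."""
    if isinstance(results, pd.DataFrame):
        m = m or len(results)
        if m < 1:
            raise DataError("m must be >= 1")
        out = results.copy()
        out["p_corrected"] = np.minimum(1.0, m * out["p_value"])
        return out
    m = m or len(results)
    if m < 1:
        raise DataError("m must be >= 1")
    for r in results:
        r.p_corrected = min(1.0, m * r.p_value)
    return results


def associate_all_genes(
    dataset: CohortDataset, score_df: pd.DataFrame, trait: str,
    assignment: pd.DataFrame, maf_cutoff: float = MAF_CUTOFF_ASSOCIATION,
    fwer: float = 0.05, apply_eaf: bool = True,
) -> pd.DataFrame:
    """Test every EAF-passing gene for one trait; Bonferroni across the
    genes actually tested."""
    binary = trait in dataset.binary_traits
    y_raw = dataset.phenotypes[trait].to_numpy(dtype=float)
    obs = ~np.isnan(y_raw)
    y = y_raw[obs] if binary else quantile_transform_phenotype(y_raw)[obs]
    X = np.column_stack([np.ones(int(obs.sum())),
                         dataset.covariates.to_numpy(dtype=float)[obs]])
    null = fit_null_logistic(y, X) if binary else fit_null_linear(y, X)
    n_for_eaf = int(y.sum()) if binary else int(obs.sum())

    qual = filter_qualifying_variants(dataset.variants, maf_cutoff)
    qual_mask = np.zeros(len(dataset.variants), dtype=bool)
    qual_mask[qual] = True
    mafs = dataset.variants["maf"].to_numpy()
    by_gene = assignment.groupby("gene_id")["variant_row"]

    rows = []
    for gene in score_df.columns:
        if gene in by_gene.groups:
            grows = by_gene.get_group(gene).to_numpy()
            grows = grows[qual_mask[grows]]
        else:
            grows = np.array([], dtype=int)
        caf, eaf, passes = compute_eaf(mafs[grows], n_for_eaf)
        if apply_eaf and not passes:
            continue
        g = score_df[gene].to_numpy(dtype=float)[obs]
        if np.allclose(g, g[0] if g.size else 0.0):
            rows.append({"gene": gene, "trait": trait, "beta": 0.0,
                         "statistic": 0.0, "p_value": 1.0, "eaf": eaf})
            continue
        res = burden_score_test(g, null, gene=gene, trait=trait, mask="impairment")
        rows.append({"gene": gene, "trait": trait,
                     "beta": _effect_size(g, null),
                     "statistic": res.statistic, "p_value": res.p_value,
                     "eaf": eaf})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = bonferroni_correct(table)
    table["significant"] = table["p_corrected"] < fwer
    return table.sort_values("p_value", ignore_index=True)


def conditional_association_test(
    scores: np.ndarray, conditioning: np.ndarray, y: np.ndarray, X: np.ndarray,
    trait_type: str = "quantitative", gene: str = "", trait: str = "",
) -> AssociationResult:
    """Score test with conditioning-variant dosages appended as covariates.

    Conditioning columns collinear with the existing design are dropped
    with a warning.  The unconditional p value is reported alongside.
    """
    base = impairment_association_test(scores, y, X, trait_type, gene, trait)
    cond = np.atleast_2d(np.asarray(conditioning, dtype=float))
    if cond.shape[0] != len(y) and cond.shape[1] == len(y):
        cond = cond.T
    if cond.size == 0:
        base.p_conditional = base.p_value
        return base
    Xc = X.copy()
    for k in range(cond.shape[1]):
        cand = np.column_stack([Xc, cond[:, k]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            Xc = cand
        else:
            logger.warning("conditioning column %d collinear with covariates for "
                           "%s/%s; dropped", k, gene, trait)
    res = impairment_association_test(scores, y, Xc, trait_type, gene, trait)
    base.p_conditional = res.p_value
    return base


# ---------------------------------------------------------------------------
# pseudodosage export
# ---------------------------------------------------------------------------


def pseudodosage(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """d = 2 psi and genotype probabilities (hom-alt, het, hom-ref) =
    (psi, 0, 1 - psi)."""
    s = np.asarray(scores, dtype=float)
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise DataError("impairment scores must lie in [0, 1]")
    probs = np.stack([s, np.zeros_like(s), 1.0 - s], axis=-1)
    return 2.0 * s, probs


def export_pseudodosage(score_df: pd.DataFrame, path: str,
                        fmt: str = "bgen", bits: int = 16) -> None:
    """Write one pseudovariant per gene in BGEN v1.2 or the TSV dialect
    (individual, gene, dosage)."""
    dosage, probs = pseudodosage(score_df.to_numpy(dtype=float))
    if fmt == "bgen":
        from .bgen import write_bgen

        write_bgen(path, probs, list(score_df.columns),
                   [str(i) for i in score_df.index], bits=bits)
    elif fmt == "tsv":
        long = score_df.reset_index().melt(id_vars=score_df.index.name or "index",
                                           var_name="gene", value_name="score")
        long["dosage"] = 2.0 * long["score"]
        long.drop(columns="score").to_csv(path, sep="\t", index=False)
    else:
        raise DataError(f"unknown pseudodosage format {fmt!r}")
    logger.info("exported %d genes x %d individuals as pseudodosage (%s)",
                score_df.shape[1], score_df.shape[0], fmt)


def import_pseudodosage(path: str, fmt: str = "bgen") -> pd.DataFrame:
    """Read pseudodosages back to an (individuals x genes) score frame."""
    if fmt == "bgen":
        from .bgen import read_bgen

        probs, genes, samples = read_bgen(path)
        scores = probs[:, :, 0]  # hom-alt probability == psi
        return pd.DataFrame(scores, index=pd.Index(samples, name="individual"),
                            columns=genes)
    if fmt == "tsv":
        long = pd.read_csv(path, sep="\t")
        idcol = long.columns[0]
        wide = long.pivot(index=idcol, columns="gene", values="dosage") / 2.0
        wide.index.name = "individual"
        return wide
    raise DataError(f"unknown pseudodosage format {fmt!r}")


# ---------------------------------------------------------------------------
# calibration diagnostics
# ---------------------------------------------------------------------------


def genomic_inflation(p_values: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic-control lambda and a Q-Q table.

    lambda = median of the chi-square(1) quantiles of the observed p
    values divided by the median of chi-square(1); the table pairs expected
    against observed -log10 p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise DataError("need at least 100 p values for inflation estimates")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise DataError("p values must lie in [0, 1]")
    p = np.clip(p, 1e-300, 1.0)
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    order = np.sort(p)
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    qq = pd.DataFrame({"expected_neglog10": -np.log10(expected),
                       "observed_neglog10": -np.log10(order)})
    return lam, qq
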