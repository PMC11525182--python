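"""Reproducible desk-scale study pipelines.

Each function runs one complete experiment — simulation, seed-gene
discovery, ensemble training, scoring, testing, metric computation — at a
problem size chosen for a single CPU, and returns its summary quantities.
The experiment designs (cohort sizes, trait structure, effect strengths,
fold counts) are fixed here so the same studies can be re-run from the
test suite, the acceptance script and the command line with nothing but a
seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import kstest, spearmanr

from .association import associate_all_genes, genomic_inflation
from .data import quantile_transform_phenotype
from .ensemble import (
    audit_no_leakage,
    make_folds,
    score_leaky,
    score_out_of_fold,
    train_cv_ensemble,
)
from .model import TrainingConfig
from .prediction import (
    _design,
    alternative_burdens,
    enrichment_by_deviation,
    extreme_phenotype_labels,
    fit_phenotype_predictor,
    r_squared,
    relative_improvement,
)
from .seedgenes import (
    burden_score_test,
    discover_seed_genes,
    fit_null_linear,
    run_burden_skat_combined,
)
from .synthetic import (
    SimulationConfig,
    TraitConfig,
    simulate_cohort,
    simulate_prs,
    true_impairment_matrix,
)

logger = logging.getLogger("setrvat")


def _sub_seed(seed: int, offset: int) -> int:
    return int((seed * 7919 + offset * 104729) % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# end-to-end null calibration
# ---------------------------------------------------------------------------


def null_calibration_experiment(seed: int = 11) -> dict:
    """Full pipeline on a cohort whose tested traits are pure noise.

    Three quantitative training traits carry real seed-gene effects; twelve
    additional traits are pure null.  Seed genes are discovered with the
    burden/SKAT combined method, the impairment ensemble is trained (K=2,
    one restart), every individual is scored out of fold, and all
    EAF-passing genes are tested against every null trait.  Reports the
    empirical type-I error at alpha = 0.05, Kolmogorov-Smirnov uniformity,
    genomic-control lambda, and the seed counts discovery reports for a
    sample of the null traits (expected ~0 under FWER control).
    """
    n_train_traits, n_null_traits = 3, 12
    traits = tuple(
        TraitConfig(name=f"train{k}", seed_genes=tuple(range(10 * k, 10 * k + 10)),
                    variance_fraction=0.4)
        for k in range(n_train_traits)
    ) + tuple(
        TraitConfig(name=f"null{k}", covariate_effect_sd=0.0)
        for k in range(n_null_traits)
    )
    cfg = SimulationConfig(n_individuals=4000, n_genes=200, traits=traits,
                           rng_seed=_sub_seed(seed, 0))
    dataset, truth = simulate_cohort(cfg)
    assignment = truth.assignment

    seeds = {}
    for k in range(n_train_traits):
        disc = discover_seed_genes(dataset, f"train{k}", assignment)
        found = sorted(disc.loc[disc["seed"], "gene"])
        if found:
            seeds[f"train{k}"] = found
    null_seed_counts = []
    for k in range(4):  # FWER check on a sample of the null traits
        disc = discover_seed_genes(dataset, f"null{k}", assignment)
        null_seed_counts.append(int(disc["seed"].sum()))

    plan = make_folds(cfg.n_individuals, K=2, R=1, rng_seed=_sub_seed(seed, 1))
    tcfg = TrainingConfig(rng_seed=_sub_seed(seed, 2))
    ensemble = train_cv_ensemble(dataset, seeds, assignment, tcfg, plan)
    scores = score_out_of_fold(ensemble, dataset, assignment)

    pvals = []
    for k in range(n_null_traits):
        tab = associate_all_genes(dataset, scores, f"null{k}", assignment)
        pvals.append(tab["p_value"].to_numpy())
    pvals = np.concatenate(pvals)
    lam, _ = genomic_inflation(pvals)
    return {
        "n_tests": int(pvals.size),
        "type_i_error": float(np.mean(pvals < 0.05)),
        "ks_uniformity_p": float(kstest(pvals, "uniform").pvalue),
        "lambda_gc": float(lam),
        "null_trait_seed_counts": null_seed_counts,
        "audit_ok": bool(audit_no_leakage(ensemble)),
        "p_values": pvals,
    }


# ---------------------------------------------------------------------------
# leaky-pipeline contrast
# ---------------------------------------------------------------------------


def leaky_pipeline_experiment(seed: int = 31) -> dict:
    """Why the leakage controls exist: a deliberately leaky pipeline
    variant versus the proper one, on the same cohort.

    Leaky variant: null-trait "seed genes" are picked at a nominal
    (uncorrected) threshold on the full cohort, enter training, and
    exactly those genes are re-tested on the same cohort with in-fold
    scores — the selection makes the retest anti-conservative
    (lambda >> 1).  Proper variant: FWER-controlled discovery (which
    selects nothing on null traits) and out-of-fold scoring over all
    genes stays calibrated (lambda ~ 1).
    """
    train_traits = tuple(
        TraitConfig(name=f"train{k}", seed_genes=tuple(range(10 * k, 10 * k + 10)),
                    variance_fraction=0.4) for k in range(2))
    null_traits = tuple(TraitConfig(name=f"null{k}", covariate_effect_sd=0.0)
                        for k in range(10))
    cfg = SimulationConfig(n_individuals=2000, n_genes=100,
                           traits=train_traits + null_traits,
                           rng_seed=_sub_seed(seed, 0))
    dataset, truth = simulate_cohort(cfg)
    assignment = truth.assignment

    selected = {}
    for k in range(10):
        tab = run_burden_skat_combined(dataset, f"null{k}", assignment,
                                       apply_eaf=False)
        picked = tab.loc[tab["p_combined"] < 0.25, "gene"].tolist()
        if picked:
            selected[f"null{k}"] = picked
    seeds = {}
    for k in range(2):
        disc = discover_seed_genes(dataset, f"train{k}", assignment)
        found = sorted(disc.loc[disc["seed"], "gene"])
        if found:
            seeds[f"train{k}"] = found
    seeds |= selected

    plan = make_folds(cfg.n_individuals, K=2, R=1, rng_seed=_sub_seed(seed, 1))
    tcfg = TrainingConfig(rng_seed=_sub_seed(seed, 2))
    ensemble = train_cv_ensemble(dataset, seeds, assignment, tcfg, plan)
    clean_scores = score_out_of_fold(ensemble, dataset, assignment)
    leaky_scores = score_leaky(ensemble, dataset, assignment)

    p_leaky, p_clean = [], []
    for trait, genes in selected.items():
        tab = associate_all_genes(dataset, leaky_scores[genes], trait,
                                  assignment, apply_eaf=False)
        p_leaky.append(tab["p_value"].to_numpy())
    for k in range(10):
        tab = associate_all_genes(dataset, clean_scores, f"null{k}", assignment,
                                  apply_eaf=False)
        p_clean.append(tab["p_value"].to_numpy())
    p_leaky = np.concatenate(p_leaky)
    p_clean = np.concatenate(p_clean)
    lam_leaky, _ = genomic_inflation(p_leaky)
    lam_clean, _ = genomic_inflation(p_clean)
    return {
        "lambda_leaky": float(lam_leaky),
        "lambda_clean": float(lam_clean),
        "n_selected_gene_trait_pairs": int(p_leaky.size),
        "audit_ok": bool(audit_no_leakage(ensemble)),
    }


# ---------------------------------------------------------------------------
# parameter recovery with linear ground truth
# ---------------------------------------------------------------------------


def linear_recovery_experiment(seed: int = 3) -> dict:
    """Does the learned score recover the true impairment?

    Linear ground truth, two traits with ten known seed genes each; the
    module is trained on the true seed genes and every individual is
    scored out of fold (so each score comes from a model that never saw
    that individual).  Reports the Spearman correlation between psi and
    the true u over carrier pairs, against the best single annotation.
    """
    traits = tuple(
        TraitConfig(name=f"t{k}", seed_genes=tuple(range(10 * k, 10 * k + 10)),
                    variance_fraction=0.4) for k in range(2))
    cfg = SimulationConfig(n_individuals=6000, n_genes=40, traits=traits,
                           rng_seed=_sub_seed(seed, 0))
    dataset, truth = simulate_cohort(cfg)
    assignment = truth.assignment
    seeds = {t: sorted(truth.seed_genes[t]) for t in ("t0", "t1")}

    plan = make_folds(cfg.n_individuals, K=2, R=1, rng_seed=_sub_seed(seed, 1))
    tcfg = TrainingConfig(rng_seed=_sub_seed(seed, 2))
    ensemble = train_cv_ensemble(dataset, seeds, assignment, tcfg, plan)
    scores = score_out_of_fold(ensemble, dataset, assignment,
                               maf_cutoff=tcfg.maf_cutoff)

    genes = list(dataset.gene_ids)
    U = true_impairment_matrix(dataset.genotypes, assignment, truth.u_variant,
                               np.array(genes))
    S = scores[genes].to_numpy()
    carriers = S > 0
    rho_psi = float(spearmanr(S[carriers], U[carriers]).statistic)
    per_annotation = {}
    for col in dataset.annotation_cols:
        B = alternative_burdens(dataset, assignment, col, genes,
                                maf_cutoff=tcfg.maf_cutoff)
        r = spearmanr(B.to_numpy()[carriers], U[carriers]).statistic
        per_annotation[col] = float(abs(r))
    return {
        "spearman_psi_truth": rho_psi,
        "per_annotation_spearman": per_annotation,
        "best_single_annotation": max(per_annotation.values()),
        "dataset": dataset,
        "truth": truth,
        "ensemble": ensemble,
        "scores": scores,
    }


# ---------------------------------------------------------------------------
# interaction truth: power ordering and nonlinearity ablation
# ---------------------------------------------------------------------------


def interaction_power_experiment(seed: int = 13, with_ablation: bool = True) -> dict:
    """Power comparison when only an annotation interaction drives
    impairment.

    Per-variant impact depends solely on the product of two annotations,
    so no single annotation is individually sufficient.  Seed genes are
    discovered with the burden/SKAT combined method, the ensemble (K=2,
    two restarts) is trained on them, and true-seed-gene recovery at
    FWER 0.05 is compared across (a) learned-score testing, (b) every
    single-annotation max-burden arm, and (c) burden/SKAT combined.  A
    linear-activation ablation of the module quantifies how much of the
    learned score's accuracy requires the nonlinearity.
    """
    traits = tuple(
        TraitConfig(name=f"t{k}", seed_genes=tuple(range(12 * k, 12 * k + 12)),
                    variance_fraction=0.5) for k in range(3))
    cfg = SimulationConfig(n_individuals=8000, n_genes=60,
                           impairment_form="interaction", traits=traits,
                           rng_seed=_sub_seed(seed, 0))
    dataset, truth = simulate_cohort(cfg)
    assignment = truth.assignment
    trait_names = [t.name for t in traits]

    seeds, burden_skat_found = {}, 0
    for t in trait_names:
        disc = discover_seed_genes(dataset, t, assignment)
        found = sorted(disc.loc[disc["seed"], "gene"])
        if found:
            seeds[t] = found
        burden_skat_found += len(set(found) & set(truth.seed_genes[t]))

    plan = make_folds(cfg.n_individuals, K=2, R=2, rng_seed=_sub_seed(seed, 1))
    tcfg = TrainingConfig(rng_seed=_sub_seed(seed, 2))
    ensemble = train_cv_ensemble(dataset, seeds, assignment, tcfg, plan)
    scores = score_out_of_fold(ensemble, dataset, assignment)

    learned_found = 0
    tested_genes = None
    for t in trait_names:
        tab = associate_all_genes(dataset, scores, t, assignment)
        learned_found += len(set(tab.loc[tab["significant"], "gene"])
                             & set(truth.seed_genes[t]))
        tested_genes = list(tab["gene"])

    # single-annotation arms at the same FWER
    arm_found = {}
    burdens = {c: alternative_burdens(dataset, assignment, c, tested_genes)
               for c in dataset.annotation_cols}
    X = np.column_stack([np.ones(cfg.n_individuals),
                         dataset.covariates.to_numpy(float)])
    for t in trait_names:
        y = quantile_transform_phenotype(dataset.phenotypes[t].to_numpy(float))
        null = fit_null_linear(y, X)
        true_set = set(truth.seed_genes[t])
        for c, B in burdens.items():
            ps = np.array([
                1.0 if np.allclose(B[g], B[g].iloc[0])
                else burden_score_test(B[g].to_numpy(), null).p_value
                for g in tested_genes])
            sig = set(np.asarray(tested_genes)[ps * len(tested_genes) < 0.05])
            arm_found[c] = arm_found.get(c, 0) + len(sig & true_set)

    out = {
        "n_true_seed_gene_trait_pairs": sum(len(truth.seed_genes[t])
                                            for t in trait_names),
        "learned_score_found": int(learned_found),
        "burden_skat_combined_found": int(burden_skat_found),
        "per_annotation_found": arm_found,
        "best_single_annotation_found": int(max(arm_found.values())),
    }

    genes = np.array(tested_genes)
    U = true_impairment_matrix(dataset.genotypes, assignment, truth.u_variant,
                               genes)
    S = scores[list(genes)].to_numpy()
    carriers = S > 0
    out["spearman_full_model"] = float(spearmanr(S[carriers], U[carriers]).statistic)
    if with_ablation:
        abl = train_cv_ensemble(dataset, seeds, assignment, tcfg, plan,
                                linear=True)
        S2 = score_out_of_fold(abl, dataset, assignment)[list(genes)].to_numpy()
        c2 = S2 > 0
        out["spearman_linear_ablation"] = float(
            spearmanr(S2[c2], U[c2]).statistic)
    return out


# ---------------------------------------------------------------------------
# phenotype prediction with rare-variant augmentation
# ---------------------------------------------------------------------------


def prediction_experiment(seed: int = 7) -> dict:
    """PRS-only vs rare-augmented prediction on held-out individuals.

    One linear-truth trait with three concentrated seed genes carrying 60%
    of the genetic-plus-noise variance — the regime of traits whose
    extreme values are genuinely rare-variant-driven.  The cohort is
    split in half: seed discovery, ensemble training, gene selection (by
    learned-score association at FWER 0.05, as the prediction gene set is
    defined) and model fitting use only the training half; R^2, Relative
    Delta-R^2, and deviation-ranked extreme-phenotype enrichment (with a
    bootstrap significance for the area above the random baseline) are
    computed on the evaluation half.  The seed-gene effects are
    trait-increasing, so the rare-driven extremes sit in the upper tail
    and enrichment is assessed against the top-1% labels.
    """
    traits = (TraitConfig(name="t", seed_genes=(0, 1, 2),
                          variance_fraction=0.6),)
    cfg = SimulationConfig(n_individuals=10_000, n_genes=40, traits=traits,
                           rng_seed=_sub_seed(seed, 0))
    dataset, truth = simulate_cohort(cfg)
    assignment = truth.assignment
    rng = np.random.default_rng(_sub_seed(seed, 3))

    n = cfg.n_individuals
    perm = rng.permutation(n)
    train_idx, eval_idx = np.sort(perm[: n // 2]), np.sort(perm[n // 2:])

    # seed discovery and ensemble training strictly on the training half
    train_view, _ = _subset_dataset(dataset, train_idx)
    disc = discover_seed_genes(train_view, "t", assignment)
    seed_genes = sorted(disc.loc[disc["seed"], "gene"])
    if not seed_genes:
        raise RuntimeError("no seed genes on the training half")
    plan = make_folds(train_idx.size, K=2, R=1, rng_seed=_sub_seed(seed, 1))
    tcfg = TrainingConfig(rng_seed=_sub_seed(seed, 2))
    ensemble = train_cv_ensemble(train_view, {"t": seed_genes}, assignment,
                                 tcfg, plan)
    from .ensemble import score_external

    # the prediction gene set comes from learned-score association on the
    # training half (out-of-fold scores), at FWER 0.05
    oof_all = score_out_of_fold(ensemble, train_view, assignment)
    assoc = associate_all_genes(train_view, oof_all, "t", assignment)
    sig_genes = sorted(assoc.loc[assoc["significant"], "gene"])
    if not sig_genes:
        raise RuntimeError("no significant genes on the training half")
    scores_train = oof_all[sig_genes]
    eval_view, _ = _subset_dataset(dataset, eval_idx)
    scores_eval = score_external(ensemble, eval_view, assignment,
                                 genes=sig_genes)

    y_all = quantile_transform_phenotype(dataset.phenotypes["t"].to_numpy(float))
    prs_all = simulate_prs(y_all, 0.3, rng)
    X_all = dataset.covariates.to_numpy(float)

    y_tr, y_ev = y_all[train_idx], y_all[eval_idx]
    X_tr, X_ev = X_all[train_idx], X_all[eval_idx]
    prs_tr, prs_ev = prs_all[train_idx], prs_all[eval_idx]
    b_tr = scores_train[sig_genes].to_numpy()
    b_ev = scores_eval[sig_genes].to_numpy()

    base = fit_phenotype_predictor(y_tr, X_tr, prs_tr, trait="t")
    rare = fit_phenotype_predictor(y_tr, X_tr, prs_tr, b_tr,
                                   gene_set=sig_genes, trait="t")
    pred_base = base.predict(_design(X_ev, prs_ev, None))
    pred_rare = rare.predict(_design(X_ev, prs_ev, b_ev))
    r2_base = r_squared(y_ev, pred_base)
    r2_rare = r_squared(y_ev, pred_rare)

    labels = extreme_phenotype_labels(y_ev, "top", 1.0)
    curve = enrichment_by_deviation(pred_base, pred_rare, labels)
    area = curve.area_above_baseline()
    boot = np.empty(1000)
    dev = np.abs(pred_rare - pred_base)
    order = np.argsort(-dev, kind="stable")
    ranked_labels = labels[order]
    ranks = np.arange(1, labels.size + 1)
    for b in range(1000):
        resampled = rng.permutation(ranked_labels)
        boot[b] = np.mean(np.cumsum(resampled) - ranks * labels.mean())
    boot_p = float(np.mean(boot >= area))

    return {
        "n_significant_genes": len(sig_genes),
        "r2_prs_only": float(r2_base),
        "r2_rare_augmented": float(r2_rare),
        "relative_delta_r2": float(relative_improvement(r2_rare, r2_base)),
        "enrichment_area_above_baseline": float(area),
        "enrichment_bootstrap_p": boot_p,
    }


def _subset_dataset(dataset, idx):
    """A view of the cohort restricted to the given individuals."""
    from .data import CohortDataset, SparseGenotypes

    geno = SparseGenotypes(
        matrix=dataset.genotypes.matrix[idx],
        maf=dataset.genotypes.maf,
        individual_ids=dataset.genotypes.individual_ids[idx],
    )
    sub = CohortDataset(
        genotypes=geno,
        variants=dataset.variants,
        annotation_cols=dataset.annotation_cols,
        exons=dataset.exons,
        covariates=dataset.covariates.iloc[idx],
        phenotypes=dataset.phenotypes.iloc[idx],
        binary_traits=dataset.binary_traits,
    )
    return sub, idx
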