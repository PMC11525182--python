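"""The gene impairment module: a permutation-invariant set network trained
end-to-end by multitask regression on seed genes.

Architecture: each variant's annotation vector x_k is embedded by a
two-layer MLP phi of width 20; the gene embedding is the element-wise
maximum over the variant set; a second MLP rho (two hidden layers of
width 10, linear output) reads out a scalar that a logistic squashing maps
to the impairment score psi in (0, 1).  Activations are leaky rectifiers
with negative slope 0.01.  The empty variant set is scored exactly 0.

Per-trait phenotype heads are linear: y-hat = x' alpha + sum_{j in seeds}
w_j psi(V_ij).  The whole model is optimised jointly with AdamW on the
per-trait mean squared error averaged across traits, with early stopping
on a 20% per-trait validation split of individuals.

The network and its gradients are implemented directly in NumPy; the
backward pass is validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    CADD_CUTOFF,
    CohortDataset,
    DataError,
    MAF_CUTOFF_TRAINING,
    filter_qualifying_variants,
    quantile_transform_phenotype,
)

logger = logging.getLogger("setrvat")

_LEAK = 0.01
_PHI_WIDTH = 20
_RHO_WIDTH = 10
_CHECKPOINT_VERSION = 1


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 1024
    min_epochs: int = 50
    max_epochs: int = 1000
    patience: int = 10
    val_fraction: float = 0.2
    weight_decay: float = 0.01
    maf_cutoff: float = MAF_CUTOFF_TRAINING
    cadd_cutoff: float = CADD_CUTOFF
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise DataError("validation fraction must lie in (0, 1)")
        if self.min_epochs > self.max_epochs:
            raise DataError("min_epochs must not exceed max_epochs")


@dataclass
class PhenotypeHead:
    """Per-trait linear head: covariate coefficients and seed-gene weights."""

    trait: str
    alpha: np.ndarray  # length q (intercept first)
    genes: list[str]
    w: np.ndarray  # length len(genes)


def _lrelu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, _LEAK * x)


def _lrelu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, _LEAK)


class ImpairmentModule:
    """The deep-set scorer psi = sigmoid(rho(max_k phi(x_k))).

    ``linear=True`` replaces the leaky-rectifier activations by the
    identity in both phi and rho (the ablation used to probe whether the
    nonlinearity is needed); the max pooling and sigmoid are kept.
    """

    def __init__(self, n_annotations: int, annotation_cols: list[str] | None = None,
                 rng_seed: int = 0, linear: bool = False):
        self.d = int(n_annotations)
        self.annotation_cols = list(annotation_cols) if annotation_cols else None
        self.linear = bool(linear)
        rng = np.random.default_rng(rng_seed)
        shapes = self._layer_shapes(self.d)
        self.params: dict[str, np.ndarray] = {}
        for name, shape in shapes.items():
            if name.endswith("_b"):
                self.params[name] = np.zeros(shape)
            else:
                fan_in = shape[0]
                self.params[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        # annotation standardisation (fit at training time, reused at scoring)
        self.ann_mean = np.zeros(self.d)
        self.ann_std = np.ones(self.d)

    @staticmethod
    def _layer_shapes(d: int) -> dict[str, tuple]:
        return {
            "phi1_W": (d, _PHI_WIDTH), "phi1_b": (_PHI_WIDTH,),
            "phi2_W": (_PHI_WIDTH, _PHI_WIDTH), "phi2_b": (_PHI_WIDTH,),
            "rho1_W": (_PHI_WIDTH, _RHO_WIDTH), "rho1_b": (_RHO_WIDTH,),
            "rho2_W": (_RHO_WIDTH, _RHO_WIDTH), "rho2_b": (_RHO_WIDTH,),
            "rho3_W": (_RHO_WIDTH, 1), "rho3_b": (1,),
        }

    def set_standardization(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.ann_mean = np.asarray(mean, dtype=float)
        self.ann_std = np.where(np.asarray(std, dtype=float) > 0, std, 1.0)

    def _act(self, x: np.ndarray) -> np.ndarray:
        return x if self.linear else _lrelu(x)

    def _act_grad(self, x: np.ndarray) -> np.ndarray:
        return np.ones_like(x) if self.linear else _lrelu_grad(x)

    # -- forward / backward over a padded batch of sets -------------------

    def forward_sets(self, A: np.ndarray, mask: np.ndarray,
                     standardized: bool = False):
        """psi for a padded batch of nonempty variant sets.

        ``A`` is (n_sets, max_size, d); ``mask`` (n_sets, max_size) marks
        real members.  Padding never influences the result: padded rows
        are excluded from the max.  Returns (psi, cache).
        """
        p = self.params
        if not standardized:
            A = (A - self.ann_mean) / self.ann_std
        z1 = A @ p["phi1_W"] + p["phi1_b"]
        h1 = self._act(z1)
        z2 = h1 @ p["phi2_W"] + p["phi2_b"]
        h2 = self._act(z2)
        masked = np.where(mask[:, :, None], h2, -np.inf)
        arg = np.argmax(masked, axis=1)  # (n_sets, width)
        M = np.take_along_axis(masked, arg[:, None, :], axis=1)[:, 0, :]
        z3 = M @ p["rho1_W"] + p["rho1_b"]
        r1 = self._act(z3)
        z4 = r1 @ p["rho2_W"] + p["rho2_b"]
        r2 = self._act(z4)
        z5 = (r2 @ p["rho3_W"] + p["rho3_b"])[:, 0]
        psi = 1.0 / (1.0 + np.exp(-z5))
        cache = (A, mask, z1, h1, z2, h2, arg, M, z3, r1, z4, r2, psi)
        return psi, cache

    def backward_sets(self, dpsi: np.ndarray, cache,
                      grads: dict[str, np.ndarray]) -> None:
        """Accumulate parameter gradients for d(loss)/d(psi) = ``dpsi``."""
        p = self.params
        A, mask, z1, h1, z2, h2, arg, M, z3, r1, z4, r2, psi = cache
        dz5 = dpsi * psi * (1.0 - psi)
        grads["rho3_W"] += r2.T @ dz5[:, None]
        grads["rho3_b"] += dz5.sum(keepdims=True)
        dr2 = dz5[:, None] @ p["rho3_W"].T
        dz4 = dr2 * self._act_grad(z4)
        grads["rho2_W"] += r1.T @ dz4
        grads["rho2_b"] += dz4.sum(axis=0)
        dr1 = dz4 @ p["rho2_W"].T
        dz3 = dr1 * self._act_grad(z3)
        grads["rho1_W"] += M.T @ dz3
        grads["rho1_b"] += dz3.sum(axis=0)
        dM = dz3 @ p["rho1_W"].T  # (n_sets, phi_width)
        # route through the max: gradient flows to the argmax member only
        dh2 = np.zeros_like(h2)
        np.put_along_axis(dh2, arg[:, None, :], dM[:, None, :], axis=1)
        dz2 = dh2 * self._act_grad(z2) * mask[:, :, None]
        grads["phi2_W"] += np.einsum("psi,psj->ij", h1, dz2)
        grads["phi2_b"] += dz2.sum(axis=(0, 1))
        dh1 = dz2 @ p["phi2_W"].T
        dz1 = dh1 * self._act_grad(z1) * mask[:, :, None]
        grads["phi1_W"] += np.einsum("psi,psj->ij", A, dz1)
        grads["phi1_b"] += dz1.sum(axis=(0, 1))

    # -- public scoring ----------------------------------------------------

    def score_gene(self, annotations: np.ndarray) -> float:
        """psi for one variant set given as a (k, d) annotation array;
        the empty set scores exactly 0."""
        arr = np.asarray(annotations, dtype=float)
        if arr.size == 0:
            return 0.0
        if arr.ndim != 2 or arr.shape[1] != self.d:
            raise DataError(f"annotation dimension {arr.shape} != (*, {self.d})")
        psi, _ = self.forward_sets(arr[None, :, :], np.ones((1, arr.shape[0]), bool))
        return float(psi[0])

    # -- checkpointing ------------------------------------------------------

    def save(self, directory: str, extra: dict | None = None) -> None:
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "version": _CHECKPOINT_VERSION,
            "n_annotations": self.d,
            "annotation_cols": self.annotation_cols,
            "linear": self.linear,
            "layer_shapes": {k: list(v.shape) for k, v in self.params.items()},
        }
        if extra:
            manifest.update(extra)
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        np.savez(os.path.join(directory, "weights.npz"),
                 ann_mean=self.ann_mean, ann_std=self.ann_std, **self.params)

    @classmethod
    def load(cls, directory: str) -> "ImpairmentModule":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        if manifest["version"] != _CHECKPOINT_VERSION:
            raise DataError("unsupported checkpoint version")
        mod = cls(manifest["n_annotations"], manifest.get("annotation_cols"),
                  linear=manifest.get("linear", False))
        with np.load(os.path.join(directory, "weights.npz")) as z:
            for k in mod.params:
                mod.params[k] = z[k]
            mod.ann_mean, mod.ann_std = z["ann_mean"], z["ann_std"]
        return mod

    def check_schema(self, annotation_cols: list[str]) -> None:
        """Refuse to score a cohort whose annotation columns differ."""
        if self.annotation_cols is None:
            return
        if list(annotation_cols) != self.annotation_cols:
            missing = set(self.annotation_cols) - set(annotation_cols)
            extra = set(annotation_cols) - set(self.annotation_cols)
            raise DataError(
                f"annotation schema mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}")


def forward_predict(module: ImpairmentModule, head: PhenotypeHead,
                    x: np.ndarray, variant_sets: dict[str, np.ndarray]) -> float:
    """y-hat for one individual and trait: x' alpha + sum_j w_j psi(V_ij).

    ``variant_sets`` maps gene id -> (k, d) annotation array for the genes
    the individual carries qualifying variants in; genes absent from the
    mapping (or outside the head's seed set) contribute nothing.
    """
    x = np.asarray(x, dtype=float)
    if x.size != head.alpha.size:
        raise DataError("covariate vector does not match head coefficients")
    yhat = float(x @ head.alpha)
    for gene, w in zip(head.genes, head.w):
        sets = variant_sets.get(gene)
        if sets is not None and np.asarray(sets).size:
            yhat += float(w) * module.score_gene(sets)
    return yhat


def multitask_loss(predictions: dict[str, np.ndarray],
                   targets: dict[str, np.ndarray]) -> float:
    """Per-trait mean squared error averaged over the traits present."""
    losses = []
    for trait, pred in predictions.items():
        y = np.asarray(targets[trait], dtype=float)
        p = np.asarray(pred, dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() == 0:
            continue
        losses.append(float(np.mean((p[ok] - y[ok]) ** 2)))
    if not losses:
        raise DataError("no valid individual-trait pairs in batch")
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# training data layout
# ---------------------------------------------------------------------------


def _ragged_take(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate ranges [starts_i, starts_i + counts_i) without a loop."""
    total = int(counts.sum())
    if total == 0:
        return np.array([], dtype=int)
    cum = np.cumsum(counts)
    offsets = np.repeat(starts - np.concatenate([[0], cum[:-1]]), counts)
    return offsets + np.arange(total)


@dataclass
class _TraitData:
    trait: str
    y: np.ndarray  # quantile-transformed, NaN removed upstream
    valid: np.ndarray  # indices of individuals with observed y
    genes: list[str]
    # pairs sorted by individual: carrier (individual, gene-slot) pairs
    pair_ind: np.ndarray
    pair_gene: np.ndarray
    ind_ptr: np.ndarray  # per-individual slice into the pair arrays (len n+1)
    set_offsets: np.ndarray  # per-pair slice into flat_rows (len n_pairs+1)
    flat_rows: np.ndarray  # variant-table rows of carried qualifying variants


@dataclass
class TrainingData:
    """Packed carrier-pair representation of a cohort for fast epochs."""

    X: np.ndarray  # standardized covariates with intercept, (n, q)
    A: np.ndarray  # standardized annotation matrix, (n_variants, d)
    ann_mean: np.ndarray
    ann_std: np.ndarray
    traits: list[_TraitData]
    n_individuals: int
    cov_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cov_std: np.ndarray = field(default_factory=lambda: np.zeros(0))


def build_training_data(
    dataset: CohortDataset, seed_genes: dict[str, list[str]],
    assignment: pd.DataFrame, config: TrainingConfig,
    individuals: np.ndarray | None = None,
) -> TrainingData:
    """Lay the cohort out as per-trait carrier pairs with packed variant sets.

    ``individuals`` restricts to a subset (positional indices) — used by the
    cross-validation driver; covariate/annotation standardisation is fit on
    that subset.
    """
    n_all = dataset.genotypes.n_individuals
    if individuals is None:
        individuals = np.arange(n_all)
    individuals = np.asarray(individuals)
    n = individuals.size

    cov = dataset.covariates.to_numpy(dtype=float)[individuals]
    cov_mean, cov_std = cov.mean(axis=0), cov.std(axis=0)
    cov_std = np.where(cov_std > 0, cov_std, 1.0)
    X = np.column_stack([np.ones(n), (cov - cov_mean) / cov_std])

    Araw = dataset.annotation_matrix()
    ann_mean, ann_std = Araw.mean(axis=0), Araw.std(axis=0)
    ann_std = np.where(ann_std > 0, ann_std, 1.0)
    A = (Araw - ann_mean) / ann_std

    qual = filter_qualifying_variants(dataset.variants, config.maf_cutoff,
                                      config.cadd_cutoff)
    qual_mask = np.zeros(len(dataset.variants), dtype=bool)
    qual_mask[qual] = True
    csc = dataset.genotypes.matrix.tocsc()
    by_gene = assignment.groupby("gene_id")["variant_row"]

    # map full-cohort row -> local position
    local = -np.ones(n_all, dtype=int)
    local[individuals] = np.arange(n)

    traits: list[_TraitData] = []
    for trait, genes in seed_genes.items():
        if not genes:
            continue
        y_raw = dataset.phenotypes[trait].to_numpy(dtype=float)[individuals]
        obs = ~np.isnan(y_raw)
        y = np.full(n, np.nan)
        y[obs] = quantile_transform_phenotype(y_raw[obs])
        p_ind, p_gene, sets = [], [], []
        for slot, gene in enumerate(genes):
            if gene not in by_gene.groups:
                continue
            rows = by_gene.get_group(gene).to_numpy()
            rows = rows[qual_mask[rows]]
            if rows.size == 0:
                continue
            sub = csc[:, rows].tocsr()[individuals]
            counts = np.diff(sub.indptr)
            carriers = np.flatnonzero(counts)
            for i in carriers:
                p_ind.append(i)
                p_gene.append(slot)
                sets.append(rows[sub.indices[sub.indptr[i]:sub.indptr[i + 1]]])
        if p_ind:
            order = np.argsort(np.asarray(p_ind), kind="stable")
            p_ind = np.asarray(p_ind)[order]
            p_gene = np.asarray(p_gene)[order]
            sets = [sets[k] for k in order]
            set_lens = np.array([len(s) for s in sets])
            set_offsets = np.concatenate([[0], np.cumsum(set_lens)])
            flat_rows = np.concatenate(sets) if sets else np.array([], dtype=int)
            ind_ptr = np.searchsorted(p_ind, np.arange(n + 1))
        else:
            p_ind = np.array([], dtype=int)
            p_gene = np.array([], dtype=int)
            set_offsets = np.array([0])
            flat_rows = np.array([], dtype=int)
            ind_ptr = np.zeros(n + 1, dtype=int)
        traits.append(_TraitData(
            trait=trait, y=y, valid=np.flatnonzero(obs), genes=list(genes),
            pair_ind=p_ind, pair_gene=p_gene, ind_ptr=ind_ptr,
            set_offsets=set_offsets, flat_rows=flat_rows,
        ))
    if not traits:
        raise DataError("no trait has any seed gene; nothing to train on")
    return TrainingData(X=X, A=A, ann_mean=ann_mean, ann_std=ann_std,
                        traits=traits, n_individuals=n,
                        cov_mean=cov_mean, cov_std=cov_std)


def _gather_pairs(td: _TraitData, batch_ind: np.ndarray):
    """Carrier pairs whose individual lies in ``batch_ind``; returns
    (pair indices, local position of each pair's individual in the batch)."""
    counts = td.ind_ptr[batch_ind + 1] - td.ind_ptr[batch_ind]
    pair_idx = _ragged_take(td.ind_ptr[batch_ind], counts)
    local = np.repeat(np.arange(batch_ind.size), counts)
    return pair_idx, local


def _padded_sets(td: _TraitData, pair_idx: np.ndarray, A: np.ndarray):
    lens = td.set_offsets[pair_idx + 1] - td.set_offsets[pair_idx]
    S = int(lens.max())
    P = pair_idx.size
    idx = np.zeros((P, S), dtype=int)
    mask = np.arange(S)[None, :] < lens[:, None]
    flat = td.flat_rows[_ragged_take(td.set_offsets[pair_idx], lens)]
    idx[mask] = flat
    return A[idx], mask


# ---------------------------------------------------------------------------
# AdamW
# ---------------------------------------------------------------------------


class _AdamW:
    def __init__(self, params: dict[str, np.ndarray], lr: float, wd: float):
        self.lr, self.wd = lr, wd
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (
                (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
                + self.wd * params[k]
            )


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _epoch_loss(module: ImpairmentModule, heads: dict[str, PhenotypeHead],
                data: TrainingData, points: dict[str, np.ndarray]) -> float:
    """Mean-over-traits MSE on the given per-trait individual subsets."""
    losses = []
    for td in data.traits:
        sub = points[td.trait]
        if sub.size == 0:
            continue
        yhat = _predict_subset(module, heads[td.trait], data, td, sub)[0]
        losses.append(float(np.mean((yhat - td.y[sub]) ** 2)))
    return float(np.mean(losses)) if losses else np.nan


def _predict_subset(module, head, data: TrainingData, td: _TraitData,
                    sub: np.ndarray):
    yhat = data.X[sub] @ head.alpha
    pair_idx, local = _gather_pairs(td, sub)
    cache = psi = None
    if pair_idx.size:
        Ab, mask = _padded_sets(td, pair_idx, data.A)
        psi, cache = module.forward_sets(Ab, mask, standardized=True)
        np.add.at(yhat, local, head.w[td.pair_gene[pair_idx]] * psi)
    return yhat, pair_idx, local, psi, cache


def train_impairment_module(
    dataset: CohortDataset, seed_genes: dict[str, list[str]],
    assignment: pd.DataFrame, config: TrainingConfig | None = None,
    individuals: np.ndarray | None = None, linear: bool = False,
    data: TrainingData | None = None,
) -> tuple[ImpairmentModule, dict[str, PhenotypeHead], pd.DataFrame]:
    """End-to-end training of the impairment module and phenotype heads.

    Shuffles individual-phenotype pairs, holds out ``val_fraction`` of
    individuals per trait, optimises with AdamW, and returns the checkpoint
    with the lowest validation loss reached between ``min_epochs`` and
    ``max_epochs`` (stopping ``patience`` epochs after the last
    improvement), together with the loss trajectory.
    """
    config = config or TrainingConfig()
    if data is None:
        data = build_training_data(dataset, seed_genes, assignment, config,
                                   individuals)
    rng = np.random.default_rng(config.rng_seed)
    module = ImpairmentModule(data.A.shape[1], dataset.annotation_cols,
                              rng_seed=config.rng_seed, linear=linear)
    module.set_standardization(data.ann_mean, data.ann_std)

    q = data.X.shape[1]
    heads = {}
    for td in data.traits:
        heads[td.trait] = PhenotypeHead(
            trait=td.trait, alpha=np.zeros(q), genes=td.genes,
            w=rng.normal(0.0, 0.01, size=len(td.genes)))

    # per-trait train/validation split over individuals with observed y
    train_pts, val_pts = {}, {}
    for td in data.traits:
        perm = rng.permutation(td.valid)
        n_val = max(1, int(round(config.val_fraction * perm.size)))
        val_pts[td.trait] = np.sort(perm[:n_val])
        train_pts[td.trait] = np.sort(perm[n_val:])

    all_params = dict(module.params)
    head_keys = {}
    for t, h in heads.items():
        all_params[f"head_{t}_alpha"] = h.alpha
        all_params[f"head_{t}_w"] = h.w
        head_keys[t] = (f"head_{t}_alpha", f"head_{t}_w")
    opt = _AdamW(all_params, config.learning_rate, config.weight_decay)

    # flat list of (trait index, individual) training points
    flat_trait = np.concatenate([
        np.full(train_pts[td.trait].size, ti)
        for ti, td in enumerate(data.traits)])
    flat_ind = np.concatenate([train_pts[td.trait] for td in data.traits])

    history = []
    best = {"val": np.inf, "epoch": -1, "params": None}
    init_train = _epoch_loss(module, heads, data, train_pts)
    for epoch in range(config.max_epochs):
        order = rng.permutation(flat_ind.size)
        for start in range(0, order.size, config.batch_size):
            sel = order[start:start + config.batch_size]
            traits_here = np.unique(flat_trait[sel])
            grads = {k: np.zeros_like(v) for k, v in all_params.items()}
            n_traits = traits_here.size
            for ti in traits_here:
                td = data.traits[ti]
                sub = flat_ind[sel[flat_trait[sel] == ti]]
                yhat, pair_idx, local, psi, cache = _predict_subset(
                    module, heads[td.trait], data, td, sub)
                resid = yhat - td.y[sub]
                dyhat = 2.0 * resid / (resid.size * n_traits)
                ka, kw = head_keys[td.trait]
                grads[ka] += data.X[sub].T @ dyhat
                if pair_idx.size:
                    gslot = td.pair_gene[pair_idx]
                    np.add.at(grads[kw], gslot, psi * dyhat[local])
                    dpsi = heads[td.trait].w[gslot] * dyhat[local]
                    module.backward_sets(dpsi, cache, grads)
            opt.step(all_params, grads)
            for k in module.params:
                module.params[k] = all_params[k]
            for t, h in heads.items():
                h.alpha = all_params[head_keys[t][0]]
                h.w = all_params[head_keys[t][1]]
        train_loss = _epoch_loss(module, heads, data, train_pts)
        val_loss = _epoch_loss(module, heads, data, val_pts)
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (non-finite loss)")
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best["val"] - 1e-12:
            best = {"val": val_loss, "epoch": epoch,
                    "params": {k: v.copy() for k, v in all_params.items()}}
        if (epoch + 1 >= config.min_epochs
                and epoch - best["epoch"] >= config.patience):
            break
    if best["params"] is not None:
        for k in module.params:
            module.params[k] = best["params"][k]
        for t, h in heads.items():
            h.alpha = best["params"][head_keys[t][0]]
            h.w = best["params"][head_keys[t][1]]
    log = pd.DataFrame(history)
    log.attrs["initial_train_loss"] = init_train
    log.attrs["best_epoch"] = best["epoch"]
    logger.info("training stopped after %d epochs (best val %.4f at epoch %d)",
                len(history), best["val"], best["epoch"])
    return module, heads, log


# ---------------------------------------------------------------------------
# scoring a cohort
# ---------------------------------------------------------------------------


def score_matrix(
    module: ImpairmentModule, dataset: CohortDataset, assignment: pd.DataFrame,
    genes: np.ndarray | list[str] | None = None,
    maf_cutoff: float = 0.001, cadd_cutoff: float = CADD_CUTOFF,
    individuals: np.ndarray | None = None,
) -> pd.DataFrame:
    """(individuals x genes) impairment scores; non-carriers score 0."""
    module.check_schema(dataset.annotation_cols)
    if genes is None:
        genes = dataset.gene_ids
    if individuals is None:
        individuals = np.arange(dataset.genotypes.n_individuals)
    individuals = np.asarray(individuals)
    qual = filter_qualifying_variants(dataset.variants, maf_cutoff, cadd_cutoff)
    qual_mask = np.zeros(len(dataset.variants), dtype=bool)
    qual_mask[qual] = True
    A = (dataset.annotation_matrix() - module.ann_mean) / module.ann_std
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
        sub = csc[:, rows].tocsr()[individuals]
        counts = np.diff(sub.indptr)
        carriers = np.flatnonzero(counts)
        if carriers.size == 0:
            continue
        S = int(counts[carriers].max())
        idx = np.zeros((carriers.size, S), dtype=int)
        mask = np.arange(S)[None, :] < counts[carriers][:, None]
        flat = rows[sub.indices[_ragged_take(sub.indptr[carriers],
                                             counts[carriers])]]
        idx[mask] = flat
        psi, _ = module.forward_sets(A[idx], mask, standardized=True)
        out[carriers, g] = psi
    ids = dataset.genotypes.individual_ids[individuals]
    return pd.DataFrame(out, index=pd.Index(ids, name="individual"), columns=list(genes))
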