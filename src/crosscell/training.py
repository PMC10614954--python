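"""Training protocol: splits, early stopping, adversarial alternation,
hyperparameter grid search with LISI-based model selection.

A prediction experiment holds out an entire cell type or tissue in the
target species as the test set. Of the remaining cells, 10% (capped at
20,000) form the validation set; training halts once the validation
loss_cVAE has not reached a new minimum for 45 consecutive epochs
(patience), and the parameters from the best epoch are returned.

With the adversarial option enabled, each minibatch runs two steps: the
discriminator is updated on its cross-entropy, then the generator
(encoder + decoder) is updated on loss_cVAE - loss_dis with the
discriminator frozen.

The hyperparameter grid is {discriminator off/on} x {n_latent 25, 50,
100}; among the fitted candidates the one whose validation embeddings
give the largest mean species LISI (local inverse Simpson's index,
perplexity 30) is selected. LISI per cell is 1 / sum_l p_l^2 where p_l
are label probabilities under perplexity-calibrated Gaussian kernel
weights over the k = 3 x perplexity nearest neighbours; it ranges from
1 (fully separated) to the number of label levels (fully mixed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .autodiff import Adam, Tensor
from .io_filters import CountMatrix
from .model import CVAE, ModelConfig

logger = logging.getLogger("crosscell")


@dataclass
class TrainConfig:
    val_fraction: float = 0.1
    val_cap: int = 20000
    patience: int = 45
    max_epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 1e-3
    lisi_perplexity: float = 30.0
    seed: int = 0
    grid_n_latent: tuple[int, ...] = (25, 50, 100)
    grid_discriminator: tuple[bool, ...] = (False, True)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainedModel:
    model: CVAE
    config: TrainConfig
    best_epoch: int
    best_val_loss: float
    lisi_score: float
    history: pd.DataFrame   # per-epoch train/val losses

    def __post_init__(self):
        if len(self.history):
            assert np.isclose(self.best_val_loss, self.history["val_loss"].min())


# -- data split ----------------------------------------------------------


def split_train_val(cells: pd.DataFrame,
                    held_out_selector: dict[str, str] | None,
                    val_fraction: float = 0.1,
                    val_cap: int = 20000,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint (train, validation, test) index cover of all cells.

    ``held_out_selector`` maps metadata columns to values; matching
    cells form the test set (may be None/empty for prospective use).
    Validation is min(ceil(val_fraction * rest), val_cap) cells sampled
    without replacement from the non-test cells.
    """
    n = len(cells)
    test_mask = np.zeros(n, dtype=bool)
    if held_out_selector:
        test_mask = np.ones(n, dtype=bool)
        for col, val in held_out_selector.items():
            test_mask &= (cells[col].astype(str) == str(val)).to_numpy()
    if test_mask.all():
        raise ValueError("held-out selector matches every cell")
    rest = np.flatnonzero(~test_mask)
    rng = np.random.default_rng(seed)
    n_val = min(int(np.ceil(val_fraction * len(rest))), val_cap)
    val_idx = np.sort(rng.choice(rest, size=n_val, replace=False))
    train_idx = np.setdiff1d(rest, val_idx)
    return train_idx, val_idx, np.flatnonzero(test_mask)


# -- LISI ----------------------------------------------------------------


def _calibrated_weights(sq_dists: np.ndarray, perplexity: float,
                        tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Per-row Gaussian kernel weights with entropy = log(perplexity)."""
    n, k = sq_dists.shape
    target = np.log(perplexity)
    weights = np.empty_like(sq_dists)
    for i in range(n):
        d = sq_dists[i] - sq_dists[i].min()
        lo, hi, beta = 0.0, np.inf, 1.0
        for _ in range(max_iter):
            w = np.exp(-beta * d)
            s = w.sum()
            p = w / s
            h = -(p * np.log(np.maximum(p, 1e-300))).sum()
            if abs(h - target) < tol:
                break
            if h > target:       # too flat -> sharpen
                lo, beta = beta, beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
            else:
                hi, beta = beta, (lo + beta) / 2
        weights[i] = w / w.sum()
    return weights


def compute_lisi(embeddings: np.ndarray, labels, perplexity: float = 30.0,
                 k: int | None = None) -> np.ndarray:
    """Per-cell local inverse Simpson's index of label mixing."""
    emb = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    n = len(emb)
    if k is None:
        k = int(3 * perplexity)
    if k >= n:
        logger.warning("compute_lisi: reducing k from %d to %d (only %d cells)",
                       k, n - 1, n)
        k = n - 1
    perplexity = min(perplexity, k / 3.0) if k < 3 * perplexity else perplexity
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    dist, idx = dist[:, 1:], idx[:, 1:]   # drop self
    w = _calibrated_weights(dist**2, perplexity)
    codes = pd.factorize(labels)[0]
    n_lab = codes.max() + 1
    lisi = np.empty(n)
    for i in range(n):
        p = np.bincount(codes[idx[i]], weights=w[i], minlength=n_lab)
        lisi[i] = 1.0 / np.sum(p**2)
    return lisi


# -- optimisation --------------------------------------------------------


class EarlyStopper:
    """Stop when the monitored loss has not improved for `patience` epochs.

    ``update`` returns True when training should halt; ``best_epoch``
    always points at the minimum seen so far.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.since_best = 0

    def update(self, epoch: int, loss: float) -> bool:
        if loss < self.best:
            self.best, self.best_epoch, self.since_best = loss, epoch, 0
            return False
        self.since_best += 1
        return self.since_best >= self.patience


def _epoch_order(rng: np.random.Generator, n: int, batch_size: int):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def fit(model: CVAE, data: CountMatrix, cfg: TrainConfig,
        train_idx: np.ndarray, val_idx: np.ndarray) -> TrainedModel:
    """Train until the validation loss stops improving for `patience` epochs."""
    x_all = np.asarray(data.values.todense(), dtype=float).T  # cells x genes
    factors = model.factor_matrix(data.cells)
    species_levels = model.levels["species"]
    species_idx = np.array([species_levels.index(s)
                            for s in data.cells["species"].astype(str)])

    x_val, f_val = x_all[val_idx], factors[val_idx]
    rng = np.random.default_rng(cfg.seed)
    gen_opt = Adam(model.generator_params(), lr=cfg.learning_rate)
    dis_opt = Adam(model.discriminator_params(), lr=cfg.learning_rate)
    use_dis = model.config.use_discriminator

    best_state = model.state_dict()
    stopper = EarlyStopper(cfg.patience)
    rows = []
    for epoch in range(cfg.max_epochs):
        train_losses = []
        for batch in _epoch_order(rng, len(train_idx), cfg.batch_size):
            idx = train_idx[batch]
            xb, fb, sb = x_all[idx], factors[idx], species_idx[idx]
            if use_dis:
                # step 1: discriminator on current embeddings (no encoder
                # gradients needed, so sample z outside the tape)
                mu_np, lv_np = model.encode_batch(xb, fb)
                z_np = mu_np + rng.standard_normal(mu_np.shape) * np.exp(0.5 * lv_np)
                dis_loss = model.discriminator_loss_tensor(
                    Tensor(z_np), sb, frozen=False)
                dis_opt.zero_grad()
                dis_loss.backward()
                dis_opt.step()
                # step 2: generator on loss_cVAE - loss_dis, discriminator frozen
                recon, kl, z = model._forward(xb, fb, rng)
                dis = model.discriminator_loss_tensor(z, sb, frozen=True)
                total = recon + kl - model.config.adv_weight * dis
                gen_opt.zero_grad()
                total.backward()
                gen_opt.step()
                train_losses.append(float((recon + kl).data))
            else:
                recon, kl, _ = model._forward(xb, fb, rng)
                total = recon + kl
                gen_opt.zero_grad()
                total.backward()
                gen_opt.step()
                train_losses.append(float(total.data))
        if not np.isfinite(train_losses).all():
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: non-finite loss")
        # validation loss_cVAE is monitored regardless of the adversary,
        # with the posterior mean (no sampling) for determinism
        v_recon, v_kl, v_total = model.cvae_loss(x_val, f_val, sample_rng=None)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                     "val_loss": v_total, "val_recon": v_recon, "val_kl": v_kl})
        improved = v_total < stopper.best
        stop = stopper.update(epoch, v_total)
        if improved:
            best_state = model.state_dict()
        if stop:
            break
    model.load_state_dict(best_state)
    mu_val, _ = model.encode_batch(x_val, f_val)
    val_species = data.cells["species"].to_numpy()[val_idx]
    if len(np.unique(val_species)) > 1:
        lisi = float(np.mean(compute_lisi(mu_val, val_species,
                                          perplexity=cfg.lisi_perplexity)))
    else:
        lisi = 1.0
    return TrainedModel(model, cfg, stopper.best_epoch, stopper.best,
                        lisi, pd.DataFrame(rows))


def grid_search(data: CountMatrix, cfg: TrainConfig,
                train_idx: np.ndarray, val_idx: np.ndarray) -> tuple[TrainedModel, pd.DataFrame]:
    """Fit every grid point; select the largest validation species LISI."""
    levels = {"species": sorted(data.cells["species"].astype(str).unique()),
              "batch": sorted(data.cells["batch"].astype(str).unique()),
              "tissue": sorted(data.cells["tissue"].astype(str).unique())}
    candidates: list[TrainedModel] = []
    records = []
    for use_dis in cfg.grid_discriminator:
        for nz in cfg.grid_n_latent:
            mc = replace(cfg.model, n_latent=nz, use_discriminator=use_dis,
                         seed=cfg.seed)
            model = CVAE(data.n_genes, levels, mc)
            try:
                tm = fit(model, data, cfg, train_idx, val_idx)
            except FloatingPointError as err:
                logger.warning("grid point (dis=%s, nz=%d) diverged: %s",
                               use_dis, nz, err)
                continue
            candidates.append(tm)
            records.append({"use_discriminator": use_dis, "n_latent": nz,
                            "best_epoch": tm.best_epoch,
                            "best_val_loss": tm.best_val_loss,
                            "lisi": tm.lisi_score})
            logger.info("grid point dis=%s nz=%d: val_loss=%.4f lisi=%.3f",
                        use_dis, nz, tm.best_val_loss, tm.lisi_score)
    if not candidates:
        raise RuntimeError("all grid points diverged")
    metrics = pd.DataFrame.from_records(records)
    best = max(candidates, key=lambda tm: tm.lisi_score)
    return best, metrics
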