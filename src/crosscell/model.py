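"""Conditional VAE with a zero-inflated negative binomial likelihood.

Each cell's raw UMI count vector X is modelled as

    X_g ~ ZINB(d * mu'_g, r_g, p_g)

where d is the cell's observed sequencing depth, mu' a per-gene rate
simplex (sums to 1 over genes: the sequencing-depth-corrected mean),
r > 0 the negative binomial dispersion (variance = m + m^2/r) and p the
logit of the dropout probability pi. The encoder maps the expression
profile together with one-hot species / batch / tissue codes to a
diagonal Gaussian posterior over an n-dimensional cell embedding z; the
decoder maps (z, codes) back to ZINB parameters. Swapping the species
code at decode time yields the cell's predicted profile in another
species.

Losses:

* reconstruction: negative ZINB log likelihood, summed over genes and
  averaged over cells;
* KL(Q(z|X,b,s,t) || N(0, I)), averaged over cells;
* optionally an adversarial term: a single affine-softmax discriminator
  predicts species from z; the generator then minimises
  loss_cVAE - loss_dis with the discriminator frozen, pushing the
  embedding toward species invariance.

Encoder and decoder have two ReLU hidden layers each (depth fixed;
width configurable). By default the encoder conditions on
log1p(depth-normalized) expression while the likelihood always scores
raw counts; raw-input conditioning is available in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln as np_gammaln

from . import autodiff as ad
from .autodiff import Tensor

DROPOUT_LOGIT_CLAMP = 15.0
DISPERSION_EPS = 1e-4
MEAN_EPS = 1e-10


# -- likelihood primitives (numpy; used for scoring and as public API) ---


def zinb_log_likelihood(x, mean, r, dropout_logit):
    """Log pmf of the zero-inflated negative binomial, elementwise.

    pi = sigmoid(dropout_logit); P(x) = pi*[x=0] + (1-pi)*NB(x; mean, r)
    with NB parameterised by mean and dispersion r (variance
    mean + mean^2/r). Stable in log space: at x = 0 the two branches are
    combined as log_sigmoid(p) + softplus(log NB(0) - p).
    """
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    r = np.asarray(r, dtype=float)
    p = np.asarray(dropout_logit, dtype=float)
    if np.any(r <= 0):
        raise ValueError("dispersion r must be > 0")
    if np.any(mean < 0):
        raise ValueError("mean must be >= 0")
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("x must be a non-negative integer count")
    m = mean + MEAN_EPS
    log_nb = (np_gammaln(x + r) - np_gammaln(r) - np_gammaln(x + 1)
              + r * np.log(r / (r + m)) + x * np.log(m / (r + m)))

    def _softplus(v):
        return np.maximum(v, 0.0) + np.log1p(np.exp(-np.abs(v)))

    log_sig_p = -_softplus(-p)      # log pi
    log_sig_np = -_softplus(p)      # log (1 - pi)
    ll_zero = log_sig_p + _softplus(log_nb - p)
    ll_pos = log_sig_np + log_nb
    return np.where(x == 0, ll_zero, ll_pos)


def kl_diag_gaussian(mu_z, logvar_z) -> float:
    """KL( N(mu, diag(exp(logvar))) || N(0, I) ), closed form."""
    mu = np.asarray(mu_z, dtype=float)
    lv = np.asarray(logvar_z, dtype=float)
    if mu.shape != lv.shape:
        raise ValueError("mu and logvar must have the same shape")
    return float(0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0))


# -- configuration and data types ----------------------------------------


@dataclass
class ModelConfig:
    n_latent: int = 25
    hidden_width: int = 128
    n_hidden_layers: int = 2          # architecture depth is fixed
    use_discriminator: bool = False
    adv_weight: float = 1.0
    encoder_input: str = "lognorm"    # "lognorm" | "raw"
    seed: int = 0

    def __post_init__(self):
        if self.n_hidden_layers != 2:
            raise ValueError("encoder/decoder depth is fixed to 2 hidden layers")
        if self.encoder_input not in ("lognorm", "raw"):
            raise ValueError("encoder_input must be 'lognorm' or 'raw'")


@dataclass
class FactorCodes:
    """One-hot species / batch / tissue codes for one cell."""

    s: np.ndarray
    b: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        for name in ("s", "b", "t"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or not np.isclose(v.sum(), 1.0) or not set(np.unique(v)) <= {0.0, 1.0}:
                raise ValueError(f"{name} must be a one-hot vector")
            setattr(self, name, v)

    def concat(self) -> np.ndarray:
        return np.concatenate([self.s, self.b, self.t])


@dataclass
class EncoderOutput:
    mu_z: np.ndarray
    logvar_z: np.ndarray


@dataclass
class DecoderOutput:
    mu_prime: np.ndarray   # simplex over genes
    r: np.ndarray          # > 0
    p: np.ndarray          # dropout logits, clamped


def _linear_init(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
    w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
    return Tensor(w, requires_grad=True), Tensor(np.zeros(n_out), requires_grad=True)


class CVAE:
    """Conditional VAE over gene-by-cell raw counts with factor codes."""

    def __init__(self, n_genes: int,
                 levels: dict[str, list[str]],
                 config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.n_genes = int(n_genes)
        self.levels = {k: list(v) for k, v in levels.items()}
        for key in ("species", "batch", "tissue"):
            self.levels.setdefault(key, ["_constant"])
        self.n_factors = sum(len(v) for v in self.levels.values())
        self.rng = np.random.default_rng(self.config.seed)

        h = self.config.hidden_width
        nz = self.config.n_latent
        r = self.rng
        g, f = self.n_genes, self.n_factors
        # encoder
        self.enc_w1, self.enc_b1 = _linear_init(r, g + f, h)
        self.enc_w2, self.enc_b2 = _linear_init(r, h, h)
        self.enc_wmu, self.enc_bmu = _linear_init(r, h, nz)
        self.enc_wlv, self.enc_blv = _linear_init(r, h, nz)
        # decoder: first layer takes z and the factor block through
        # separate weight matrices (equivalent to concatenation)
        self.dec_wz1, self.dec_b1 = _linear_init(r, nz + f, h)
        self.dec_wz1.data = self.dec_wz1.data[:nz]
        self.dec_wf1 = Tensor(self.rng.normal(0.0, np.sqrt(2.0 / (nz + f)), size=(f, h)),
                              requires_grad=True)
        self.dec_w2, self.dec_b2 = _linear_init(r, h, h)
        self.dec_wmu, self.dec_bmu = _linear_init(r, h, g)
        self.dec_wr, self.dec_br = _linear_init(r, h, g)
        self.dec_wp, self.dec_bp = _linear_init(r, h, g)
        # single affine-layer species discriminator
        ns = len(self.levels["species"])
        self.dis_w, self.dis_b = _linear_init(r, nz, ns)

    # -- parameter bookkeeping ------------------------------------------

    def generator_params(self) -> list[Tensor]:
        return [self.enc_w1, self.enc_b1, self.enc_w2, self.enc_b2,
                self.enc_wmu, self.enc_bmu, self.enc_wlv, self.enc_blv,
                self.dec_wz1, self.dec_wf1, self.dec_b1, self.dec_w2, self.dec_b2,
                self.dec_wmu, self.dec_bmu, self.dec_wr, self.dec_br,
                self.dec_wp, self.dec_bp]

    def discriminator_params(self) -> list[Tensor]:
        return [self.dis_w, self.dis_b]

    # -- factor encoding -------------------------------------------------

    def factor_matrix(self, cells: pd.DataFrame,
                      species_override: str | None = None) -> np.ndarray:
        """One-hot factor block for a cell table (n_cells x n_factors)."""
        blocks = []
        for key, col in (("species", "species"), ("batch", "batch"), ("tissue", "tissue")):
            lv = self.levels[key]
            block = np.zeros((len(cells), len(lv)))
            if lv == ["_constant"]:
                block[:, 0] = 1.0
            else:
                vals = ([species_override] * len(cells)
                        if key == "species" and species_override is not None
                        else cells[col].astype(str).tolist())
                for i, v in enumerate(vals):
                    try:
                        block[i, lv.index(v)] = 1.0
                    except ValueError:
                        raise KeyError(f"unknown {key} level {v!r}") from None
            blocks.append(block)
        return np.column_stack(blocks)

    def factor_codes(self, species: str, batch: str | None = None,
                     tissue: str | None = None) -> FactorCodes:
        def onehot(key, value):
            lv = self.levels[key]
            v = np.zeros(len(lv))
            v[lv.index(value) if value is not None else 0] = 1.0
            return v
        return FactorCodes(onehot("species", species), onehot("batch", batch),
                           onehot("tissue", tissue))

    # -- forward passes --------------------------------------------------

    def _encoder_input(self, x: np.ndarray, depth: np.ndarray) -> np.ndarray:
        if self.config.encoder_input == "raw":
            return x
        return np.log1p(x * (1e4 / np.maximum(depth, 1.0)[:, None]))

    def _encode_tensor(self, xin: np.ndarray, factors: np.ndarray) -> tuple[Tensor, Tensor]:
        inp = Tensor(np.column_stack([xin, factors]))
        h1 = ad.relu(inp @ self.enc_w1 + self.enc_b1)
        h2 = ad.relu(h1 @ self.enc_w2 + self.enc_b2)
        mu = h2 @ self.enc_wmu + self.enc_bmu
        logvar = ad.clip(h2 @ self.enc_wlv + self.enc_blv, -10.0, 10.0)
        return mu, logvar

    def _decode_tensor(self, z: Tensor, factors: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        fac = Tensor(factors)
        h1 = ad.relu(z @ self.dec_wz1 + fac @ self.dec_wf1 + self.dec_b1)
        h2 = ad.relu(h1 @ self.dec_w2 + self.dec_b2)
        mu_prime = ad.softmax(h2 @ self.dec_wmu + self.dec_bmu, axis=-1)
        r = ad.softplus(h2 @ self.dec_wr + self.dec_br) + DISPERSION_EPS
        p = ad.clip(h2 @ self.dec_wp + self.dec_bp,
                    -DROPOUT_LOGIT_CLAMP, DROPOUT_LOGIT_CLAMP)
        return mu_prime, r, p

    # numpy-facing wrappers

    def encode_batch(self, x: np.ndarray, factors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance for raw-count rows (cells x genes)."""
        depth = x.sum(axis=1)
        mu, logvar = self._encode_tensor(self._encoder_input(x, depth), factors)
        return mu.data, logvar.data

    def decode_batch(self, z: np.ndarray,
                     factors: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mu_prime, r, p = self._decode_tensor(Tensor(z), factors)
        return mu_prime.data, r.data, p.data

    def encode(self, x_row: np.ndarray, f: FactorCodes) -> EncoderOutput:
        if x_row.shape != (self.n_genes,):
            raise ValueError("x_row length must equal n_genes")
        mu, lv = self.encode_batch(x_row[None, :], f.concat()[None, :])
        return EncoderOutput(mu[0], lv[0])

    def decode(self, z: np.ndarray, f: FactorCodes) -> DecoderOutput:
        z = np.asarray(z, dtype=float)
        if z.shape != (self.config.n_latent,):
            raise ValueError("z length must equal n_latent")
        mu_prime, r, p = self.decode_batch(z[None, :], f.concat()[None, :])
        return DecoderOutput(mu_prime[0], r[0], p[0])

    # -- losses ----------------------------------------------------------

    def _zinb_nll_tensor(self, x: np.ndarray, depth: np.ndarray,
                         mu_prime: Tensor, r: Tensor, p: Tensor) -> Tensor:
        """Mean-over-cells negative ZINB log likelihood (summed over genes)."""
        xt = Tensor(x)
        m = mu_prime * Tensor(depth[:, None]) + MEAN_EPS
        log_ratio_r = ad.log(r / (r + m))
        log_ratio_m = ad.log(m / (r + m))
        log_nb = (ad.gammaln(xt + r) - ad.gammaln(r) - Tensor(np_gammaln(x + 1.0))
                  + r * log_ratio_r + xt * log_ratio_m)
        ll_zero = ad.log_sigmoid(p) + ad.softplus(log_nb - p)
        ll_pos = ad.log_sigmoid(-p) + log_nb
        mask = (x == 0).astype(float)
        ll = Tensor(mask) * ll_zero + Tensor(1.0 - mask) * ll_pos
        return -(ll.sum(axis=1).mean())

    def _kl_tensor(self, mu: Tensor, logvar: Tensor) -> Tensor:
        return (0.5 * (mu**2 + ad.exp(logvar) - logvar - 1.0).sum(axis=1)).mean()

    def _forward(self, x: np.ndarray, factors: np.ndarray,
                 sample_rng: np.random.Generator | None):
        depth = x.sum(axis=1)
        mu, logvar = self._encode_tensor(self._encoder_input(x, depth), factors)
        if sample_rng is not None:
            eps = sample_rng.standard_normal(mu.data.shape)
            z = mu + Tensor(eps) * ad.exp(0.5 * logvar)
        else:
            z = mu
        mu_prime, r, p = self._decode_tensor(z, factors)
        recon = self._zinb_nll_tensor(x, depth, mu_prime, r, p)
        kl = self._kl_tensor(mu, logvar)
        return recon, kl, z

    def cvae_loss(self, x: np.ndarray, factors: np.ndarray,
                  sample_rng: np.random.Generator | None = None):
        """(loss_reconstr, loss_KL, loss_cVAE) on a batch, as floats."""
        recon, kl, _ = self._forward(x, factors, sample_rng)
        return float(recon.data), float(kl.data), float(recon.data + kl.data)

    def discriminator_logits(self, z: Tensor, frozen: bool = False) -> Tensor:
        w = Tensor(self.dis_w.data) if frozen else self.dis_w
        b = Tensor(self.dis_b.data) if frozen else self.dis_b
        return z @ w + b

    def discriminator_loss_tensor(self, z: Tensor, species_idx: np.ndarray,
                                  frozen: bool = False) -> Tensor:
        logits = self.discriminator_logits(z, frozen=frozen)
        logp = ad.log_softmax(logits, axis=-1)
        onehot = np.zeros(logp.data.shape)
        onehot[np.arange(len(species_idx)), species_idx] = 1.0
        return -((Tensor(onehot) * logp).sum(axis=1).mean())

    def discriminator_loss(self, z: np.ndarray, species_labels) -> float:
        """Mean cross-entropy of the species discriminator on embeddings."""
        lv = self.levels["species"]
        idx = np.array([lv.index(str(s)) for s in species_labels])
        return float(self.discriminator_loss_tensor(Tensor(np.asarray(z, dtype=float)),
                                                    idx).data)

    def adversarial_objective(self, x: np.ndarray, factors: np.ndarray,
                              species_idx: np.ndarray,
                              sample_rng: np.random.Generator | None = None) -> float:
        """loss_cVAE - adv_weight * loss_dis with the discriminator frozen."""
        recon, kl, z = self._forward(x, factors, sample_rng)
        if not self.config.use_discriminator:
            return float(recon.data + kl.data)
        dis = self.discriminator_loss_tensor(z, species_idx, frozen=True)
        return float(recon.data + kl.data - self.config.adv_weight * dis.data)

    # -- persistence -----------------------------------------------------

    _PARAM_NAMES = ("enc_w1", "enc_b1", "enc_w2", "enc_b2", "enc_wmu", "enc_bmu",
                    "enc_wlv", "enc_blv", "dec_wz1", "dec_wf1", "dec_b1", "dec_w2", "dec_b2",
                    "dec_wmu", "dec_bmu", "dec_wr", "dec_br", "dec_wp", "dec_bp",
                    "dis_w", "dis_b")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name).data.copy() for name in self._PARAM_NAMES}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name in self._PARAM_NAMES:
            getattr(self, name).data = np.array(state[name], dtype=np.float64)

    def save(self, path) -> None:
        """Single-archive checkpoint: config + factor levels + parameters."""
        meta = {"format_version": 1, "n_genes": self.n_genes,
                "levels": self.levels, "config": asdict(self.config)}
        np.savez(Path(path), __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path) -> "CVAE":
        with np.load(Path(path), allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            state = {k: archive[k] for k in cls._PARAM_NAMES}
        model = cls(meta["n_genes"], meta["levels"], ModelConfig(**meta["config"]))
        model.load_state_dict(state)
        return model
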