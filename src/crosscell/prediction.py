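"""Cross-species prediction by species-factor swapping, and its
evaluation protocol: three baselines, pseudobulk Pearson correlation,
relative prediction error, and gene binning.

Prediction encodes each source-species cell with its own factor codes
using the posterior mean (no sampling, so prediction is deterministic),
then decodes with the species code replaced by the target species. The
decoder's mu' head is itself a depth-normalized profile (sums to 1 over
genes), so the prediction is directly comparable to depth-normalized
observed profiles.

Baselines (all on depth-normalized, log2(x+1)-transformed pseudobulk):

* species baseline — the source species profile transferred through the
  ortholog map unchanged ("expression does not evolve");
* cell type baseline — the target-species profile of the source cell
  type nearest (Euclidean) to the held-out type;
* donor baseline — mean pairwise Pearson correlation between donors
  within the held-out stratum (a ceiling estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_filters import CountMatrix
from .model import CVAE


@dataclass
class PredictionResult:
    """Predicted depth-normalized expression, genes x cells."""

    values: np.ndarray
    genes: pd.DataFrame
    cells: pd.DataFrame
    source_species: str | None
    target_species: str
    checkpoint_id: str | None = None

    def __post_init__(self):
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("prediction shape does not match tables")
        if (self.values < 0).any():
            raise ValueError("negative predicted expression")


def predict_cross_species(model: CVAE, cells: CountMatrix, target_species: str,
                          scale: float = 1.0,
                          checkpoint_id: str | None = None) -> PredictionResult:
    """Encode with own factors (posterior mean), decode as ``target_species``.

    Returns mu' per cell, optionally multiplied by ``scale`` (e.g. 1e4
    for a counts-per-10k convention).
    """
    if target_species not in model.levels["species"]:
        raise KeyError(f"unknown species {target_species!r}")
    x = np.asarray(cells.values.todense(), dtype=float).T
    f_own = model.factor_matrix(cells.cells)
    f_target = model.factor_matrix(cells.cells, species_override=target_species)
    mu, _ = model.encode_batch(x, f_own)
    mu_prime, _, _ = model.decode_batch(mu, f_target)
    sources = cells.cells["species"].astype(str).unique()
    return PredictionResult(mu_prime.T * scale, cells.genes.copy(), cells.cells.copy(),
                            sources[0] if len(sources) == 1 else None,
                            target_species, checkpoint_id)


def predicted_pseudobulk(pred: PredictionResult, log_transform: bool = False) -> np.ndarray:
    """Mean predicted profile over cells (linear averaging)."""
    pb = pred.values.mean(axis=1)
    return np.log2(pb + 1.0) if log_transform else pb


# -- baselines -----------------------------------------------------------


def species_baseline(source_profile: np.ndarray, source_genes: pd.Index | list,
                     target_genes: pd.Index | list,
                     gene_map: dict[str, str]) -> np.ndarray:
    """Transfer the source profile to the target gene space via orthologs.

    ``gene_map`` maps source gene ID -> target gene ID and must cover
    the target gene set.
    """
    source_pos = {g: i for i, g in enumerate(source_genes)}
    inverse = {tgt: src for src, tgt in gene_map.items()}
    out = np.empty(len(target_genes))
    for j, tgt in enumerate(target_genes):
        src = inverse.get(tgt)
        if src is None or src not in source_pos:
            raise KeyError(f"target gene {tgt!r} has no mapped source gene")
        out[j] = source_profile[source_pos[src]]
    return out


def celltype_baseline(held_out_ct: str,
                      source_pseudobulks: dict[str, np.ndarray],
                      target_pseudobulks: dict[str, np.ndarray]) -> tuple[str, np.ndarray]:
    """Nearest source cell type (Euclidean), then its target profile."""
    if held_out_ct not in source_pseudobulks:
        raise KeyError(f"held-out cell type {held_out_ct!r} missing from source")
    ref = source_pseudobulks[held_out_ct]
    candidates = sorted(ct for ct in source_pseudobulks
                        if ct != held_out_ct and ct in target_pseudobulks)
    if not candidates:
        raise ValueError("no candidate cell types with profiles in both species")
    best = min(candidates,
               key=lambda ct: (float(np.linalg.norm(source_pseudobulks[ct] - ref)), ct))
    return best, target_pseudobulks[best]


def donor_baseline(donor_pseudobulks: dict[str, np.ndarray]) -> float | None:
    """Mean pairwise Pearson correlation across donors; None if < 2 donors."""
    donors = sorted(donor_pseudobulks)
    if len(donors) < 2:
        return None
    cors = []
    for i, a in enumerate(donors):
        for b in donors[i + 1:]:
            cors.append(stats.pearsonr(donor_pseudobulks[a], donor_pseudobulks[b])[0])
    return float(np.mean(cors))


# -- correlation metrics -------------------------------------------------


def pearson_pseudobulk(pred_pb: np.ndarray, truth_pb: np.ndarray) -> float:
    pred_pb, truth_pb = np.asarray(pred_pb, float), np.asarray(truth_pb, float)
    if pred_pb.std() == 0 or truth_pb.std() == 0:
        raise ValueError("zero-variance profile; correlation undefined")
    return float(stats.pearsonr(pred_pb, truth_pb)[0])


def indiv_prediction(pred_pb: np.ndarray,
                     donor_pseudobulks: dict[str, np.ndarray]) -> float:
    """Mean correlation of the prediction against each donor's pseudobulk."""
    if not donor_pseudobulks:
        raise ValueError("no donor profiles")
    return float(np.mean([pearson_pseudobulk(pred_pb, pb)
                          for pb in donor_pseudobulks.values()]))


def relative_prediction_error(pred_pb: np.ndarray, truth_target_pb: np.ndarray,
                              truth_source_pb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|pred - target| / |source - target| per gene.

    Returns (errors, defined_mask); where source == target the ratio is
    undefined and the gene is excluded from summaries (error set NaN).
    """
    pred = np.asarray(pred_pb, float)
    tgt = np.asarray(truth_target_pb, float)
    src = np.asarray(truth_source_pb, float)
    denom = np.abs(src - tgt)
    defined = denom > 0
    err = np.full(pred.shape, np.nan)
    err[defined] = np.abs(pred - tgt)[defined] / denom[defined]
    return err, defined


def bin_genes(statistic: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile bin assignment (0..n_bins-1), sizes differing by <= 1.

    Ties are broken deterministically by rank (stable sort on the
    statistic, then position).
    """
    stat = np.asarray(statistic, float)
    if len(stat) < n_bins:
        raise ValueError("need at least n_bins genes")
    order = np.argsort(stat, kind="stable")
    ranks = np.empty(len(stat), dtype=int)
    ranks[order] = np.arange(len(stat))
    return (ranks * n_bins) // len(stat)


def binned_error_summary(errors: np.ndarray, statistic: np.ndarray,
                         flag: np.ndarray | None = None,
                         n_bins: int = 10) -> pd.DataFrame:
    """Median error per quantile bin, optionally stratified by a gene flag."""
    bins = bin_genes(statistic, n_bins)
    df = pd.DataFrame({"bin": bins, "error": errors})
    group_cols = ["bin"]
    if flag is not None:
        df["flag"] = np.asarray(flag)
        group_cols.append("flag")
    return (df.dropna(subset=["error"])
              .groupby(group_cols, observed=True)["error"]
              .agg(["median", "mean", "count"])
              .reset_index())
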