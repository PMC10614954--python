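"""Cross-species comparison of predicted profiles: housekeeping
normalization, per-cell log2 fold changes, X-chromosome gene grouping,
upregulation tests, m6A (GGACH) motif analysis, and disease-transfer
evaluation.

The X-upregulation (XCU) analysis asks whether genes increase their
expression after becoming X-linked (and thus halving their copy number
in XY males). Orthologs are grouped by evolutionary origin:

* XAR (X-added region): X-linked in eutherians (mouse) but autosomal in
  metatherians (opossum) and birds (chicken);
* XCR (X-conserved region): X-linked in both mammalian clades, autosomal
  in birds;
* autosomal: autosomal in all three.

Per-cell log2 fold changes between two species-factor predictions of
the same cells are summarised per gene by the median across cells, and
each group is tested with one-sided one-sample Wilcoxon signed-rank
tests (e.g. H0: median log2FC <= -1, the no-upregulation expectation
under halved dose).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("crosscell")

X_LABELS = {"X", "chrX", "x", "chrx"}
NON_AUTOSOMAL = {"Y", "chrY", "MT", "chrM", "chrMT", "M"}

GGACH_RE = re.compile(r"(?=GGAC[ACTU])")


# -- normalization and fold changes --------------------------------------


def housekeeping_normalize(profiles: np.ndarray, hk_mask: np.ndarray,
                           constant: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Scale each cell so summed housekeeping expression equals `constant`.

    ``profiles`` is genes x cells; ``hk_mask`` a boolean gene mask.
    Returns (normalized profiles, kept-cell mask); cells with zero
    housekeeping signal are flagged and excluded (dropped columns).
    """
    hk_mask = np.asarray(hk_mask, dtype=bool)
    if not hk_mask.any():
        raise ValueError("no housekeeping genes in the gene space")
    hk_sum = profiles[hk_mask].sum(axis=0)
    keep = hk_sum > 0
    if not keep.all():
        logger.warning("housekeeping_normalize: excluding %d cells with zero "
                       "housekeeping signal", int((~keep).sum()))
    return profiles[:, keep] * (constant / hk_sum[keep]), keep


def per_cell_log2fc(pred_a: np.ndarray, pred_b: np.ndarray,
                    eps: float = 1e-6) -> np.ndarray:
    """Per-gene median over cells of log2((a + eps) / (b + eps)).

    ``pred_a`` and ``pred_b`` are genes x cells predictions for the SAME
    cells under two species codes (same embedding, two decodes).
    """
    if pred_a.shape != pred_b.shape:
        raise ValueError("predictions must cover the same cells and genes")
    fc = np.log2((pred_a + eps) / (pred_b + eps))
    return np.median(fc, axis=1)


# -- gene grouping -------------------------------------------------------


def _chrom_class(chrom) -> str:
    if chrom is None or (isinstance(chrom, float) and np.isnan(chrom)) or chrom == "":
        return "missing"
    c = str(chrom)
    if c in X_LABELS:
        return "X"
    if c in NON_AUTOSOMAL:
        return "other"
    return "autosomal"


def assign_gene_groups(annotations: pd.DataFrame,
                       eutherian_col: str = "chrom_mouse",
                       metatherian_col: str = "chrom_opossum",
                       bird_col: str = "chrom_chicken") -> pd.Series:
    """Group orthologs into XAR / XCR / autosomal / excluded.

    A pure function of the per-species chromosome columns: XAR is
    X-linked in the eutherian but autosomal in metatherian and bird,
    XCR is X-linked in both mammalian clades and autosomal in the bird,
    autosomal is autosomal everywhere; anything else (including missing
    annotations) is excluded.
    """
    out = []
    for _, row in annotations.iterrows():
        eut = _chrom_class(row[eutherian_col])
        met = _chrom_class(row[metatherian_col])
        bird = _chrom_class(row[bird_col])
        if eut == "X" and met == "autosomal" and bird == "autosomal":
            out.append("XAR")
        elif eut == "X" and met == "X" and bird == "autosomal":
            out.append("XCR")
        elif eut == met == bird == "autosomal":
            out.append("autosomal")
        else:
            out.append("excluded")
    return pd.Series(out, index=annotations.index, name="group")


# -- statistics ----------------------------------------------------------


def test_group_shift(values: np.ndarray, null_median: float,
                     alternative: str = "greater") -> tuple[float, bool]:
    """One-sided one-sample Wilcoxon signed-rank test against ``null_median``.

    Exact null distribution for n <= 25 (after dropping exact ties with
    the null), normal approximation with continuity correction above.
    Returns (p, all_tied_flag); if every value ties with the null the
    test is vacuous and p = 1 is reported with the flag set.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    diffs = np.asarray(values, float) - null_median
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0, True
    if diffs.size < 5:
        logger.warning("test_group_shift: only %d non-tied values", diffs.size)
    method = "exact" if diffs.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(diffs, alternative=alternative, method=method,
                             correction=(method == "approx"))
    except ValueError:
        # tied ranks make the exact null unavailable; fall back
        res = stats.wilcoxon(diffs, alternative=alternative, method="approx",
                             correction=True)
    return float(res.pvalue), False


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def xcu_group_tests(median_log2fc: np.ndarray, groups: pd.Series,
                    null_median: float = -1.0, alternative: str = "greater",
                    test_groups: tuple[str, ...] = ("XAR", "XCR")) -> pd.DataFrame:
    """Run the group-shift test per gene group and BH-adjust across them."""
    groups = pd.Series(np.asarray(groups), name="group")
    rows = []
    for g in test_groups:
        vals = median_log2fc[(groups == g).to_numpy()]
        p, tied = test_group_shift(vals, null_median, alternative)
        rows.append({"group": g, "n_genes": int(len(vals)),
                     "null_median": null_median, "alternative": alternative,
                     "p": p, "all_tied": tied})
    df = pd.DataFrame(rows)
    df["p_adj"] = adjust_pvalues(df["p"].to_numpy())
    return df


# -- motif analysis ------------------------------------------------------


def count_ggach(cds: str) -> tuple[int, float]:
    """Overlapping GGACH (H = A/C/T/U) occurrences and per-kb frequency."""
    if not cds:
        raise ValueError("empty sequence")
    seq = cds.upper()
    if not set(seq) <= set("ACGTUN"):
        raise ValueError("sequence must be over A/C/G/T/U/N")
    n = len(GGACH_RE.findall(seq))
    return n, n * 1000.0 / len(seq)


def compare_motif_shift(freq_species1: np.ndarray, freq_species2: np.ndarray,
                        groups: pd.Series,
                        x_groups: tuple[str, ...] = ("XAR", "XCR"),
                        reference_group: str = "autosomal") -> pd.DataFrame:
    """Rank-sum test of per-ortholog motif-frequency deltas, X vs autosomal.

    Delta = freq_species1 - freq_species2 per ortholog; the one-sided
    alternative is that the X group's deltas are more negative (motif
    loss on becoming X-linked) than the autosomal group's.
    """
    groups = pd.Series(np.asarray(groups))
    delta = np.asarray(freq_species1, float) - np.asarray(freq_species2, float)
    ref = delta[(groups == reference_group).to_numpy()]
    if len(ref) < 5:
        raise ValueError("reference group has fewer than 5 genes")
    rows = []
    for g in x_groups:
        dg = delta[(groups == g).to_numpy()]
        if len(dg) < 5:
            raise ValueError(f"group {g!r} has fewer than 5 genes")
        p = stats.mannwhitneyu(dg, ref, alternative="less")[1]
        rows.append({"group": g, "n": len(dg), "n_ref": len(ref),
                     "median_delta": float(np.median(dg)),
                     "median_delta_ref": float(np.median(ref)), "p": float(p)})
    return pd.DataFrame(rows)


# -- disease transfer ----------------------------------------------------


def disease_log2fc(pb_case: np.ndarray, pb_control: np.ndarray) -> np.ndarray:
    """log2((case + 1) / (control + 1)) on 10,000-scaled pseudobulk."""
    case = np.asarray(pb_case, float)
    ctrl = np.asarray(pb_control, float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("empty group")
    return np.log2((case + 1.0) / (ctrl + 1.0))


def transfer_eval(pred_case_log2fc: dict[str, np.ndarray],
                  observed_log2fc: dict[str, np.ndarray],
                  baseline_log2fc: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-cell-type Pearson of predicted and baseline log2FC vs observed.

    All three dicts map cell type -> per-gene log2 fold change
    (case vs control); the baseline is typically the source-species
    (mouse) log2FC used directly as a proxy.
    """
    rows = []
    for ct in sorted(observed_log2fc):
        obs = observed_log2fc[ct]
        if np.std(obs) == 0:
            raise ValueError(f"zero-variance observed log2FC for {ct!r}")
        row = {"cell_type": ct}
        row["prediction_cor"] = float(stats.pearsonr(pred_case_log2fc[ct], obs)[0])
        row["baseline_cor"] = float(stats.pearsonr(baseline_log2fc[ct], obs)[0])
        rows.append(row)
    return pd.DataFrame(rows)
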