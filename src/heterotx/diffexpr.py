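"""Normalization, FPKM, replicate QC and negative-binomial differential
expression.

The DE engine is a transparent NB Wald test: per-gene group means on
median-of-ratios-normalized counts, method-of-moments dispersion (shared
across genes by default, no shrinkage), delta-method standard error on the
log2 fold change, and a two-sided normal reference.  Calling follows the
rule |fold change| > 2 at Benjamini–Hochberg FDR < 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import TrioExpressionSet

__all__ = [
    "Contrast",
    "size_factors",
    "normalized_counts",
    "fpkm",
    "replicate_correlation",
    "nb_wald",
    "nb_test",
    "bh_adjust",
    "call_de",
]

_ALPHA_FLOOR = 1e-8
_PSEUDO_MEAN = 0.5  # normalized-count floor inside the log when a side is all-zero
LN2 = np.log(2.0)


@dataclass(frozen=True)
class Contrast:
    """A two-cell comparison: numerator vs denominator design cell."""

    name: str
    numerator: tuple  # (trio_id, role, condition)
    denominator: tuple

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator cells are identical")

    def __str__(self) -> str:
        return self.name


# ---------------------------------------------------------------------------
# normalization and QC
# ---------------------------------------------------------------------------

def size_factors(counts) -> np.ndarray:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Only genes with nonzero counts in every sample contribute.  If no such
    gene exists, falls back to total-count scaling with a warning.
    """
    mat = np.asarray(counts, dtype=float)
    all_pos = np.all(mat > 0, axis=1)
    if not all_pos.any():
        warnings.warn("no gene expressed in all samples; "
                      "falling back to total-count size factors")
        totals = mat.sum(axis=0)
        factors = np.ones_like(totals)
        pos = totals > 0  # wholly empty libraries keep factor 1
        if pos.any():
            factors[pos] = totals[pos] / np.exp(np.mean(np.log(totals[pos])))
        return factors
    log_mat = np.log(mat[all_pos])
    log_ref = log_mat.mean(axis=1)  # per-gene geometric-mean reference
    factors = np.exp(np.median(log_mat - log_ref[:, None], axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def normalized_counts(eset: TrioExpressionSet) -> pd.DataFrame:
    sf = size_factors(eset.counts)
    return eset.counts / sf


def fpkm(counts, gene_lengths: pd.Series, size_basis: str = "raw_total"
         ) -> pd.DataFrame:
    """Fragments per kilobase of exon model per million mapped reads.

    fpkm[g, j] = counts[g, j] * 1e9 / (length_g * N_j), where N_j is the
    per-library total: the raw column sum (``raw_total``) or the
    median-of-ratios effective total, size_factor_j times the geometric
    mean of raw totals (``normalized_total``).
    """
    counts = pd.DataFrame(counts)
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise KeyError(f"no length for genes: {list(missing)[:5]}")
    lengths = gene_lengths.loc[counts.index].to_numpy(dtype=float)
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if size_basis == "raw_total":
        n_j = totals
    elif size_basis == "normalized_total":
        n_j = size_factors(counts) * np.exp(np.mean(np.log(totals)))
    else:
        raise ValueError(f"unknown size_basis {size_basis!r}")
    return counts * 1e9 / (lengths[:, None] * n_j[None, :])


def replicate_correlation(expr, log_transform: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples.

    Computed on log2(expr + 1) by default (variance-stabilized scale, the
    community default for sample-level QC).  Returns a symmetric matrix
    with unit diagonal.
    """
    expr = pd.DataFrame(expr)
    mat = np.log2(expr.to_numpy(dtype=float) + 1.0) if log_transform \
        else expr.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.columns, columns=expr.columns)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def _mom_dispersion(groups) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion from replicate groups.

    For each group, alpha = (s^2 - m) / m^2 (variance in excess of
    Poisson); estimates are averaged over groups with positive mean.
    Values may be negative (underdispersion); callers floor them.
    """
    num = np.zeros(groups[0].shape[0])
    den = np.zeros(groups[0].shape[0])
    for g in groups:
        m = g.mean(axis=1)
        v = g.var(axis=1, ddof=1)
        ok = m > 0
        est = np.zeros_like(m)
        est[ok] = (v[ok] - m[ok]) / m[ok] ** 2
        num += np.where(ok, est, 0.0)
        den += ok.astype(float)
    with np.errstate(invalid="ignore"):
        alpha = num / den
    return np.where(den > 0, alpha, 0.0)


def _resolve_alpha(groups, alpha_mode) -> np.ndarray:
    n_genes = groups[0].shape[0]
    if isinstance(alpha_mode, (int, float)):
        return np.full(n_genes, max(float(alpha_mode), _ALPHA_FLOOR))
    raw = _mom_dispersion(groups)
    if alpha_mode == "per_gene_mom":
        return np.maximum(raw, _ALPHA_FLOOR)
    if alpha_mode == "shared_mom":
        # pooled ratio-of-sums: sum(v - m) / sum(m^2) over genes and groups.
        # Nearly unbiased at small n, unlike the median of per-gene ratios.
        num = 0.0
        den = 0.0
        for g in groups:
            m = g.mean(axis=1)
            v = g.var(axis=1, ddof=1)
            ok = m > 0
            num += float(np.sum(v[ok] - m[ok]))
            den += float(np.sum(m[ok] ** 2))
        shared = num / den if den > 0 else 0.0
        return np.full(n_genes, max(shared, _ALPHA_FLOOR))
    raise ValueError(f"unknown alpha_mode {alpha_mode!r}")


def nb_wald(group1: np.ndarray, group2: np.ndarray,
            alpha_mode="shared_mom") -> pd.DataFrame:
    """NB Wald test between two replicate groups of normalized values.

    ``group1``/``group2`` are genes x replicates arrays on a common
    (library-size-normalized) scale; ``group1`` is the numerator of the
    fold change.  ``alpha_mode`` is ``"shared_mom"``, ``"per_gene_mom"``
    or a fixed numeric dispersion.

    Genes with all-zero values in both groups get p = 1 and log2fc = 0.
    When exactly one side is all-zero, a pseudo-mean floor of 0.5
    normalized counts enters the log for the fold change and its variance.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.shape[0] != g2.shape[0]:
        raise ValueError("groups must cover the same genes")
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("each group needs >= 2 replicates")
    if np.any(g1 < 0) or np.any(g2 < 0):
        raise ValueError("negative values in count data")

    alpha = _resolve_alpha((g1, g2), alpha_mode)
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    n1, n2 = g1.shape[1], g2.shape[1]
    both_zero = (m1 == 0) & (m2 == 0)
    mf1 = np.where(m1 == 0, _PSEUDO_MEAN, m1)
    mf2 = np.where(m2 == 0, _PSEUDO_MEAN, m2)

    log2fc = np.log2(mf1 / mf2)
    # delta method on the NB group means: Var(mean) = (mu + alpha mu^2)/n
    v1 = (mf1 + alpha * mf1 ** 2) / n1
    v2 = (mf2 + alpha * mf2 ** 2) / n2
    se = np.sqrt(v1 / mf1 ** 2 + v2 / mf2 ** 2) / LN2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.where(both_zero, 0.0, log2fc)
    p = np.where(both_zero, 1.0, p)
    return pd.DataFrame({
        "base_mean": (m1 * n1 + m2 * n2) / (n1 + n2),
        "log2fc": log2fc,
        "se_log2fc": se,
        "p_value": np.clip(p, 0.0, 1.0),
    })


def nb_test(eset: TrioExpressionSet, contrast: Contrast,
            alpha_mode="shared_mom") -> pd.DataFrame:
    """NB Wald DE test for one contrast of a trio expression set.

    Counts are normalized with size factors computed on the full matrix;
    returns one row per gene with ``gene_id``, Wald statistics and the
    contrast name (FDR and calls are added by :func:`bh_adjust` /
    :func:`call_de`).
    """
    num_samples = eset.sheet.samples(*contrast.numerator)
    den_samples = eset.sheet.samples(*contrast.denominator)
    if len(num_samples) < 2 or len(den_samples) < 2:
        raise ValueError(f"contrast {contrast.name!r}: each cell needs >= 2 "
                         "replicates")
    sf = pd.Series(size_factors(eset.counts), index=eset.counts.columns)
    g1 = (eset.counts[num_samples] / sf[num_samples]).to_numpy()
    g2 = (eset.counts[den_samples] / sf[den_samples]).to_numpy()
    res = nb_wald(g1, g2, alpha_mode=alpha_mode)
    res.insert(0, "gene_id", eset.gene_ids.to_numpy())
    res["contrast"] = contrast.name
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ties kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, fc_threshold: float = 2.0,
            fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Attach BH FDR and up/down/ns calls at |FC| > fc and FDR < fdr.

    A gene is ``up`` iff log2fc > log2(fc_threshold) and fdr < fdr_threshold
    (``down`` symmetric); the fold-change gate applies to the point
    estimate.
    """
    out = results.copy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    lfc_gate = np.log2(fc_threshold)
    call = np.full(len(out), "ns", dtype=object)
    sig = out["fdr"].to_numpy() < fdr_threshold
    call[sig & (out["log2fc"].to_numpy() > lfc_gate)] = "up"
    call[sig & (out["log2fc"].to_numpy() < -lfc_gate)] = "down"
    out["call"] = call
    return out
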