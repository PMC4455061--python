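"""Negative-binomial differential expression and regulatory classification.

Per assay, each gene is tested for a strain effect with an NB GLM (log
link, strain indicator, size-factor offsets) and a Wald test; per-gene
dispersions come from a method-of-moments estimator on normalized counts.
Genes are then classified by the pattern of DE flags across the two
RNA-seq assays and the Ribo-seq assay:

========  ========  ========  ==============================
RNA-seq1  RNA-seq2  Ribo-seq  class
========  ========  ========  ==============================
DE        DE        DE        RNA+RIBO   (forwarded)
DE        DE        --        RNA_only   (buffered)
--        --        DE        RIBO_only  (reinforced)
--        --        --        none
any other pattern             discordant
========  ========  ========  ==============================

Fold changes are log2(SHR / BN); the RNA fold change of a gene is the
average of the two RNA-seq assays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._nb import ALPHA_FLOOR, nb_two_group_wald
from .containers import (
    CLASS_BUFFERED,
    CLASS_DISCORDANT,
    CLASS_FORWARDED,
    CLASS_NONE,
    CLASS_REINFORCED,
    CountMatrix,
)
from .prep import SizeFactors

LOG2 = np.log(2.0)


def estimate_dispersion(
    counts: CountMatrix, groups, size_fac: SizeFactors | None = None, shrink: bool = False
) -> pd.Series:
    """Method-of-moments per-gene NB dispersion.

    On size-factor-normalized counts, ``alpha_g = max((pooled within-group
    variance - mean) / mean^2, 1e-8)``.  Genes with all-zero counts are
    returned as NaN (not testable).

    With ``shrink=True`` the raw per-gene values are moderated toward a
    mean-dispersion trend ``a0 + a1 / mean`` by an empirical-Bayes
    log-normal shrinkage: the posterior log-dispersion weighs the gene
    estimate and the trend by their variances, with the sampling variance
    of a log-dispersion estimate approximated as ``trigamma((m - 2) / 2)``
    for ``m`` samples.  With few replicates the raw estimator is noisy
    enough to cost real power; moderation recovers most of it.
    """
    if size_fac is None:
        from .prep import size_factors as _sf

        size_fac = _sf(counts)
    k = counts.values().astype(float) / size_fac.to_numpy()[None, :]
    g = np.asarray(groups)
    levels = np.unique(g)
    if min((g == lv).sum() for lv in levels) < 2:
        raise ValueError("need >=2 replicates per group to estimate dispersion")
    num = np.zeros(k.shape[0])
    den = 0.0
    for lv in levels:
        sub = k[:, g == lv]
        num += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        den += sub.shape[1] - 1
    pooled_var = num / den
    mean = k.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    raw = np.maximum(alpha, ALPHA_FLOOR)
    raw[mean <= 0] = np.nan
    if shrink:
        raw = _shrink_dispersion(raw, mean, n_samples=k.shape[1], n_groups=len(levels))
    return pd.Series(raw, index=counts.genes, name="dispersion")


def _shrink_dispersion(raw: np.ndarray, mean: np.ndarray, n_samples: int, n_groups: int) -> np.ndarray:
    """Empirical-Bayes moderation of raw dispersions toward an
    ``a0 + a1/mean`` trend (log-normal prior around the trend)."""
    from scipy.special import polygamma

    ok = np.isfinite(raw) & (mean > 0)
    use = ok & (raw > 10 * ALPHA_FLOOR)  # floored genes carry no information
    if use.sum() < 10:
        return raw
    # robust two-pass least squares for the trend
    X = np.column_stack([np.ones(use.sum()), 1.0 / mean[use]])
    yv = raw[use]
    keep = np.ones(len(yv), dtype=bool)
    coef = np.array([np.median(yv), 0.0])
    for _ in range(2):
        c, *_ = np.linalg.lstsq(X[keep], yv[keep], rcond=None)
        c[0] = max(c[0], 1e-6)
        c[1] = max(c[1], 0.0)
        fit = X @ c
        resid = np.log(yv / fit)
        keep = np.abs(resid - np.median(resid)) < 2.0 * 1.4826 * np.median(
            np.abs(resid - np.median(resid))
        ) + 1e-12
        coef = c
    trend = np.maximum(coef[0] + coef[1] / np.where(mean > 0, mean, 1.0), 1e-8)
    df = max(n_samples - n_groups, 1)
    var_samp = float(polygamma(1, df / 2.0))
    log_resid = np.log(raw[use] / trend[use])
    mad = np.median(np.abs(log_resid - np.median(log_resid))) * 1.4826
    var_prior = max(mad**2 - var_samp, 0.0625)
    w = var_prior / (var_prior + var_samp)  # weight on the per-gene estimate
    out = raw.copy()
    out[use] = np.exp(w * np.log(raw[use]) + (1 - w) * np.log(trend[use]))
    out[ok & ~use] = trend[ok & ~use]  # floored genes fall back to the trend
    return out


def nb_wald_test(
    counts: CountMatrix,
    size_fac: SizeFactors,
    dispersions: pd.Series,
    groups=None,
    reference: str = "BN",
) -> pd.DataFrame:
    """Per-gene NB Wald test of the strain effect for one assay.

    Returns a DataFrame with ``log2fc`` (non-reference over reference),
    ``se`` (log2 scale), ``stat``, ``pvalue`` and ``testable``.  Genes with
    undefined dispersion or an all-zero strain are flagged not testable
    (NaN p) and are excluded from multiple testing downstream.
    """
    if groups is None:
        groups = counts.strain_indicator(reference)
    g = np.asarray(groups)
    if len(np.unique(g)) != 2 or min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need two groups with >=2 samples each")
    alpha = dispersions.reindex(counts.genes).to_numpy()
    testable = np.isfinite(alpha)
    y = counts.values().astype(float)
    s = size_fac.to_numpy()
    res = nb_two_group_wald(
        y, s[None, :], np.where(testable, alpha, 1.0), g
    )
    out = pd.DataFrame(
        {
            "log2fc": res["beta"] / LOG2,
            "se": res["se"] / LOG2,
            "stat": res["z"],
            "pvalue": res["p"],
        },
        index=counts.genes,
    )
    out.loc[~testable, ["log2fc", "se", "stat", "pvalue"]] = np.nan
    out["testable"] = testable & np.isfinite(out["pvalue"])
    return out


def adjust_and_call(de: pd.DataFrame, method: str = "bonferroni", threshold: float = 0.01) -> pd.DataFrame:
    """Multiple-testing adjustment over testable genes plus the DE flag.

    ``method`` is ``"bonferroni"`` or ``"BH"``; genes flagged not testable
    keep NaN adjusted p and a False flag and do not count toward the
    correction denominator.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    out = de.copy()
    mask = out["testable"].to_numpy() if "testable" in out else np.isfinite(out["pvalue"].to_numpy())
    padj = np.full(len(out), np.nan)
    if mask.any():
        padj[mask] = multipletests(out.loc[mask, "pvalue"].to_numpy(), method=key)[1]
    out["padj"] = padj
    out["de"] = (padj <= threshold) & mask
    return out


def average_rna_fc(de_rna1: pd.DataFrame, de_rna2: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the two RNA-seq log2 fold changes.

    Genes testable in only one assay get that assay's value (the mean of
    the available values); genes testable in neither are NaN.
    """
    if not de_rna1.index.equals(de_rna2.index):
        raise ValueError("RNA DE tables must share the same gene universe")
    both = pd.concat([de_rna1["log2fc"], de_rna2["log2fc"]], axis=1)
    return both.mean(axis=1, skipna=True).rename("rna_fc")


def classify_genes(
    de_rna1: pd.DataFrame, de_rna2: pd.DataFrame, de_ribo: pd.DataFrame
) -> pd.DataFrame:
    """Three-way regulatory classification from the per-assay DE flags.

    Classes: RNA+RIBO (DE in both RNA assays and Ribo-seq), RNA_only (DE in
    both RNA assays, not in Ribo-seq), RIBO_only (DE in Ribo-seq only),
    none (no DE anywhere), discordant (any other pattern).  Genes not
    testable in all three assays are excluded with a reason.
    """
    idx = de_rna1.index
    if not (idx.equals(de_rna2.index) and idx.equals(de_ribo.index)):
        raise ValueError("DE tables must share the same gene universe")
    for d in (de_rna1, de_rna2, de_ribo):
        if "de" not in d:
            raise ValueError("run adjust_and_call before classification")
    f1 = de_rna1["de"].to_numpy()
    f2 = de_rna2["de"].to_numpy()
    fr = de_ribo["de"].to_numpy()
    testable = (
        de_rna1["testable"].to_numpy()
        & de_rna2["testable"].to_numpy()
        & de_ribo["testable"].to_numpy()
    )

    label = np.full(len(idx), CLASS_DISCORDANT, dtype=object)
    label[f1 & f2 & fr] = CLASS_FORWARDED
    label[f1 & f2 & ~fr] = CLASS_BUFFERED
    label[~f1 & ~f2 & fr] = CLASS_REINFORCED
    label[~f1 & ~f2 & ~fr] = CLASS_NONE
    label[~testable] = "excluded"

    rna_fc = average_rna_fc(de_rna1, de_rna2)
    out = pd.DataFrame(
        {
            "class_label": label,
            "rna_fc": rna_fc,
            "ribo_fc": de_ribo["log2fc"],
            "testable": testable,
            "exclude_reason": np.where(testable, "", "not testable in all assays"),
        },
        index=idx,
    )
    return out


def fc_correlation(rna_fc, ribo_fc):
    """Pearson correlation between RNA and Ribo fold changes with its
    two-sided t-based p-value; genome-wide concordance diagnostic."""
    x = np.asarray(rna_fc, dtype=float)
    y = np.asarray(ribo_fc, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >=3 genes with both fold changes")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in fold changes")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def run_de(
    counts: CountMatrix,
    method: str = "bonferroni",
    threshold: float = 0.01,
    reference: str = "BN",
) -> pd.DataFrame:
    """Convenience: size factors + dispersion + Wald + adjustment for one assay."""
    from .prep import size_factors as _sf

    sf = _sf(counts)
    groups = counts.strain_indicator(reference)
    disp = estimate_dispersion(counts, groups, sf, shrink=True)
    de = nb_wald_test(counts, sf, disp, groups)
    return adjust_and_call(de, method=method, threshold=threshold)
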