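"""Quantifying translational regulation.

The central quantity is the standardized major-axis (SMA) slope of Ribo-seq
fold changes on RNA-seq fold changes within a gene class.  SMA treats both
axes as error-bearing: the slope is ``sign(r) * sd(y) / sd(x)``.  A slope
near 1 means transcriptional differences are forwarded unchanged to
translation; slopes above/below 1 mean reinforcement/buffering.  Classes
are compared with a likelihood-ratio test of a common SMA slope under a
bivariate-normal model (profile likelihood over the shared slope).

Translational efficiency (TE) is the ratio of normalized Ribo-seq to
RNA-seq read density over the coding sequence, on an FPKM scale so UTR
length cannot distort the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CountMatrix


@dataclass
class SMAFit:
    slope: float
    intercept: float
    r: float
    n: int
    ci: tuple  # 95% CI of the slope


def _moments(x: np.ndarray, y: np.ndarray):
    """ML (divide-by-n) second moments used by the SMA likelihood."""
    n = x.size
    sxx = x.var()
    syy = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return n, sxx, sxy, syy


def sma_fit(x, y, alpha: float = 0.05, r_floor: float = 0.05) -> SMAFit:
    """Standardized major-axis fit of y on x.

    slope = sign(r) * sd(y) / sd(x); the confidence interval uses the
    standard SMA pivot ``b * (sqrt(B+1) +/- sqrt(B))`` with
    ``B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need n >= 3 finite pairs")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) < r_floor:
        import warnings

        warnings.warn(f"|r| = {abs(r):.3g} below {r_floor}; SMA slope is unstable")
    sign = 1.0 if r >= 0 else -1.0
    b = sign * float(np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(y.mean() - b * x.mean())
    n = x.size
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r**2) / (n - 2)
    lo, hi = sorted((b * (np.sqrt(B + 1) - np.sqrt(B)), b * (np.sqrt(B + 1) + np.sqrt(B))))
    return SMAFit(slope=b, intercept=intercept, r=r, n=n, ci=(float(lo), float(hi)))


def _profile_loglik(b: float, n: int, sxx: float, sxy: float, syy: float) -> float:
    """Max bivariate-normal log-likelihood over (scale, correlation) with the
    covariance constrained so the SMA slope equals ``b`` (syy = b^2 sxx).

    Closed form: rho* = 2 b sxy / (b^2 sxx + syy);
    c* = (b^2 sxx - 2 rho* b sxy + syy) / (2 b^2 (1 - rho*^2)).
    """
    rho = 2.0 * b * sxy / (b * b * sxx + syy)
    rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    c = (b * b * sxx - 2.0 * rho * b * sxy + syy) / (2.0 * b * b * (1.0 - rho * rho))
    det = b * b * c * c * (1.0 - rho * rho)
    return -0.5 * n * (np.log(det) + 2.0) - n * np.log(2.0 * np.pi)


def _group_max_loglik(n: int, sxx: float, sxy: float, syy: float) -> float:
    det = sxx * syy - sxy * sxy
    return -0.5 * n * (np.log(det) + 2.0) - n * np.log(2.0 * np.pi)


def sma_common_slope_test(groups: list) -> dict:
    """Likelihood-ratio test that all groups share one SMA slope.

    ``groups`` is a list of ``(x, y)`` pairs (one per gene class).  The
    statistic is ``-2 (l_common - sum l_group)`` where the common-slope
    likelihood profiles a single slope across groups; it is referred to a
    chi-square with ``len(groups) - 1`` degrees of freedom.

    Returns ``{"statistic", "df", "pvalue", "common_slope", "slopes"}``.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    moms, slopes = [], []
    for i, (x, y) in enumerate(groups):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or x.var() == 0 or y.var() == 0:
            raise ValueError(f"group {i} fails SMA preconditions (n>=3, positive variance)")
        n, sxx, sxy, syy = _moments(x, y)
        moms.append((n, sxx, sxy, syy))
        slopes.append(np.sign(sxy if sxy != 0 else 1.0) * np.sqrt(syy / sxx))

    def neg_common(logab, sign):
        b = sign * np.exp(logab)
        return -sum(_profile_loglik(b, *m) for m in moms)

    best = None
    mags = np.abs(slopes)
    lo, hi = np.log(mags.min()) - 3.0, np.log(mags.max()) + 3.0
    for sign in (1.0, -1.0):
        res = optimize.minimize_scalar(neg_common, args=(sign,), bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-12})
        if best is None or res.fun < best[0]:
            best = (res.fun, sign * np.exp(res.x))
    l_common = -best[0]
    l_sep = sum(_group_max_loglik(*m) for m in moms)
    lam = max(0.0, 2.0 * (l_sep - l_common))
    df = len(groups) - 1
    p = float(stats.chi2.sf(lam, df))
    return {
        "statistic": float(lam),
        "df": df,
        "pvalue": p,
        "common_slope": float(best[1]),
        "slopes": [float(s) for s in slopes],
    }


def fpkm(counts: CountMatrix, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads, per sample."""
    lens = lengths.reindex(counts.genes)
    depth = counts.counts.sum(axis=0).to_numpy(dtype=float)
    return counts.counts / (lens.to_numpy()[:, None] / 1e3) / (depth[None, :] / 1e6)


def translational_efficiency(
    ribo: CountMatrix,
    rna1: CountMatrix,
    rna2: CountMatrix,
    cds_lengths: pd.Series,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene TE = mean Ribo CDS FPKM / mean RNA CDS FPKM.

    RNA density is the average of the two RNA-seq assays.  Genes below
    ``min_fpkm`` in either layer, or without a positive CDS length, are
    returned with ``te = NaN`` and ``defined = False`` (reason recorded).
    """
    genes = ribo.genes
    for cm in (rna1, rna2):
        if not cm.genes.equals(genes):
            raise ValueError("assays must share the same gene universe")
    lens = cds_lengths.reindex(genes)
    bad_len = ~(lens > 0) | ~np.isfinite(lens)
    safe_lens = lens.where(~bad_len, 1.0)

    ribo_f = fpkm(ribo, safe_lens).mean(axis=1)
    rna_f = (fpkm(rna1, safe_lens).mean(axis=1) + fpkm(rna2, safe_lens).mean(axis=1)) / 2.0
    low = (ribo_f < min_fpkm) | (rna_f < min_fpkm)
    defined = ~(bad_len.to_numpy() | low.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(defined, ribo_f / rna_f, np.nan)
    reason = np.where(bad_len, "no CDS length", np.where(low, f"FPKM < {min_fpkm}", ""))
    return pd.DataFrame(
        {"te": te, "ribo_fpkm": ribo_f, "rna_fpkm": rna_f, "defined": defined, "reason": reason},
        index=genes,
    )


def class_metric_compare(metric: pd.Series, classes: pd.Series, pair: tuple, sided: str = "two-sided"):
    """Mann-Whitney U comparison of a per-gene metric between two classes.

    Exact p for combined n <= 50 without ties, otherwise the normal
    approximation with tie correction.  ``sided`` is "two-sided", "greater"
    (first class stochastically larger) or "less".
    """
    a = metric[classes == pair[0]].dropna().to_numpy(dtype=float)
    b = metric[classes == pair[1]].dropna().to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty class in pair {pair}")
    combined = np.concatenate([a, b])
    ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 50 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=sided, method=method)
    return float(res.statistic), float(res.pvalue)
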