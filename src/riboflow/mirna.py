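"""miRNA differential expression and target enrichment.

miRNA libraries are normalized by upper-quartile scaling (the upper
quartile of each library's nonzero counts is brought to the geometric mean
of upper quartiles, counts rounded back to integers).  Differential
expression between strains uses a quasi-Poisson GLM: a Poisson log-link
fit whose standard errors are inflated by the Pearson dispersion, with a
t-reference — counts from small-RNA libraries are overdispersed, and a
plain Poisson test would be anticonservative.  Targets of DE miRNAs are
then tested for enrichment among translationally reinforced (RIBO_only)
versus forwarded (RNA+RIBO) genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CLASS_FORWARDED, CLASS_REINFORCED, CountMatrix

#: Sentinel returned when no miRNA passes the DE filter.
NO_DE_MIRNAS = "no DE miRNAs"


def quantile_scale(counts: CountMatrix, quantile: float = 0.75) -> CountMatrix:
    """Quantile-based count scaling (upper quartile by default).

    Each library is multiplied by ``geomean(UQ) / UQ_j`` where ``UQ_j`` is
    the ``quantile`` of that library's nonzero counts, then rounded to
    integers.  Raises if a library has no nonzero counts.
    """
    k = counts.values().astype(float)
    uq = np.empty(k.shape[1])
    for j in range(k.shape[1]):
        nz = k[:, j][k[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"library {counts.samples[j]!r} has all-zero counts")
        uq[j] = np.quantile(nz, quantile)
    target = np.exp(np.mean(np.log(uq)))
    scaled = np.rint(k * (target / uq)[None, :]).astype(np.int64)
    return CountMatrix(
        pd.DataFrame(scaled, index=counts.genes, columns=counts.samples),
        counts.sample_meta.copy(),
    )


def quasipoisson_de(scaled: CountMatrix, reference: str = "BN") -> pd.DataFrame:
    """Quasi-Poisson strain test per miRNA on scaled counts.

    For the two-group log-link design the Poisson MLE group means are the
    sample means; the strain coefficient is ``ln(mean_1 / mean_0)`` with
    ``SE^2 = phi * (1/T0 + 1/T1)`` (group totals T), where the dispersion
    ``phi`` is the Pearson chi-square over ``n - 2``.  The coefficient is
    referred to a t distribution with ``n - 2`` df and BH-adjusted.
    miRNAs with an all-zero group are not estimable and are excluded from
    the adjustment (reported with NaN p).
    """
    g = scaled.strain_indicator(reference)
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need >=2 replicates per strain")
    y = scaled.values().astype(float)
    n = y.shape[1]
    t0 = y[:, g == 0].sum(axis=1)
    t1 = y[:, g == 1].sum(axis=1)
    n0, n1 = int((g == 0).sum()), int((g == 1).sum())
    m0, m1 = t0 / n0, t1 / n1
    mu = np.where(g[None, :] == 0, m0[:, None], m1[:, None])
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = ((y - mu) ** 2 / mu).sum(axis=1) / df
        coef = np.log(m1 / m0)
        se = np.sqrt(np.maximum(phi, 1e-12) * (1.0 / t0 + 1.0 / t1))
        tstat = coef / se
    estimable = (t0 > 0) & (t1 > 0)
    p = np.where(estimable, 2.0 * stats.t.sf(np.abs(tstat), df), np.nan)
    out = pd.DataFrame(
        {
            "coef": np.where(estimable, coef, np.nan),
            "log2fc": np.where(estimable, coef / np.log(2.0), np.nan),
            "phi": np.where(estimable, phi, np.nan),
            "pvalue": p,
            "estimable": estimable,
        },
        index=scaled.genes,
    )
    q = np.full(len(out), np.nan)
    if estimable.any():
        q[estimable] = multipletests(p[estimable], method="fdr_bh")[1]
    out["qvalue"] = q
    return out


def fisher_combine(pvalues) -> dict:
    """Fisher's method: X^2 = -2 sum(ln p) ~ chi-square(2k)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0 or np.any(~np.isfinite(p)) or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    x2 = float(-2.0 * np.log(p).sum())
    return {"statistic": x2, "df": 2 * p.size, "pvalue": float(stats.chi2.sf(x2, 2 * p.size))}


def target_enrichment(
    de_mirnas,
    targets: dict,
    classes_by_tissue: dict,
    class_a: str = CLASS_REINFORCED,
    class_b: str = CLASS_FORWARDED,
    yates: bool = False,
):
    """Enrichment of DE-miRNA targets among reinforced vs forwarded genes.

    ``de_mirnas`` is the set of differentially expressed miRNA ids,
    ``targets`` maps miRNA id -> target gene set, and ``classes_by_tissue``
    maps tissue name -> per-gene class-label Series.  Per tissue, genes of
    the two classes are cross-tabulated against membership in the union of
    DE-miRNA target sets; Fisher's exact test and the chi-square test are
    both reported, and tissue-level Fisher p-values are combined with
    Fisher's method.

    Returns the sentinel string ``NO_DE_MIRNAS`` when ``de_mirnas`` is
    empty.
    """
    de_mirnas = set(de_mirnas)
    if not de_mirnas:
        return NO_DE_MIRNAS
    union = set()
    for m in de_mirnas:
        union |= set(targets.get(m, ()))
    per_tissue = {}
    fisher_ps = []
    for tissue, classes in classes_by_tissue.items():
        genes_a = classes.index[classes == class_a]
        genes_b = classes.index[classes == class_b]
        if len(genes_a) == 0 or len(genes_b) == 0:
            raise ValueError(f"empty class in tissue {tissue!r}")
        a_t = sum(g in union for g in genes_a)
        b_t = sum(g in union for g in genes_b)
        table = np.array([[a_t, len(genes_a) - a_t], [b_t, len(genes_b) - b_t]])
        orat, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        try:
            chi2_res = stats.chi2_contingency(table, correction=yates)
            chi2_p = float(chi2_res.pvalue)
        except ValueError:  # a zero margin
            chi2_p = np.nan
        per_tissue[tissue] = {
            "table": table,
            "odds_ratio": float(orat) if np.isfinite(orat) else np.inf,
            "fisher_p": float(fisher_p),
            "chi2_p": chi2_p,
        }
        fisher_ps.append(fisher_p)
    combined = fisher_combine(fisher_ps)
    return {"per_tissue": per_tissue, "combined": combined, "n_target_union": len(union)}
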