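"""eQTL mapping by NB trait-marker regression over a recombinant-inbred panel.

For each gene and biallelic marker, a negative-binomial regression of the
expression counts on the genotype indicator (log link, size-factor
offsets, fixed per-gene dispersion) is compared with an intercept-only
null via the likelihood ratio.  Significance of the per-gene maximum LR
over markers is assessed by permuting strain labels — the permutation unit
is the whole expression vector, so the marker correlation structure
(linkage disequilibrium) is preserved exactly under the null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._nb import fit_log_mean, group_loglik
from .containers import CountMatrix


def _lr_scan(y: np.ndarray, geno: np.ndarray, offsets: np.ndarray, alpha: float) -> np.ndarray:
    """LR statistics for one (possibly permuted) expression vector.

    ``y``/``offsets``: (..., n_strains); ``geno``: (n_markers, n_strains).
    Returns LR with shape (..., n_markers).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(offsets, dtype=float)
    b_null, _ = fit_log_mean(y, s, alpha)
    ll_null = group_loglik(y, s, alpha, b_null)
    ye = y[..., None, :]
    se = np.broadcast_to(s, y.shape)[..., None, :]
    m0 = geno[None, ...] == 0 if y.ndim > 1 else geno == 0
    b0, _ = fit_log_mean(ye, se, alpha, mask=m0)
    b1, _ = fit_log_mean(ye, se, alpha, mask=~m0)
    ll0 = group_loglik(ye, se, alpha, np.where(np.isfinite(b0), b0, -60.0), mask=m0)
    ll1 = group_loglik(ye, se, alpha, np.where(np.isfinite(b1), b1, -60.0), mask=~m0)
    lr = 2.0 * (ll0 + ll1 - ll_null[..., None])
    return np.maximum(lr, 0.0)


def nb_marker_lr(expr_counts, genotype_col, size_fac, dispersion: float) -> float:
    """Likelihood-ratio statistic of one gene against one marker.

    Full model: intercept + genotype; null: intercept only; NB likelihood
    with fixed dispersion and ``log(size factor)`` offsets.
    """
    y = np.asarray(expr_counts, dtype=float)
    g = np.asarray(genotype_col)
    if y.size < 8:
        raise ValueError("need >= 8 strains")
    if g.min() == g.max():
        raise ValueError("marker is monomorphic")
    s = np.asarray(size_fac, dtype=float)
    return float(_lr_scan(y, g[None, :], s, dispersion)[0])


def permutation_scan(
    expr_counts,
    genotypes,
    size_fac,
    dispersion: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation p-value for one gene's max-over-markers LR.

    ``p = (1 + #{permuted max >= observed max}) / (n_perm + 1)``, permuting
    the strain labels of the expression vector (offsets travel with their
    sample).  Deterministic given ``seed``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 limits the resolution of permutation p-values")
    y = np.asarray(expr_counts, dtype=float)
    geno = np.asarray(genotypes, dtype=np.int64)
    if geno.ndim != 2:
        raise ValueError("genotypes must be strains x markers")
    geno_t = geno.T  # markers x strains
    s = np.asarray(size_fac, dtype=float)
    rng = np.random.default_rng(seed)

    obs = _lr_scan(y, geno_t, s, dispersion)
    obs_max = float(obs.max())
    best = int(obs.argmax())

    idx = np.argsort(rng.random((n_perm, y.size)), axis=1)
    perm_lr = _lr_scan(y[idx], geno_t, s[idx], dispersion)
    perm_max = perm_lr.max(axis=-1)
    p = (1.0 + float((perm_max >= obs_max - 1e-9).sum())) / (n_perm + 1.0)
    return {"lr": obs_max, "best_marker": best, "pvalue": p, "lr_per_marker": obs}


def eqtl_scan(
    counts: CountMatrix,
    genotypes: pd.DataFrame,
    dispersions: pd.Series,
    n_perm: int = 200,
    seed: int = 0,
    fdr: float = 0.05,
    size_fac=None,
) -> pd.DataFrame:
    """Genome-wide scan: per gene, best marker, max LR, permutation p, BH q.

    Permutations are drawn independently per gene from a seeded stream.
    Genes whose dispersion is undefined (all-zero counts) are skipped.
    """
    strains = list(genotypes.index)
    if list(counts.samples) != strains:
        counts = CountMatrix(counts.counts[strains], counts.sample_meta.loc[strains])
    if size_fac is None:
        from .prep import size_factors as _sf

        size_fac = _sf(counts)
    s = size_fac.to_numpy()
    geno = genotypes.to_numpy(dtype=np.int64)
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(counts.genes))
    y_all = counts.values().astype(float)
    alpha_all = dispersions.reindex(counts.genes).to_numpy()
    for i, gene in enumerate(counts.genes):
        alpha = alpha_all[i]
        if not np.isfinite(alpha):
            rows.append((gene, -1, np.nan, np.nan))
            continue
        res = permutation_scan(
            y_all[i], geno, s, float(alpha), n_perm=n_perm, seed=int(child_seeds[i])
        )
        rows.append((gene, res["best_marker"], res["lr"], res["pvalue"]))
    out = pd.DataFrame(rows, columns=["gene", "best_marker", "lr", "pvalue"]).set_index("gene")
    ok = np.isfinite(out["pvalue"].to_numpy())
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok] = multipletests(out.loc[ok, "pvalue"].to_numpy(), method="fdr_bh")[1]
    out["qvalue"] = q
    out["eqtl"] = (out["qvalue"] <= fdr) & ok
    return out


def class_eqtl_enrichment(classes: pd.Series, eqtl_flags: pd.Series) -> pd.DataFrame:
    """Per-class 2x2 test of association between class membership and
    having an eQTL, against all remaining genes.

    Uses the chi-square test; falls back to Fisher's exact test when an
    expected cell count is below 1 (noted in the ``method`` column).
    """
    genes = classes.index.intersection(eqtl_flags.index)
    cls = classes.loc[genes]
    flag = eqtl_flags.loc[genes].astype(bool)
    rows = []
    for label in sorted(cls.unique()):
        inc = cls == label
        table = np.array(
            [
                [int((inc & flag).sum()), int((inc & ~flag).sum())],
                [int((~inc & flag).sum()), int((~inc & ~flag).sum())],
            ]
        )
        expected = stats.contingency.expected_freq(table) if table.sum() else np.zeros((2, 2))
        if table.sum() and expected.min() >= 1.0:
            res = stats.chi2_contingency(table, correction=False)
            stat, p, method = float(res.statistic), float(res.pvalue), "chi2"
        else:
            _, p = stats.fisher_exact(table)
            stat, method = np.nan, "fisher (low expected count)"
        n_class = int(inc.sum())
        rows.append(
            {
                "class_label": label,
                "n": n_class,
                "n_eqtl": int((inc & flag).sum()),
                "statistic": stat,
                "pvalue": float(p),
                "method": method,
            }
        )
    return pd.DataFrame(rows).set_index("class_label")
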