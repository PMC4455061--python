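"""Conditional-independence tests for the RNA -> translation -> protein chain.

If translation fully mediates the effect of transcript levels on protein
levels, then across genes RNA and protein are conditionally independent
given Ribo-seq: the partial correlation rho(RNA, protein | Ribo) is zero,
while rho(Ribo, protein | RNA) stays large.  Under a joint Gaussian model
a zero partial correlation is equivalent to conditional independence, and
the coefficient can be computed by correlating the residuals of each
variable regressed on the conditioning one; significance uses the
t-distribution with n - 3 degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix


def partial_correlation(x, y, z) -> dict:
    """Partial correlation of x and y given z by the residual method.

    Returns ``{"rho", "t", "df", "pvalue", "n"}``; df = n - 3.  Raises if
    x or y is (numerically) an exact linear function of z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 complete observations")
    zc = np.column_stack([np.ones(n), z])
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    scale = max(x.var(), 1e-30)
    if rx.var() <= 1e-12 * scale or ry.var() <= 1e-12 * max(y.var(), 1e-30):
        raise ValueError("degenerate conditioning: residual variance is zero")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = rho * np.sqrt(df / max(1.0 - rho * rho, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return {"rho": rho, "t": float(t), "df": df, "pvalue": p, "n": n}


def partial_correlation_precision(x, y, z) -> float:
    """Same coefficient from the inverse covariance matrix:
    ``-Omega_xy / sqrt(Omega_xx * Omega_yy)``.  Cross-check route."""
    m = np.cov(np.vstack([x, y, z]))
    omega = np.linalg.inv(m)
    return float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))


def strain_log_means(counts: CountMatrix, pseudo: float = 0.5) -> pd.DataFrame:
    """Log mean CPM per gene per strain (one column per strain)."""
    cpm = counts.counts / counts.counts.sum(axis=0) * 1e6
    strains = counts.sample_meta["strain"]
    cols = {s: np.log(cpm.loc[:, (strains == s).to_numpy()].mean(axis=1) + pseudo)
            for s in sorted(strains.unique())}
    return pd.DataFrame(cols, index=counts.genes)


def conditional_independence_suite(
    rna: pd.DataFrame, ribo: pd.DataFrame, protein: pd.DataFrame
) -> pd.DataFrame:
    """All three partial-correlation tests, per strain.

    Inputs are gene x strain frames of log-scale values (RNA = average of
    the two RNA assays, already expression-filtered); only shared genes and
    strains are used.  For each strain the table reports
    rho(RNA, protein | Ribo), rho(Ribo, protein | RNA) and
    rho(RNA, Ribo | protein) with t-based p-values.
    """
    genes = rna.index.intersection(ribo.index).intersection(protein.index)
    if len(genes) < 4:
        raise ValueError("fewer than 4 genes shared across the three layers")
    strains = [s for s in rna.columns if s in ribo.columns and s in protein.columns]
    rows = []
    for strain in strains:
        r = rna.loc[genes, strain].to_numpy()
        b = ribo.loc[genes, strain].to_numpy()
        p = protein.loc[genes, strain].to_numpy()
        for pair, given, (vx, vy, vz) in (
            (("RNA", "protein"), "Ribo", (r, p, b)),
            (("Ribo", "protein"), "RNA", (b, p, r)),
            (("RNA", "Ribo"), "protein", (r, b, p)),
        ):
            res = partial_correlation(vx, vy, vz)
            rows.append(
                {
                    "strain": strain,
                    "pair": f"{pair[0]}~{pair[1]}",
                    "given": given,
                    "rho": res["rho"],
                    "t": res["t"],
                    "df": res["df"],
                    "pvalue": res["pvalue"],
                    "n": res["n"],
                }
            )
    return pd.DataFrame(rows)


def protein_class_shift(
    protein_log_ratio: pd.Series,
    classes: pd.Series,
    ribo_fc: pd.Series,
    target_class: str = "RIBO_only",
) -> dict:
    """Protein-level confirmation of translationally driven differences.

    Splits the target-class genes by the direction of their Ribo-seq fold
    change and tests (one-sided Mann-Whitney) whether genes with higher
    ribosome occupancy in SHR also show higher SHR protein log-ratios —
    concordance of translation and protein levels.
    """
    sel = classes == target_class
    up = protein_log_ratio[sel & (ribo_fc > 0)].dropna()
    down = protein_log_ratio[sel & (ribo_fc < 0)].dropna()
    if len(up) < 2 or len(down) < 2:
        raise ValueError(
            "a direction group is (nearly) empty; consider a two-sided global test"
        )
    u, p = stats.mannwhitneyu(up, down, alternative="greater")
    return {"U": float(u), "pvalue": float(p), "n_up": int(len(up)), "n_down": int(len(down))}
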