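"""Vectorized negative-binomial (NB2) fitting primitives.

The NB parameterization throughout is mean/dispersion: for counts ``y`` with
mean ``mu`` and dispersion ``alpha``, ``Var(y) = mu + alpha * mu**2`` (the
DESeq-family convention).  All fits here are intercept-plus-group-indicator
models with a log link and known per-sample offsets (size factors), which
reduce to one scalar log-mean parameter per group.  They are solved by
Fisher scoring, vectorized over an arbitrary number of leading axes so that
thousands of genes (or permutations, or markers) are fit simultaneously.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

ALPHA_FLOOR = 1e-8


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Elementwise NB2 log-likelihood; broadcasts over all arguments."""
    y = np.asarray(y, dtype=np.float64)
    mu = np.maximum(np.asarray(mu, dtype=np.float64), 1e-300)
    alpha = np.maximum(np.asarray(alpha, dtype=np.float64), ALPHA_FLOOR)
    r = 1.0 / alpha
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def fit_log_mean(
    y: np.ndarray,
    offsets: np.ndarray,
    alpha,
    mask: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-12,
):
    """Solve the NB score equation for a single log-mean parameter.

    Model: ``y_j ~ NB(mean = s_j * exp(beta), dispersion = alpha)`` over the
    samples selected by ``mask`` along the last axis.  Returns ``(beta, W)``
    where ``W = sum_j s_j e^beta / (1 + alpha s_j e^beta)`` is the Fisher
    information of ``beta`` at the optimum.

    All inputs broadcast; the last axis indexes samples.  Cells where the
    masked counts are all zero get ``beta = -inf`` and ``W = 0``.
    """
    y = np.asarray(y, dtype=np.float64)
    off = np.asarray(offsets, dtype=np.float64)
    mk = None if mask is None else np.asarray(mask, dtype=np.float64)
    shape = np.broadcast_shapes(
        y.shape, off.shape, *(() if mk is None else (mk.shape,))
    )
    s = np.broadcast_to(off, shape)
    y = np.broadcast_to(y, shape)
    m = np.ones(shape) if mk is None else np.broadcast_to(mk, shape)
    a = np.maximum(np.asarray(alpha, dtype=np.float64), ALPHA_FLOOR)
    a = a[..., None] if a.ndim and a.shape == y.shape[:-1] else a

    tot_y = (m * y).sum(axis=-1)
    tot_s = (m * s).sum(axis=-1)
    empty = (tot_y <= 0) | (tot_s <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(np.where(empty, 1.0, tot_y) / np.where(tot_s > 0, tot_s, 1.0))
    beta = np.where(empty, 0.0, beta)  # placeholder; fixed up at the end

    for _ in range(max_iter):
        mu = s * np.exp(beta)[..., None]
        denom = 1.0 + a * mu
        U = (m * (y - mu) / denom).sum(axis=-1)
        W = (m * mu / denom).sum(axis=-1)
        step = np.where(W > 0, U / np.where(W > 0, W, 1.0), 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.all(np.abs(step) < tol):
            break

    mu = s * np.exp(beta)[..., None]
    W = (m * mu / (1.0 + a * mu)).sum(axis=-1)
    beta = np.where(empty, -np.inf, beta)
    W = np.where(empty, 0.0, W)
    return beta, W


def group_loglik(y, offsets, alpha, beta, mask=None):
    """Summed NB log-likelihood of masked samples at ``mu = s*exp(beta)``."""
    y = np.asarray(y, dtype=np.float64)
    s = np.asarray(offsets, dtype=np.float64)
    a = np.asarray(alpha, dtype=np.float64)
    a = a[..., None] if a.ndim and a.shape == np.broadcast_shapes(y.shape, s.shape)[:-1] else a
    with np.errstate(over="ignore"):
        mu = s * np.exp(np.asarray(beta)[..., None])
    ll = nb_loglik(y, mu, a)
    if mask is not None:
        ll = ll * mask
    return ll.sum(axis=-1)


def nb_two_group_wald(y, offsets, alpha, group):
    """Wald test of a strain (group) effect in the two-group NB model.

    ``group`` is a 0/1 indicator along the sample axis.  Returns a dict with
    natural-log effect ``beta`` (group1 minus group0), its standard error,
    Wald ``z`` and the two-sided normal p-value, broadcast over leading axes.
    Genes with an all-zero group are flagged non-estimable (NaN).
    """
    g = np.asarray(group)
    b0, w0 = fit_log_mean(y, offsets, alpha, mask=(g == 0))
    b1, w1 = fit_log_mean(y, offsets, alpha, mask=(g == 1))
    ok = np.isfinite(b0) & np.isfinite(b1) & (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / np.where(w0 > 0, w0, np.nan) + 1.0 / np.where(w1 > 0, w1, np.nan))
        beta = b1 - b0
        z = beta / se
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    beta = np.where(ok, beta, np.nan)
    se = np.where(ok, se, np.nan)
    z = np.where(ok, z, np.nan)
    p = np.where(ok, p, np.nan)
    return {"beta": beta, "se": se, "z": z, "p": p, "b0": b0, "b1": b1}
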