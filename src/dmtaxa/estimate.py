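"""Method-of-moments and maximum-likelihood estimation of (pi, theta).

The moment estimator of ``pi`` is the read-weighted average of per-sample
taxa frequencies, i.e. column totals over the grand total. The moment
estimator of ``theta`` is the pooled between/within mean-square ratio in the
Weir-Hill style: per taxon, the between-sample mean square of frequencies
(read-weighted) is compared with the within-sample binomial mean square, and
the ratios are pooled over taxa. The MLE maximizes the DM log-likelihood
numerically over the simplex x [0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model import DMParams, dm_log_pmf_matrix
from .table import TaxaCountTable

__all__ = [
    "DMEstimate",
    "estimate_pi_mom",
    "estimate_theta_mom",
    "fit_mom",
    "estimate_mle",
    "log_likelihood",
]


@dataclass(frozen=True)
class DMEstimate:
    """A fitted (pi, theta) pair with fit metadata.

    ``theta_raw`` keeps the untruncated moment estimate (possibly negative)
    as a diagnostic; ``params.theta`` is truncated into [0, 1).
    """

    params: DMParams
    method: str
    n_samples: int
    total_reads: int
    loglik: float | None = None
    theta_raw: float | None = None
    converged: bool = True


def _drop_empty_samples(table: TaxaCountTable) -> TaxaCountTable:
    totals = table.row_totals
    if np.all(totals > 0):
        return table
    keep = np.flatnonzero(totals > 0)
    dropped = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
    warnings.warn(
        f"dropping {len(dropped)} zero-read sample(s) before estimation: {dropped}",
        stacklevel=3,
    )
    if keep.size == 0:
        raise ValueError("all samples have zero reads")
    return table.select_samples(list(keep))


def estimate_pi_mom(table: TaxaCountTable) -> np.ndarray:
    """Read-weighted mean frequency per taxon: column total / grand total."""
    table = _drop_empty_samples(table)
    return table.col_totals / table.grand_total


def estimate_theta_mom(table: TaxaCountTable, truncate: bool = True) -> float:
    """Pooled moment estimator of the overdispersion ``theta``.

    For taxon ``k`` with per-sample frequencies ``p_ik = X_ik / N_i`` and the
    pooled ``p_k``, the between mean square is
    ``S_k = sum_i N_i (p_ik - p_k)^2 / (P - 1)`` and the within mean square
    ``G_k = sum_i N_i p_ik (1 - p_ik) / (N - P)``. With the effective read
    depth ``n_c = (N - sum_i N_i^2 / N) / (P - 1)``,

        theta = sum_k (S_k - G_k) / sum_k (S_k + (n_c - 1) G_k).

    Negative estimates (no excess variation) are truncated to 0 unless
    ``truncate=False``.
    """
    table = _drop_empty_samples(table)
    if table.n_samples < 2:
        raise ValueError("theta estimation needs at least 2 samples")
    n_i = table.row_totals.astype(float)
    total = n_i.sum()
    p = table.n_samples
    freqs = table.counts / n_i[:, None]
    pooled = table.col_totals / total

    s_k = (n_i[:, None] * (freqs - pooled) ** 2).sum(axis=0) / (p - 1)
    g_k = (n_i[:, None] * freqs * (1.0 - freqs)).sum(axis=0) / (total - p)
    n_c = (total - np.sum(n_i**2) / total) / (p - 1)

    denom = np.sum(s_k + (n_c - 1.0) * g_k)
    if denom <= 0:
        return 0.0
    theta = float(np.sum(s_k - g_k) / denom)
    if truncate:
        return min(max(theta, 0.0), 1.0 - 1e-12)
    return theta


def log_likelihood(table: TaxaCountTable, params: DMParams) -> float:
    """DM log-likelihood of the table (samples independent)."""
    return float(dm_log_pmf_matrix(table.counts, params.pi, params.theta).sum())


def fit_mom(table: TaxaCountTable) -> DMEstimate:
    """Method-of-moments fit of both parameters."""
    table = _drop_empty_samples(table)
    pi = estimate_pi_mom(table)
    raw = estimate_theta_mom(table, truncate=False)
    theta = min(max(raw, 0.0), 1.0 - 1e-12)
    params = DMParams(pi, theta)
    return DMEstimate(
        params=params,
        method="mom",
        n_samples=table.n_samples,
        total_reads=table.grand_total,
        loglik=log_likelihood(table, params),
        theta_raw=raw,
    )


# -- MLE ---------------------------------------------------------------------

_LOGIT_CLIP = 30.0


def _pack(pi: np.ndarray, theta: float) -> np.ndarray:
    # log-ratio transform of pi (vs last component) + logit(theta)
    ref = pi[-1]
    z = np.log(np.clip(pi[:-1], 1e-12, None) / max(ref, 1e-12))
    t = np.log(theta / (1.0 - theta))
    return np.concatenate([z, [t]])


def _unpack(x: np.ndarray) -> tuple[np.ndarray, float]:
    z = np.clip(x[:-1], -_LOGIT_CLIP, _LOGIT_CLIP)
    e = np.exp(np.concatenate([z, [0.0]]))
    pi = e / e.sum()
    t = float(np.clip(x[-1], -_LOGIT_CLIP, _LOGIT_CLIP))
    theta = 1.0 / (1.0 + np.exp(-t))
    return pi, theta


def estimate_mle(
    table: TaxaCountTable,
    init: DMParams | None = None,
    tol: float = 1e-8,
) -> DMEstimate:
    """Maximum-likelihood fit of (pi, theta) by quasi-Newton optimization.

    Optimizes in unconstrained coordinates (additive log-ratio of ``pi``,
    logit of ``theta``) from several starts (the moment estimate, a uniform
    start, and ``init`` if given) and keeps the best. All-zero taxa are held
    at frequency 0. The returned log-likelihood is never allowed below the
    moment estimate's.
    """
    table = _drop_empty_samples(table)
    if table.n_samples < 2:
        raise ValueError("MLE needs at least 2 samples")
    present = table.col_totals > 0
    if present.sum() < 2:
        raise ValueError("MLE needs at least 2 observed taxa")
    sub = table.select_taxa(list(np.flatnonzero(present)))
    counts = sub.counts

    def neg_loglik(x: np.ndarray) -> float:
        pi, theta = _unpack(x)
        return -float(dm_log_pmf_matrix(counts, pi, theta).sum())

    mom = fit_mom(sub)
    k = counts.shape[1]
    starts = []
    if init is not None:
        pi0 = np.asarray(init.pi, dtype=float)[present]
        pi0 = np.clip(pi0, 1e-10, None)
        starts.append(_pack(pi0 / pi0.sum(), np.clip(init.theta, 1e-4, 0.9)))
    starts.append(
        _pack(np.clip(mom.params.pi, 1e-10, None), np.clip(mom.params.theta, 1e-4, 0.9))
    )
    starts.append(_pack(np.full(k, 1.0 / k), 0.05))

    best_x, best_val, converged = None, np.inf, False
    for x0 in starts:
        res = minimize(
            neg_loglik,
            x0,
            method="Nelder-Mead" if k <= 3 else "Powell",
            options={"xatol": 1e-8, "fatol": tol, "maxiter": 20000}
            if k <= 3
            else {"xtol": 1e-8, "ftol": tol, "maxiter": 20000},
        )
        # polish with BFGS on numerical gradients
        res2 = minimize(neg_loglik, res.x, method="BFGS", options={"gtol": 1e-8})
        cand = res2 if res2.fun <= res.fun else res
        if cand.fun < best_val:
            best_x, best_val = cand.x, float(cand.fun)
            converged = bool(cand.success or res.success)

    pi_hat, theta_hat = _unpack(best_x)
    loglik = -best_val
    if mom.loglik is not None and loglik < mom.loglik - 1e-6:
        # optimizer failed to beat the moment estimate; fall back to it
        pi_hat, theta_hat = mom.params.pi, mom.params.theta
        loglik = mom.loglik
        converged = False

    pi_full = np.zeros(table.n_taxa)
    pi_full[present] = pi_hat
    return DMEstimate(
        params=DMParams(pi_full, theta_hat),
        method="mle",
        n_samples=table.n_samples,
        total_reads=table.grand_total,
        loglik=loglik,
        converged=converged,
    )
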