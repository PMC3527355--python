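"""Hypothesis tests for taxa-frequency vectors under the DM model.

Four tests are provided:

* ``test_overdispersion`` — multinomial vs Dirichlet-multinomial
  (H0: theta = 0), a Pearson-type statistic over all samples and taxa.
* ``test_one_sample`` — H0: pi = pi0 against a stated reference vector,
  a generalized Wald statistic with a Moore-Penrose pseudo-inverse.
* ``test_two_samples`` — H0: pi_1 = pi_2 for two groups.
* ``test_several_samples`` — H0: pi_1 = ... = pi_J for J >= 2 groups,
  the ANOVA-style weighted quadratic form.

All Wald statistics use method-of-moments estimates: the covariance of a
group's mean frequency vector is the multinomial simplex covariance built
around the pooled null estimate, inflated by the group's design effect
``sum_i N_i (1 + (N_i - 1) theta_m) / N_m^2``. Because simplex covariances
are rank-deficient (rows sum to zero), inversion uses the Moore-Penrose
pseudo-inverse and the chi-square degrees of freedom equal the rank:
``K - 1`` for one- and two-group tests, ``(J - 1)(K - 1)`` for J groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Sequence

import numpy as np
from scipy import stats

from .estimate import estimate_pi_mom, estimate_theta_mom
from .model import DMParams
from .table import GroupedTables, TaxaCountTable, pool_rare_taxa

__all__ = [
    "TestResult",
    "test_overdispersion",
    "test_one_sample",
    "test_two_samples",
    "test_several_samples",
    "pairwise_comparisons",
]

#: relative singular-value cutoff for pseudo-inverse and rank decisions
_PINV_RTOL = 1e-12


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: float
    p_value: float
    method: str
    estimates: dict[str, DMParams] = field(default_factory=dict)
    notes: dict[str, Any] = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.method}: statistic = {self.statistic:.6g}, "
            f"df = {self.df:g}, p = {self.p_value:.4g}"
        )


def _pinv_and_rank(mat: np.ndarray) -> tuple[np.ndarray, int]:
    u, s, vt = np.linalg.svd(mat, hermitian=True)
    cutoff = _PINV_RTOL * (s[0] if s.size else 0.0)
    nz = s > cutoff
    inv = (vt[nz].T / s[nz]) @ u[:, nz].T
    return inv, int(nz.sum())


def _design_effect_scale(table: TaxaCountTable, theta: float) -> float:
    """``C = sum_i N_i (1 + (N_i - 1) theta) / N_tot^2`` — variance scale of pi-hat."""
    n_i = table.row_totals.astype(float)
    total = n_i.sum()
    return float(np.sum(n_i * (1.0 + (n_i - 1.0) * theta)) / total**2)


def _simplex_cov(pi: np.ndarray) -> np.ndarray:
    return np.diag(pi) - np.outer(pi, pi)


# ---------------------------------------------------------------------------
# Overdispersion test
# ---------------------------------------------------------------------------

def _pearson_var_known_pi(n: float, pi: np.ndarray) -> float:
    """Exact variance of the Pearson statistic for Multinomial(n, pi), pi known.

    Derived from multinomial factorial moments of ``U = sum_k X_k^2 / pi_k``
    (the statistic is ``U / n - n``); exact for any n and pi.
    """
    n2 = n * (n - 1.0)
    n3 = n2 * (n - 2.0)
    n4 = n3 * (n - 3.0)
    k = pi.size
    sum_sq = float(np.sum(pi**2))
    sum_inv = float(np.sum(1.0 / pi))
    # E[U^2], diagonal + off-diagonal fourth-moment contributions
    diag = n4 * sum_sq + 6.0 * n3 + 7.0 * n2 * k + n * sum_inv
    off = n4 * (1.0 - sum_sq) + 2.0 * n3 * (k - 1.0) + n2 * k * (k - 1.0)
    e_u = n * (k - 1.0) + n * n
    var_u = diag + off - e_u**2
    return var_u / n**2


def test_overdispersion(
    table: TaxaCountTable, null_moments: str = "analytic", n_boot: int = 2000,
    seed: int | None = None,
) -> TestResult:
    """Test H0: theta = 0 (multinomial) against overdispersion (theta > 0).

    The statistic is ``T = sum_i sum_k (X_ik - N_i pi_k)^2 / (N_i pi_k)``
    with ``pi`` the pooled moment estimate. With equal reads per sample the
    null is chi-square with ``(P - 1)(K - 1)`` degrees of freedom. With
    unequal reads the null is approximated by a moment-matched scaled
    chi-square: from the null mean ``mu`` and variance ``sigma^2`` of ``T``,
    the scale is ``c = sigma^2 / (2 mu)`` and the degrees of freedom
    ``nu = 2 mu^2 / sigma^2``, and ``T / c`` is referred to chi-square(nu).
    ``null_moments="bootstrap"`` estimates (mu, sigma^2) by parametric
    bootstrap under the fitted multinomial instead of the analytic moments.
    """
    if table.n_samples < 2:
        raise ValueError("overdispersion test needs at least 2 samples")
    dropped = [t for t, c in zip(table.taxon_labels, table.col_totals) if c == 0]
    if dropped:
        keep = np.flatnonzero(table.col_totals > 0)
        table = table.select_taxa(list(keep))
    if table.n_taxa < 2:
        raise ValueError("overdispersion test needs at least 2 observed taxa")

    pi = estimate_pi_mom(table)
    n_i = table.row_totals.astype(float)
    expected = n_i[:, None] * pi[None, :]
    t_stat = float(np.sum((table.counts - expected) ** 2 / expected))
    p_samples, k = table.n_samples, table.n_taxa
    df_equal = (p_samples - 1) * (k - 1)

    notes: dict[str, Any] = {}
    if dropped:
        notes["dropped_taxa"] = dropped

    if np.unique(n_i).size == 1:
        scale, df = 1.0, float(df_equal)
        notes["null"] = "chi-square (equal reads)"
    else:
        if null_moments == "bootstrap":
            rng = np.random.default_rng(seed)
            sims = np.empty(n_boot)
            for b in range(n_boot):
                x = rng.multinomial(n_i.astype(np.int64), np.broadcast_to(pi, (p_samples, k)))
                pb = x.sum(axis=0) / n_i.sum()
                eb = n_i[:, None] * pb[None, :]
                with np.errstate(divide="ignore", invalid="ignore"):
                    tb = np.where(eb > 0, (x - eb) ** 2 / eb, 0.0)
                sims[b] = tb.sum()
            mu, var = float(sims.mean()), float(sims.var(ddof=1))
            notes["null"] = f"moment-matched scaled chi-square (bootstrap, B={n_boot})"
        else:
            # Exact per-sample Pearson variances at the plug-in pi, minus the
            # mean/variance absorbed by estimating the pooled pi-hat; the
            # subtraction makes the approximation reduce to the classical
            # chi-square((P-1)(K-1)) homogeneity null when reads are large.
            mu = float(df_equal)
            var = float(
                sum(_pearson_var_known_pi(n, pi) for n in n_i) - 2.0 * (k - 1.0)
            )
            notes["null"] = "moment-matched scaled chi-square (analytic)"
        if var <= 0 or mu <= 0:  # degenerate matching; fall back to plain null
            scale, df = 1.0, float(df_equal)
            notes["null"] = "chi-square (moment matching degenerate)"
        else:
            scale = var / (2.0 * mu)
            df = 2.0 * mu**2 / var
    notes["scale"] = scale
    notes["statistic_normalized"] = t_stat / scale
    p_value = float(stats.chi2.sf(t_stat / scale, df))
    return TestResult(
        statistic=t_stat,
        df=df,
        p_value=p_value,
        method="overdispersion",
        estimates={"pooled": DMParams(pi, 0.0)},
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Generalized Wald tests
# ---------------------------------------------------------------------------

def test_one_sample(table: TaxaCountTable, pi0: Sequence[float]) -> TestResult:
    """Generalized Wald test of H0: pi = pi0 for one set of samples.

    The covariance of the mean frequency vector is evaluated under the null:
    ``Sigma = C (diag(pi0) - pi0 pi0^T)`` with the design-effect scale ``C``
    built from the moment estimate of theta. df = rank(Sigma).
    """
    pi0 = np.asarray(pi0, dtype=float)
    if pi0.size != table.n_taxa:
        raise ValueError(
            f"pi0 has length {pi0.size}, table has {table.n_taxa} taxa"
        )
    if np.any(pi0 < 0) or abs(pi0.sum() - 1.0) > 1e-8:
        raise ValueError("pi0 must be a probability vector summing to 1")
    if table.n_samples < 2:
        raise ValueError("one-sample test needs at least 2 samples")

    pi_hat = estimate_pi_mom(table)
    theta_hat = estimate_theta_mom(table)
    scale = _design_effect_scale(table, theta_hat)
    sigma = scale * _simplex_cov(pi0)
    inv, rank = _pinv_and_rank(sigma)
    diff = pi_hat - pi0
    stat = float(diff @ inv @ diff)
    p_value = float(stats.chi2.sf(stat, rank))
    return TestResult(
        statistic=stat,
        df=rank,
        p_value=p_value,
        method="one-sample",
        estimates={"sample": DMParams(pi_hat, theta_hat)},
        notes={"pi0": pi0},
    )


def _group_moments(groups: GroupedTables):
    """Per-group MoM estimates plus pooled-null covariance pieces.

    Returns aligned arrays after removing taxa absent from every group, the
    per-group mean vectors, covariances around the pooled estimate, and the
    per-group (pi, theta) estimates.
    """
    for name, t in groups:
        if t.n_samples < 2:
            raise ValueError(f"group {name!r} needs at least 2 samples")
    col_sums = np.sum([t.col_totals for t in groups.tables], axis=0)
    removed = [
        lab for lab, c in zip(groups.taxon_labels, col_sums) if c == 0
    ]
    if removed:
        keep = list(np.flatnonzero(col_sums > 0))
        groups = groups.map_tables(lambda t: t.select_taxa(keep))
        col_sums = col_sums[np.asarray(keep)]
    pooled_pi = col_sums / col_sums.sum()

    means, covs, ests = [], [], {}
    base = _simplex_cov(pooled_pi)
    for name, t in groups:
        pi_m = estimate_pi_mom(t)
        theta_m = estimate_theta_mom(t)
        means.append(pi_m)
        covs.append(_design_effect_scale(t, theta_m) * base)
        ests[name] = DMParams(pi_m, theta_m)
    k = pooled_pi.size
    return np.array(means), covs, ests, k, removed


def test_two_samples(groups: GroupedTables) -> TestResult:
    """Generalized Wald test of H0: pi_1 = pi_2 for two groups.

    Statistic ``(pi_1 - pi_2)^T (Sigma_1 + Sigma_2)^+ (pi_1 - pi_2)`` with
    each ``Sigma_m`` the simplex covariance at the pooled estimate scaled by
    the group's design effect; chi-square null with ``K - 1`` df.
    """
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    means, covs, ests, k, removed = _group_moments(groups)
    diff = means[0] - means[1]
    inv, _ = _pinv_and_rank(covs[0] + covs[1])
    stat = float(diff @ inv @ diff)
    df = k - 1
    notes: dict[str, Any] = {}
    if removed:
        notes["removed_taxa"] = removed
    return TestResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        method="two-sample",
        estimates=ests,
        notes=notes,
    )


def test_several_samples(groups: GroupedTables) -> TestResult:
    """Generalized Wald test of H0: pi_1 = ... = pi_J across J >= 2 groups.

    With weights ``W_m = Sigma_m^+`` and the weighted grand mean
    ``pi_bar = (sum W_m)^+ sum W_m pi_m``, the statistic is
    ``sum_m (pi_m - pi_bar)^T W_m (pi_m - pi_bar)`` on a chi-square null
    with ``(J - 1)(K - 1)`` df. For J = 2 it agrees with the two-group test.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    means, covs, ests, k, removed = _group_moments(groups)
    weights = [_pinv_and_rank(c)[0] for c in covs]
    w_sum = np.sum(weights, axis=0)
    w_sum_inv, _ = _pinv_and_rank(w_sum)
    grand = w_sum_inv @ np.sum(
        [w @ m for w, m in zip(weights, means)], axis=0
    )
    stat = float(
        sum((m - grand) @ w @ (m - grand) for m, w in zip(means, weights))
    )
    j = len(groups)
    df = (j - 1) * (k - 1)
    notes: dict[str, Any] = {}
    if removed:
        notes["removed_taxa"] = removed
    return TestResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        method="several-sample",
        estimates=ests,
        notes=notes,
    )


def pairwise_comparisons(
    groups: GroupedTables,
    adjustment: str = "bonferroni",
    pool_threshold: float | None = None,
) -> list[TestResult]:
    """Two-group tests on every pair of groups, with Bonferroni adjustment.

    The adjusted p-value is ``min(1, p * number_of_pairs)``. When
    ``pool_threshold`` is given, rare-taxa pooling is recomputed on each
    pair before testing (the pooled set depends on which groups are in play).
    """
    if len(groups) < 3:
        raise ValueError("pairwise comparisons apply to 3 or more groups")
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    pairs = list(combinations(range(len(groups)), 2))
    results = []
    for a, b in pairs:
        sub = GroupedTables((groups.groups[a], groups.groups[b]))
        if pool_threshold is not None:
            sub = pool_rare_taxa(sub, threshold=pool_threshold)
        res = test_two_samples(sub)
        notes = dict(res.notes)
        notes["pair"] = (groups.labels[a], groups.labels[b])
        notes["p_unadjusted"] = res.p_value
        notes["n_comparisons"] = len(pairs)
        p = res.p_value
        if adjustment == "bonferroni":
            p = min(1.0, p * len(pairs))
        results.append(
            TestResult(
                statistic=res.statistic,
                df=res.df,
                p_value=p,
                method=f"two-sample ({adjustment})",
                estimates=res.estimates,
                notes=notes,
            )
        )
    return results
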