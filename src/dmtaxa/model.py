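"""The Dirichlet-multinomial (DM) distribution in the (pi, theta) parameterization.

A microbiome sample with ``N`` reads over ``K`` taxa is modelled as
multinomial with a probability vector that itself varies between samples
following a Dirichlet distribution. ``pi`` is the vector of expected taxa
frequencies and ``theta`` in [0, 1) the overdispersion: the variance of a
taxon's count is inflated over the multinomial by the design effect
``1 + (N - 1) * theta``, so per-sample frequencies do not concentrate on
``pi`` as read depth grows when ``theta > 0``. ``theta = 0`` recovers the
plain multinomial. The equivalent Dirichlet concentration is
``alpha_k = pi_k * (1 - theta) / theta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .table import TaxaCountTable

__all__ = [
    "DMParams",
    "dm_log_pmf",
    "dm_log_pmf_matrix",
    "dm_sample",
    "pi_theta_to_alpha",
    "alpha_to_pi_theta",
]

_SIMPLEX_TOL = 1e-10


@dataclass(frozen=True)
class DMParams:
    """Expected taxa frequencies ``pi`` (simplex) and overdispersion ``theta``."""

    pi: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or pi.size < 1:
            raise ValueError("pi must be a 1-D vector")
        if np.any(pi < 0):
            raise ValueError("pi entries must be non-negative")
        if abs(pi.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"pi must sum to 1 (got {pi.sum()!r})")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError(f"theta must lie in [0, 1), got {self.theta!r}")
        pi = pi.copy()
        pi.setflags(write=False)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "theta", float(self.theta))

    @property
    def n_taxa(self) -> int:
        return self.pi.size


def pi_theta_to_alpha(params: DMParams) -> np.ndarray:
    """Dirichlet concentration ``alpha_k = pi_k (1 - theta) / theta``.

    Undefined at ``theta = 0`` (the multinomial limit has infinite
    concentration); callers must branch to the multinomial there.
    """
    if params.theta == 0.0:
        raise ValueError("alpha is infinite at theta = 0; use the multinomial")
    return params.pi * (1.0 - params.theta) / params.theta


def alpha_to_pi_theta(alpha: np.ndarray) -> DMParams:
    """Inverse map: ``pi = alpha / sum(alpha)``, ``theta = 1 / (1 + sum(alpha))``."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or alpha.sum() <= 0:
        raise ValueError("alpha must be non-negative with a positive sum")
    total = alpha.sum()
    return DMParams(alpha / total, 1.0 / (1.0 + total))


def _check_counts(x: np.ndarray, k: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape[-1] != k:
        raise ValueError(f"count vector length {x.shape[-1]} != len(pi) = {k}")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(x.dtype, np.integer):
        rounded = np.rint(x)
        if np.max(np.abs(x - rounded), initial=0.0) > 1e-9:
            raise ValueError("counts must be integers")
        x = rounded
    return x.astype(np.int64)


def dm_log_pmf_matrix(counts: np.ndarray, pi: np.ndarray, theta: float) -> np.ndarray:
    """Row-wise DM (or multinomial at theta=0) log-pmf for a count matrix.

    Taxa with ``pi_k = 0`` contribute probability 1 when their count is 0 and
    drive the log-pmf to ``-inf`` otherwise.
    """
    counts = np.atleast_2d(_check_counts(counts, len(pi)))
    pi = np.asarray(pi, dtype=float)
    n = counts.sum(axis=1)
    coeff = gammaln(n + 1.0) - gammaln(counts + 1.0).sum(axis=1)

    support = pi > 0
    impossible = (counts[:, ~support] > 0).any(axis=1)
    x = counts[:, support]
    p = pi[support]

    if theta == 0.0:
        body = (x * np.log(p)).sum(axis=1)
    else:
        alpha = p * (1.0 - theta) / theta
        a_total = (1.0 - theta) / theta
        body = (
            gammaln(a_total)
            - gammaln(n + a_total)
            + (gammaln(x + alpha) - gammaln(alpha)).sum(axis=1)
        )
    out = coeff + body
    out[impossible] = -np.inf
    return out


def dm_log_pmf(x: np.ndarray, params: DMParams) -> float:
    """log P(X = x | N = sum(x), pi, theta) for one count vector."""
    return float(dm_log_pmf_matrix(np.asarray(x), params.pi, params.theta)[0])


def dm_sample(
    params: DMParams,
    n_samples: int,
    reads: int | np.ndarray,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    sample_prefix: str = "sample",
    taxon_labels: tuple[str, ...] | None = None,
) -> TaxaCountTable:
    """Draw ``n_samples`` DM count vectors as a :class:`TaxaCountTable`.

    Each sample is generated by drawing a probability vector from
    ``Dirichlet(alpha)`` with ``alpha_k = pi_k (1 - theta) / theta`` and then
    counts from a multinomial at the sample's read depth; ``theta = 0`` skips
    the Dirichlet stage. ``reads`` may be a scalar or a per-sample vector.
    Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    depths = np.broadcast_to(np.asarray(reads, dtype=np.int64), (n_samples,))
    if np.any(depths < 1):
        raise ValueError("reads must be >= 1")
    rng = np.random.default_rng(seed)

    k = params.n_taxa
    support = params.pi > 0
    counts = np.zeros((n_samples, k), dtype=np.int64)
    if params.theta == 0.0:
        probs = np.broadcast_to(params.pi[support], (n_samples, support.sum()))
    else:
        alpha = params.pi[support] * (1.0 - params.theta) / params.theta
        probs = rng.dirichlet(alpha, size=n_samples)
    counts[:, support] = rng.multinomial(depths, np.ascontiguousarray(probs))
    ids = tuple(f"{sample_prefix}_{i + 1}" for i in range(n_samples))
    if taxon_labels is None:
        taxon_labels = tuple(f"taxon_{j + 1}" for j in range(k))
    return TaxaCountTable(counts, ids, taxon_labels)
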