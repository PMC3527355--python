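"""Effect size and Monte-Carlo power / sample-size calculation.

Power for the generalized Wald tests has no convenient closed form under the
DM model, so it is estimated by simulation: repeatedly draw studies from the
stated group parameters, run the requested test, and report the rejection
fraction at the chosen level with its binomial Monte-Carlo standard error.
Effect size between group frequency vectors is a modified Cramer's phi on
the table of proportions with equal group masses, which ranges over [0, 1],
is 0 exactly when all groups share one frequency vector, and by construction
does not depend on subject counts or read depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .inference import (
    test_one_sample,
    test_several_samples,
    test_two_samples,
)
from .model import DMParams, dm_sample
from .table import GroupedTables, pool_rare_taxa, to_rank_abundance

__all__ = [
    "EffectSize",
    "PowerResult",
    "SampleSizeResult",
    "effect_size_phi",
    "power_mc",
    "sample_size_search",
]


@dataclass(frozen=True)
class EffectSize:
    """Modified Cramer's phi in [0, 1] for a set of group frequency vectors."""

    phi: float
    group_params: tuple[DMParams, ...]
    variant: str = "cramer_equal_mass"


def effect_size_phi(group_params: Sequence[DMParams]) -> EffectSize:
    """Cramer's phi with equal group masses on the J x K proportion table.

    With ``c_k`` the unweighted mean of the group frequencies,

        phi = sqrt( [sum_mk (pi_mk - c_k)^2 / (J c_k)] / min(J-1, K-1) ).

    phi = 0 iff every group has the same frequency vector; phi = 1 for
    maximally disjoint groups (e.g. two groups supported on different taxa).
    """
    if len(group_params) < 2:
        raise ValueError("need at least 2 groups")
    k = group_params[0].n_taxa
    if any(p.n_taxa != k for p in group_params):
        raise ValueError("all groups must share the same number of taxa")
    pis = np.array([p.pi for p in group_params])
    j = pis.shape[0]
    center = pis.mean(axis=0)
    support = center > 0
    chi2 = float(
        np.sum((pis[:, support] - center[support]) ** 2 / (j * center[support]))
    )
    phi = np.sqrt(chi2 / min(j - 1, k - 1))
    return EffectSize(phi=float(min(phi, 1.0)), group_params=tuple(group_params))


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimates over a (subjects x reads) grid."""

    alpha: float
    subjects_grid: tuple[int, ...]
    reads_grid: tuple[int, ...]
    power: np.ndarray  # shape (len(subjects_grid), len(reads_grid))
    mc_se: np.ndarray
    n_reps: int
    seed: int
    test: str

    def at(self, subjects: int, reads: int) -> float:
        i = self.subjects_grid.index(subjects)
        j = self.reads_grid.index(reads)
        return float(self.power[i, j])


def _run_test(tables, test: str, pi0, pool_threshold, rad: bool):
    if rad:
        tables = [to_rank_abundance(t) for t in tables]
    if test == "one":
        return test_one_sample(tables[0], pi0)
    grouped = GroupedTables.from_tables(
        (f"g{m + 1}", t) for m, t in enumerate(tables)
    )
    if pool_threshold is not None:
        grouped = pool_rare_taxa(grouped, threshold=pool_threshold)
    if test == "two":
        return test_two_samples(grouped)
    if test == "many":
        return test_several_samples(grouped)
    raise ValueError(f"unknown test mode {test!r}")


def power_mc(
    group_params: Sequence[DMParams],
    subjects: int | Sequence[int],
    reads: int | Sequence[int],
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
    test: str = "two",
    pi0: Sequence[float] | None = None,
    pool_threshold: float | None = None,
    rad: bool = False,
) -> PowerResult:
    """Monte-Carlo power of a test over a grid of (subjects, reads).

    For each grid point, ``n_reps`` studies are simulated: every group draws
    ``subjects`` DM samples at the given read depth from its own parameters,
    the requested test runs (``"two"``, ``"many"``, or ``"one"`` against
    ``pi0``, which defaults to the second parameter set's pi), optionally
    after per-sample rank transformation (``rad``) and/or rare-taxa pooling,
    and the rejection fraction at level ``alpha`` is recorded. Deterministic
    given ``seed``; under identical group parameters the estimate is the
    empirical size of the test.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    subjects_grid = tuple(
        int(s) for s in (np.atleast_1d(subjects).astype(int))
    )
    reads_grid = tuple(int(r) for r in (np.atleast_1d(reads).astype(int)))
    if not subjects_grid or not reads_grid:
        raise ValueError("empty grid")
    if any(s < 2 for s in subjects_grid) or any(r < 1 for r in reads_grid):
        raise ValueError("grids need subjects >= 2 and reads >= 1")
    if test == "one":
        if pi0 is None:
            if len(group_params) < 2:
                raise ValueError("one-sample power needs pi0 or a second parameter set")
            pi0 = group_params[1].pi
        sim_params = group_params[:1]
    else:
        if len(group_params) < 2:
            raise ValueError("two/many-group power needs >= 2 parameter sets")
        sim_params = tuple(group_params)

    root = np.random.SeedSequence(seed)
    power = np.zeros((len(subjects_grid), len(reads_grid)))
    for i, n_subj in enumerate(subjects_grid):
        for j, depth in enumerate(reads_grid):
            cell_seed = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(i, j)
            )
            rng = np.random.default_rng(cell_seed)
            rejections = 0
            for _ in range(n_reps):
                tables = [
                    dm_sample(p, n_subj, depth, seed=rng) for p in sim_params
                ]
                res = _run_test(tables, test, pi0, pool_threshold, rad)
                if res.p_value <= alpha:
                    rejections += 1
            power[i, j] = rejections / n_reps
    mc_se = np.sqrt(power * (1.0 - power) / n_reps)
    return PowerResult(
        alpha=alpha,
        subjects_grid=subjects_grid,
        reads_grid=reads_grid,
        power=power,
        mc_se=mc_se,
        n_reps=n_reps,
        seed=seed,
        test=test,
    )


@dataclass(frozen=True)
class SampleSizeResult:
    """Smallest per-group subject count reaching the target power."""

    n: int
    power_at_n: float
    mc_se: float
    target_power: float
    alpha: float
    bracket: dict[int, float] = field(default_factory=dict)


def sample_size_search(
    group_params: Sequence[DMParams],
    target_power: float = 0.80,
    alpha: float = 0.05,
    reads: int = 1000,
    n_reps: int = 1000,
    seed: int = 0,
    test: str = "two",
    pi0: Sequence[float] | None = None,
    cap: int = 10_000,
    **power_kwargs,
) -> SampleSizeResult:
    """Search the Monte-Carlo power curve for the minimum per-group size.

    Doubles the per-group subject count from 2 until the estimated power
    reaches ``target_power``, then bisects. Each size is evaluated once with
    a seed derived deterministically from ``seed`` and the size, so repeated
    runs agree. Raises if the target is unreachable below ``cap`` (e.g. a
    null effect, where power stays near ``alpha``).
    """
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")

    evaluated: dict[int, float] = {}

    def power_at(n: int) -> float:
        if n not in evaluated:
            sub_seed = int(
                np.random.SeedSequence([seed, n]).generate_state(1)[0] % (2**31)
            )
            res = power_mc(
                group_params,
                subjects=n,
                reads=reads,
                alpha=alpha,
                n_reps=n_reps,
                seed=sub_seed,
                test=test,
                pi0=pi0,
                **power_kwargs,
            )
            evaluated[n] = float(res.power[0, 0])
        return evaluated[n]

    lo, hi = 2, 2
    while power_at(hi) < target_power:
        lo = hi
        hi *= 2
        if hi > cap:
            raise RuntimeError(
                f"target power {target_power} unreachable below {cap} "
                f"subjects/group (power {power_at(min(lo, cap)):.3f} at {min(lo, cap)})"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    p_hi = power_at(hi)
    return SampleSizeResult(
        n=hi,
        power_at_n=p_hi,
        mc_se=float(np.sqrt(p_hi * (1.0 - p_hi) / n_reps)),
        target_power=target_power,
        alpha=alpha,
        bracket=dict(sorted(evaluated.items())),
    )
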