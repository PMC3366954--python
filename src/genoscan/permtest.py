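"""Two-sample Monte Carlo permutation test with an exact-enumeration mode.

The statistic is the difference in sample means, mean(x) - mean(y),
tested two-sided via its absolute value. The Monte Carlo p-value uses
the add-one estimator (b + 1) / (B + 1), which never returns zero; the
reported Z standardizes the observed statistic against the permutation
null's moments. For small samples :func:`perm_test_exact` enumerates
every group assignment and serves as the oracle for the Monte Carlo
version.

Ties are counted with a small tolerance: a permuted statistic within
1e-9 of the observed magnitude (relative to the largest pooled value)
counts as at least as extreme. Summing the pooled values in permuted
order can shift an exact tie by a unit in the last place, and a strict
comparison would then drop it and bias the p-value low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

_CHUNK = 100_000
_EXACT_LIMIT = 1_000_000


@dataclass(frozen=True)
class PermResult:
    """Outcome of a two-sample permutation test.

    ``p_hat`` is (b + 1)/(B + 1) in Monte Carlo mode (b = number of
    permuted \\|statistic\\| >= \\|observed\\|) and the exact proportion in
    enumeration mode. ``z_score`` is (observed - null mean) / null sd.
    """

    statistic_obs: float
    p_hat: float
    z_score: float
    B: int
    seed: Optional[int]
    exact: bool = False


def _tie_tolerance(pooled: np.ndarray) -> float:
    # rounding slack for tie detection, far above summation error
    return 1e-9 * float(np.max(np.abs(pooled)))


def _validate(x: np.ndarray, y: np.ndarray) -> None:
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"each group needs >= 2 observations (got {len(x)} and {len(y)})"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must contain only finite values")


def perm_test(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 100_000,
    seed: int = 0,
) -> PermResult:
    """Seeded Monte Carlo two-sample permutation test.

    Draws ``B`` random relabelings of the pooled data, recomputes the
    mean difference under each, and reports the two-sided add-one
    p-value. Deterministic for fixed ``(x, y, B, seed)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")

    obs = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(pooled)
    total = pooled.sum()
    tol = _tie_tolerance(pooled)
    rng = np.random.default_rng(seed)

    b_ge = 0
    s = 0.0
    s2 = 0.0
    done = 0
    while done < B:
        m = min(_CHUNK, B - done)
        # row-wise random permutations via argsort of uniform keys
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :nx]
        sx = pooled[idx].sum(axis=1)
        stat = sx / nx - (total - sx) / (n - nx)
        b_ge += int((np.abs(stat) >= abs(obs) - tol).sum())
        s += float(stat.sum())
        s2 += float((stat * stat).sum())
        done += m

    p_hat = (b_ge + 1) / (B + 1)
    mean_null = s / B
    var_null = (s2 - B * mean_null**2) / (B - 1) if B > 1 else 0.0
    sd_null = math.sqrt(max(var_null, 0.0))
    z = (obs - mean_null) / sd_null if sd_null > 0 else 0.0
    return PermResult(
        statistic_obs=obs, p_hat=p_hat, z_score=z, B=B, seed=seed, exact=False
    )


def perm_test_exact(x: Sequence[float], y: Sequence[float]) -> PermResult:
    """Exhaustive permutation test over all C(|x|+|y|, |x|) assignments.

    The p-value is the exact proportion of assignments whose
    \\|mean difference\\| is at least the observed one. Limited to
    C(n, |x|) <= 1e6; larger problems should use :func:`perm_test`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    nx, ny = len(x), len(y)
    n_comb = math.comb(nx + ny, nx)
    if n_comb > _EXACT_LIMIT:
        raise ValueError(
            f"C({nx + ny}, {nx}) = {n_comb} assignments exceed the exact "
            f"limit ({_EXACT_LIMIT}); use perm_test instead"
        )

    obs = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    total = pooled.sum()
    stats = np.empty(n_comb)
    for i, idx in enumerate(combinations(range(nx + ny), nx)):
        sx = pooled[list(idx)].sum()
        stats[i] = sx / nx - (total - sx) / ny

    p = float((np.abs(stats) >= abs(obs) - _tie_tolerance(pooled)).mean())
    sd = float(stats.std(ddof=0))
    z = (obs - float(stats.mean())) / sd if sd > 0 else 0.0
    return PermResult(
        statistic_obs=obs, p_hat=p, z_score=z, B=n_comb, seed=None, exact=True
    )
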