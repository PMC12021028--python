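"""Two-sample tests used by the motility and adhesion analyses."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["TestResult", "mann_whitney_u", "student_t"]

EXACT_LIMIT = 64  # exact enumeration when n1 * n2 <= this


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x over y with midrank tie handling."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test.

    The U statistic uses midranks for ties.  For small problems
    (n1*n2 <= 64) the two-sided p-value is computed by full enumeration of
    all group assignments of the pooled sample (the exact permutation null,
    valid with ties); otherwise a normal approximation with tie correction
    and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if n1 * n2 <= EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        total = comb(n1 + n2, n1)
        obs_dev = abs(u - mu)
        count = 0
        for idx in combinations(range(n1 + n2), n1):
            r1 = ranks[list(idx)].sum()
            u_perm = r1 - n1 * (n1 + 1) / 2.0
            if abs(u_perm - mu) >= obs_dev - 1e-9:
                count += 1
        p = count / total
        method = "exact-enumeration"
    else:
        pooled = np.concatenate([x, y])
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)  # continuity correction
            p = float(2 * sps.norm.sf(max(z, 0.0)))
        p = min(p, 1.0)
        method = "normal-approximation"
    return TestResult(u, p, n1, n2, method)


def student_t(x, y, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t test (Student by default, Welch optional).

    The Welch variant is always reported alongside in ``extra``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs at least 2 values")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    tw, pw = sps.ttest_ind(x, y, equal_var=False)
    if np.isnan(p):  # identical constant groups
        t, p = 0.0, 1.0
    if np.isnan(pw):
        tw, pw = 0.0, 1.0
    return TestResult(
        float(t),
        float(p),
        len(x),
        len(y),
        "student-t" if equal_var else "welch-t",
        extra={"welch_t": float(tw), "welch_p": float(pw)},
    )
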