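"""EV production metrics and exact nonparametric group comparison.

EVs-per-cell is the ratio of NTA particle counts to the number of cells
retrieved from the culture; conditions are compared with a Mann-Whitney U
test whose p-value is exact (full null distribution by dynamic programming)
whenever the combined sample size is <= 20 and there are no ties, and a
normal approximation with tie correction otherwise.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

EXACT_MAX_N = 20


@dataclass
class YieldRecord:
    """One biological replicate's EV yield (NTA particles over cells)."""

    replicate_id: str
    condition: str  # "2D" | "3D"
    total_particles: float
    total_cells: float
    mode_size_nm: float | None = None
    mean_size_nm: float | None = None

    def __post_init__(self) -> None:
        if self.total_particles < 0:
            raise ValueError(f"{self.replicate_id}: total_particles must be >= 0")
        if self.total_cells <= 0:
            raise ValueError(f"{self.replicate_id}: total_cells must be > 0")
        for attr in ("mode_size_nm", "mean_size_nm"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{self.replicate_id}: {attr} must be > 0")

    @property
    def ratio(self) -> float:
        return self.total_particles / self.total_cells


@dataclass(frozen=True)
class ExactTestResult:
    u_statistic: float
    n1: int
    n2: int
    p_two_sided: float  # p for the requested alternative, in (0, 1]
    method: str  # "exact" | "normal_approx"
    alternative: str = "two_sided"


def evs_per_cell(records: Sequence[YieldRecord]) -> dict[str, dict[str, float]]:
    """Per-condition mean and sample sd of the particles/cells ratios.

    With a single replicate the sd is NaN.  Below four replicates per
    condition a warning is issued (the design calls for at least four)."""
    if not records:
        raise ValueError("no yield records")
    out: dict[str, dict[str, float]] = {}
    conditions = sorted({r.condition for r in records})
    for cond in conditions:
        ratios = np.array([r.ratio for r in records if r.condition == cond])
        if len(ratios) < 4:
            warnings.warn(
                f"condition {cond}: only {len(ratios)} replicates "
                "(at least four recommended)",
                stacklevel=2,
            )
        out[cond] = {
            "n": int(len(ratios)),
            "mean": float(ratios.mean()),
            "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else float("nan"),
        }
    return out


@functools.lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> list[int]:
    """Count of rank labelings giving each U1 value, U1 = 0..n1*n2.

    Recurrence on which sample holds the largest rank: from sample 1 it
    beats all n2 of sample 2 (U1 += n2), from sample 2 it adds nothing.
    """
    table: dict[tuple[int, int], list[int]] = {}

    def counts(a: int, b: int) -> list[int]:
        if (a, b) in table:
            return table[(a, b)]
        if a == 0 or b == 0:
            res = [1]
        else:
            res = [0] * (a * b + 1)
            for u, c in enumerate(counts(a - 1, b)):
                res[u + b] += c
            for u, c in enumerate(counts(a, b - 1)):
                res[u] += c
        table[(a, b)] = res
        return res

    return counts(n1, n2)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def mann_whitney_exact(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
) -> ExactTestResult:
    """Mann-Whitney U test with exact small-sample p-value.

    U is computed from mid-ranks.  When n1+n2 <= 20 and there are no ties,
    the p-value comes from the full exact null distribution of U; otherwise
    from the normal approximation with tie correction and continuity
    correction.  Two-sided exact p is P(U <= min(U, n1*n2 - U)) doubled and
    capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in {"two_sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = len(np.unique(pooled)) < pooled.size

    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        cnt = _u_null_counts(n1, n2)
        total = comb(n1 + n2, n1)
        u1i = int(round(u1))
        cum = np.cumsum(cnt)

        def p_le(u: int) -> float:
            u = min(max(u, -1), n1 * n2)
            return 0.0 if u < 0 else cum[u] / total

        if alternative == "two_sided":
            p = min(1.0, 2.0 * p_le(min(u1i, n1 * n2 - u1i)))
        elif alternative == "greater":  # a shifted above b -> large U1
            p = 1.0 - p_le(u1i - 1)
        else:
            p = p_le(u1i)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        sigma = math.sqrt(sigma2) if sigma2 > 0 else 0.0
        if sigma == 0.0:
            p = 1.0
        elif alternative == "two_sided":
            z = (abs(u1 - mu) - 0.5) / sigma
            p = min(1.0, 2.0 * stats.norm.sf(z))
        elif alternative == "greater":
            z = (u1 - mu - 0.5) / sigma
            p = float(stats.norm.sf(z))
        else:
            z = (u1 - mu + 0.5) / sigma
            p = float(stats.norm.cdf(z))
        method = "normal_approx"

    return ExactTestResult(
        u_statistic=float(u1),
        n1=n1,
        n2=n2,
        p_two_sided=max(float(p), np.nextafter(0, 1)),
        method=method,
        alternative=alternative,
    )


def size_summary(
    size_samples_nm: Sequence[float], bin_width_nm: float
) -> dict[str, float]:
    """Arithmetic mean and histogram-mode of NTA particle sizes.

    The mode is the center of the most populated bin; sizes are assigned to
    the nearest multiple of ``bin_width_nm`` (half-way points round up) and
    ties go to the smaller center."""
    sizes = np.asarray(size_samples_nm, dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one size")
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be > 0")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    centers = np.floor(sizes / bin_width_nm + 0.5) * bin_width_nm
    uniq, counts = np.unique(centers, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # np.argmax -> first (smallest) center
    return {"mode": mode, "mean": float(sizes.mean())}
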