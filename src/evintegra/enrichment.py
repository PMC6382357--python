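"""Enrichment statistics: hypergeometric over-representation analysis and
unweighted running-sum set enrichment with exact dynamic-programming
p-values.

The running-sum statistic walks down a ranked list of N features adding
+(N-k) at each of the k category members and -k elsewhere, so every path
ends at 0 and the state space stays integer-valued (Kolmogorov-Smirnov-type
unweighted GSEA).  The exact tail probability of the maximum absolute
deviation under uniform random placement of the k members is obtained by
counting lattice paths that never reach +/-s: along any path the running
sum after i steps with j members seen equals j*N - i*k, so a simple
(position, members-used) DP restricted to |j*N - i*k| < s counts the
surviving paths, and p = 1 - #surviving / C(N, k), evaluated in exact
integer arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from evintegra.tables_io import CategoryDB, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One category's over-representation test result.

    ``significant`` follows the study rule: nominal p < alpha AND at least
    two members overlap the query.  ``q`` is the Benjamini-Hochberg value,
    reported alongside but not used for that flag.
    """

    category_id: str
    universe_size: int  # N
    category_in_universe: int  # K
    query_size: int  # n
    overlap: int  # k
    p: float
    q: float
    significant: bool


@dataclass(frozen=True)
class RunningSumResult:
    category_id: str
    list_size: int  # N
    members_in_list: int  # k
    rs_path: tuple[int, ...]  # cumulative sum after each of the N steps
    rs_max: int  # max |rs_path|
    p_exact: float


def ora(
    query: set[str],
    universe: set[str],
    db: CategoryDB,
    alpha: float = 0.05,
    min_overlap: int = 2,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric over-representation of each category.

    Category members are intersected with the universe before testing;
    p = P(X >= k | N, K, n).  Records come back sorted by ascending p
    (ties by category id).
    """
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query ids outside the universe: {stray}")
    N, n = len(universe), len(query)
    rows = []
    for cid in db:
        members = db.members(cid) & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((cid, K, k, min(p, 1.0)))
    if not rows:
        return []
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    records = [
        EnrichmentRecord(
            category_id=cid,
            universe_size=N,
            category_in_universe=K,
            query_size=n,
            overlap=k,
            p=p,
            q=float(q),
            significant=bool(p < alpha and k >= min_overlap),
        )
        for (cid, K, k, p), q in zip(rows, qvals)
    ]
    records.sort(key=lambda r: (r.p, r.category_id))
    return records


def exact_p_running_sum(N: int, k: int, s: int, two_sided: bool = True) -> float:
    """Exact P(max deviation >= s) of the unweighted running sum.

    Under uniform random placement of the k members among N list positions,
    counts the lattice paths whose running sum j*N - i*k stays strictly
    inside (-s, s) (two-sided) or below s (one-sided) at every step, in
    exact integer arithmetic.  s <= 0 gives p = 1 (every path attains
    |RS| >= 0).
    """
    if not 0 < k <= N:
        raise ValueError(f"need 0 < k <= N, got k={k}, N={N}")
    if s <= 0:
        return 1.0
    # dp[j] = number of prefixes of length i with j members, all inside
    dp = [0] * (k + 1)
    dp[0] = 1
    for i in range(1, N + 1):
        new = [0] * (k + 1)
        for j in range(min(i, k) + 1):
            ways = dp[j] + (dp[j - 1] if j else 0)
            if not ways:
                continue
            rs = j * N - i * k
            if rs >= s or (two_sided and rs <= -s):
                continue
            new[j] = ways
        dp = new
    surviving = dp[k]
    p = 1 - Fraction(surviving, comb(N, k))
    return float(p)


def running_sum(
    ranked_ids: Sequence[str], members: set[str], two_sided: bool = True
) -> RunningSumResult:
    """Running-sum enrichment of ``members`` within a ranked list.

    Walks the list adding +(N-k) at members and -k elsewhere, records the
    maximum absolute deviation and attaches its exact tail probability.
    """
    if not members:
        raise ValueError("empty member set")
    if len(set(ranked_ids)) != len(ranked_ids):
        raise ValueError("ranked list contains duplicates")
    stray = sorted(set(members) - set(ranked_ids))
    if stray:
        raise ValueError(f"members not in ranked list: {stray}")
    N, k = len(ranked_ids), len(members)
    path = []
    rs = 0
    for fid in ranked_ids:
        rs += (N - k) if fid in members else -k
        path.append(rs)
    rs_max = max(abs(v) for v in path)
    return RunningSumResult(
        category_id="",
        list_size=N,
        members_in_list=k,
        rs_path=tuple(path),
        rs_max=rs_max,
        p_exact=exact_p_running_sum(N, k, rs_max, two_sided=two_sided),
    )


def rank_features(
    matrix: ExpressionMatrix,
    rank_by: str = "mean_abundance",
    group_a: Sequence[str] | None = None,
    group_b: Sequence[str] | None = None,
) -> list[str]:
    """Rank features descending by mean abundance or by log2 fold change
    (B over A); ties break ascending by feature id."""
    if rank_by == "mean_abundance":
        with np.errstate(invalid="ignore"):
            key = np.nanmean(matrix.data.to_numpy(dtype=float), axis=1)
    elif rank_by == "log2fc":
        if group_a is None or group_b is None:
            raise ValueError("log2fc ranking needs group_a and group_b")
        from evintegra.differential import fold_change, fold_change_frame

        fcf = fold_change_frame(
            fold_change(matrix, group_a, group_b, zero_policy="epsilon")
        )
        key = fcf["log2fc"].to_numpy()
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    order = sorted(
        range(len(matrix.feature_ids)),
        key=lambda i: (-(key[i] if np.isfinite(key[i]) else -np.inf), matrix.feature_ids[i]),
    )
    return [matrix.feature_ids[i] for i in order]


def gsea_ranked_mirnas(
    matrix: ExpressionMatrix,
    members_db: CategoryDB,
    rank_by: str = "mean_abundance",
    group_a: Sequence[str] | None = None,
    group_b: Sequence[str] | None = None,
    two_sided: bool = True,
) -> list[RunningSumResult]:
    """Running-sum enrichment of every category against a ranked feature
    list (e.g. detected EV miRNAs ranked by average FPKM).

    Categories with fewer than two members in the list are skipped with a
    log entry.  Results come back sorted by ascending exact p.
    """
    ranked = rank_features(matrix, rank_by, group_a, group_b)
    if not ranked:
        raise ValueError("empty ranked list")
    in_list = set(ranked)
    results = []
    for cid in members_db:
        members = members_db.members(cid) & in_list
        if len(members) < 2:
            logger.info("category %s: <2 members in ranked list, skipped", cid)
            continue
        res = running_sum(ranked, members, two_sided=two_sided)
        results.append(
            RunningSumResult(
                category_id=cid,
                list_size=res.list_size,
                members_in_list=res.members_in_list,
                rs_path=res.rs_path,
                rs_max=res.rs_max,
                p_exact=res.p_exact,
            )
        )
    results.sort(key=lambda r: (r.p_exact, r.category_id))
    return results
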