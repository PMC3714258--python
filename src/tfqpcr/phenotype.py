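"""Nonparametric comparison of somatic-embryogenesis capacity between lines.

Mutant or transgenic lines are compared against the parental control on two
endpoints, SE efficiency (percent of explants forming somatic embryos) and
SE productivity (mean embryos per responding explant), with the Mann-Whitney
U test; multi-group questions use Kruskal-Wallis.  Sample sizes here are tiny
(typically n = 3 per line), so the U distribution is enumerated exactly:
below ``exact_limit`` total observations every C(n1+n2, n1) labelling of the
pooled mid-ranks is evaluated, which handles ties correctly.  Above the limit
a normal approximation with tie and continuity corrections is used.

Note the hard floor this implies: with n = 3 vs 3 the smallest achievable
exact two-sided p is 2/C(6,3) = 0.1, i.e. complete separation is *not*
significant at alpha = 0.05 under the exact test.  Results therefore carry
both the exact and the approximate p so the discrepancy is visible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeAssay

EXACT_LIMIT = 12  # total observations at or below which U is enumerated


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # mann_whitney_exact | mann_whitney_normal | kruskal_wallis
    n1: int
    n2: int
    significant: bool


def _rank_sum_u(a: Sequence[float], b: Sequence[float]) -> float:
    """U statistic of sample ``a`` from pooled mid-ranks (tie-aware)."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2)


def mann_whitney_exact(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    exact_limit: int = EXACT_LIMIT,
) -> TestResult:
    """Two-sided Mann-Whitney U test, exact by enumeration at small n.

    With ``n1 + n2 <= exact_limit`` the null distribution of U is built by
    enumerating every assignment of the pooled mid-ranks to the two groups;
    the two-sided p is twice the smaller one-sided tail (capped at 1).
    Larger samples fall back to the normal approximation with tie and
    continuity corrections.
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    u_obs = _rank_sum_u(a, b)

    if n1 + n2 <= exact_limit:
        pooled = np.asarray(a + b, float)
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2
        total = 0
        lo = hi = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            # inclusive tails (mid-rank ties land exactly on u_obs)
            if u <= u_obs + 1e-9:
                lo += 1
            if u >= u_obs - 1e-9:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        method = "mann_whitney_exact"
    else:
        mu = n1 * n2 / 2.0
        pooled = np.asarray(a + b, float)
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
        method = "mann_whitney_normal"
    return TestResult(
        statistic=u_obs, p_value=float(p), method=method,
        n1=n1, n2=n2, significant=bool(p < alpha),
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-squared p on k-1 df."""
    arrays = [np.asarray(list(g), float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return TestResult(
        statistic=float(h), p_value=float(p), method="kruskal_wallis",
        n1=int(arrays[0].size), n2=int(pooled.size - arrays[0].size),
        significant=bool(p < alpha),
    )


def compare_lines_to_control(
    assays: Sequence[PhenotypeAssay],
    control: str = "Col-0",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney comparison of every line against the control line.

    One row per line per endpoint (efficiency, productivity) with the exact
    (or approximate, at larger n) p and the normal-approximation p side by
    side.  Lines with fewer than 2 replicates are skipped with a warning row
    left out of the table.
    """
    df = pd.DataFrame([a.__dict__ for a in assays])
    if control not in set(df["line"]):
        raise ValueError(f"control line {control!r} absent from assays")
    ctrl = df[df["line"] == control]
    if len(ctrl) < 2:
        raise ValueError(f"control line {control!r} has < 2 replicates")
    rows = []
    for line, grp in df[df["line"] != control].groupby("line", sort=True):
        if len(grp) < 2:
            import warnings

            warnings.warn(f"line {line!r} skipped: < 2 replicates", stacklevel=2)
            continue
        for endpoint in ("efficiency", "productivity"):
            a = grp[endpoint].tolist()
            b = ctrl[endpoint].tolist()
            res = mann_whitney_exact(a, b, alpha=alpha)
            approx = mann_whitney_exact(a, b, alpha=alpha, exact_limit=0)
            rows.append(dict(
                line=line, endpoint=endpoint, n_line=res.n1, n_control=res.n2,
                u_statistic=res.statistic, method=res.method,
                p_value=res.p_value, p_normal=approx.p_value,
                significant=res.significant,
            ))
    return pd.DataFrame(rows)
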