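"""Mann-Whitney U comparisons of stage distributions between groups.

Stages are heavily tied integers, so U is computed from midranks; the
two-sided p-value uses the normal approximation with tie-corrected variance
and continuity correction.  An exact mode computes U by brute-force pair
counting and, for tie-free inputs, an exact p-value from the enumerated
null distribution of U.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

EXACT_MAX_PRODUCT = 400

CONTRASTS = (
    "YA_vs_OA",
    "dementia_vs_none_within_OA",
    "APOE4_vs_APOE2_within_group",
    "APOE4_vs_APOE3_within_group",
)


@dataclass
class ComparisonResult:
    contrast: str
    subgroup: str   # "all", "YA" or "OA"
    n_a: int
    n_b: int
    U: float        # statistic for group a (pairs with a > b, ties half)
    p: float
    direction: str  # which group is staged later

    def __post_init__(self) -> None:
        if not 0.0 <= self.U <= self.n_a * self.n_b:
            raise ConfigurationError("U must lie in [0, n_a * n_b]")
        if not 0.0 < self.p <= 1.0:
            raise ConfigurationError("p must lie in (0, 1]")


def _exact_null_dist(n_a: int, n_b: int) -> np.ndarray:
    """Tie-free null distribution of U over all rank interleavings.

    Recurrence on the last element of the interleaving:
    N(m, n, u) = N(m-1, n, u-n) + N(m, n-1, u), N(0, n, 0) = N(m, 0, 0) = 1.
    """
    prev = [np.array([1.0]) for _ in range(n_b + 1)]  # m = 0 row
    for m in range(1, n_a + 1):
        cur: list[np.ndarray] = []
        for n in range(n_b + 1):
            arr = np.zeros(m * n + 1)
            a_last = prev[n]
            arr[n : n + a_last.size] += a_last
            if n > 0:
                b_last = cur[n - 1]
                arr[: b_last.size] += b_last
            cur.append(arr)
        prev = cur
    counts = prev[n_b]
    return counts / counts.sum()


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U_a, p)`` where ``U_a`` counts pairs with a > b plus half the
    tied pairs.  ``method='asymptotic'`` uses midranks with tie-corrected
    variance and continuity correction.  ``method='exact'`` computes U by
    brute-force pair counting (inputs with n_a * n_b <= 400 only) and an
    exact enumeration p-value when there are no ties; with ties it falls
    back to the asymptotic p while keeping the pair-counted U.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both groups must be nonempty")
    n_a, n_b = a.size, b.size

    if method == "exact":
        if n_a * n_b > EXACT_MAX_PRODUCT:
            raise ConfigurationError(
                f"exact mode limited to n_a * n_b <= {EXACT_MAX_PRODUCT}"
            )
        diff = a[:, None] - b[None, :]
        u_a = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
        has_ties = np.unique(np.concatenate([a, b])).size < n_a + n_b
        if has_ties:
            _, p = mann_whitney_u(a, b, method="asymptotic")
            return u_a, p
        null = _exact_null_dist(n_a, n_b)
        u_int = int(round(u_a))
        lower = null[: u_int + 1].sum()
        upper = null[u_int:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        return u_a, max(p, np.finfo(float).tiny)
    if method != "asymptotic":
        raise ConfigurationError(f"unknown method {method!r}")

    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return u_a, 1.0
    # continuity correction shrinks |U - mu| by 0.5
    z = (u_a - mu - 0.5 * np.sign(u_a - mu)) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return u_a, max(p, np.finfo(float).tiny)


def _direction(a: np.ndarray, b: np.ndarray, label_a: str, label_b: str) -> str:
    u_a, _ = mann_whitney_u(a, b, method="asymptotic")
    half = a.size * b.size / 2.0
    if u_a > half:
        return label_a
    if u_a < half:
        return label_b
    return "neither"


def run_contrasts(
    stages: pd.DataFrame, cohort: pd.DataFrame, method: str = "asymptotic"
) -> pd.DataFrame:
    """Run the study's group contrasts on assigned stages.

    Contrasts: YA vs OA over everyone; dementia vs no dementia within OA;
    APOE4 vs APOE2 and APOE4 vs APOE3 within YA and OA separately (APOE 2:4
    carriers and unknown genotypes are omitted).  A contrast with an empty
    cell is skipped with a logged warning.
    """
    merged = stages.merge(
        cohort[["participant_id", "age_group", "dementia", "apoe_group"]],
        on="participant_id",
        validate="one_to_one",
    )
    plans: list[tuple[str, str, pd.Series, pd.Series, str, str]] = []
    ya = merged["age_group"] == "YA"
    oa = merged["age_group"] == "OA"
    plans.append(("YA_vs_OA", "all", ya, oa, "YA", "OA"))
    plans.append(
        (
            "dementia_vs_none_within_OA",
            "OA",
            oa & (merged["dementia"] == "diagnosed"),
            oa & (merged["dementia"] == "none"),
            "dementia",
            "no_dementia",
        )
    )
    for subgroup, mask in (("YA", ya), ("OA", oa)):
        e4 = mask & (merged["apoe_group"] == "APOE4")
        plans.append(
            (
                "APOE4_vs_APOE2_within_group",
                subgroup,
                e4,
                mask & (merged["apoe_group"] == "APOE2"),
                "APOE4",
                "APOE2",
            )
        )
        plans.append(
            (
                "APOE4_vs_APOE3_within_group",
                subgroup,
                e4,
                mask & (merged["apoe_group"] == "APOE3"),
                "APOE4",
                "APOE3",
            )
        )

    rows = []
    for contrast, subgroup, mask_a, mask_b, label_a, label_b in plans:
        a = merged.loc[mask_a, "stage"].to_numpy(float)
        b = merged.loc[mask_b, "stage"].to_numpy(float)
        if a.size == 0 or b.size == 0:
            logger.warning(
                "skipping contrast %s (%s): empty cell (n_a=%d, n_b=%d)",
                contrast,
                subgroup,
                a.size,
                b.size,
            )
            continue
        u, p = mann_whitney_u(a, b, method=method)
        result = ComparisonResult(
            contrast=contrast,
            subgroup=subgroup,
            n_a=a.size,
            n_b=b.size,
            U=u,
            p=p,
            direction=_direction(a, b, label_a, label_b),
        )
        rows.append(result.__dict__)
    return pd.DataFrame(rows)
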