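"""Modulation index and the exact two-sided Mann-Whitney U test.

The preference of an injection site for one of two complementary regions is
summarized per case by the modulation index

    MI = (Q_a - Q_b) / (Q_a + Q_b)

where Q is the quantified amount of tracer (cell count or percent area) in
each region.  MI is bounded in [-1, 1]; positive values indicate a
preference for region a.  Group differences in MI between the two injection
cohorts are tested with an exact two-sided Mann-Whitney U test at
alpha = 0.05.  With cohorts of five and four cases, complete separation of
the groups yields the smallest achievable two-sided exact p, 2/126 = .016.

The exact null distribution of U is computed here by dynamic programming
(tie-free data) or by enumeration over all equally likely assignments of
the pooled values to groups (tied data, midranks); a normal approximation
with tie correction is used only when the enumeration would be infeasibly
large.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, erf, sqrt
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ModulationInput",
    "GroupComparison",
    "modulation_index",
    "mannwhitney_exact",
    "compare_preference",
    "format_p",
]

DEFAULT_ALPHA = 0.05

#: largest number of group assignments enumerated exactly for tied data
_ENUMERATION_LIMIT = 500_000


@dataclass(frozen=True)
class ModulationInput:
    """Quantified tracer in two complementary regions for one case."""

    q_a: float
    q_b: float
    case_id: str = ""
    region_pair: str = ""

    def __post_init__(self) -> None:
        if self.q_a < 0 or self.q_b < 0:
            raise ValueError("tracer quantities must be non-negative")


@dataclass(frozen=True)
class GroupComparison:
    """Two groups of modulation indices with the exact test result."""

    mi_group1: tuple[float, ...]
    mi_group2: tuple[float, ...]
    u_stat: float
    p_value: float
    alpha: float = DEFAULT_ALPHA
    group_labels: tuple[str, str] = ("group1", "group2")
    region_pair: str = ""
    method: str = "exact-dp"

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "region_pair": self.region_pair,
            "groups": list(self.group_labels),
            "mi_group1": list(self.mi_group1),
            "mi_group2": list(self.mi_group2),
            "U": self.u_stat,
            "p": self.p_value,
            "p_display": format_p(self.p_value),
            "alpha": self.alpha,
            "significant": self.significant,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# Modulation index
# ---------------------------------------------------------------------------

def modulation_index(x: ModulationInput) -> float:
    """(Q_a - Q_b) / (Q_a + Q_b); undefined (error) when both are zero."""
    total = x.q_a + x.q_b
    if total <= 0:
        raise ValueError(f"case {x.case_id!r}: Q_a + Q_b = 0, modulation index undefined")
    return (x.q_a - x.q_b) / total


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of the C(n1+n2, n1) tie-free arrangements with U1 = u.

    Recursion on the largest pooled value: placed in group 1 it exceeds all
    n2 group-2 values (U1 gains n2); placed in group 2 it gains nothing.
    """
    table: dict[tuple[int, int], np.ndarray] = {}

    def rec(m: int, n: int) -> np.ndarray:
        if (m, n) in table:
            return table[(m, n)]
        if m == 0 or n == 0:
            arr = np.zeros(1)
            arr[0] = 1.0
        else:
            a = rec(m - 1, n)
            b = rec(m, n - 1)
            arr = np.zeros(m * n + 1)
            arr[n : n + len(a)] += a
            arr[: len(b)] += b
        table[(m, n)] = arr
        return arr

    return rec(n1, n2)


def _u1_from_values(g1: np.ndarray, g2: np.ndarray) -> float:
    """U statistic of group 1 via midranks of the pooled sample."""
    n1 = len(g1)
    ranks = rankdata(np.concatenate([g1, g2]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _two_sided_p_tiefree(u: float, n1: int, n2: int) -> float:
    counts = _u_counts(n1, n2)
    total = comb(n1 + n2, n1)
    tail = float(counts[: int(np.floor(u)) + 1].sum())
    return min(1.0, 2.0 * tail / total)


def _two_sided_p_enumerate(g1: np.ndarray, g2: np.ndarray, u1_obs: float) -> float:
    """Exact p over all group assignments of the observed (tied) multiset."""
    pooled = np.concatenate([g1, g2])
    ranks = rankdata(pooled)  # midranks fixed by the pooled multiset
    n1, n = len(g1), len(pooled)
    offset = n1 * (n1 + 1) / 2.0
    n_le = n_ge = 0
    total = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n), n1):
        u1 = ranks[list(idx)].sum() - offset
        total += 1
        if u1 <= u1_obs + eps:
            n_le += 1
        if u1 >= u1_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def _two_sided_p_normal(g1: np.ndarray, g2: np.ndarray, u1_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([g1, g2]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u1_obs - mu) - 0.5) / sqrt(var)
    return min(1.0, 2.0 * 0.5 * (1.0 - erf(max(z, 0.0) / sqrt(2.0))))


def mannwhitney_exact(
    g1: Sequence[float],
    g2: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    group_labels: tuple[str, str] = ("group1", "group2"),
    region_pair: str = "",
) -> GroupComparison:
    """Exact two-sided Mann-Whitney U test for two small samples.

    ``U`` is reported as min(U1, U2), U1 + U2 = n1*n2.  The two-sided p is
    twice the exact probability (over all C(n1+n2, n1) equally likely group
    assignments under the null) of a U at or beyond the observed one,
    capped at 1.  Pooled-distinct data use the dynamic-programming null
    distribution; tied data are handled by midranks with enumeration over
    assignments of the observed multiset (normal approximation with tie
    correction only when the enumeration is infeasible).
    """
    a = np.asarray(list(g1), dtype=float)
    b = np.asarray(list(g2), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u1 = _u1_from_values(a, b)
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free:
        p = _two_sided_p_tiefree(u, n1, n2)
        method = "exact-dp"
    elif comb(n1 + n2, n1) <= _ENUMERATION_LIMIT:
        p = _two_sided_p_enumerate(a, b, u1)
        method = "exact-enumeration"
    else:
        p = _two_sided_p_normal(a, b, u1)
        method = "normal-approx"
    return GroupComparison(
        mi_group1=tuple(float(v) for v in a),
        mi_group2=tuple(float(v) for v in b),
        u_stat=float(u),
        p_value=float(p),
        alpha=alpha,
        group_labels=group_labels,
        region_pair=region_pair,
        method=method,
    )


def compare_preference(
    cases_by_group: Mapping[str, Sequence[ModulationInput]],
    alpha: float = DEFAULT_ALPHA,
) -> GroupComparison:
    """Per-case modulation indices for two injection groups, then the exact test.

    Cases with Q_a + Q_b = 0 (no label in either region) are excluded: the
    index is undefined there.
    """
    if len(cases_by_group) != 2:
        raise ValueError(f"need exactly two injection groups, got {len(cases_by_group)}")
    (lab1, cases1), (lab2, cases2) = cases_by_group.items()
    mis: list[list[float]] = []
    region_pair = ""
    for cases in (cases1, cases2):
        vals = []
        for c in cases:
            if c.q_a + c.q_b <= 0:
                continue  # undefined MI, case excluded
            vals.append(modulation_index(c))
            region_pair = c.region_pair or region_pair
        mis.append(vals)
    if not mis[0] or not mis[1]:
        raise ValueError("a group has no cases with defined modulation index")
    return mannwhitney_exact(
        mis[0], mis[1], alpha=alpha, group_labels=(lab1, lab2), region_pair=region_pair
    )


def format_p(p: float) -> str:
    """Three decimals with leading-zero suppression: 0.015873 -> '.016'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p out of range: {p}")
    s = f"{p:.3f}"
    return s[1:] if s.startswith("0.") else s
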