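"""Threshold-group construction and the group hypothesis tests.

Performances are split into four groups by two boolean threshold conditions
(e.g. time on the wheel within 4.935 s; pike-mount knee angle over 162.5
degrees).  Group I satisfies both conditions, II only the first, III only
the second, IV neither.  Dunnett's many-to-one comparison then tests the
reference group against the other three, and Mann-Whitney U tests each
condition alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "Condition",
    "GroupAssignment",
    "TestResult",
    "assign_groups",
    "mann_whitney_u",
    "dunnett_test",
]

GROUP_LABELS = ("I", "II", "III", "IV")

_OPS = {
    "<=": lambda v, t: v <= t,
    "<": lambda v, t: v < t,
    ">=": lambda v, t: v >= t,
    ">": lambda v, t: v > t,
}


@dataclass(frozen=True)
class Condition:
    """A single boolean threshold condition on one feature."""

    feature: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise InputError(f"unknown comparator {self.op!r}")

    def holds(self, values: np.ndarray) -> np.ndarray:
        return _OPS[self.op](np.asarray(values, dtype=float), self.threshold)

    @classmethod
    def parse(cls, text: str) -> "Condition":
        """Parse e.g. ``"time_on_wheel<=4.935"`` or ``"knee_pikemount>162.5"``."""
        for op in ("<=", ">=", "<", ">"):
            if op in text:
                feature, _, thr = text.partition(op)
                return cls(feature.strip(), op, float(thr))
        raise InputError(f"cannot parse condition {text!r}")

    def __str__(self) -> str:
        return f"{self.feature}{self.op}{self.threshold:g}"


@dataclass(frozen=True)
class GroupAssignment:
    """Per-record group labels from two conditions (I = both hold)."""

    labels: tuple[str, ...]
    cond_a: Condition
    cond_b: Condition

    @property
    def sizes(self) -> dict[str, int]:
        return {g: self.labels.count(g) for g in GROUP_LABELS}

    def values_by_group(self, values: Sequence[float]) -> dict[str, np.ndarray]:
        values = np.asarray(values, dtype=float)
        if len(values) != len(self.labels):
            raise InputError("values length does not match the assignment")
        lab = np.asarray(self.labels)
        return {g: values[lab == g] for g in GROUP_LABELS}


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    alternative: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InputError(f"p-value {self.p_value} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_sizes": list(self.group_sizes),
            "alternative": self.alternative,
            **self.extra,
        }


def assign_groups(
    frame: pd.DataFrame, cond_a: Condition, cond_b: Condition
) -> GroupAssignment:
    """Partition records into groups I-IV by the two conditions.

    I = A and B, II = A and not B, III = not A and B, IV = neither.  The
    comparator senses are taken literally from the conditions (``<=`` is
    inclusive, ``>`` exclusive).
    """
    for cond in (cond_a, cond_b):
        if cond.feature not in frame.columns:
            raise InputError(f"feature {cond.feature!r} not in the table")
    a = cond_a.holds(frame[cond_a.feature].to_numpy())
    b = cond_b.holds(frame[cond_b.feature].to_numpy())
    labels = tuple(
        "I" if ai and bi else "II" if ai else "III" if bi else "IV"
        for ai, bi in zip(a, b)
    )
    return GroupAssignment(labels=labels, cond_a=cond_a, cond_b=cond_b)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(ranks_x: np.ndarray, nx: int) -> float:
    return float(ranks_x.sum() - nx * (nx + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_cap: int = 200_000,
) -> TestResult:
    """Rank-sum Mann-Whitney U test with midrank ties.

    The p-value is exact -- a full enumeration of which ranks belong to
    ``x`` (valid with ties, using midranks) -- whenever the number of
    combinations is at most ``exact_cap``; otherwise it falls back to the
    normal approximation with tie and continuity corrections.  The reported
    statistic is U for the first sample.  Two-sided exact p counts outcomes
    at least as far from the null mean as observed (so identical samples
    give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    if alternative not in ("two-sided", "less", "greater"):
        raise InputError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:nx], nx)
    mu = nx * ny / 2.0

    if math.comb(nx + ny, nx) <= exact_cap:
        us = np.array(
            [
                _u_statistic(ranks[list(idx)], nx)
                for idx in combinations(range(nx + ny), nx)
            ]
        )
        tol = 1e-9
        if alternative == "two-sided":
            p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - tol))
        elif alternative == "less":
            p = float(np.mean(us <= u_obs + tol))
        else:
            p = float(np.mean(us >= u_obs - tol))
        method = "mann-whitney-u-exact"
        extra = {"exact": True}
    else:
        n = nx + ny
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        sd = math.sqrt(nx * ny / 12.0 * ((n + 1) - tie_term))
        if sd == 0.0:
            p = 1.0
        else:
            if alternative == "two-sided":
                z = (abs(u_obs - mu) - 0.5) / sd
                p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
            elif alternative == "less":
                z = (u_obs - mu + 0.5) / sd
                p = float(sps.norm.cdf(z))
            else:
                z = (u_obs - mu - 0.5) / sd
                p = float(sps.norm.sf(z))
        method = "mann-whitney-u-normal"
        extra = {"exact": False}
    return TestResult(
        method=method,
        statistic=u_obs,
        p_value=p,
        group_sizes=(nx, ny),
        alternative=alternative,
        extra=extra,
    )


# ---------------------------------------------------------------------------
# Dunnett's many-to-one comparison
# ---------------------------------------------------------------------------

def _pooled_t_stats(
    control: np.ndarray, treatments: list[np.ndarray]
) -> tuple[np.ndarray, float, int]:
    groups = [control] + treatments
    n_total = sum(g.size for g in groups)
    df = n_total - len(groups)
    ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if df <= 0 or ss <= 0.0:
        raise InputError("zero pooled variance; Dunnett test is degenerate")
    s2 = ss / df
    ts = np.array(
        [
            (t.mean() - control.mean()) / math.sqrt(s2 * (1 / t.size + 1 / control.size))
            for t in treatments
        ]
    )
    return ts, s2, df


def dunnett_test(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    alpha: float = 0.05,
    alternative: str = "two-sided",
    backend: str = "analytic",
    n_mc: int = 100_000,
    seed: int = 0,
) -> list[TestResult]:
    """Compare each treatment mean against the control with family-wise
    adjustment over the many-to-one comparisons.

    ``backend="analytic"`` integrates the multivariate t distribution of
    the comparison statistics; ``backend="montecarlo"`` estimates the null
    distribution of the most extreme statistic from ``n_mc`` simulated
    datasets with the observed group sizes (fixed seed; the Monte-Carlo
    standard error of each p-value is reported in ``extra``).
    """
    control = np.asarray(control, dtype=float)
    tr = [np.asarray(t, dtype=float) for t in treatments]
    if control.size < 2 or any(t.size < 2 for t in tr):
        raise InputError("control and every treatment need >= 2 observations")
    if alternative not in ("two-sided", "less", "greater"):
        raise InputError(f"unknown alternative {alternative!r}")
    ts, _, df = _pooled_t_stats(control, tr)
    sizes = tuple([control.size] + [t.size for t in tr])

    if backend == "analytic":
        res = sps.dunnett(
            *tr, control=control, alternative=alternative, rng=seed
        )
        pvals = np.atleast_1d(res.pvalue)
        stats = np.atleast_1d(res.statistic)
        return [
            TestResult(
                method="dunnett-analytic",
                statistic=float(stats[i]),
                p_value=float(min(1.0, max(0.0, pvals[i]))),
                group_sizes=sizes,
                alternative=alternative,
                extra={"df": df, "alpha": alpha},
            )
            for i in range(len(tr))
        ]
    if backend != "montecarlo":
        raise InputError(f"unknown backend {backend!r}")

    rng = np.random.default_rng(seed)
    null_extreme = np.empty(n_mc)
    for i in range(n_mc):
        c = rng.standard_normal(control.size)
        sim = [rng.standard_normal(t.size) for t in tr]
        sim_ts, _, _ = _pooled_t_stats(c, sim)
        if alternative == "two-sided":
            null_extreme[i] = np.max(np.abs(sim_ts))
        elif alternative == "greater":
            null_extreme[i] = np.max(sim_ts)
        else:
            null_extreme[i] = np.min(sim_ts)

    out = []
    for i, t_obs in enumerate(ts):
        if alternative == "two-sided":
            p = float(np.mean(null_extreme >= abs(t_obs)))
        elif alternative == "greater":
            p = float(np.mean(null_extreme >= t_obs))
        else:
            p = float(np.mean(null_extreme <= t_obs))
        se = math.sqrt(max(p * (1 - p), 1e-12) / n_mc)
        out.append(
            TestResult(
                method="dunnett-montecarlo",
                statistic=float(t_obs),
                p_value=p,
                group_sizes=sizes,
                alternative=alternative,
                extra={"df": df, "alpha": alpha, "mc_se": se, "n_mc": n_mc},
            )
        )
    return out
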