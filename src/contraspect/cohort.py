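"""Timeline assembly and the rank-based two-condition comparison.

The Mann-Whitney U test is implemented here in full rather than delegated:
the exact null distribution of U is built by the standard counting recursion
(number of rank arrangements per U value), giving exact p-values for tie-free
data up to a configurable total sample size; otherwise a normal approximation
with mid-ranks, tie correction and continuity correction is used.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from functools import lru_cache
from math import comb, erf, sqrt
from typing import Sequence

import numpy as np
import pandas as pd

from .contrast import ContrastResult
from .errors import ValidationError
from .image_io import CatalogRecord, Condition

#: largest n_a + n_b for which the exact null distribution is enumerated.
EXACT_MAX_TOTAL = 28


class Sidedness(str, enum.Enum):
    TWO_SIDED = "two_sided"
    #: alternative: group_b (the "high" condition) tends to exceed group_a
    ONE_SIDED_GREATER = "one_sided_greater"


class TestMethod(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


@dataclass(frozen=True)
class CohortRow:
    image_id: str
    order_index: int
    date_label: str
    condition: Condition
    variance_contrast: float
    rms_contrast: float


@dataclass(frozen=True)
class CohortTable:
    """Chronologically ordered per-image contrast records."""

    rows: tuple[CohortRow, ...]

    def __post_init__(self) -> None:
        orders = [r.order_index for r in self.rows]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise ValidationError("rows must be strictly ascending in order_index")
        object.__setattr__(self, "rows", tuple(self.rows))

    def __len__(self) -> int:
        return len(self.rows)

    def metric_values(self, metric: str, condition: Condition) -> np.ndarray:
        if metric not in ("variance", "rms"):
            raise ValidationError(f"metric must be 'variance' or 'rms', got {metric!r}")
        key = "variance_contrast" if metric == "variance" else "rms_contrast"
        return np.array(
            [getattr(r, key) for r in self.rows if r.condition is condition]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": r.image_id,
                    "order_index": r.order_index,
                    "date_label": r.date_label,
                    "condition": r.condition.value,
                    "variance_contrast": r.variance_contrast,
                    "rms_contrast": r.rms_contrast,
                }
                for r in self.rows
            ]
        )


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the two-sample rank comparison."""

    u_statistic: float
    p_value: float
    method: TestMethod
    sidedness: Sidedness
    n_low: int
    n_high: int
    median_low: float
    median_high: float

    def to_dict(self) -> dict:
        return {
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "method": self.method.value,
            "sidedness": self.sidedness.value,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "median_low": self.median_low,
            "median_high": self.median_high,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def assemble_timeline(
    records: Sequence[CatalogRecord], contrasts: Sequence[ContrastResult]
) -> CohortTable:
    """Merge catalog records with contrast results, matched on image_id."""
    by_id = {c.image_id: c for c in contrasts}
    if len(by_id) != len(contrasts):
        raise ValidationError("duplicate image_id among contrast results")
    missing = [r.image_id for r in records if r.image_id not in by_id]
    if missing:
        raise ValidationError(f"no contrast result for image_id(s) {missing}")
    extra = set(by_id) - {r.image_id for r in records}
    if extra:
        raise ValidationError(f"contrast result(s) without catalog record: {sorted(extra)}")
    rows = tuple(
        CohortRow(
            image_id=r.image_id,
            order_index=r.order_index,
            date_label=r.date_label,
            condition=r.condition,
            variance_contrast=by_id[r.image_id].variance_contrast,
            rms_contrast=by_id[r.image_id].rms_contrast,
        )
        for r in sorted(records, key=lambda r: r.order_index)
    )
    return CohortTable(rows=rows)


@lru_cache(maxsize=64)
def _u_null_cdf(n_a: int, n_b: int) -> np.ndarray:
    """Exact null CDF of U over 0..n_a*n_b via the counting recursion.

    f(a, b, u) = f(a-1, b, u-b) + f(a, b-1, u) counts the rank arrangements
    of a-group observations among a+b with U statistic u.  Evaluated
    iteratively; exact in integer arithmetic, normalised at the end.
    """
    m = n_a * n_b
    # table[b][u] = f(a, b, u) for the current a
    table = np.zeros((n_b + 1, m + 1), dtype=object)
    table[:, 0] = 1
    for _a in range(1, n_a + 1):
        new = np.zeros_like(table)
        new[0, 0] = 1
        for b in range(1, n_b + 1):
            for u in range(m + 1):
                shifted = table[b, u - b] if u >= b else 0
                new[b, u] = shifted + new[b - 1, u]
        table = new
    counts = table[n_b]
    total = comb(n_a + n_b, n_a)
    assert sum(counts) == total
    cum = np.cumsum([int(c) for c in counts], dtype=object)
    return np.array([float(c) / float(total) for c in cum])


def _rank_sums(values: np.ndarray, n_a: int) -> tuple[float, float, bool]:
    """Mid-rank U statistics (U_a, U_b) and a tie flag for pooled data."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    # mid-ranks over tied runs
    i = 0
    has_ties = False
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            has_ties = True
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r_a = ranks[:n_a].sum()
    n_b = len(values) - n_a
    u_a = r_a - n_a * (n_a + 1) / 2.0
    return u_a, n_a * n_b - u_a, has_ties


def _normal_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    sidedness: Sidedness = Sidedness.TWO_SIDED,
    exact_max_total: int = EXACT_MAX_TOTAL,
) -> GroupComparison:
    """Mann-Whitney U test of ``group_a`` (low) versus ``group_b`` (high).

    For tie-free data with ``n_a + n_b <= exact_max_total`` the p-value is
    exact: two-sided ``p = min(1, 2 P(U <= min(U_a, U_b)))``; one-sided
    (alternative: b > a) ``p = P(U <= U_a)``.  Otherwise a normal
    approximation with tie and continuity corrections is used.  The reported
    U is ``min(U_a, U_b)`` two-sided and ``U_a`` one-sided.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("non-finite values in input groups")
    sidedness = Sidedness(sidedness)
    n_a, n_b = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    u_a, u_b, has_ties = _rank_sums(pooled, n_a)
    u_min = min(u_a, u_b)

    if not has_ties and n_a + n_b <= exact_max_total:
        cdf = _u_null_cdf(n_a, n_b)
        if sidedness is Sidedness.TWO_SIDED:
            p = min(1.0, 2.0 * float(cdf[int(round(u_min))]))
            u_report = u_min
        else:
            p = float(cdf[int(round(u_a))])
            u_report = u_a
        method = TestMethod.EXACT
    else:
        n = n_a + n_b
        _, tie_sizes = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_sizes**3 - tie_sizes).sum()) / (n * (n - 1)))
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        mu = n_a * n_b / 2.0
        if sigma2 <= 0:
            p = 1.0
        elif sidedness is Sidedness.TWO_SIDED:
            z = (u_min - mu + 0.5) / sqrt(sigma2)
            p = min(1.0, 2.0 * (1.0 - _normal_sf(z)))
        else:
            z = (u_a - mu + 0.5) / sqrt(sigma2)
            p = 1.0 - _normal_sf(z)
        u_report = u_min if sidedness is Sidedness.TWO_SIDED else u_a
        method = TestMethod.NORMAL_APPROX

    return GroupComparison(
        u_statistic=float(u_report),
        p_value=float(p),
        method=method,
        sidedness=sidedness,
        n_low=n_a,
        n_high=n_b,
        median_low=float(np.median(a)),
        median_high=float(np.median(b)),
    )


def compare_conditions(
    table: CohortTable,
    metric: str = "rms",
    sidedness: Sidedness = Sidedness.TWO_SIDED,
) -> GroupComparison:
    """Split the cohort by condition and rank-test the chosen contrast metric.

    Because ranks are invariant under strictly increasing transforms, the U
    statistic (and p) are identical for ``metric='variance'`` and
    ``metric='rms'``.
    """
    low = table.metric_values(metric, Condition.LOW)
    high = table.metric_values(metric, Condition.HIGH)
    if low.size == 0 or high.size == 0:
        raise ValidationError(
            "cohort table must contain both conditions "
            f"(n_low={low.size}, n_high={high.size})"
        )
    return mann_whitney_u(low, high, sidedness)


def plot_timeline(table: CohortTable, path, metric: str = "rms") -> None:
    """Ordered contrast-versus-rank scatter/line plot, condition color-coded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    key = "variance_contrast" if metric == "variance" else "rms_contrast"
    xs = [r.order_index for r in table.rows]
    ys = [getattr(r, key) for r in table.rows]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(xs, ys, color="0.6", lw=1, zorder=1)
    for cond, color in ((Condition.LOW, "tab:blue"), (Condition.HIGH, "tab:red")):
        sel = [(x, y) for x, y, r in zip(xs, ys, table.rows) if r.condition is cond]
        if sel:
            ax.scatter(*zip(*sel), color=color, label=cond.value, zorder=2)
    ax.set_xlabel("chronological rank")
    ax.set_ylabel(f"{metric} contrast")
    ax.legend(title="condition")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
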