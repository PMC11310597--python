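"""Disproportionality statistics: 2x2 tables, ROR and IC, and the signal rule.

For a drug (exposure group) and an event, reports are cross-classified as

    ============================  ==============  ============
                                  target event    other events
    ============================  ==============  ============
    target drug / group           a               b
    all other reports             c               d
    ============================  ==============  ============

The reporting odds ratio is ``ROR = (a d)/(b c)`` with the Woolf log-scale
95% interval ``exp(ln ROR ± z sqrt(1/a + 1/b + 1/c + 1/d))``; zero cells are
handled by the Haldane–Anscombe +0.5 correction.

The information component is the shrunk log2 observed-to-expected ratio of
the Bayesian confidence propagation framework,

    E  = (a + b)(a + c) / N,        IC = log2((a + 0.5) / (E + 0.5)),

with either the Norén credible-interval approximation (default)

    IC025 = IC - 3.3 (a+0.5)^-1/2 - 2   (a+0.5)^-3/2
    IC975 = IC + 2.4 (a+0.5)^-1/2 - 0.5 (a+0.5)^-3/2

or a normal interval from the closed-form posterior variance of the original
BCPNN formulation (``method="bate_variance"``).

A drug–event pair is a *signal* when the pair has at least ``min_cases``
reports, the ROR lower bound exceeds 1, and the IC lower bound exceeds 0 —
the joint rule is deliberately conservative against small-count false
positives.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

Z95 = 1.96
DEFAULT_MIN_CASES = 3
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d) of a drug–event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            value = getattr(self, name)
            if value != int(value) or value < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {value!r}")
        if self.n <= 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class RorEstimate(NamedTuple):
    ror: float
    low: float
    high: float
    haldane_applied: bool


class IcEstimate(NamedTuple):
    ic: float
    low: float
    high: float


def ror(table: ContingencyTable, z: float = Z95,
        haldane: bool | None = None) -> RorEstimate:
    """Reporting odds ratio with a Woolf log-scale confidence interval.

    ``haldane=None`` (default) applies the +0.5 correction exactly when some
    cell is zero; ``haldane=False`` raises on zero cells instead.
    """
    cells = table.cells()
    has_zero = any(v == 0 for v in cells)
    if haldane is None:
        haldane = has_zero
    if not haldane and has_zero:
        raise ValueError(
            "zero cell in contingency table; pass haldane=True (or None) to "
            "apply the +0.5 continuity correction")
    a, b, c, d = ((v + 0.5 for v in cells) if haldane else (float(v) for v in cells))
    a, b, c, d = float(a), float(b), float(c), float(d)
    estimate = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(estimate)
    return RorEstimate(
        ror=estimate,
        low=math.exp(log_ror - z * se),
        high=math.exp(log_ror + z * se),
        haldane_applied=bool(haldane),
    )


def _ic_point(a: int, expected: float) -> float:
    return math.log2((a + 0.5) / (expected + 0.5))


def _noren_interval(ic_value: float, a: int) -> tuple[float, float]:
    s = a + 0.5
    low = ic_value - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    high = ic_value + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
    return low, high


def _bate_variance(table: ContingencyTable) -> tuple[float, float]:
    """Posterior expectation and variance of IC in the original closed-form
    BCPNN parameterisation (priors alpha1 = beta1 = 1, alpha = beta = 2,
    gamma11 = 1)."""
    a, b, c, d = table.cells()
    n = table.n
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    row = a + b + a1
    col = a + c + b1
    gamma = g11 * (n + al) * (n + be) / (row * col)
    expectation = math.log((a + g11) * (n + al) * (n + be) / ((n + gamma) * row * col)) / LN2
    variance = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + al - a1) / (row * (1 + n + al))
        + (n - (a + c) + be - b1) / (col * (1 + n + be))
    ) / (LN2 ** 2)
    return expectation, variance


def ic(table: ContingencyTable, method: str = "noren_credible",
       z: float = Z95) -> IcEstimate:
    """Information component with a 95% credibility interval.

    ``noren_credible`` keeps the shrunk log2 observed/expected point estimate
    and the Norén two-term interval approximation; ``bate_variance`` uses the
    closed-form posterior expectation and a normal interval from its
    variance.
    """
    if method == "noren_credible":
        point = _ic_point(table.a, table.expected)
        low, high = _noren_interval(point, table.a)
    elif method == "bate_variance":
        point, variance = _bate_variance(table)
        half = z * math.sqrt(variance)
        low, high = point - half, point + half
    else:
        raise ValueError(f"unknown IC method {method!r}")
    return IcEstimate(ic=point, low=low, high=high)


@dataclass(frozen=True)
class SignalResult:
    """Point estimates, interval bounds and the signal flag for one pair."""

    n_cases: int
    ror: float
    ror_low: float
    ror_high: float
    ic: float
    ic_low: float
    ic_high: float
    expected: float
    is_signal: bool
    haldane_applied: bool = False
    min_cases: int = DEFAULT_MIN_CASES
    ic_method: str = "noren_credible"
    table: ContingencyTable | None = None


def is_signal(n_cases: int, ror_low: float, ic_low: float,
              min_cases: int = DEFAULT_MIN_CASES) -> bool:
    """The joint signal rule: enough cases, ROR025 > 1 and IC025 > 0."""
    return (n_cases >= min_cases) and (ror_low > 1.0) and (ic_low > 0.0)


def evaluate_signal(
    table: ContingencyTable,
    min_cases: int = DEFAULT_MIN_CASES,
    z: float = Z95,
    ic_method: str = "noren_credible",
    haldane: bool | None = None,
) -> SignalResult:
    """Compute ROR, IC and the signal flag for one contingency table."""
    ror_est = ror(table, z=z, haldane=haldane)
    ic_est = ic(table, method=ic_method, z=z)
    return SignalResult(
        n_cases=table.a,
        ror=ror_est.ror,
        ror_low=ror_est.low,
        ror_high=ror_est.high,
        ic=ic_est.ic,
        ic_low=ic_est.low,
        ic_high=ic_est.high,
        expected=table.expected,
        is_signal=is_signal(table.a, ror_est.low, ic_est.low, min_cases),
        haldane_applied=ror_est.haldane_applied,
        min_cases=min_cases,
        ic_method=ic_method,
        table=table,
    )


def build_table(
    labeled: pd.DataFrame,
    group: str | Sequence[str],
    comparator: str = "rest_of_store",
    background: tuple[int, int] | None = None,
    group_col: str = "group",
    case_col: str = "is_case",
) -> ContingencyTable:
    """2x2 table for an exposure group in a labeled report store.

    ``labeled`` holds one row per analysis unit (report, or report–PT pair)
    with its exposure label and a boolean event column.  ``group`` may be a
    single label or a collection of labels treated as one aggregate.  With
    ``comparator="rest_of_store"`` cells c/d come from all other rows; with
    ``comparator="explicit_background"`` the caller supplies ``background=(c,
    d)`` — e.g. counts from a full database the store does not contain.
    """
    groups = [group] if isinstance(group, str) else list(group)
    in_group = labeled[group_col].isin(groups).to_numpy()
    if not in_group.any():
        raise ValueError(f"no exposed reports for group {group!r}")
    cases = labeled[case_col].astype(bool).to_numpy()
    a = int((in_group & cases).sum())
    b = int((in_group & ~cases).sum())
    if comparator == "rest_of_store":
        c = int((~in_group & cases).sum())
        d = int((~in_group & ~cases).sum())
    elif comparator == "explicit_background":
        if background is None:
            raise ValueError("explicit_background comparator requires background=(c, d)")
        c, d = (int(v) for v in background)
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    return ContingencyTable(a=a, b=b, c=c, d=d)


def signal_table(
    labeled: pd.DataFrame,
    groups: Iterable[str | tuple[str, Sequence[str]]],
    comparator: str = "rest_of_store",
    background: tuple[int, int] | None = None,
    min_cases: int = DEFAULT_MIN_CASES,
    z: float = Z95,
    ic_method: str = "noren_credible",
    group_col: str = "group",
    case_col: str = "is_case",
) -> pd.DataFrame:
    """Evaluate the signal rule for several groups and return a flat table.

    Each element of ``groups`` is either a label present in ``labeled`` or a
    ``(name, [labels...])`` aggregate.  Groups with no exposed rows are
    skipped.
    """
    rows = []
    for entry in groups:
        name, members = entry if isinstance(entry, tuple) else (entry, entry)
        try:
            table = build_table(labeled, members, comparator=comparator,
                                background=background, group_col=group_col,
                                case_col=case_col)
        except ValueError:
            continue
        res = evaluate_signal(table, min_cases=min_cases, z=z, ic_method=ic_method)
        rows.append({
            "group": name,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "ror": res.ror, "ror_low": res.ror_low, "ror_high": res.ror_high,
            "ic": res.ic, "ic_low": res.ic_low, "ic_high": res.ic_high,
            "expected": res.expected,
            "is_signal": res.is_signal,
            "below_threshold": table.a < min_cases,
            "haldane_applied": res.haldane_applied,
            "ic_method": ic_method,
        })
    return pd.DataFrame(rows)
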