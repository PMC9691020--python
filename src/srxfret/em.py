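"""Negative-stain EM conformation tallies: open vs closed (IHM) molecules.

Each preparation yields counts of molecules classified as closed (folded,
IHM), open, or unclear.  Percentages are computed over classifiable
molecules only (closed + open), with a Wilson 95% confidence interval on
the closed proportion.  The mutant/WT closed-percentage ratio summarises
how strongly a mutation stabilises the IHM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Any

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = ["EmTally", "tally_percentages", "closed_ratio"]


@dataclass(frozen=True)
class EmTally:
    """Counts of molecule conformations from one EM preparation."""

    prep: Any
    closed: int
    open: int
    unclear: int = 0
    pct_closed: float = np.nan
    pct_open: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    classifiable_fraction: float = np.nan
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("closed", "open", "unclear"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")
        if not np.isnan(self.pct_closed):
            if abs(self.pct_closed + self.pct_open - 100.0) > 1e-9:
                raise ValueError("%closed + %open must equal 100")

    @property
    def classifiable(self) -> int:
        return self.closed + self.open

    @property
    def total(self) -> int:
        return self.closed + self.open + self.unclear


def tally_percentages(t: EmTally) -> EmTally:
    """Fill percentages of classifiable molecules and a Wilson 95% CI.

    %closed = 100 * closed / (closed + open); unclear molecules are
    excluded from the denominator but enter the classifiable fraction of
    the total.
    """
    n = t.classifiable
    if n < 1:
        raise ValueError("no classifiable molecules (closed + open == 0)")
    pct_closed = 100.0 * t.closed / n
    lo, hi = proportion_confint(t.closed, n, alpha=0.05, method="wilson")
    return replace(
        t,
        pct_closed=pct_closed,
        pct_open=100.0 - pct_closed,
        ci_low=100.0 * float(lo),
        ci_high=100.0 * float(hi),
        classifiable_fraction=n / t.total if t.total else np.nan,
    )


def _round_half_away(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def closed_ratio(mutant: "EmTally | float", wt: "EmTally | float") -> dict[str, float]:
    """Ratio of closed percentages, mutant over WT.

    Accepts tallies (percentages computed on the fly) or closed
    percentages directly.  Returns the unrounded ratio and the value
    rounded half-away-from-zero to one decimal, matching conventional
    table presentation.
    """

    def pct(x: "EmTally | float") -> float:
        if isinstance(x, EmTally):
            if np.isnan(x.pct_closed):
                x = tally_percentages(x)
            return x.pct_closed
        return float(x)

    p_mut, p_wt = pct(mutant), pct(wt)
    if p_wt == 0:
        raise ZeroDivisionError("WT closed percentage is zero: ratio undefined")
    ratio = p_mut / p_wt
    return {"ratio": ratio, "ratio_rounded": _round_half_away(ratio, 1)}
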