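"""Steady-state ATPase fitting, NH4+ ATPase rates, and motility aggregation.

Actin-activated ATPase curves are fitted to a Michaelis-Menten form with a
basal offset, v(a) = v0 + k_cat * a / (K_ATPase + a), yielding the maximal
rate k_cat (s^-1 per head) and the actin concentration at half-maximal
activation K_ATPase (uM).  High-salt NH4+ ATPase converts a linear
phosphate-liberation time course into a per-head turnover rate.  In vitro
motility velocities are aggregated replicate-aware (SuperPlot style): the
grand mean is the mean of per-preparation means, never of pooled filaments,
and stuck filaments (velocity exactly 0 nm/s) are excluded from velocity
means but reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "AtpaseCurve",
    "PhosphateTimecourse",
    "MotilitySet",
    "fit_michaelis_menten",
    "fold_change",
    "nh4_per_head_rate",
    "standard_curve",
    "motility_summary",
]


@dataclass(frozen=True)
class AtpaseCurve:
    """Actin-dependence of the steady-state ATPase rate.

    Before fitting, only ``actin_uM`` and ``rates`` (s^-1 per head) are
    set; :func:`fit_michaelis_menten` fills ``v0``, ``k_cat`` and
    ``k_atpase`` with standard errors.
    """

    actin_uM: np.ndarray
    rates: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)
    v0: float | None = None
    k_cat: float | None = None
    k_atpase: float | None = None
    v0_se: float = np.nan
    k_cat_se: float = np.nan
    k_atpase_se: float = np.nan
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.actin_uM, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "actin_uM", a)
        object.__setattr__(self, "rates", r)
        if a.shape != r.shape or a.ndim != 1:
            raise ValueError("actin_uM and rates must be matching 1-D arrays")
        if np.any(a < 0):
            raise ValueError("actin concentrations must be non-negative")
        if np.any(r < 0):
            raise ValueError("ATPase rates must be non-negative")
        if self.k_atpase is not None and self.k_atpase <= 0:
            raise ValueError("fitted K_ATPase must be positive")

    def predict(self, actin_uM: np.ndarray) -> np.ndarray:
        if self.k_cat is None:
            raise ValueError("curve not fitted yet")
        a = np.asarray(actin_uM, dtype=float)
        return self.v0 + self.k_cat * a / (self.k_atpase + a)


@dataclass(frozen=True)
class PhosphateTimecourse:
    """Phosphate liberation vs time for the high-salt NH4+ ATPase assay.

    ``pi_uM`` is the free-phosphate concentration at each sampling time,
    obtained from a colorimetric standard curve; ``heads_uM`` the myosin
    head concentration.  ``standard_curve_r2`` carries the calibration
    fit quality when the conversion was done here.
    """

    times_min: np.ndarray
    pi_uM: np.ndarray
    heads_uM: float
    standard_curve_r2: float = np.nan
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        p = np.asarray(self.pi_uM, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "pi_uM", p)
        if t.size < 3:
            raise ValueError("at least 3 time points required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.heads_uM <= 0:
            raise ValueError("head concentration must be positive")


@dataclass(frozen=True)
class MotilitySet:
    """Per-preparation filament velocity samples (nm/s, stuck = exact 0)."""

    preps: tuple[np.ndarray, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.preps) < 1:
            raise ValueError("at least one preparation required")
        object.__setattr__(
            self, "preps", tuple(np.asarray(p, dtype=float) for p in self.preps)
        )


# ---------------------------------------------------------------------------


def _mm(a: np.ndarray, v0: float, k_cat: float, K: float) -> np.ndarray:
    return v0 + k_cat * a / (K + a)


def fit_michaelis_menten(curve: AtpaseCurve) -> AtpaseCurve:
    """Least-squares fit of v(a) = v0 + k_cat*a/(K_ATPase + a).

    Requires at least four distinct actin concentrations including 0
    (which anchors the basal rate v0).  Flat data (no actin activation)
    degenerates to v0 = mean rate with K unconstrained, flagged
    ``"k-unconstrained"``; a fitted K exceeding 10x the largest actin
    concentration is flagged ``"poorly-constrained-K"``.
    """
    a, r = curve.actin_uM, curve.rates
    if len(np.unique(a)) < 4:
        raise ValueError("need >= 4 distinct actin concentrations")
    if not np.any(a == 0):
        raise ValueError("a zero-actin (basal) point is required")

    if np.ptp(r) < 1e-12:
        return replace(
            curve,
            v0=float(r.mean()),
            k_cat=0.0,
            k_atpase=None,
            flags=curve.flags + ("k-unconstrained",),
        )

    amax = a.max()
    p0 = (max(r[a == 0].mean(), 1e-6), max(np.ptp(r), 1e-6), np.median(a[a > 0]))
    popt, pcov = curve_fit(
        _mm, a, r, p0=p0,
        bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    ses = np.sqrt(np.clip(np.diag(pcov), 0, None))
    flags = list(curve.flags)
    if popt[2] > 10 * amax:
        flags.append("poorly-constrained-K")
    return replace(
        curve,
        v0=float(popt[0]),
        k_cat=float(popt[1]),
        k_atpase=float(popt[2]),
        v0_se=float(ses[0]),
        k_cat_se=float(ses[1]),
        k_atpase_se=float(ses[2]),
        flags=tuple(flags),
    )


def fold_change(a: AtpaseCurve, b: AtpaseCurve, param: str = "k_cat") -> float:
    """Ratio of a fitted parameter between two fitted curves (a / b)."""
    va, vb = getattr(a, param), getattr(b, param)
    if va is None or vb is None:
        raise ValueError("both curves must be fitted first")
    if vb == 0:
        raise ZeroDivisionError(f"{param} of denominator curve is zero")
    return float(va / vb)


def standard_curve(
    conc_uM: Sequence[float], absorbance: Sequence[float]
) -> dict[str, float]:
    """OLS calibration line absorbance = slope*[Pi] + intercept.

    Returns slope, intercept and R^2; the inverse map converts assay
    absorbances to phosphate concentrations.  The intercept is retained
    (the line is not forced through zero).
    """
    res = stats.linregress(np.asarray(conc_uM, float), np.asarray(absorbance, float))
    if res.slope <= 0:
        raise ValueError("standard curve must be monotone increasing")
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
    }


def nh4_per_head_rate(tc: PhosphateTimecourse) -> dict[str, float]:
    """Per-head NH4+ ATPase rate from a linear phosphate time course.

    [Pi] (uM) is regressed on time (min); the slope, divided by the head
    concentration and converted to seconds, is the turnover rate in
    s^-1 per head.
    """
    res = stats.linregress(tc.times_min, tc.pi_uM)
    if res.slope < 0:
        raise ValueError("negative phosphate-liberation slope: invalid assay")
    rate = res.slope / 60.0 / tc.heads_uM
    rate_se = (res.stderr / 60.0 / tc.heads_uM) if np.isfinite(res.stderr) else np.nan
    return {"rate_per_head_s": float(rate), "rate_se": float(rate_se),
            "slope_uM_per_min": float(res.slope), "r2": float(res.rvalue**2)}


def motility_summary(
    ms: MotilitySet, other: MotilitySet | None = None
) -> dict[str, Any]:
    """Replicate-aware summary of in vitro motility velocities.

    Per preparation: mean velocity of moving (non-stuck) filaments and
    percent stuck.  The grand mean +/- SD is computed over preparation
    means (SuperPlot aggregation), making it invariant to per-prep
    sample size.  When a second set is supplied, an unpaired equal-
    variance t-test on the preparation means is reported.
    """

    def summarise(s: MotilitySet) -> pd.DataFrame:
        rows = []
        for i, v in enumerate(s.preps):
            stuck = v == 0.0
            moving = v[~stuck]
            rows.append(
                {
                    "prep": i + 1,
                    "n_filaments": v.size,
                    "n_stuck": int(stuck.sum()),
                    "percent_stuck": 100.0 * stuck.mean() if v.size else np.nan,
                    "mean_velocity": moving.mean() if moving.size else np.nan,
                }
            )
        return pd.DataFrame(rows)

    per_prep = summarise(ms)
    means = per_prep["mean_velocity"].to_numpy()
    flags = []
    if np.any(np.isnan(means)):
        flags.append("all-stuck-prep")
    valid = means[~np.isnan(means)]
    out: dict[str, Any] = {
        "per_prep": per_prep,
        "grand_mean": float(valid.mean()) if valid.size else np.nan,
        "grand_sd": float(valid.std(ddof=1)) if valid.size > 1 else np.nan,
        "percent_stuck_mean": float(per_prep["percent_stuck"].mean()),
        "flags": tuple(flags),
    }
    if other is not None:
        other_means = summarise(other)["mean_velocity"].dropna().to_numpy()
        if valid.size >= 2 and other_means.size >= 2:
            t = stats.ttest_ind(valid, other_means, equal_var=True)
            p = float(t.pvalue)
            out["p_value"] = 1.0 if np.isnan(p) else p
        else:
            out["p_value"] = np.nan
    return out
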