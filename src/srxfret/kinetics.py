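"""Candidate mechanisms for Cy3ATP binding and IHM formation.

Two mass-action mechanisms can explain the bi-phasic FRET transients seen
when Cy3ATP binds two-headed cardiac myosin carrying a C-terminal GFP tag:

Scheme 1 (two apo conformations, both binding-competent)::

    Apo_Open --k_T*[ATP]-->  OpenATP --k_IHM-->  IHM
    Apo_ALT  --k'_T*[ATP]--> ALTATP  --k'_IHM--> IHM

  The alternate (ALT) conformation binds ATP 10-20-fold slower than the
  Open conformation, so both observed phases are ATP-concentration
  dependent.  Open<->ALT interconversion is off on the transient's time
  scale (the slow phase is ATP dependent, implying direct binding from
  ALT).

Scheme 2 (slow isomerisation from a binding-incompetent conformation)::

    Apo_INC <--k_iso+/k_iso--> Apo_Open --k_T*[ATP]--> OpenATP --k_IHM--> IHM

  Here the slow phase arises from the INC -> Open isomerisation that must
  precede binding.

FRET (donor quenching) reports the summed occupancy of the FRET-visible
state set, by default {IHM}.  ATP is treated as in excess
(pseudo-first-order binding), making both schemes linear ODE systems; an
exact bimolecular mode is available via ``simulate_scheme(..., pseudo_first_order=False)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .containers import Transient
from .transients import fit_exponentials, _aicc

__all__ = [
    "KineticScheme",
    "SchemeTrajectory",
    "BindingKinetics",
    "SchemeFit",
    "SimulationError",
    "simulate_scheme",
    "extract_kobs",
    "global_fit_scheme",
    "compare_schemes",
]

SCHEME_STATES: dict[str, tuple[str, ...]] = {
    "scheme1": ("Apo_Open", "Apo_ALT", "OpenATP", "ALTATP", "IHM"),
    "scheme2": ("Apo_Open", "Apo_INC", "OpenATP", "IHM"),
}


class SimulationError(RuntimeError):
    """ODE integration failure, carrying the offending scheme."""


@dataclass(frozen=True)
class KineticScheme:
    """A mass-action mechanism for Cy3ATP binding and IHM formation.

    Parameters
    ----------
    scheme_id : {"scheme1", "scheme2"}
    k_T : float
        Second-order ATP binding rate of the Open conformation (uM^-1 s^-1).
    kp_T : float
        Second-order binding rate of the ALT conformation (scheme1 only;
        must be smaller than ``k_T``).  Ignored by scheme2.
    k_IHM, kp_IHM : float
        First-order transitions (s^-1) of the ATP-bound Open / ALT states
        into the IHM.  ``kp_IHM`` applies to scheme1 only.
    k_iso_plus, k_iso_minus : float
        Apo isomerisation rates (s^-1) INC -> Open and Open -> INC
        (scheme2 only; its defining feature).
    open_fraction : float
        Initial occupancy of Apo_Open; the remainder starts in Apo_ALT
        (scheme1) or Apo_INC (scheme2).
    fret_states : tuple of str
        States whose summed occupancy produces FRET (donor quenching).
    """

    scheme_id: str
    k_T: float
    kp_T: float = 0.0
    k_IHM: float = 0.0
    kp_IHM: float = 0.0
    k_iso_plus: float = 0.0
    k_iso_minus: float = 0.0
    open_fraction: float = 1.0
    fret_states: tuple[str, ...] = ("IHM",)

    def __post_init__(self) -> None:
        if self.scheme_id not in SCHEME_STATES:
            raise ValueError(f"unknown scheme_id {self.scheme_id!r}")
        for name in ("k_T", "kp_T", "k_IHM", "kp_IHM", "k_iso_plus", "k_iso_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.open_fraction <= 1.0:
            raise ValueError("open_fraction must lie in [0, 1]")
        if self.scheme_id == "scheme1" and self.kp_T >= self.k_T and self.kp_T > 0:
            raise ValueError("scheme1 requires kp_T < k_T (ALT binds slower)")
        unknown = set(self.fret_states) - set(self.states)
        if unknown:
            raise ValueError(f"fret_states not in scheme: {sorted(unknown)}")

    @property
    def states(self) -> tuple[str, ...]:
        return SCHEME_STATES[self.scheme_id]

    def initial_occupancy(self) -> np.ndarray:
        p0 = np.zeros(len(self.states))
        p0[0] = self.open_fraction
        p0[1] = 1.0 - self.open_fraction
        return p0

    def rate_matrix(self, atp_uM: float) -> np.ndarray:
        """Generator matrix Q with d p/dt = Q @ p (pseudo-first-order)."""
        idx = {s: i for i, s in enumerate(self.states)}
        Q = np.zeros((len(idx), len(idx)))

        def add(src: str, dst: str, rate: float) -> None:
            Q[idx[src], idx[src]] -= rate
            Q[idx[dst], idx[src]] += rate

        if self.scheme_id == "scheme1":
            add("Apo_Open", "OpenATP", self.k_T * atp_uM)
            add("Apo_ALT", "ALTATP", self.kp_T * atp_uM)
            add("OpenATP", "IHM", self.k_IHM)
            add("ALTATP", "IHM", self.kp_IHM)
        else:  # scheme2
            add("Apo_INC", "Apo_Open", self.k_iso_plus)
            add("Apo_Open", "Apo_INC", self.k_iso_minus)
            add("Apo_Open", "OpenATP", self.k_T * atp_uM)
            add("OpenATP", "IHM", self.k_IHM)
        return Q

    def to_dict(self) -> dict[str, Any]:
        return {
            "scheme_id": self.scheme_id,
            "k_T": self.k_T,
            "kp_T": self.kp_T,
            "k_IHM": self.k_IHM,
            "kp_IHM": self.kp_IHM,
            "k_iso_plus": self.k_iso_plus,
            "k_iso_minus": self.k_iso_minus,
            "open_fraction": self.open_fraction,
            "fret_states": list(self.fret_states),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "KineticScheme":
        d = dict(d)
        if "fret_states" in d:
            d["fret_states"] = tuple(d["fret_states"])
        return cls(**d)


@dataclass(frozen=True)
class SchemeTrajectory:
    """Occupancy trajectories from a scheme simulation."""

    time: np.ndarray
    occupancy: np.ndarray  # shape (n_t, n_states)
    states: tuple[str, ...]
    f_fret: np.ndarray

    def occupancy_of(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "time_s", self.time)
        df["f_fret"] = self.f_fret
        return df


def simulate_scheme(
    scheme: KineticScheme,
    atp_uM: float,
    grid: np.ndarray,
    myosin_uM: float | None = None,
    pseudo_first_order: bool = True,
) -> SchemeTrajectory:
    """Integrate the mechanism and return occupancies and f_FRET(t).

    With ``pseudo_first_order=True`` (the experimental regime: ATP in
    excess over heads) the system is linear and the nucleotide
    concentration is held constant.  The exact bimolecular mode depletes
    ATP stoichiometrically (requires ``myosin_uM``, total head sites).
    Integration uses a stiff solver at rtol 1e-8 / atol 1e-10, and
    occupancy conservation is verified at every output time.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")
    if atp_uM <= 0:
        raise ValueError("atp_uM must be positive")

    p0 = scheme.initial_occupancy()
    idx = {s: i for i, s in enumerate(scheme.states)}

    if pseudo_first_order:
        Q = scheme.rate_matrix(atp_uM)

        def rhs(_t: float, p: np.ndarray) -> np.ndarray:
            return Q @ p

        y0 = p0
    else:
        if myosin_uM is None:
            raise ValueError("exact bimolecular mode requires myosin_uM")

        binding = []  # (source index, second-order rate)
        if scheme.scheme_id == "scheme1":
            binding = [(idx["Apo_Open"], scheme.k_T), (idx["Apo_ALT"], scheme.kp_T)]
        else:
            binding = [(idx["Apo_Open"], scheme.k_T)]

        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            p, atp = y[:-1], y[-1]
            Q = scheme.rate_matrix(max(atp, 0.0))
            dp = Q @ p
            datp = -sum(rate * atp * p[i] for i, rate in binding) * myosin_uM
            return np.append(dp, datp)

        y0 = np.append(p0, atp_uM)

    t0 = min(0.0, grid[0])
    sol = solve_ivp(
        rhs,
        (t0, grid[-1]),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed ({sol.message}) for scheme {scheme.to_dict()}"
        )
    occ = sol.y[: len(scheme.states)].T
    total = occ.sum(axis=1)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise SimulationError(
            f"occupancy conservation violated (max dev {np.max(np.abs(total - 1.0)):.2e}) "
            f"for scheme {scheme.to_dict()}"
        )
    fret_idx = [idx[s] for s in scheme.fret_states]
    f_fret = occ[:, fret_idx].sum(axis=1)
    return SchemeTrajectory(grid, occ, scheme.states, f_fret)


# ---------------------------------------------------------------------------
# phenomenological k_obs extraction


@dataclass(frozen=True)
class BindingKinetics:
    """Observed binding phenomenology across Cy3ATP concentrations.

    ``table`` holds per-concentration observed rates and amplitudes;
    slopes of the observed rates against [Cy3ATP] are the apparent
    second-order binding constants (uM^-1 s^-1).  ``a_fast_mean`` is the
    mean relative fast-phase amplitude.
    """

    table: pd.DataFrame
    k_fast_slope: float
    k_fast_slope_se: float
    k_fast_intercept: float
    k_slow_slope: float
    k_slow_slope_se: float
    k_slow_intercept: float
    a_fast_mean: float
    flags: tuple[str, ...] = ()


def _binding_rate_grid(t: np.ndarray) -> np.ndarray:
    span = float(t[-1] - t[0])
    return np.logspace(np.log10(1.0 / span), np.log10(100.0 / span), 6)


def extract_kobs(
    transients: Sequence[Transient], atp_uM: Sequence[float] | None = None
) -> BindingKinetics:
    """Fit each binding transient and regress observed rates on [Cy3ATP].

    Concentrations are taken from ``atp_uM`` or from each transient's
    ``meta["ligand_uM"]``.  At least three distinct concentrations are
    required.  Single-phase fits contribute their rate to the fast branch
    with a relative fast amplitude of 1.
    """
    if atp_uM is None:
        atp_uM = [float(tr.meta["ligand_uM"]) for tr in transients]
    atp = np.asarray(atp_uM, dtype=float)
    if len(atp) != len(transients):
        raise ValueError("one concentration per transient required")
    if len(np.unique(atp)) < 3:
        raise ValueError(
            "insufficient design: >= 3 distinct Cy3ATP concentrations required"
        )

    rows = []
    for conc, tr in zip(atp, transients):
        fit = fit_exponentials(tr, n_components="auto", rate_grid=_binding_rate_grid(tr.time))
        if fit.n_components == 1:
            rows.append(
                {"atp_uM": conc, "k_fast_obs": fit.rates[0], "k_slow_obs": np.nan,
                 "a_fast": 1.0}
            )
        else:
            rows.append(
                {
                    "atp_uM": conc,
                    "k_fast_obs": fit.rates[0],
                    "k_slow_obs": fit.rates[1],
                    "a_fast": fit.fractional_amplitudes[0],
                }
            )
    table = pd.DataFrame(rows).sort_values("atp_uM").reset_index(drop=True)

    flags: list[str] = []

    def regress(col: str) -> tuple[float, float, float]:
        sub = table.dropna(subset=[col])
        if len(sub) < 3:
            flags.append(f"{col}-insufficient-points")
            return np.nan, np.nan, np.nan
        res = stats.linregress(sub["atp_uM"], sub[col])
        if np.isfinite(res.stderr) and abs(res.slope) < 1.96 * res.stderr:
            flags.append(f"{col}-concentration-independent")
        return float(res.slope), float(res.stderr), float(res.intercept)

    kf, kf_se, kf_b = regress("k_fast_obs")
    ks, ks_se, ks_b = regress("k_slow_obs")
    return BindingKinetics(
        table=table,
        k_fast_slope=kf,
        k_fast_slope_se=kf_se,
        k_fast_intercept=kf_b,
        k_slow_slope=ks,
        k_slow_slope_se=ks_se,
        k_slow_intercept=ks_b,
        a_fast_mean=float(table["a_fast"].mean()),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# global fitting


@dataclass(frozen=True)
class SchemeFit:
    """Result of a global scheme fit across concentrations."""

    scheme: KineticScheme
    scales: tuple[tuple[float, float], ...]  # per transient (S0, dS)
    ss: float
    aicc: float
    n_points: int
    n_parameters: int
    flags: tuple[str, ...] = ()


_SCHEME_PARAMS = {
    "scheme1": ("k_T", "kp_T", "k_IHM", "kp_IHM"),
    "scheme2": ("k_T", "k_IHM", "k_iso_plus", "k_iso_minus"),
}


def _scheme_residuals(
    scheme: KineticScheme, transients: Sequence[Transient], atp: np.ndarray
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    res_all = []
    scales = []
    for conc, tr in zip(atp, transients):
        traj = simulate_scheme(scheme, conc, tr.time)
        # signal ~ S0 - dS * f_fret: linear in (S0, dS) per transient
        X = np.column_stack([np.ones_like(traj.f_fret), -traj.f_fret])
        coef, *_ = np.linalg.lstsq(X, tr.signal, rcond=None)
        res_all.append(X @ coef - tr.signal)
        scales.append((float(coef[0]), float(coef[1])))
    return np.concatenate(res_all), scales


def global_fit_scheme(
    s0: KineticScheme,
    transients: Sequence[Transient],
    atp_uM: Sequence[float] | None = None,
    fit_open_fraction: bool = True,
) -> SchemeFit:
    """Simultaneously fit one mechanism to transients at several [Cy3ATP].

    Rate constants (and optionally the initial Open fraction) are shared
    across transients; each transient gets its own signal scale (S0, dS),
    solved linearly at every iteration (variable projection).  Parameters
    whose profile is flat at the optimum (negligible Jacobian column)
    are flagged ``"<name>-unidentifiable"`` rather than silently fixed.
    """
    if atp_uM is None:
        atp_uM = [float(tr.meta["ligand_uM"]) for tr in transients]
    atp = np.asarray(atp_uM, dtype=float)
    if len(np.unique(atp)) < 3:
        raise ValueError(
            "insufficient design: >= 3 distinct Cy3ATP concentrations required"
        )

    names = _SCHEME_PARAMS[s0.scheme_id]
    x0 = [np.log(max(getattr(s0, n), 1e-6)) for n in names]
    if fit_open_fraction:
        f = np.clip(s0.open_fraction, 1e-4, 1 - 1e-4)
        x0.append(np.log(f / (1 - f)))
    x0 = np.asarray(x0)

    def build(x: np.ndarray) -> KineticScheme:
        kw = {n: float(np.exp(v)) for n, v in zip(names, x[: len(names)])}
        if fit_open_fraction:
            kw["open_fraction"] = float(1.0 / (1.0 + np.exp(-x[len(names)])))
        return replace(s0, **kw)

    def resid(x: np.ndarray) -> np.ndarray:
        try:
            r, _ = _scheme_residuals(build(x), transients, atp)
        except SimulationError:
            return np.full(sum(tr.n_points for tr in transients), 1e6)
        return r

    sol = least_squares(resid, x0, method="trf", ftol=1e-12, xtol=1e-12)
    fitted = build(sol.x)
    r, scales = _scheme_residuals(fitted, transients, atp)
    ss = float(r @ r)
    n = r.size
    n_par = len(sol.x) + 2 * len(transients)

    flags = []
    J = sol.jac
    col_norms = np.linalg.norm(J, axis=0)
    scale = max(col_norms.max(), 1e-30)
    for i, norm in enumerate(col_norms):
        if norm < 1e-8 * scale:
            pname = names[i] if i < len(names) else "open_fraction"
            flags.append(f"{pname}-unidentifiable")

    return SchemeFit(
        scheme=fitted,
        scales=tuple(scales),
        ss=ss,
        aicc=_aicc(ss, n, n_par),
        n_points=n,
        n_parameters=n_par,
        flags=tuple(flags),
    )


def compare_schemes(
    s1_0: KineticScheme,
    s2_0: KineticScheme,
    transients: Sequence[Transient],
    atp_uM: Sequence[float] | None = None,
) -> dict[str, Any]:
    """Globally fit both mechanisms and compare them by AICc.

    Returns the two :class:`SchemeFit` objects and ``delta_aicc``
    (scheme1 minus scheme2; negative favours scheme1).
    """
    fit1 = global_fit_scheme(s1_0, transients, atp_uM)
    fit2 = global_fit_scheme(s2_0, transients, atp_uM)
    return {
        "scheme1": fit1,
        "scheme2": fit2,
        "delta_aicc": fit1.aicc - fit2.aicc,
        "preferred": "scheme1" if fit1.aicc <= fit2.aicc else "scheme2",
    }
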