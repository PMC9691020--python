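"""Seeded generators for every input the analysis pipeline consumes.

Real inputs are stopped-flow fluorescence transients, TCSPC photon
histograms, ATPase rate tables, EM tallies and motility velocity tables.
The generators here emulate those records with the statistical structure
the downstream analysis assumes: additive Gaussian noise for analogue
stopped-flow channels, Poisson counting noise for photon histograms,
binomial sampling for EM tallies, and a stuck (exact-zero) subpopulation
for motility.

The default parameter sets (:data:`TURNOVER_PARAMS`, :data:`BINDING_PARAMS`,
:data:`ATPASE_PARAMS`, :data:`EM_PROPORTIONS`, :data:`MOTILITY_PARAMS`)
encode reported measurements for WT and E525K human beta-cardiac myosin
constructs (two-headed 15-heptad HMM-GFP and single-headed S1) across KCl
concentrations, so simulations run at realistic study conditions out of
the box.

Randomness is reproducible: each generator call derives its own RNG
stream from ``(cfg.seed, kind, stream)``, so adding generators never
perturbs existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from .assays import AtpaseCurve, MotilitySet, PhosphateTimecourse
from .containers import LifetimeDecay, Transient
from .em import EmTally
from .kinetics import KineticScheme, simulate_scheme
from .transients import SRXMeasurement

__all__ = [
    "SimConfig",
    "gen_single_turnover",
    "gen_binding_transient",
    "gen_lifetime_decay",
    "gen_assay_data",
    "TURNOVER_PARAMS",
    "TURNOVER_SD",
    "S1_TURNOVER_PARAMS",
    "BINDING_PARAMS",
    "ATPASE_PARAMS",
    "EM_PROPORTIONS",
    "MOTILITY_PARAMS",
    "turnover_measurement",
    "default_scheme1",
]


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings and condition metadata for one simulated record.

    ``noise_sd`` is the additive Gaussian noise SD expressed as a fraction
    of the total signal amplitude (0.005 = 0.5%, typical of averaged
    stopped-flow traces).  ``duration`` is the observation window in
    seconds and ``n_points`` the number of samples.  The same seed always
    reproduces the same record bit-for-bit.
    """

    seed: int = 0
    noise_sd: float = 0.005
    n_points: int = 2000
    duration: float = 1000.0
    t_min: float = 0.1
    construct: str = "WT"
    fragment: str = "HMM-15HPZ-GFP"
    kcl_mM: float = 20.0
    ligand_uM: float = 1.0
    channel: str = "mant"

    def __post_init__(self) -> None:
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.t_min < self.duration:
            raise ValueError("t_min must lie in (0, duration)")

    def meta(self) -> dict[str, Any]:
        return {
            "construct": self.construct,
            "fragment": self.fragment,
            "kcl_mM": self.kcl_mM,
            "ligand_uM": self.ligand_uM,
            "channel": self.channel,
            "seed": self.seed,
        }


def _rng(cfg: SimConfig, kind: str, stream: int = 0) -> np.random.Generator:
    """Independent RNG stream per (seed, generator kind, stream index)."""
    key = zlib.crc32(kind.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, key, stream]))


# ---------------------------------------------------------------------------
# reference parameter sets (means and between-preparation SDs)

#: Single-turnover DRX/SRX parameters for the two-headed HMM-GFP construct:
#: (construct, KCl mM) -> (k_DRX s^-1, f_DRX, k_SRX s^-1, f_SRX)
TURNOVER_PARAMS: dict[tuple[str, int], tuple[float, float, float, float]] = {
    ("WT", 20): (0.014, 0.11, 0.0033, 0.89),
    ("WT", 50): (0.013, 0.43, 0.0054, 0.57),
    ("WT", 75): (0.015, 0.59, 0.0069, 0.41),
    ("WT", 100): (0.016, 0.85, 0.0058, 0.15),
    ("WT", 150): (0.018, 0.87, 0.0071, 0.13),
    ("E525K", 20): (0.027, 0.05, 0.0022, 0.95),
    ("E525K", 50): (0.019, 0.06, 0.0026, 0.94),
    ("E525K", 75): (0.016, 0.08, 0.0030, 0.92),
    ("E525K", 100): (0.014, 0.10, 0.0033, 0.90),
    ("E525K", 150): (0.013, 0.21, 0.0042, 0.79),
}

#: Between-preparation SDs matching :data:`TURNOVER_PARAMS`.
TURNOVER_SD: dict[tuple[str, int], tuple[float, float, float, float]] = {
    ("WT", 20): (0.002, 0.01, 0.0001, 0.01),
    ("WT", 50): (0.001, 0.05, 0.0005, 0.05),
    ("WT", 75): (0.002, 0.08, 0.0009, 0.08),
    ("WT", 100): (0.001, 0.03, 0.0004, 0.03),
    ("WT", 150): (0.001, 0.02, 0.0008, 0.02),
    ("E525K", 20): (0.008, 0.01, 0.0002, 0.01),
    ("E525K", 50): (0.002, 0.01, 0.0001, 0.01),
    ("E525K", 75): (0.006, 0.02, 0.0001, 0.02),
    ("E525K", 100): (0.003, 0.02, 0.0001, 0.02),
    ("E525K", 150): (0.002, 0.03, 0.0001, 0.03),
}

#: Single-headed S1 turnover parameters (small, salt-insensitive SRX).
S1_TURNOVER_PARAMS: dict[tuple[str, int], tuple[float, float, float, float]] = {
    ("WT", 20): (0.039, 0.95, 0.0075, 0.05),
    ("WT", 150): (0.028, 0.97, 0.0044, 0.03),
    ("E525K", 20): (0.085, 0.94, 0.0197, 0.06),
    ("E525K", 150): (0.074, 0.97, 0.0129, 0.03),
}

#: Cy3ATP-binding phenomenology at 20 mM KCl:
#: construct -> dict(k_fast uM^-1 s^-1, k_slow uM^-1 s^-1, a_fast)
BINDING_PARAMS: dict[str, dict[str, float]] = {
    "WT": {"k_fast": 1.9, "k_slow": 0.15, "a_fast": 0.65},
    "E525K": {"k_fast": 1.4, "k_slow": 0.06, "a_fast": 0.25},
}

#: Actin-activated ATPase parameters: (construct, fragment) ->
#: dict(v0 s^-1, k_cat s^-1, k_atpase uM); NH4+ per-head rates separate.
ATPASE_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    ("WT", "S1"): {"v0": 0.02, "k_cat": 7.8, "k_atpase": 52.2, "nh4_rate": 4.24},
    ("E525K", "S1"): {"v0": 0.03, "k_cat": 10.6, "k_atpase": 1.8, "nh4_rate": 5.03},
    ("WT", "HMM-15HPZ-GFP"): {"v0": 0.02, "k_cat": 1.1, "k_atpase": 99.9, "nh4_rate": 4.14},
    ("E525K", "HMM-15HPZ-GFP"): {"v0": 0.01, "k_cat": 0.41, "k_atpase": 53.3, "nh4_rate": 4.93},
}

#: Closed-molecule proportions per EM preparation (classifiable basis).
EM_PROPORTIONS: dict[str, tuple[float, float, float]] = {
    "WT": (0.169, 0.085, 0.065),
    "E525K": (0.569, 0.348, 0.270),
}

#: Motility velocities (nm/s) and stuck fractions for the HMM construct.
MOTILITY_PARAMS: dict[str, dict[str, float]] = {
    "WT": {"mean": 853.0, "sd": 150.0, "stuck_fraction": 0.278},
    "E525K": {"mean": 852.0, "sd": 150.0, "stuck_fraction": 0.348},
}

#: Standard actin concentration grid (uM) incl. the basal (0) point.
ATPASE_ACTIN_GRID = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0)


def turnover_measurement(
    construct: str, kcl_mM: int, fragment: str = "HMM-15HPZ-GFP"
) -> SRXMeasurement:
    """Reference single-turnover parameter set as an :class:`SRXMeasurement`."""
    table = TURNOVER_PARAMS if fragment.startswith("HMM") else S1_TURNOVER_PARAMS
    k_drx, f_drx, k_srx, f_srx = table[(construct, kcl_mM)]
    return SRXMeasurement(
        drx_rate=k_drx,
        drx_fraction=f_drx,
        srx_rate=k_srx,
        srx_fraction=f_srx,
        meta={"construct": construct, "kcl_mM": float(kcl_mM), "fragment": fragment},
    )


def default_scheme1(
    construct: str = "WT", slow_factor: float | None = None
) -> KineticScheme:
    """Scheme-1 mechanism parameterised from the binding phenomenology.

    The Open-state binding constant is the observed fast slope, the ALT
    constant the observed slow slope (10-20-fold slower), IHM transitions
    are fast (100 s^-1, well above binding on the transient time scale),
    and the initial Open fraction equals the observed relative fast
    amplitude.
    """
    p = BINDING_PARAMS[construct]
    kp_T = p["k_slow"] if slow_factor is None else p["k_fast"] / slow_factor
    return KineticScheme(
        scheme_id="scheme1",
        k_T=p["k_fast"],
        kp_T=kp_T,
        k_IHM=100.0,
        kp_IHM=100.0,
        open_fraction=p["a_fast"],
    )


# ---------------------------------------------------------------------------
# generators


def gen_single_turnover(
    params: SRXMeasurement,
    cfg: SimConfig,
    amplitude: float = 1.0,
    offset: float = 0.1,
    stream: int = 0,
) -> Transient:
    """Simulate a single-ATP-turnover mant-fluorescence transient.

    The noiseless signal is
    ``F(t) = offset + amplitude * (f_DRX exp(-k_DRX t) + f_SRX exp(-k_SRX t))``
    sampled on a log-spaced grid over ``[cfg.t_min, cfg.duration]``
    (resolving both the fast and slow phase), plus Gaussian noise of SD
    ``cfg.noise_sd * amplitude``.
    """
    t = np.geomspace(cfg.t_min, cfg.duration, cfg.n_points)
    clean = offset + amplitude * (
        params.drx_fraction * np.exp(-params.drx_rate * t)
        + params.srx_fraction * np.exp(-params.srx_rate * t)
    )
    noise = 0.0
    if cfg.noise_sd > 0:
        rng = _rng(cfg, "single_turnover", stream)
        noise = rng.normal(0.0, cfg.noise_sd * amplitude, size=t.shape)
    meta = cfg.meta()
    meta.update(params.meta)
    return Transient(time=t, signal=clean + noise, meta=meta)


def gen_binding_transient(
    scheme: KineticScheme,
    atp_uM: float,
    cfg: SimConfig,
    s0: float = 1.0,
    delta_s: float = 0.1,
    stream: int = 0,
) -> Transient:
    """Simulate a Cy3ATP-binding FRET transient (donor quenching).

    The mechanism is integrated at the given nucleotide concentration and
    the donor signal modelled as ``S(t) = s0 - delta_s * f_FRET(t)``
    (quenching grows as the IHM forms), plus Gaussian noise of SD
    ``cfg.noise_sd * delta_s``.  Time is linearly spaced over
    ``[0, cfg.duration]`` as in a stopped-flow acquisition.
    """
    if atp_uM <= 0:
        raise ValueError("atp_uM must be positive")
    t = np.linspace(0.0, cfg.duration, cfg.n_points)
    traj = simulate_scheme(scheme, atp_uM, t)
    clean = s0 - delta_s * traj.f_fret
    noise = 0.0
    if cfg.noise_sd > 0:
        rng = _rng(cfg, "binding_transient", stream)
        noise = rng.normal(0.0, cfg.noise_sd * delta_s, size=t.shape)
    meta = cfg.meta()
    meta.update({"ligand_uM": float(atp_uM), "channel": "donor-quench",
                 "scheme_id": scheme.scheme_id})
    return Transient(time=t, signal=clean + noise, meta=meta)


def gen_lifetime_decay(
    lifetimes_ns: Sequence[float],
    amplitudes: Sequence[float],
    total_counts: float,
    cfg: SimConfig,
    t_max_ns: float = 50.0,
    n_channels: int = 1024,
    poisson: bool = True,
    stream: int = 0,
) -> LifetimeDecay:
    """Simulate a TCSPC fluorescence-lifetime decay histogram.

    Expected counts per channel are proportional to
    ``sum_i A_i exp(-t / tau_i)`` and scaled to ``total_counts`` photons;
    realised counts are Poisson-sampled (``poisson=False`` returns the
    continuous expectation, the infinite-counts surrogate).  Histograms
    below 1000 total photons are flagged ``low_counts``.
    """
    taus = np.asarray(lifetimes_ns, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    if np.any(amps < 0) or amps.sum() == 0:
        raise ValueError("amplitudes must be >= 0 and not all zero")
    if total_counts < 1:
        raise ValueError("total_counts must be >= 1")
    keep = amps > 0
    taus, amps = taus[keep], amps[keep]

    edges = np.linspace(0.0, t_max_ns, n_channels + 1)
    t = 0.5 * (edges[:-1] + edges[1:])
    expected = np.zeros_like(t)
    for a, tau in zip(amps, taus):
        expected += a * np.exp(-t / tau)
    expected *= total_counts / expected.sum()

    if poisson:
        rng = _rng(cfg, "lifetime_decay", stream)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return LifetimeDecay(
        t_ns=t,
        counts=counts,
        meta=cfg.meta(),
        low_counts=total_counts < 1000,
    )


def gen_assay_data(
    kind: str, params: dict[str, Any], cfg: SimConfig, stream: int = 0
) -> AtpaseCurve | PhosphateTimecourse | EmTally | MotilitySet:
    """Generate steady-state assay inputs.

    ``kind`` selects the record type:

    - ``"atpase"``: rates on the standard actin grid from planted
      (v0, k_cat, k_atpase), Gaussian noise of ``cfg.noise_sd * k_cat``.
    - ``"nh4"``: a linear phosphate-vs-time course (sampled every 2 min
      over 10 min) at a planted per-head rate, plus a calibration line.
    - ``"em"``: closed counts drawn Binomial(n, p_closed) over a fixed
      classifiable total ``n``; unclear molecules drawn with independent
      odds ``p_unclear / (1 - p_unclear)`` per classifiable molecule.
    - ``"motility"``: Gaussian velocities with an exact-zero stuck
      subpopulation, one array per preparation.
    """
    rng = _rng(cfg, f"assay_{kind}", stream)

    if kind == "atpase":
        actin = np.asarray(params.get("actin_uM", ATPASE_ACTIN_GRID), dtype=float)
        if np.any(actin < 0):
            raise ValueError("actin concentrations must be non-negative")
        v0, k_cat, K = params["v0"], params["k_cat"], params["k_atpase"]
        rates = v0 + k_cat * actin / (K + actin)
        if cfg.noise_sd > 0:
            rates = rates + rng.normal(0.0, cfg.noise_sd * max(k_cat, v0), actin.shape)
        return AtpaseCurve(actin_uM=actin, rates=np.clip(rates, 0, None), meta=cfg.meta())

    if kind == "nh4":
        rate = params["rate_per_head_s"]  # s^-1
        heads = params.get("heads_uM", 0.5)
        times = np.asarray(params.get("times_min", np.arange(0.0, 10.1, 2.0)), float)
        pi = rate * heads * 60.0 * times
        if cfg.noise_sd > 0:
            pi = pi + rng.normal(0.0, cfg.noise_sd * max(pi.max(), 1e-12), times.shape)
        return PhosphateTimecourse(
            times_min=times, pi_uM=pi, heads_uM=heads,
            standard_curve_r2=params.get("standard_curve_r2", 1.0), meta=cfg.meta(),
        )

    if kind == "em":
        p_closed = params["p_closed"]
        n = int(params["n"])
        p_unclear = params.get("p_unclear", 0.2)
        if not 0.0 <= p_closed <= 1.0 or not 0.0 <= p_unclear < 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        closed = int(rng.binomial(n, p_closed))
        unclear = int(rng.binomial(n, p_unclear / (1.0 - p_unclear)))
        return EmTally(
            prep=params.get("prep", 1), closed=closed, open=n - closed,
            unclear=unclear, meta=cfg.meta(),
        )

    if kind == "motility":
        mean = params["mean"]
        sd = params.get("sd", 150.0)
        stuck = params.get("stuck_fraction", 0.0)
        if not 0.0 <= stuck <= 1.0:
            raise ValueError("stuck_fraction must lie in [0, 1]")
        n_preps = int(params.get("n_preps", 3))
        n_fil = int(params.get("n_filaments", 300))
        preps = []
        for _ in range(n_preps):
            v = np.abs(rng.normal(mean, sd, n_fil))
            is_stuck = rng.random(n_fil) < stuck
            v[is_stuck] = 0.0
            preps.append(v)
        return MotilitySet(preps=tuple(preps), label=params.get("label", cfg.construct))

    raise ValueError(f"unknown assay kind {kind!r}")


def replicate_configs(cfg: SimConfig, n: int) -> list[SimConfig]:
    """Derive n reproducible per-replicate configs from a base config."""
    return [replace(cfg, seed=(cfg.seed * 100003 + i) % 2**31) for i in range(n)]
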