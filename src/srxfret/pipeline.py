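"""Configuration-driven orchestration of the full analysis.

Reproduces the study's analysis end to end on synthetic (or user) data:
simulate single-turnover transients -> fit and decompose into SRX/DRX ->
predict FRET from the SRX fraction and compare with measured efficiency
-> extract Cy3ATP-binding phenomenology from the Scheme-1 mechanism ->
fit ATPase curves and NH4+ rates -> aggregate motility -> tally EM
conformations.  Each stage writes a CSV; all headline quantities land in
a single JSON report.  Runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .assays import fit_michaelis_menten, motility_summary, nh4_per_head_rate
from .em import EmTally, closed_ratio, tally_percentages
from .fret import distance_conversion, predict_fret_from_srx, steady_state_efficiency
from .kinetics import extract_kobs
from .synthetic import (
    ATPASE_PARAMS,
    EM_PROPORTIONS,
    MOTILITY_PARAMS,
    SimConfig,
    TURNOVER_SD,
    default_scheme1,
    gen_assay_data,
    gen_binding_transient,
    gen_single_turnover,
    turnover_measurement,
)
from .transients import (
    SRXMeasurement,
    decompose_srx,
    fit_exponentials,
    srx_salt_profile,
    with_meta,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("srxfret.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a full synthetic-data pipeline run.

    Every stage is seeded from ``seed``; ``salts`` is the KCl series in
    mM; ``n_preps`` the number of simulated protein preparations per
    condition; ``r0`` the Förster radius in Angstrom and ``e_ihm`` the
    assumed whole-IHM FRET efficiency.
    """

    seed: int = 1
    out_dir: str | None = None
    r0: float = 63.0
    e_ihm: float = 0.060
    salts: tuple[int, ...] = (20, 50, 75, 100, 150)
    constructs: tuple[str, ...] = ("WT", "E525K")
    n_preps: int = 3
    noise_sd: float = 0.005
    turnover_points: int = 1000
    binding_atp_uM: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.5)
    stages: tuple[str, ...] = ("turnover", "fret", "binding", "assays", "em")

    def __post_init__(self) -> None:
        known = {"turnover", "fret", "binding", "assays", "em"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
        if "fret" in self.stages and "turnover" not in self.stages:
            raise ValueError("stage 'fret' requires stage 'turnover' (SRX fractions)")
        if self.n_preps < 1:
            raise ValueError("n_preps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("salts", "constructs", "binding_atp_uM", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jitter_measurement(
    base: SRXMeasurement, sd: tuple[float, float, float, float], rng: np.random.Generator
) -> SRXMeasurement:
    """Draw preparation-level parameters around the condition means."""
    k_drx = max(rng.normal(base.drx_rate, sd[0]), 1e-4)
    k_srx = min(max(rng.normal(base.srx_rate, sd[2]), 1e-5), k_drx * 0.99)
    f_srx = float(np.clip(rng.normal(base.srx_fraction, sd[3]), 0.0, 1.0))
    return replace(
        base, drx_rate=k_drx, srx_rate=k_srx,
        drx_fraction=1.0 - f_srx, srx_fraction=f_srx,
    )


def _stage_turnover(cfg: PipelineConfig, report: dict) -> list[SRXMeasurement]:
    measurements = []
    for ci, construct in enumerate(cfg.constructs):
        for si, salt in enumerate(cfg.salts):
            base = turnover_measurement(construct, salt)
            sd = TURNOVER_SD[(construct, salt)]
            for prep in range(cfg.n_preps):
                seed = (cfg.seed * 7919 + ci * 1009 + si * 101 + prep) % 2**31
                rng = np.random.default_rng(seed)
                planted = _jitter_measurement(base, sd, rng)
                sim = SimConfig(
                    seed=seed, noise_sd=cfg.noise_sd, n_points=cfg.turnover_points,
                    construct=construct, kcl_mM=float(salt),
                )
                tr = gen_single_turnover(planted, sim)
                fit = fit_exponentials(tr, n_components=2)
                m = with_meta(decompose_srx(fit), prep=prep + 1)
                measurements.append(m)
    profile = srx_salt_profile(measurements)
    report["srx_profile"] = profile.to_dict(orient="records")
    report["_srx_profile_df"] = profile
    return measurements


def _stage_fret(cfg: PipelineConfig, report: dict) -> None:
    profile = report["_srx_profile_df"]
    rng = np.random.default_rng((cfg.seed * 104729 + 7) % 2**31)
    rows = []
    for _, row in profile.iterrows():
        f_srx = row["srx_fraction_mean"]
        e_pred = predict_fret_from_srx(f_srx, cfg.e_ihm)
        # emulate a measured steady-state efficiency: donor quench around the
        # prediction with small intensity noise
        f_d = 1.0
        f_da = float(np.clip(1.0 - e_pred + rng.normal(0.0, cfg.noise_sd), 1e-6, None))
        measured = steady_state_efficiency(f_d, f_da, background=0.0, r0=cfg.r0)
        rows.append(
            {
                "construct": row["construct"],
                "kcl_mM": row["kcl_mM"],
                "srx_fraction": f_srx,
                "e_predicted": e_pred,
                "e_measured": measured.e,
                "r_predicted_A": distance_conversion(e=e_pred, r0=cfg.r0).r
                if 0 < e_pred < 1
                else np.nan,
            }
        )
    report["fret"] = rows
    report["ihm_distance_A"] = distance_conversion(e=cfg.e_ihm, r0=cfg.r0).r


def _stage_binding(cfg: PipelineConfig, report: dict) -> None:
    out = {}
    for ci, construct in enumerate(cfg.constructs):
        scheme = default_scheme1(construct)
        transients = []
        for ai, atp in enumerate(cfg.binding_atp_uM):
            sim = SimConfig(
                seed=(cfg.seed * 15485863 + ci * 211 + ai) % 2**31,
                noise_sd=cfg.noise_sd, n_points=1000,
                duration=60.0 / atp if atp < 1 else 60.0,
                construct=construct, channel="donor-quench",
            )
            transients.append(gen_binding_transient(scheme, atp, sim))
        bk = extract_kobs(transients)
        out[construct] = {
            "k_fast_uM_s": bk.k_fast_slope,
            "k_fast_se": bk.k_fast_slope_se,
            "k_slow_uM_s": bk.k_slow_slope,
            "k_slow_se": bk.k_slow_slope_se,
            "a_fast": bk.a_fast_mean,
            "flags": list(bk.flags),
        }
    report["binding"] = out


def _stage_assays(cfg: PipelineConfig, report: dict) -> None:
    atpase = {}
    for i, ((construct, fragment), params) in enumerate(sorted(ATPASE_PARAMS.items())):
        sim = SimConfig(seed=(cfg.seed * 32452843 + i) % 2**31, noise_sd=cfg.noise_sd,
                        construct=construct, fragment=fragment)
        curve = gen_assay_data("atpase", params, sim)
        fit = fit_michaelis_menten(curve)
        nh4 = nh4_per_head_rate(
            gen_assay_data("nh4", {"rate_per_head_s": params["nh4_rate"]}, sim)
        )
        atpase[f"{construct}_{fragment}"] = {
            "v0": fit.v0, "k_cat": fit.k_cat, "k_atpase": fit.k_atpase,
            "nh4_rate_s": nh4["rate_per_head_s"], "flags": list(fit.flags),
        }
    s1 = atpase.get("WT_S1", {}).get("k_cat")
    hmm = atpase.get("WT_HMM-15HPZ-GFP", {}).get("k_cat")
    if s1 and hmm:
        atpase["k_cat_fold_S1_over_HMM"] = s1 / hmm
    report["atpase"] = atpase

    motility = {}
    sets = {}
    for i, construct in enumerate(cfg.constructs):
        sim = SimConfig(seed=(cfg.seed * 49979687 + i) % 2**31, construct=construct)
        sets[construct] = gen_assay_data(
            "motility", dict(MOTILITY_PARAMS[construct], n_preps=cfg.n_preps), sim
        )
    for construct, ms in sets.items():
        other = next((v for k, v in sets.items() if k != construct), None)
        summ = motility_summary(ms, other)
        motility[construct] = {
            "grand_mean_nm_s": summ["grand_mean"],
            "grand_sd": summ["grand_sd"],
            "percent_stuck": summ["percent_stuck_mean"],
            "p_vs_other": summ.get("p_value", np.nan),
        }
    report["motility"] = motility


def _stage_em(cfg: PipelineConfig, report: dict) -> None:
    tallies: dict[str, list[EmTally]] = {}
    for ci, construct in enumerate(cfg.constructs):
        tallies[construct] = []
        props = EM_PROPORTIONS.get(construct, EM_PROPORTIONS["WT"])
        for prep, p in enumerate(props, start=1):
            sim = SimConfig(seed=(cfg.seed * 86028121 + ci * 11 + prep) % 2**31,
                            construct=construct)
            t = gen_assay_data("em", {"p_closed": p, "n": 284, "prep": prep}, sim)
            tallies[construct].append(tally_percentages(t))
    rows = []
    for construct, ts in tallies.items():
        for t in ts:
            rows.append(
                {"construct": construct, "prep": t.prep, "closed": t.closed,
                 "open": t.open, "unclear": t.unclear, "pct_closed": t.pct_closed,
                 "ci_low": t.ci_low, "ci_high": t.ci_high}
            )
    report["em"] = {"tallies": rows}
    if "WT" in tallies and "E525K" in tallies:
        ratios = [
            closed_ratio(m, w)
            for m, w in zip(tallies["E525K"], tallies["WT"])
        ]
        report["em"]["closed_ratios"] = [r["ratio"] for r in ratios]
        report["em"]["closed_ratios_rounded"] = [r["ratio_rounded"] for r in ratios]


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages in dependency order.

    Returns the report dict; when ``cfg.out_dir`` is set, also writes
    ``report.json``, per-stage CSVs and a run log there.  A stage failure
    raises with the stage name while preserving partial outputs.
    """
    report: dict[str, Any] = {
        "seed": cfg.seed,
        "version": __version__,
        "r0_A": cfg.r0,
        "e_ihm": cfg.e_ihm,
    }
    stage_fns = {
        "turnover": _stage_turnover,
        "fret": _stage_fret,
        "binding": _stage_binding,
        "assays": _stage_assays,
        "em": _stage_em,
    }
    order = [s for s in ("turnover", "fret", "binding", "assays", "em") if s in cfg.stages]
    for stage in order:
        log.info("running stage %s", stage)
        try:
            stage_fns[stage](cfg, report)
        except Exception as exc:
            _write_outputs(cfg, report, partial=True)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_outputs(cfg, report, partial=False)
    profile_df = report.pop("_srx_profile_df", None)
    if profile_df is not None and cfg.out_dir:
        profile_df.to_csv(Path(cfg.out_dir) / "srx_profile.csv", index=False)
    return report


def _write_outputs(cfg: PipelineConfig, report: dict, partial: bool) -> None:
    if not cfg.out_dir:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serialisable = {k: v for k, v in report.items() if not k.startswith("_")}
    name = "report.partial.json" if partial else "report.json"
    (out / name).write_text(
        json.dumps(serialisable, sort_keys=True, indent=2, default=_json_default)
    )
    (out / "run.log").write_text(
        f"seed={cfg.seed}\nversion={__version__}\nstages={','.join(cfg.stages)}\n"
    )


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
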