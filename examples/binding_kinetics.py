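"""Cy3ATP-binding FRET kinetics: simulate a mechanism and extract k_obs.

Simulates the two-pathway binding mechanism (Open and slow-binding ALT
apo conformations, each transitioning rapidly into the IHM after binding)
across five Cy3ATP concentrations, fits every transient, and regresses
the observed rates on concentration to recover the second-order binding
constants and the relative fast amplitude.
"""

from srxfret import SimConfig, extract_kobs, gen_binding_transient
from srxfret.synthetic import default_scheme1

scheme = default_scheme1("WT")  # k_T=1.9, k'_T=0.15 uM^-1 s^-1, Open fraction 0.65
transients = []
for i, atp in enumerate((0.25, 0.5, 1.0, 1.5, 2.5)):
    cfg = SimConfig(
        seed=10 + i, noise_sd=0.005, n_points=1000,
        duration=60.0 / atp if atp < 1 else 60.0, channel="donor-quench",
    )
    transients.append(gen_binding_transient(scheme, atp, cfg))

bk = extract_kobs(transients)
print(bk.table.to_string(index=False))
print(f"\nk_fast slope: {bk.k_fast_slope:.3f} +/- {bk.k_fast_slope_se:.3f} 1/(uM s)")
print(f"k_slow slope: {bk.k_slow_slope:.3f} +/- {bk.k_slow_slope_se:.3f} 1/(uM s)")
print(f"mean A_fast:  {bk.a_fast_mean:.3f}")
print(
    "\nBoth observed rates grow linearly with [Cy3ATP] (second-order binding); "
    "the fast-phase amplitude reports the fraction of molecules starting in "
    "the fast-binding Open conformation."
)
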