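"""FRET efficiency and Förster distances for the IHM biosensor.

Computes steady-state (donor quench) and time-resolved (lifetime)
efficiencies, converts the assumed whole-IHM efficiency to a distance,
and predicts the ensemble efficiency expected from a given SRX fraction.
"""

from srxfret import (
    SimConfig,
    distance_conversion,
    ensemble_ihm_efficiency,
    gen_lifetime_decay,
    lifetime_efficiency,
    predict_fret_from_srx,
    steady_state_efficiency,
)

# steady state: donor quenched from 1.000 to 0.945 by the acceptor
ss = steady_state_efficiency(f_d=1.000, f_da=0.945)
print(f"steady-state E = {ss.e:.3f} ({ss.e:.1%} donor quench)")

# time-resolved: two-exponential lifetime fits, amplitude-weighted average
cfg = SimConfig(seed=1)
donor = gen_lifetime_decay([2.6, 0.9], [0.7, 0.3], 1e6, cfg)
donor_acc = gen_lifetime_decay([2.6 * 0.94, 0.9 * 0.94], [0.7, 0.3], 1e6, cfg, stream=1)
tr = lifetime_efficiency(donor, donor_acc)
print(f"time-resolved E = {tr.e:.3f} (tau_D {tr.tau_d:.2f} ns -> tau_DA {tr.tau_da:.2f} ns)")

# the whole-IHM assumption: 6% efficiency <-> ~100 A at R0 = 63 A
conv = distance_conversion(e=0.060, r0=63.0)
print(f"E=6.0% at R0=63 A corresponds to r = {conv.r:.1f} A")

# ensemble average over the closed-state structural pair distances
e_ens = ensemble_ihm_efficiency([100.0, 130.0, 135.0, 140.0], r0=63.0)
print(f"ensemble efficiency over 90-140 A pair set: {e_ens:.4f}")

# predicted efficiency if 89% of heads are in the SRX/IHM state
print(f"predicted E at f_SRX=0.89: {predict_fret_from_srx(0.89):.4f}")
print(
    "\nThe prediction assumes zero FRET in the open state, so the ensemble "
    "efficiency scales linearly with the fraction of folded (IHM) molecules."
)
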