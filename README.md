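# srxfret

Quantitative analysis of the **super-relaxed (SRX) state** of cardiac myosin
and its structural counterpart, the **interacting-heads motif (IHM)**, in
solution. The package is aimed at muscle biophysicists working with
single-ATP-turnover kinetics, stopped-flow FRET biosensors, TCSPC lifetime
measurements and the supporting steady-state assays (actin-activated ATPase,
NH₄⁺ ATPase, in vitro motility, negative-stain EM tallies).

## The science in brief

Two-headed cardiac myosin (HMM-like constructs) can fold into an
auto-inhibited conformation, the IHM, in which ATP turnover is 5–10-fold
slower than in open heads. In a single-turnover experiment the mant-ATP
fluorescence decay is a two-exponential mixture,

```
F(t) = F∞ + A · [ f_DRX · exp(−k_DRX t) + f_SRX · exp(−k_SRX t) ]
```

whose slow-phase fractional amplitude `f_SRX` measures the SRX population.
A FRET biosensor — GFP on the tail (donor), Cy3ATP in the active site
(acceptor) — reports the folded state directly: steady-state efficiency
`E = 1 − F_DA/F_D`, time-resolved `E = 1 − τ_DA/τ_D`, and distances via the
Förster relation `r = R₀ ((1−E)/E)^{1/6}` with `R₀ = 63 Å`. Assuming zero
FRET in the open state and a whole-IHM efficiency `E_IHM ≈ 6.0 %` (a ~100 Å
ensemble distance), the predicted efficiency is linear in the SRX fraction,
`E_pred = f_SRX · E_IHM`, which is the correlation model linking the
biochemical and structural states. Cy3ATP-binding transients are modelled
by two candidate mass-action mechanisms (a slow-binding second apo
conformation vs. a slow apo isomerisation), simulated as linear ODE systems
and fit globally across nucleotide concentrations.

## Worked example

```python
from srxfret import SimConfig, fit_exponentials, decompose_srx, gen_single_turnover
from srxfret.synthetic import turnover_measurement

planted = turnover_measurement("WT", 20)          # WT construct, 20 mM KCl
cfg = SimConfig(seed=1, noise_sd=0.005)           # 0.5% noise, 1000 s window
tr = gen_single_turnover(planted, cfg)
srx = decompose_srx(fit_exponentials(tr, n_components="auto"))
print(f"{srx.srx_fraction:.3f}")                  # -> 0.897
```

The printed number is the recovered SRX fraction — the relative amplitude
of the slow turnover phase — which lands on the planted value (0.89) to
within the fit noise. `examples/` contains one narrative script per
capability (single turnover, binding kinetics, FRET efficiency/distances,
supporting assays, and the full pipeline); each prints the quantities it
computes and one line on what they mean. `run_pipeline` orchestrates the
whole chain from a `PipelineConfig` (or YAML file) and writes per-stage
CSVs plus a deterministic JSON report.

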