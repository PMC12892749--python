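# eznetsi

Noninvasive localization of the epileptogenic zone (EZ) from preictal
scalp EEG, for researchers working on presurgical evaluation in
MRI-negative focal drug-resistant epilepsy.

Roughly a third of focal epilepsies are drug-resistant, and in the
MRI-negative subgroup no structural lesion guides surgery.  `eznetsi`
implements a source-space network analysis of the 10 minutes of scalp EEG
preceding seizure onset:

1. **Preprocessing** — 0.5–80 Hz zero-phase band-pass, 48–52 Hz mains
   notch, preictal-window selection, 2-s epoching.
2. **Source imaging** — sLORETA on a spherical-head forward model:
   `T = Gᵀ(GGᵀ + αI)⁺`, standardized as `ŝⱼ = (Ty)ⱼ/√(TG)ⱼⱼ`, with
   region time series for the 68 Desikan–Killiany areas.
3. **Directed networks** — ridge-regularized MVAR fits pooled over epochs,
   directed transfer function
   `γ²ᵢⱼ(f) = |Hᵢⱼ(f)|²/Σₘ|Hᵢₘ(f)|²`, averaged per frequency band
   (δ, θ, α, β, low-γ, high-γ).
4. **Centrality hubs** — weighted degree centralities DC/DCin/DCout under
   a proportional-threshold sweep (densities 0.05–0.50), scored by the
   area under the metric-vs-threshold curve; normalized scores ≥ 0.95 mark
   hubs.
5. **Seizure index** — each region is a bistable node
   `dxᵢ = [xᵢ − xᵢ³ + c·Σⱼ Wⱼᵢ(xⱼ − xᵢ)]dt + √(2Dᵢ)dWᵢ` with noise set by
   the Hilbert-envelope coefficient of variation; `SI = 1/τ̄`, the inverse
   mean escape time from the resting (−1) to the seizure (+1) attractor.
   Normalized SI ≥ 0.95 flags highly epileptogenic regions.
6. **Evaluation** — TP/FP/TN/FN against the resection/Engel-outcome
   reference standard; sensitivity, specificity, accuracy, PLR, NLR, DOR
   with Wilson 95% CIs; chi-square/Fisher comparisons between metrics.

A fully ground-truthed synthetic-data module (MVAR sources with
band-shaped innovations, bursty delta-band driver, analytic
conducting-sphere lead field, 21-electrode 10–20 montage) makes every
stage testable without patient data.  See `docs/methods.md` for models,
assumptions and limitations.

## Worked example

Simulate a reduced preictal scenario (16 regions, 60 s at 256 Hz, one
delta-band driver, sensor SNR 5) and run the full chain:

```bash
cat > demo.json <<'EOF'
{
  "seed": 1,
  "io": {"out_dir": "demo_out"},
  "simulate": {"n_regions": 16, "duration": 60.0},
  "si": {"realizations": 200}
}
EOF
eznetsi run-all --config demo.json
```

The run writes `demo_out/node_metrics.tsv` (one row per region × band ×
metric) and a reproducibility manifest.  Filtering the hub rows
(`is_hub == True`) of this run gives:

```
    region_id   band  metric       raw  normalized  is_hub
15         16  delta      dc  0.768555    1.000000    True
17          2  delta   dc_in  0.282738    0.978603    True
18          3  delta   dc_in  0.288920    1.000000    True
47         16  delta  dc_out  0.755888    1.000000    True
63         16  delta      si  0.064757    1.000000    True
```

`raw` is the threshold-sweep AUC (for si, the escape rate 1/τ̄ in inverse
model-time units) and `normalized` scales each metric to its maximum.
The planted driver (region 16, chosen automatically as the best-resolved
source) tops DC, DCout **and** the seizure index, while DCin flags its
coupling targets (regions 2–3) — outflow centrality marks the driver,
inflow centrality marks the propagation zone, which is exactly the
interpretation the metrics are designed for.

Other subcommands: `eznetsi simulate` (writes an EDF recording, the lead
field, and ground truth), `eznetsi evaluate` (diagnostic statistics from
per-patient prediction and clinical TSVs).  The library API mirrors the
stages: `synthetic_data`, `preprocessing`, `inverse_imaging`, `spectral`,
`network_dtf`, `seizure_index`, `evaluation`, `cli_config`.

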