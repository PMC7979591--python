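# liveriron

Simulation and analysis pipeline for comparing multi-echo gradient-echo MRI
methods of liver iron quantification. The package covers the full chain:

1. **Signal model** (`liveriron.signal`) — multi-peak fat dephasing,
   noiseless chemical-shift-encoded magnitude signal
   `|w + c(t)·f|·exp(−R2*·t)`, and the Rician first-moment operator
   `E_σ{·}` (closed form via scaled Bessel functions, asymptotic branch for
   extreme SNR). Three acquisition presets are shipped (`me-gre`, `qdixon`,
   `qdixon-wip`) differing in initial TE, echo spacing and echo count.
2. **Synthetic data** (`liveriron.synth`) — elliptical liver phantoms with
   vessels, Rician-noise acquisition under any protocol (with optional
   fat-saturation emulation), and reproducible patient cohorts with
   log-normal liver R2*, Beta-distributed fat fraction and an optional
   global fat/water swap arm.
3. **Fitting engines** (`liveriron.fitting`) —
   * truncation fit: mono-exponential with iterative noise-floor echo
     truncation (reference method);
   * magnitude Dixon fit: variable-projection-style grid over
     (R2*, fat fraction) with closed-form amplitude and bounded nonlinear
     refinement, including water/fat-ambiguity (swap) flagging and an
     optional R2* output cap;
   * noise-corrected fit: the same model wrapped in the Rician expectation
     with the noise level a known input, removing the noise-floor bias that
     makes naive magnitude fits saturate at high R2* under long echo times.
   Plus a rule-based organ-level swap detector/reverser.
4. **ROI measurement** (`liveriron.roi`) — three co-registered circular
   liver ROIs (pixel-center rasterization, area sanity bounds); the
   per-patient value is the unweighted mean of the three ROI means.
5. **LIC calibration** (`liveriron.calibration`) — a registry of affine
   R2*→LIC equations, affine cross-calibration by regression inversion,
   mg/g ↔ μmol/g conversion (Fe molar mass 55.845 g/mol) and iron-burden
   classification (strict > 36 μmol/g pathologic call, configurable
   severity boundaries).
6. **Agreement statistics** (`liveriron.agreement`) — OLS regression,
   Bland-Altman, Lin's concordance correlation coefficient with Fisher-z
   CI, contingency tables, overall percent agreement and unweighted
   Cohen's kappa with asymptotic SE.
7. **Pipeline + CLI** (`liveriron.pipeline`, `liveriron.cli`) — the full
   simulate → fit → measure → calibrate → compare study, plus
   recomputation of the published contingency-table arithmetic from the
   transcribed counts in `liveriron/data/paper_tables/`.

## CLI

```bash
liveriron --help
liveriron simulate --config config.yaml --seed 1 --out out/   # NIfTI + truth CSV
liveriron fit out/p0000_qdixon-wip.nii --engine noise_corrected
liveriron rois out/p0000_qdixon-wip_r2star.nii --rois rois.json --pixel-spacing 2.5
liveriron compare measurements.csv --out agreement.json
liveriron tables                                              # published-table arithmetic
liveriron run --config config.yaml --seed 1 --out out/        # full pipeline
```

The config is a YAML rendering of `PipelineConfig` (see
`PipelineConfig().to_dict()` for every default). Reports are deterministic,
sorted-key JSON: the same config and seed reproduce byte-identical output.

## Notes and assumptions

- The six-peak fat spectrum (`liveriron/data/fat_spectrum.json`) is a
  standard liver triglyceride model; vendor spectra are unpublished, so it
  is shipped as swappable data.
- Severity-class boundaries for the ordinal iron classification are
  configuration, not constants; the published class counts are consumed
  directly as data.
- The signal model carries no T1/flip-angle term; TR and flip angle are
  stored as inert protocol metadata.
- Simulation is magnitude-only (no phase, field map, k-space or coil
  effects) with noise independent across echoes.
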