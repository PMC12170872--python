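# mitoquant

Quantification pipeline for studies of mitochondrial Ca²⁺ handling at the
outer mitochondrial membrane (OMM). The package implements, as tested and
reusable Python, the measurement procedures such studies combine:

- **Ratiometric trace analysis** — background subtraction, photobleaching
  correction by exponential extrapolation of the pre-stimulus baseline,
  sensor-specific emission ratios (FRET 530/480, GEM-GECO 480/530,
  Fura-2 340/385, TMRM mito/nucleus), and peak/basal/Δ response metrics.
- **Concentration–response fitting** — four-parameter logistic (Hill)
  fits on log₁₀ concentration with seeded bootstrap 95% CIs for the EC₅₀.
- **3D mitochondrial morphometrics** — rolling-ball background
  subtraction, merged global + local (640 nm radius) Otsu segmentation,
  26-connected labelling, volume/surface measurement, moment-derived
  ellipsoid axes (elongation a/b, flatness b/c), and a branching index
  (volume over fitted-ellipsoid volume; lower = more branched).
- **Cristae quantification** — cristae membrane amount (cristae/mito
  perimeter) and density (cristae perimeter/mito area) from TEM masks, and
  the radial cristae density profile ρCM: iterative 2-px erosions
  (5.88 nm at 2.94 nm/px) with per-shell coverage, interpolated onto 100
  positions from the OMM (0) to the centre (100).
- **Immunogold spatial statistics** — compartment assignment and the
  signed shortest particle-to-OMM distance (positive toward the matrix,
  negative toward the cytosol), relative-occurrence histograms, and the
  fraction of particles within a 20 nm membrane window.
- **Subcellular fractionation algebra** — the band-intensity formulas for
  the mitochondrial vs cytosolic split and the inner/outer OMM-leaflet
  split, with purification-loss (K_pl) and damaged-mitochondria (K_dm)
  correction factors.
- **Single-channel patch-clamp analysis** — half-amplitude threshold
  idealization from the all-points histogram, NPo from level-weighted open
  times, slope conductance from the unitary i–V relation, channel
  occurrence across patches, and Po(V).

Because studies of this kind deposit no machine-readable raw data, the
`synth` module generates every input the pipeline consumes — 3D stacks
with cristae-like texture, bleaching two-channel traces, two-state Markov
single-channel sweeps under the stepped voltage protocol (2 s steps from
0 mV to −60…−120 mV, 10 kHz sampling, 1 kHz filtering), gold-particle
fields around a closed OMM contour, and fractionation sheets — with the
generating parameters serialized as ground truth, so every stage is
testable end to end by parameter recovery.

## Worked example

```python
from mitoquant import patch, synth, traces
from mitoquant.core import SynthConfig

config = SynthConfig(seed=7)

# single-channel conductance from synthetic mitochondria-attached sweeps
recordings, truth = synth.make_patch_sweeps(
    config, gamma_pS=35.0, sweeps_per_potential=10
)
rec = recordings[0]
idealized = [
    patch.idealize(s, fs_hz=rec.fs_hz, filter_hz=rec.filter_hz)
    for s in rec.sweeps
]
iv = patch.mean_unitary_amplitudes(idealized)
gamma, ci = patch.conductance(iv, n_boot=500, seed=7)
print(f"slope conductance: {gamma:.1f} pS (95% CI {ci[0]:.1f}-{ci[1]:.1f})")

# EC50 of a histamine-style concentration-response experiment
doses, _ = synth.make_dose_response(config, ec50_uM=1.3, n_cells=50, cv=0.10)
fit = traces.fit_hill(
    doses["conc_uM"].to_numpy(), doses["response"].to_numpy(), seed=7
)
print(f"EC50: {fit.ec50_uM:.2f} uM (95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f})")
```

Output:

```
slope conductance: 35.1 pS (95% CI 34.7-35.6)
EC50: 1.30 uM (95% CI 1.21-1.39)
```

The recovered conductance matches the 35 pS used to generate the sweeps,
and the Hill fit returns the generating EC₅₀ of 1.3 µM with a bootstrap
interval that covers it. `patch.po_voltage(idealized)` additionally shows
the open probability rising with hyperpolarisation (Po 0.11 at −60 mV to
0.40 at −120 mV for the default gating parameters).

A thin CLI chains the stages into reproducible runs:

```bash
mitoquant --seed 7 --out run/ all   # synth -> morpho/traces/cristae/gold/fraction/patch -> report
```

Every output directory carries the run configuration, its hash, and the
package version; re-running with the same seed is byte-identical.

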