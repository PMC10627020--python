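# boldkernel

Estimate the spatial smoothness of the BOLD fMRI response relative to
electrocorticography (ECoG), for researchers combining intracranial
recordings with task fMRI — multimodal mapping, pre-surgical functional
localization, and BCI electrode placement all need to know how far a focal
electrophysiological source spreads in a 3T activation map.

The package implements the full analysis as a tested pipeline, together
with a seeded synthetic paired-recording generator, so every stage runs
end to end with no data download.

## The analysis

ECoG is taken as spatial ground truth: each subdural electrode records
from the cortex directly beneath its contact. For a block-design motor
task (30 s rest / 30 s movement):

1. **ECoG band response.** Channels whose variance falls outside
   mean ± 3 SD of the other channels are rejected; the rest are
   re-referenced to the common average. Log band power (mean of
   log-transformed 0.5 Hz PSD bins under a Hanning taper) is computed in
   2 s windows for the high-frequency broadband (HFB, 65–95 Hz), alpha
   (8–12 Hz) and beta (13–30 Hz) bands, and movement vs rest is tested
   per electrode with an unpaired two-sample *t*-test; *t* is mapped to a
   signed z-score through its two-sided *p*. Electrodes with *p* < 0.05
   (uncorrected) enter the correlation.
2. **BOLD z-map.** Gray-matter voxel series are high-pass filtered by
   Gaussian-weighted running-line fitting (σ = 45 s) and fit with a
   single-regressor GLM (movement boxcar ⊗ canonical double-gamma HRF),
   giving a voxelwise z-map restricted to the gray-matter mask.
3. **Kernel-width sweep.** For each kernel width σ ∈ [1, 20] mm, the fMRI
   z at electrode *e* is the Gaussian-weighted average
   ẑ(e, σ) = Σᵢ wᵢ zᵢ, wᵢ ∝ exp(−dᵢ²/2σ²), over gray-matter voxel
   centers (world-mm distances). Correlating ẑ with the ECoG z-scores
   across electrodes yields the explained-variance curve r²(σ).
4. **Two summary widths.** The **peak kernel width** is argmax r²(σ) —
   the best ECoG–fMRI agreement. The **maximum-downwards-concavity
   width** is the σ at the most negative discrete second derivative of
   r²(σ) — the point where additional smoothing stops paying off, which
   estimates the spatial specificity of the BOLD point-spread function.

The synthetic generator builds a gray-matter slab with an 8×8 electrode
grid at 10 mm pitch (4 mm isotropic voxels, 512 Hz ECoG, TR 0.608 s), a
ground-truth activation field, band-specific ECoG power modulation (HFB
up, alpha/beta down during movement), and a BOLD response equal to the
truth field blurred by a known width σ_true — so the recovery of σ_true
can be tested, not assumed.

## Worked example

`python examples/05_kernel_width_sweep.py` simulates one subject with
σ_true = 4 mm and runs the whole analysis:

```
  hfb: n=52 electrodes | peak r^2=0.89 at sigma=10.25 mm | concavity at 4.25 mm | slope at peak +0.38
alpha: n=39 electrodes | peak r^2=0.89 at sigma=11.75 mm | concavity at 4.0 mm | slope at peak -0.46
 beta: n=46 electrodes | peak r^2=0.88 at sigma=7.25 mm | concavity at 4.0 mm | slope at peak -0.46
```

The concavity width recovers the 4 mm ground-truth point spread in every
band; the peak width is larger because averaging more (noisy) voxels keeps
improving the correlation well past the point spread. The fitted
BOLD-on-ECoG slope is positive for broadband power and negative for
alpha/beta — the two low-frequency bands anti-correlate with BOLD.

The other scripts in `examples/` show the individual capabilities: task
design and HRF regressor, dataset simulation and the BIDS-like on-disk
layout, per-electrode band z-scores, and the gray-matter GLM z-map.

## Command line

The same stages run from a shell over a BIDS-like tree:

```bash
boldkernel all --root data --subject sub-01 --subject sub-02 --seed 1
boldkernel group --root data --subject sub-01 --subject sub-02
```

Subcommands `simulate`, `ecog`, `fmri`, `kernel`, `group` run stages
individually; `--config cfg.yaml` overrides any analysis parameter, and
the effective configuration is serialized next to the outputs.

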