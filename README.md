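# frapquant

Quantification toolkit for junctional-protein dynamics experiments:
fluorescence recovery after photobleaching (FRAP) at cell–cell junctions,
per-pixel junctional intensity measurement with reference normalization,
Western-blot densitometry ratios, and replicate-table statistics
(one-/two-way ANOVA) — all driven by synthetic-data generators with known
ground truth so every stage can be validated by parameter recovery.

It is aimed at cell biologists analysing adherens/tight-junction imaging
experiments (e.g. E-cadherin-GFP FRAP in epithelial monolayers, mixed
cultures of marker-positive and marker-negative cells) who want a scripted,
reproducible replacement for spreadsheet-based FRAP arithmetic and manual
ImageJ measurements.

## The model

A bleached junctional region recovers as a single exponential. After
photofading correction and pre-bleach normalization (pre-bleach mean = 100%),
the post-bleach frames are fitted to

    I(t) = P − (P − I0) · e^(−τt)

with free plateau `P`, post-bleach level `I0` and rate `τ` (1/s). From the
fit:

- **half-life** `t½ = ln 0.5 / (−τ) = ln 2 / τ` — how fast fluorescence
  returns;
- **mobile fraction** = percentage recovery at plateau,
  `100·(P − I0)/(100 − I0)` in the default full-scale convention (the
  literal percent-of-pre-bleach reading `P` is selectable);
- **immobile fraction** = 100 − mobile.

Photofading correction divides the bleach-ROI signal by the whole-cell
fading factor (whole-cell mean / its pre-bleach mean). Per-condition results
are pooled as mean ± SEM over cells, with a logged warning when fewer than
12 cells converge.

Junctional intensity is measured per junction as the per-pixel mean over a
label mask (size-independent), junctions are classified by their
marker-channel mean against a threshold, and marker-negative junctions form
the reference population whose mean normalized intensity is 1.

## Worked example

Simulate 12 noisy FRAP traces with known ground truth (mobile fraction 0.5,
τ = 0.05/s, 2% multiplicative noise, photofading 0.002/s) and run the full
analysis:

```python
import frapquant as fq

cfg = fq.SimFrapConfig(mobile_fraction_true=0.5, tau_true=0.05,
                       photofade_rate=0.002, noise_sd_frac=0.02,
                       n_traces=12, seed=1)
traces, truth = fq.simulate_frap_traces(cfg)
fits, summaries = fq.analyze_frap_experiment(traces)
s = summaries[0]
print(f"n_cells = {s.n_cells}")
for m in ("t_half", "mobile_pct", "immobile_pct"):
    print(f"{m}: {s.metrics[m]['mean']:.2f} +/- {s.metrics[m]['sem']:.2f}")
```

prints

```
n_cells = 12
t_half: 14.05 +/- 0.19
mobile_pct: 49.77 +/- 0.24
immobile_pct: 50.23 +/- 0.24
```

i.e. the pipeline recovers the generating truth (t½ = ln 2/0.05 ≈ 13.86 s,
mobile 50%) from noisy data, with the SEM quantifying between-cell spread.

The same stages are available from the shell:

```sh
frapquant simulate --kind frap --seed 1 --out demo
frapquant frap-fit --traces demo/frap_traces.csv --out demo/fit
frapquant run --demo --seed 1 --out demo_run   # full multi-stage pipeline
```

`frapquant run` writes a manifest with the config, seed and sha256 of every
output, so identical config + seed reproduces byte-identical results.

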