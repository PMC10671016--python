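# microdff

Analysis pipeline for **drug-evoked dopamine release imaged by an
implantable micro-CMOS sensor**. A needle-shaped 40 × 90-pixel CMOS imager
(7.5 µm pitch, 300 µm × 675 µm field) records dLight1.2 fluorescence in the
nucleus accumbens of freely moving mice while a subcutaneous injection of
morphine, cocaine, or saline is given at t = 0. Because dLight emission
tracks extracellular dopamine, the session-wide fluorescence transient
carries the drug's pharmacological signature: opioids disinhibit VTA
dopamine neurons (gradual rise peaking 30–60 min, slow decline), dopamine-
transporter blockade acts fast (peak 15–45 min) and ends in a sharp
sustained drop below baseline, and saline stays flat.

The package implements, as tested, reusable code:

* **Synthetic session generator** (`microdff.simulate`) — ground-truthed
  stacks emulating the sensor: Gaussian release sites, illumination
  gradient, read + shot noise, an injection-handling dip, and Bateman-minus-
  logistic drug kinetics. Every downstream claim is validated against what
  was planted.
* **ΔF/F₀ processing** (`microdff.dff`) — per-pixel
  ΔF/F₀ % = (F − F₀)/F₀ × 100 against the 15-min pre-injection baseline,
  interval averaging into end-labelled 5- or 15-min bins, whole-image
  traces.
* **ROI detection** (`microdff.roi`) — adaptive binarization (local mean +
  offset) of every post-injection frame, morphological open–close cleaning,
  occupancy-map thresholding, connected components, numbered ROI traces and
  the ROI × time heatmap with a whole-image row "W".
* **Group statistics** (`microdff.stats`) — one-way repeated-measures ANOVA
  over the animals × 15-min-interval table, computed from first principles,
  with Holm-adjusted post-hoc comparisons against the pre-injection control
  bin.
* **I/O and orchestration** (`microdff.session_io`, `microdff.pipeline`,
  `microdff` CLI) — multi-page TIFF + JSON sidecars, CSV/JSON/PNG results
  with hashed manifests, deterministic end-to-end runs.

## Worked example

```python
import numpy as np
from microdff import (PipelineConfig, run_drug_group)
from microdff.pipeline import group_mean_trace

config = PipelineConfig(seed=1, make_figures=False)
sessions, table, anova = run_drug_group(config, "morphine")

labels, mean_trace = group_mean_trace(sessions)
post = labels > 0
peak = labels[post][np.argmax(mean_trace[post])]
p_adj = {c.label: c.p_adjusted for c in anova.posthoc}[peak]
print(f"peak {mean_trace[post].max():.2f}% dF/F0 at the {peak:.0f}-min bin, "
      f"adjusted p vs pre = {p_adj:.2e}")
```

prints

```
peak 4.14% dF/F0 at the 45-min bin, adjusted p vs pre = 1.99e-40
```

i.e. three simulated morphine animals (seeds 1–3) show a group-mean
whole-image peak of ~4 % ΔF/F₀ in the (30, 45] interval — inside the
30–60-min window expected for opioid kinetics — and the repeated-measures
post hoc marks that bin as overwhelmingly significant against the
pre-injection control. The same run for cocaine peaks at the 30-min bin
and undershoots to ≈ −1.3 % late in the session (see
`results/drug_comparison.csv`).

The `analysis/` scripts tell the same story as a narrative:
`01_simulate_sessions.py` (write the 3 × 3 synthetic sessions),
`02_dff_traces.py` (ΔF/F₀ + binned whole-image traces →
`results/traces.csv`), `03_detect_rois.py` (ROI sets and heatmaps; on the
representative sessions all 12 planted sites are recovered with ~0.1 px
median centroid error), `04_group_stats.py` (RM-ANOVA per drug) and
`05_compare_drugs.py` (profile comparison). A one-command version is
`microdff demo --out runs/demo --seed 1`.

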