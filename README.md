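# mitoscreen

Open, tested quantification for high-content imaging of mitochondrial
biology in cultured neurons — the kind of assays used to characterise
Parkinson's-disease patient lines carrying *PRKN* (parkin) mutations:

* **Live mitophagy assay** — a mitophagy event is a mitochondrion whose
  maximum-projection mask is 100 % contained in a single lysosome label;
  per-cell fractions *m* = engulfed/total are tracked over time-lapses
  sampled every 18 minutes, under basal or inhibitor-induced (antimycin A +
  oligomycin) conditions.
* **Segmentation stack** — nuclei, cell regions (cytoplasm including
  projections), mitochondria, lysosomes and bright puncta from multi-channel
  z-stacks, all quantified on per-frame maximum projections.
* **Morphometrics** — mitochondrial number, size, mean intensity and
  interconnectivity I = mean area/perimeter (µm; disc of radius r → r/2,
  lower = more fragmented); cell roundness R = P²/(4πA) and elongation
  E = major/minor axis; normalisation to a control group (control mean ≡ 100 %).
* **ATP metabolic partitioning** — from inhibitor plates (oligomycin blocks
  OXPHOS, 2-deoxyglucose blocks glycolysis): %OXPHOS = 100(U−O)/U,
  %glycolysis = 100(U−D)/U, %residual = 100·B/U, plus the metabolic-switch
  day at which %OXPHOS first exceeds %glycolysis.
* **Statistics** — two-way ANOVA (genotype × timepoint) with Sidak or Tukey
  multiple-comparison correction, and mixed (repeated-measures) ANOVA across
  time-lapse points with the differentiation round as the unit of replication.
* **Synthetic scene generator** — ground-truthed fields (cell shape,
  per-mitochondrion engulfment dynamics, photon/readout noise, 7 z-planes)
  and ATP plates emulating control vs. mutant phenotypes, so every pipeline
  stage is validated against known truth without real patient images.

See `docs/methods.md` for the model, parameter and design details.

## Worked example

```python
import numpy as np
import mitoscreen as ms
from mitoscreen.config import RunConfig
from mitoscreen.metabolics import atp_partition
from mitoscreen.synthgen import generate_atp_plate
from mitoscreen.workflows import analyze_live_stack

# ATP partition of a day-27 neuron plate (condition means in a.u.)
plate = generate_atp_plate(
    {"untreated": 15.1, "oligomycin": 3.5, "2DG": 8.5}, cv=0.0, n_wells=6, seed=0
)
part = atp_partition(plate)
print(f"%OXPHOS      = {part.pct_oxphos:.1f}")
print(f"%glycolysis  = {part.pct_glycolysis:.1f}")

# live mitophagy assay on a synthetic field with 9 % basal engulfment
scene = ms.generate_scene(ms.SceneParams(n_cells=8, basal_engulf_prob=0.09, seed=1))
stack = ms.render_timelapse(scene)          # [T, Z, C, Y, X] uint16
events, fractions = analyze_live_stack(stack, RunConfig())
m = np.concatenate([s.to_numpy() for s in fractions])
print(f"events detected        : {len(events)}")
print(f"mean mitophagy fraction: {m.mean():.4f}")
print(f"ground-truth fraction  : {np.nanmean(scene.ground_truth_fractions):.4f}")
```

prints

```
%OXPHOS      = 76.8
%glycolysis  = 43.7
events detected        : 125
mean mitophagy fraction: 0.0821
ground-truth fraction  : 0.0821
```

The partition says these cells draw ~77 % of their ATP from oxidative
phosphorylation. The measured mitophagy fraction equals the generator's
ground truth exactly on this field, and both sit within sampling error of
the 0.09 engulfment probability (8 cells × ~20 mitochondria × 10 frames).

A CLI mirrors the assay structure (`mitoscreen simulate | mitophagy |
morphology | metabolics | stats`), reads OME-TIFF stacks and plate CSVs,
and writes events/time-course/summary CSVs with the resolved configuration
alongside for provenance; reruns are bit-identical.

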