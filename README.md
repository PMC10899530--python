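# ktrq — kinase-translocation-reporter quantification

`ktrq` is a Python toolkit for quantifying single-cell ERK signaling from
live-cell kinase-translocation-reporter (KTR) imaging, and for measuring
metastatic tumor burden from fluorescent histology. It is aimed at
cell-signaling and cancer-biology labs that image reporter lines such as
ERKTR/H2B on automated microscopes and stain lung sections with
DAPI/vimentin/marker panels.

## What it computes

**Live-cell KTR analysis.** An ERK translocation reporter leaves the nucleus
when ERK is active, so the background-corrected intensity ratio

&nbsp;&nbsp;&nbsp;&nbsp;activity(t) = (cytoplasmic mean − bg) / (nuclear mean − bg)

read per cell per frame is an instantaneous single-cell ERK activity trace.
The pipeline segments nuclei from the H2B channel (Otsu threshold,
distance-transform watershed, minimum-area filter), builds per-nucleus
cytoplasmic rings, links cells across frames by greedy nearest-neighbor
matching, and extracts traces on the acquisition schedule (default: 6-min
frames, 4 h baseline, ligand addition, 15 h post, then MEK inhibitor to
drive ERK to its floor).

**Responder statistics.** Each cell's trace is normalized to its
MEK-inhibited floor, then tested with a paired t-test on order-matched 1-h
pre/post-treatment frame windows (significant at *P* < 0.005, increase
only). For responders the pipeline computes the maximum response amplitude
within 1 h of ligand addition and the 12-h baseline-subtracted AUC
(surrogate for response duration), the population responder fraction with a
Wilson 95% CI, a Hill fit *p*(dose) = *p*max / (1 + (EC50/dose)^*h*) of
fraction versus dose, and an ensemble response-class call: transient
(class 1), prolonged-but-waning (class 2), or sustained (class 3).

**Histology quantification.** Lung tissue is segmented by auto-threshold of
the DAPI channel and tumors by auto-threshold of vimentin within the tissue
mask; the report gives lung area, tumor area and count, metastatic burden =
100 · tumor area / lung area, and the 90th-percentile marker intensity
inside the vimentin mask. Bland–Altman bias and limits of agreement
(bias ± 1.96·SD of paired differences) compare manual versus automated
counts. Fold changes, organoid percent survival, mean ± SEM summaries and
Benjamini–Hochberg FDR adjustment round out the reporting layer.

**Synthetic data with exact ground truth.** Every stage is testable at desk
scale: `ktrq.synth` generates trace ensembles from the three response-class
kinetics, renders two-channel (H2B + ERKTR) movies whose cytoplasm/nucleus
ratio equals the true activity by construction, and renders
DAPI/vimentin/marker sections with known lung area, tumor count/areas and
marker percentiles.

## Worked example

```python
from ktrq.synth import SimParams, simulate_trace_ensemble
from ktrq.responder import (normalize_traces, call_responders,
                            responder_fraction, classify_response_class)
import numpy as np

params = SimParams(response_class=2, n_cells=500, dose=10.0, seed=42)
traces, truth = simulate_trace_ensemble(params)

norm = normalize_traces(traces)            # floor-normalize to MEKi window
calls = call_responders(norm)              # paired t-test per cell
frac, (lo, hi) = responder_fraction(calls)
cls = classify_response_class(norm, calls)

amps = [c.amplitude for c in calls if c.amplitude is not None]
aucs = [c.auc for c in calls if c.auc is not None]
print(f"true responder probability: {truth.responder_probability:.3f}")
print(f"observed responder fraction: {frac:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print(f"mean amplitude: {np.mean(amps):.2f}   "
      f"mean 12-h AUC: {np.mean(aucs):.2f} activity*h")
print(f"assigned response class: {cls}")
```

```
true responder probability: 0.400
observed responder fraction: 0.394 (95% CI 0.352-0.437)
mean amplitude: 7.05   mean 12-h AUC: 28.28 activity*h
assigned response class: 2
```

At 10 ng/mL the dose–response model gives a 0.40 responder probability; the
per-cell test recovers 0.394 with a CI covering the truth, and the ensemble
mean trace is correctly recognized as a prolonged-but-waning (class 2)
response. Amplitude and AUC are on the floor-normalized scale (MEK-inhibited
activity ≡ 1).

The same analyses are available from the shell:

```bash
ktrq simulate-traces --response-class 3 --dose 100 --n-cells 500 --seed 42 --out traces.csv
ktrq responders --traces traces.csv --alpha 0.005 --out calls.csv
ktrq simulate-tissue --n-tumors 12 --seed 7 --out section.tif
ktrq tissue-quant --image section.tif --out report.json
ktrq report --config config.yaml        # full pipeline from a YAML config
```

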