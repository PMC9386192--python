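# thermentropy

Quantitative texture analysis of infrared thermography during graded
exercise.

During an incremental cycling test to exhaustion, the *mean* skin
temperature of the torso barely moves — but the *spatial distribution* of
temperature changes markedly as warm, tree-shaped patterns (superficial
perforator vessels dilating over the working respiratory muscles) emerge
on the chest. `thermentropy` implements the image-processing and
statistical pipeline that captures this: per-region temperature
quantization, Shannon-entropy texture trajectories, percent-of-exhaustion
time normalization, and the correlation of chest entropy with pulmonary
ventilation (VE) and exercise intensity. Because no public thermogram
dataset exists for this protocol, the package includes a first-class
synthetic generator that emulates the study conditions (160 × 120
radiometric frames every 30 s, ~10 min tests, two-breakpoint VE curves)
and is used by the test suite and the acceptance script.

It is aimed at exercise physiologists and biomedical-imaging researchers
who want a reproducible, scriptable alternative to manual thermal-image
workflows.

## The statistic at the core

For a region of interest (ROI — forehead, chest or abdomen), temperatures
are rounded to 0.1 °C, the ROI minimum is subtracted, and the result is
expressed as non-negative integer levels x_k. The texture entropy is the
Shannon entropy of the level histogram,

    H = − Σ_k p(x_k) · log₂ p(x_k)        [bits]

where p(x_k) is the relative frequency of level x_k among the ROI's
pixels. H = 0 for a thermally uniform region and grows as the temperature
distribution becomes more heterogeneous; subtracting the minimum makes it
insensitive to the absolute temperature. The ROI mean temperature is
computed separately on the raw (unrounded) values.

Each subject's trajectory is rescaled so that exhaustion = 100 % of
exercise time, resampled onto a common percent grid, and averaged across
subjects. The statistical layer provides Spearman rank correlation (exact
permutation p-values for n ≤ 8), one-way repeated-measures ANOVA across
timepoints, and detection of the two ventilatory thresholds (VT1/VT2) on
the VE curve by an exhaustive continuous three-segment piecewise-linear
least-squares search.

## Worked example

```python
from thermentropy import RunConfig, run_pipeline
import json

out = run_pipeline(RunConfig(n_subjects=18, master_seed=0), "runs/demo")
report = json.load(open(out / "stats_report.json"))
print(report["correlations"]["chest_entropy_vs_time"])
print(report["correlations"]["chest_mean_temp_vs_time"])
print(report["thresholds"]["group"])
```

prints (exactly, for this seed):

```
{'method': 't-approximation', 'n': 20, 'p_value': 0.0, 'rho': 1.0}
{'method': 't-approximation', 'n': 20, 'p_value': 0.6134176645307824, 'rho': -0.12030075187969923}
{'low_confidence': False, 'slopes': [0.6028383720340149, 1.245152051492033, 2.444619126847189], 'sse': 2.550927290331484, 'vt1_pct': 45.0, 'vt2_pct': 80.0}
```

Reading: over the 18-subject synthetic cohort the group chest entropy
rises strictly monotonically with percent of exercise time (Spearman
rho = 1.0), the group chest *mean* temperature shows no trend
(rho = −0.12, p = 0.61), and the two breakpoints of the group VE curve
are detected at 45 % and 80 % of exercise duration with the fitted
segment slopes increasing (0.60 → 1.25 → 2.44 L/min per percent-point).
For this seed the cohort's chest entropy runs from 4.62 ± 0.29 bits at
the start of exercise to 5.11 ± 0.20 bits at exhaustion (`features.csv`
in the run directory has the per-frame values).

The same pipeline is available from the shell:

```bash
thermentropy run --subjects 18 --seed 0 --outdir runs/demo
thermentropy simulate --subjects 2 --seed 1 --outdir sessions/   # interchange files
thermentropy features --indir sessions/ --outdir runs/from-disk
```

Frames interchange as headerless CSV matrices of °C (or scaled 16-bit
TIFF with a JSON sidecar), ROIs as polygon-vertex JSON, VE as a two-column
CSV — see `thermentropy.io`.

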