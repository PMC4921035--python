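# spikeqc

Quality control of ERCC spike-in RNA control pools built on a modified Latin
square mixture design, for transcriptomics platforms (hybridisation
microarrays and RNA-Seq).

## The problem

Spike-in RNA controls of known concentration let an expression assay be
judged against ground truth.  In the design this package implements, ERCC
controls are split into five subpools, each spanning a 2^20 ladder of
relative abundance; subpools B–E are mixed into four pools at 10/15/25/40 %
in a Latin square while subpool A is held constant at 10 %.  Every pairwise
pool comparison then carries known fold changes — 4, 2.7, 2.5, 1.7, 1.6,
1.5 and 1 — across the whole dynamic range, so a single four-sample
experiment measures, at once: each control's individual dose-response,
the platform's signal response over the full range, and its ability to
detect ratios between samples.

`spikeqc` is for platform developers and core labs running such pools: it
encodes and validates the design, fits the platform dose-response model,
flags misbehaving controls, demarcates the usable linear region, and
quantifies ratio compression.

## The models

Hybridisation signal saturates and is fit with the Langmuir isotherm

    I = I_max · C / (K_d + C) + bg

where `I_max` is anchored to the average signal of the most abundant control
in each pool, `bg` to the omitted control ERCC-00073, and the dissociation
constant `K_d` is the single fitted parameter (least squares on log2
residuals over per-control centroids).  Counting (RNA-Seq) signal does not
saturate and is fit with a unit-slope line in log2–log2 space.  Per-control
screens: log2–log2 slope (ideal m = 1) and exact Spearman monotonicity
(ρ = 1 required) across the 10 < 15 < 25 < 40 % titration.  Controls outside
the 99 % interval of the fit are response-curve outliers; the inflection
points of the model's expected slope curve bound the linear region used to
interpret non-monotonic controls and Bland-Altman (MA) ratio panels.  See
`docs/methods.md` for the full account.

## A worked example

```python
from spikeqc import (AnomalySpec, ArraySimConfig, RunConfig,
                     load_design, run_assessment, simulate_microarray)

design = load_design()
signals = simulate_microarray(
    design, ArraySimConfig(seed=42),
    AnomalySpec(offset_controls={"ERCC-00004": 2.0}),  # 4x concentration error
)
result = run_assessment(RunConfig(platform="array", signals=signals))
print(result.fit)
print(result.region)
print(result.outlier_table)
```

prints (abridged; `python examples/array_assessment.py` runs this):

```
Langmuir fit: K_d = 9231 (true 10000), I_max anchor = 15945, bg anchor = 32.6
residual SD = 0.215 log2 units over 89 centroids
linear region: log2 abundance in [4.21, 13.20]

control_id subpool  log2_base_abundance  rho  residual  outlier_class
ERCC-00004       C                  9.0  1.0  1.924519 response_curve
```

The dissociation constant is recovered within 8 % from one noisy run, the
linear region spans ~9 log2 units of the 22-unit design range, and the one
control whose concentration was corrupted by 4x is the one flagged — with
ρ = 1 (still monotone), so it is a response-curve outlier, not a
mis-assignment.

The `examples/` directory has one narrative script per capability: the
design table and its fold-change closure, an array assessment, an RNA-Seq
assessment with detection limits, and the ratio-compression curves.

A thin CLI wraps the same library:

```
spikeqc simulate --platform array --seed 1 --out signals.tsv
spikeqc assess --platform array --signals signals.tsv --out report/
spikeqc report --dir report/
```

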