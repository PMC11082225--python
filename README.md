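# bh3flow

Analysis of BH3-profiling flow cytometry: from raw cytometer events to
apoptotic-priming scores, anti-apoptotic dependency calls, dynamic
delta-priming, and EC90 dose–response — with a synthetic data generator
that makes the whole chain testable by parameter recovery.

## Who this is for

BH3 profiling exposes permeabilized cells to BH3-domain peptides and
measures mitochondrial cytochrome c (cyt c) release by flow cytometry. It
is the workhorse functional assay for asking how close a tumor cell is to
the apoptotic threshold ("priming") and which pro-survival protein —
BCL-2, MCL-1, BCL-xL or BFL-1 — it depends on, questions that directly
steer BH3-mimetic therapy (venetoclax, S63845, A-1331852). This package is
for analysts who have per-tube event files and a tube manifest and want a
reproducible, scriptable route from events to cohort-level conclusions,
and for methodologists who want a ground-truthed simulator to validate
gating and normalization choices.

## The model in brief

Per tube, hierarchical gating (FSC-A/SSC-A morphology → FSC-H/FSC-A
singlets → viability dye → CD5+CD19+ immunophenotype) isolates the target
population, whose median cyt-c fluorescence (MFI) is the readout. Two
controls anchor each sample: PUMA2A (inert, full retention) and 25 μM
alamethicin (complete release):

    % cyt c loss = 100 · (MFI_PUMA2A − MFI_sample) / (MFI_PUMA2A − MFI_alamethicin)

Selective peptides deconvolve dependencies (BAD − HRK → BCL-2; MS-1 →
MCL-1; HRK → BCL-xL; FS-1 → BFL-1); dynamic profiling measures
drug-induced change, `delta priming = loss_drug − loss_DMSO`; and
titrations are fit with the variable-slope four-parameter logistic

    y(c) = bottom + (top − bottom) / (1 + 10^(hill·(logEC50 − log10 c))),

from which EC90 follows in closed form, with a typed `NOT_REACHED` when
the curve never attains 90% in the tested range. Cohorts are compared with
unpaired two-tailed Student t tests (pooled variance), reported as
mean ± SEM. See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
from bh3flow import make_preset, dependency_metrics, call_dependencies
from bh3flow.recovery import simulate_profiles

preset = make_preset("RS1050")   # a Richter-transformation model
profile = simulate_profiles(
    preset, [("BAD", 10.0), ("HRK", 10.0), ("MS-1", 10.0), ("FS-1", 10.0)],
    n_samples=1, n_events=10000, seed=3)[0]
panel = dependency_metrics(profile)
print({k: round(v, 1) for k, v in panel.metrics().items()})
print(call_dependencies(panel, threshold=20.0))
```

prints

```
{'BCL-2': 1.8, 'MCL-1': 46.4, 'BCL-xL': 44.3, 'BFL-1': 38.9}
{'BCL-2': False, 'MCL-1': True, 'BCL-xL': True, 'BFL-1': True,
 'no_clear_dependency': False}
```

i.e. the pipeline recovers, from simulated raw events, that this model is
co-dependent on MCL-1, BCL-xL and BFL-1 but not on BCL-2 — each metric is
the percentage of cyt c released in response to the protein-selective
probe, and a metric ≥ 20 points is called a dependency. The scripts in
`examples/` walk through each capability the same way (gating, profiling,
dependencies, dose–response, dynamic profiling, the full cohort pipeline);
a thin CLI (`bh3flow simulate|gate|cohort|doseresponse`) chains the stages
from the shell.

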