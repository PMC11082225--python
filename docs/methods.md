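# Methods

## The assay being modeled

BH3 profiling exposes digitonin-permeabilized cells to BH3-domain peptides
or BH3-mimetic drugs and measures mitochondrial cytochrome c (cyt c)
release by flow cytometry. Promiscuous peptides (BIM, BID, PUMA, BMF)
antagonize all major pro-survival proteins and report overall *apoptotic
priming* — how close a cell sits to the mitochondrial death threshold.
Selective peptides deconvolve which pro-survival protein the cell depends
on: BAD binds BCL-2 and BCL-xL, HRK only BCL-xL, MS-1 only MCL-1, FS-1
only BFL-1. Hence

    BCL-2 dependence  = response(BAD) − response(HRK)
    BCL-xL dependence = response(HRK)
    MCL-1 dependence  = response(MS-1)
    BFL-1 dependence  = response(FS-1)

Two controls anchor the scale in every sample: the inert PUMA2A peptide
defines full cyt c retention and 25 μM alamethicin (a pore former) defines
complete release. With the cyt-c median fluorescence intensity (MFI) of
the gated target population as readout,

    % cyt c loss = 100 × (MFI_PUMA2A − MFI_sample) / (MFI_PUMA2A − MFI_alamethicin).

The widely printed form of this ratio, `(MFI_sample − MFI_alam) /
(MFI_PUMA2A − MFI_alam)`, evaluates to the *retained* fraction under these
control semantics (it is 1 when the sample matches the retention control);
`cytc_loss(..., as_printed=True)` returns that literal quantity, the
default returns 100 − retention so that 0 means fully retained and 100
fully released. This orientation choice is deliberate and documented here
because the two conventions are easy to conflate.

Losses are computed per tube and then averaged across duplicate tubes
(normalize-then-average), which is robust to per-tube intensity scaling;
control MFIs are averaged across their replicates first because they enter
every condition of the sample. Raw losses outside [0, 100] are kept and
flagged (`out_of_range`); clamping happens only in display outputs
(heatmap). Dependency metrics are clamped into [−100, 100]; a negative
BCL-2 metric is kept raw with a `negative_bcl2_dep` flag. Dependency
*calls* use a configurable working threshold of 20 percentage points
(`≥` counts as dependent); the threshold is a package convention — the
assay literature interprets dependencies qualitatively.

Dynamic BH3 profiling (DBP) compares drug- versus vehicle-pretreated cells
probed with a weak BIM dose: `delta priming = loss_drug − loss_DMSO`. The
probe dose is chosen so the vehicle arm releases 10–30% (strong enough to
see increases, weak enough not to saturate); a vehicle loss outside that
window sets a `basal_outside_window` flag. Extended DBP applies the same
difference to each dependency metric, at matched probe concentration
(1 μM by default), per timepoint.

## Dose–response

`fit_4pl` fits the variable-slope logistic in log10 concentration,

    y(c) = bottom + (top − bottom) / (1 + 10^(hill·(logEC50 − log10 c))),

by bounded least squares (soft bounds bottom ∈ [−10, 50], top ∈ [10, 110],
hill ∈ [0.1, 10]) with a 7-point multi-start grid over logEC50 spanning one
decade beyond the tested range; the grid prevents top/EC50 trade-off
pathologies on shallow curves. `converged` is honest: it is False when the
optimizer fails or any parameter lands on a bound, and an all-equal
response vector returns a degenerate fit rather than fabricated
parameters. Zero-dose (vehicle) points are not log-transformable and can
anchor the bottom plateau through a weighted pseudo-residual
(`baseline_anchor`) instead of entering the design.

ECf, the concentration attaining an absolute response of f percent, has the
closed form `EC50 × (f_rel/(100 − f_rel))^(1/hill)` with
`f_rel = 100(f − bottom)/(top − bottom)`. When the fitted plateau never
reaches f, or the required concentration exceeds the largest tested dose,
the result is the typed singleton `NOT_REACHED` — never a sentinel number —
because "EC90 not reached" is itself the biologically meaningful outcome
for unprimed samples.

## Gating

Four parameterized stages reproduce the manual hierarchy: a rectangular
FSC-A/SSC-A morphology region, an FSC-H/FSC-A ratio band (default
0.80–1.15) for singlets, a viability-dye cutoff, and marker positivity
(`CD5+CD19+` for primary samples, `CD19+` for xenograft models). The
original gates were drawn by eye in analysis software; here every boundary
is an explicit config value so results are reproducible, and the defaults
are tuned to the synthetic generator rather than inferred from any real
instrument. The viability cutoff supports an `auto` mode that smooths the
log10 histogram with a fixed-width Gaussian kernel, requires two modes of
at least 5% relative prominence, and splits at the valley between them;
unimodal channels fall back to the configured cutoff with a
`viability_auto_fallback` flag. MFI uses the standard midpoint convention
for even counts. A final gate below `min_gated_events` (default 30,000,
matching the acquisition scale of the assay) sets `low_event_count`; an
empty final gate is a hard flag with an undefined MFI.

## The synthetic generator

No raw patient data are deposited for this assay family, so the package
ships a generator whose presets encode known truths, making every stage
verifiable by parameter recovery. A tube is a mixture of five populations
(defaults: 5% debris, 5% doublets, 7% dead, 20% non-target, 63% target).
Scatter and marker channels are log-normal per population; doublets sum
two singlet scatter draws (pulse height ≈ max of the two), pushing their
FSC-H/FSC-A ratio to ≈0.5, below the singlet band; dead cells carry ~10×
viability-dye intensity and release cyt c with probability 0.9 regardless
of condition; debris sits at low scatter. Control roles override the
condition's release probability exactly (PUMA2A → 0, alamethicin → 1), so
control tubes are extreme by construction. The generator oversamples raw
events by the expected target fraction so ≈ `n_events` target cells survive
gating, mirroring fixed-target acquisition. Randomness is counter-based:
`SeedSequence(master_seed, sample_index, tube_index)`, so cohorts are
reproducible tube-by-tube and byte-identical on re-simulation.

**Cyt-c channel and median linearity.** The cyt-c channel is a
two-component mixture — retained cells high, released cells strictly
lower — but, unlike the other channels, its components are broad
*truncated normals with equal spread* (means 4000 and 3100, sd 1400,
clipped at zero; clipping does not move the medians). This is a deliberate
departure from log-normal components. The pipeline's readout is the
*median* of the mixture, normalized linearly between the two control
medians; for scale-family (log-normal) components the mixture median
interpolates geometrically between the component medians while the
normalization interpolates arithmetically, producing a ~3-point mid-range
bias that no amount of data removes. With equal-spread, near-symmetric
components whose overlap is large relative to their separation, the
mixture median is approximately linear in the released fraction: the
worst-case deviation over the full range is ≈0.6 points (computed
numerically from the component CDFs), at the price of a per-tube median
sampling noise of ≈1 point at 30,000 gated events. Biologically this
overlapping-mixture choice emulates the graded, partial per-cell cyt c
release seen in permeabilized cells, rather than an idealized
all-or-nothing bimodal stain. What passing recovery tests therefore show
is that gating + normalization + averaging is faithful *given* a readout
that responds smoothly to the released fraction; they do not certify
performance on strongly bimodal real data, where median readouts are
intrinsically coarser.

**Presets.** Named presets encode the CLL/Richter contrast. Values that a
cohort or sample reports are encoded exactly (divided by 100): CLL
promiscuous-peptide truths 0.972/0.970/0.975/0.964 (BIM/BID/PUMA/BMF), RS
composite 0.714/0.603/0.671/0.725, RS1050's 0.423 response to A-1331852,
RSVR3's MS-1 response 0.908 before and 0.399 during ibrutinib, and the
RS1316 copanlisib-6h deltas +0.38/+0.47/+0.40 (MS-1/HRK/FS-1) over its
1 μM baseline. Quantities the source material only constrains
qualitatively were fixed once as plausible values: the individual BAD and
HRK levels behind the BCL-2-dependence differences (CLL: 0.90/0.172,
difference 0.728; RS: 0.35/0.162, difference 0.188), the RS1050
co-dependency magnitudes (0.50/0.45/0.40), and the RS1316 1 μM baselines
(0.12/0.10/0.08), the last matching the convention that a treated MS-1
response of 50% over a vehicle response of 12% yields a +38 delta.
Dose-response truths use bottom 0, top 100, hill 1 with logEC50 set so the
closed-form EC90 equals 0.08 μM (CLL) or 0.73 μM (RSVR3). Absolute
fluorescence scales are conventional (arbitrary units); no spillover,
plate effects or instrument drift are simulated.

## Statistics

Group comparisons are unpaired two-tailed Student t tests with pooled
variance (the assay convention), Welch behind a flag; descriptives are
mean ± SEM with SEM = SD/√n. Two zero-variance groups with equal means
return t = 0, p = 1 by convention. No multiple-testing correction is
applied by default, mirroring per-peptide reporting practice. Star
rendering (\*, \*\*, \*\*\*, \*\*\*\* at 0.05/0.01/0.001/0.0001) is
display-only.

## Problem sizes and numerical choices

Recovery experiments use 30,000 target cells per tube and duplicate tubes,
the assay's own acquisition scale; cohort targets use 17 (CLL-like) and 9
(RS-like) samples. At that scale the per-condition loss estimate has
sd ≈ 1 point and the deterministic median bias is ≤0.6 points, so
cohort-mean recoveries land within ±1.5 points and single-sample metrics
within ±2. Dose-response recovery uses 8 log-spaced doses over
0.001–10 μM with 3-point Gaussian response noise and takes the median EC90
over 50 replicate fits. Unit tests and examples run smaller tubes
(3,000–10,000 events) since gate recall and determinism do not need
acquisition scale.

Ties and degenerate inputs: events with FSC-A = 0 are excluded from the
singlet gate rather than divided; empty gates propagate as flags, not
exceptions, until the MFI is actually requested; equal control MFIs are a
hard error naming the tube pair; a dependency metric whose reagent is
missing is `None`, never 0.

## Known limitations

- Compensation/spillover, plate and drift effects are out of scope; the
  generator's populations are well separated, so the ≥95–99% gate recalls
  demonstrated here are upper bounds on messy real data.
- The 4PL top and EC50 trade off on shallow curves with few doses; the
  honest `converged` flag and multi-start mitigate but cannot remove this
  identifiability limit.
- FCS support covers single-dataset float list-mode 3.0/3.1 files — enough
  to round-trip the generator's output and typical exports, not the full
  standard (no integer data types, analysis segments, or multi-dataset
  files).
- `DMSO` is accepted as a manifest control role for vehicle arms of
  dynamic profiling, but vehicle tubes are normalized like any other
  condition; pairing of drug and vehicle arms is the caller's
  responsibility (`delta_priming` takes the two profiles explicitly).
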