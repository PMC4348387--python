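# aslcomp

Noninvasive mapping of **cerebral arterial compliance (AC)** from short
inversion time pulsed arterial spin labeling (PASL).

Large cerebral arteries (middle, anterior, and posterior cerebral arteries)
swell in systole and relax in diastole. At short inversion times (TI < 1 s)
the PASL tag/control difference signal ΔM is dominated by labeled blood still
inside these arteries, so the **arterial blood volume** (aBV, in percent of
voxel volume, %v) can be measured separately in systole and diastole by
retrospectively sorting image slices by cardiac phase. Combined with brachial
cuff pressures this yields a local, noninvasive compliance estimate —
something transcranial Doppler cannot provide, because it measures velocity,
not geometry.

## Model

The macrovascular difference signal is a dispersed plug-flow bolus:

    ΔM(t) = 2 α (aBV/100) M0,a exp(−t/T1,a) · c(t)

    c(t)  = ½ [ erf((t − Δt)/(σ√2)) − erf((t − Δt − τ)/(σ√2)) ]

i.e. a square bolus of duration τ (fixed at 700 ms by the QUIPSS II
saturation cut-off) convolved with a unit-area Gaussian of width σ centered
on the arrival time Δt. Defaults: α = 1, T1,a = 1664 ms (arterial blood at
3 T). Voxel-wise bounded least squares over the seven TIs (250–850 ms,
slice-delay corrected) estimates (aBV, Δt, σ) per cardiac-phase bin.
Compliance is the diastole-normalized volume change per unit pulse pressure
(PP, mm Hg):

    AC = 100 · (aBV_sys − aBV_dia) / (aBV_dia · PP)      [%/mm Hg]

and AC·PP is the percent aBV change over one cardiac cycle.

The pipeline: plethysmograph peak detection → 225 ms finger-delay shift →
per-slice cardiac phase φc = (t_acq − t1)/(t2 − t1) → 8 phase bins → per-bin
ΔM maps with tag/control balance accounting → voxel-wise kinetic fits →
per-slice 95th-percentile vessel mask × territory masks → AC map and
territory medians. A synthetic acquisition generator with known ground truth
(territory blobs, cardiac-modulated parameters, matching pulse waveform,
tissue background) makes everything testable without scanner data.

## Worked example

Simulate a phantom acquisition, run the full pipeline, and run the
two-compartment contamination study:

```bash
aslcomp simulate -o demo/data --seed 7 --n-pairs 30
cat > demo/config.yaml <<'YAML'
data_dir: demo/data
output_dir: demo/out
bp_readings: [[115.6, 62.8]]
fit:
  bins: [1, 6]          # early diastole and early systole
roi:
  summary_slice: 4      # slice just above the circle of Willis
YAML
aslcomp run -c demo/config.yaml
head -8 demo/out/territory_summary.csv
```

prints

```
territory,parameter,n_voxels,median
RMCA,ac,7,0.5248047913127761
RMCA,abv_dia,7,2.254122619404443
RMCA,abv_sys,7,2.8750838015775755
RMCA,dt_dia,7,429.03508859451506
RMCA,dt_sys,7,463.7199779008394
RMCA,sigma_dia,7,87.95276080868304
RMCA,sigma_sys,7,65.43718858044366
```

The right-MCA territory (planted AC 0.57 %/mm Hg, diastolic aBV 2.2 %v)
comes back with a median compliance of 0.52 %/mm Hg, a diastolic aBV of
2.25 %v and a systolic aBV of 2.88 %v; the fitted arrival time is ~35 ms
later and the dispersion ~23 ms narrower in systole, matching the planted
cardiac modulation. The contamination study

```bash
aslcomp study -o demo/study.csv --abv 1.65 --abv 3.0 --dt-tiss 700 --dt-tiss 800
```

reports, for each true aBV and tissue arrival time, how much an
arterial-only fit overestimates aBV when tissue perfusion (60 mL/100 g/min)
leaks into the late TIs, e.g. 2.3% at aBV = 1.65 %v with tissue arrival
700 ms, falling to 0.8% at 800 ms — small enough to justify fitting without
a tissue compartment in large-vessel voxels.

## Layout

- `src/aslcomp/signal_model.py` — arterial and tissue kinetic models
- `src/aslcomp/cardiac_sync.py` — peak detection, phase assignment, binning
- `src/aslcomp/voxel_fit.py` — M0 calibration and voxel-wise fitting
- `src/aslcomp/roi_compliance.py` — vessel masks, territory ROIs, AC maps
- `src/aslcomp/synthetic_data.py` — phantom generator and contamination study
- `src/aslcomp/{io,config,pipeline,cli}.py` — formats, YAML config, stages, CLI

See `docs/methods.md` for the modeling assumptions, parameter choices, and
known limitations.
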