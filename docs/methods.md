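# Methods

## Arterial kinetic model

A voxel containing a large artery receives a plug-flow bolus of labeled
blood of duration τ, arriving at Δt, with edges smeared by Gaussian
dispersion of width σ accrued during transit. The difference signal is

    ΔM(t) = 2 α (aBV/100) M0,a exp(−t/T1,a) · c(t),
    c(t) = ½ [erf((t−Δt)/(σ√2)) − erf((t−Δt−τ)/(σ√2))],

the closed form of a square weighting function (half-open support
[Δt, Δt+τ), so its integral is exactly τ) convolved with a unit-area
Gaussian. At σ = 0 the square bolus is recovered exactly.

Where the T1 decay acts is a genuine modeling choice: applying
exp(−t/T1,a) at the observation time (outside the convolution) keeps the
σ → 0 limit exact and matches the undispersed plug-flow model on the
plateau; applying it per labeled spin inside the convolution is also
defensible and has the closed form

    c_label(t) = exp(σ²/(2 T1,a²)) exp(−t/T1,a) ·
                 ½ [erf((t−Δt−σ²/T1,a)/(σ√2)) − erf((t−Δt−τ−σ²/T1,a)/(σ√2))].

The observation-time convention is the default; `decay="label"` switches to
the alternative. For σ ≲ 100 ms and T1,a = 1664 ms the two differ by less
than σ²/(2T1,a²) ≈ 0.2%.

Units: all times in ms; aBV is carried in %v throughout the API (printed
values such as 1.68 %v round-trip without conversion) and divided by 100
only inside signal evaluation.

Defaults: τ = 700 ms (QUIPSS II cut-off — used at *all* TIs, including
TI < τ where the trailing edge simply has not yet appeared), α = 1,
T1,a = 1664 ms (arterial blood at 3 T).

## Tissue compartment

Used only by the generator and the contamination study, never in the
production fit. Single well-mixed compartment: delivered label decays with
the blood rate 1/T1,a until uptake at time s and with the apparent tissue
rate 1/T1app = 1/T1,t + f/λ afterwards,

    ΔM_tiss(t) = 2 α M0,a f ∫_{Δt_tiss}^{min(t, Δt_tiss+τ)}
                 e^{−s/T1,a} e^{−(t−s)/T1app} ds,

evaluated in closed form. f is CBF converted to mL·mL⁻¹·ms⁻¹ (unit tissue
density). λ = 0.9 mL/g and T1,t = 1330 ms (3 T gray matter) are
conventional values, both config-exposed; the contamination results are
insensitive to them (< 0.1 percentage point across T1,t 1000–1500 ms)
because at TI < 1 s the tissue signal is dominated by the short delivery
window, not by tissue relaxation.

## Retrospective cardiac synchronization

Systolic peaks are detected on the band-passed (0.5–8 Hz, zero-phase)
plethysmograph trace with a 250 ms refractory period and a prominence floor
of a quarter of the filtered peak-to-peak amplitude. Smoothing the
asymmetric beat shape biases the detected maximum by ~8–10 ms (~1% of a
cycle), which is immaterial after phase binning. Peaks are shifted earlier
by the finger transit delay (default 225 ms, configurable) so they mark
cerebral systole.

Each (volume, slice) gets the phase φc = (t_acq − t1)/(t2 − t1) of its own
acquisition time (slice mode: volume start + slice_index × slice delay) or
of the volume's labeling event (label mode: the volume start time for every
slice — the constant TI offset between label and readout shifts all phases
uniformly and cancels in binning, leaving the exact identity
φ_label = φ_slice − s·slice_delay/RR at constant R-R). Volumes with
timestamps outside the peak-covered interval are dropped with a logged
warning, not errored. Tag/control identity always comes from acquisition
metadata, never from image intensities.

Bins are the eight half-open intervals [k/8, (k+1)/8) — a true partition;
bin 1 is early diastole and bin 6 early systole. Per (TI, bin, slice),
ΔM = mean(control) − mean(tag); a bin missing either image type at a slice
yields a represented missing value. Counts are tracked per (TI, bin, slice)
and reported at a reference slice, flagging bins below a count floor
(default 3).

## Voxel-wise fitting

Bounded nonlinear least squares (trust-region reflective) over the seven
ΔM values at slice-delay-corrected TIs, three free parameters. Bounds:
aBV ∈ [0, 100] %v, Δt ∈ [0, 1500] ms, σ ∈ [0, 500] ms. Initialization is
data-driven and deterministic: aBV from the peak ΔM via the plateau closed
form, Δt from the earliest TI exceeding 10% of the peak, σ = 50 ms; no
random restarts, so fixed data give fixed results. Voxels with fewer than
4 finite ΔM values (3 parameters + 1 dof) are left unfit; per-voxel
failures are recorded and never abort a map.

The reported fit error is the degrees-of-freedom-adjusted residual standard
error √(SS/(n−3)); with Gaussian noise of known s.d. it converges to that
s.d. (the unadjusted root mean square would converge to √(4/7) ≈ 0.76 of
it at n = 7).

M0,a is calibrated as the median of a fully relaxed calibration image over
a CSF mask times a configurable CSF-to-arterial-blood conversion factor.

Identifiability note: with an undispersed truth (σ = 0) and 100 ms TI
spacing, Δt and σ are only jointly constrained to the inter-TI interval;
aBV, set by the plateau height, remains exact.

## ROIs and compliance

Vessel voxels are the strict top 5% of the whole-series mean ΔM image at
TI = 750 ms (the TI of maximal arterial contrast), thresholded per slice;
ties at the threshold are excluded, keeping counts minimal, and constant
slices yield empty masks with a warning. Territory ROIs are the
intersection with broad labeled masks (five labels: RMCA, LMCA, ACA, RPCA,
LPCA; one ACA label because left/right are not separable at this voxel
size). AC = 100(aBV_sys − aBV_dia)/(aBV_dia·PP), defined only where
aBV_dia > 0 (missing elsewhere, never infinite). Summaries are medians —
of the voxelwise AC, not the AC of median aBVs (the alternative can be
composed from the reported aBV medians) — optionally restricted to a
configured slice just above the circle of Willis.

## Synthetic generator

The generator's defaults are the modeled protocol: TR 1400 ms, seven TIs
250–850 ms in seed-randomized series order, 80 tag-control pairs per TI,
14 slices at 29 ms slice delay, heart rate 65 ± 3.25 bpm (~5% beat-to-beat
s.d., i.i.d. normal intervals), finger delay 225 ms, pulse pressure
52.8 mm Hg (115.6/62.8). Five 2×2-voxel territory blobs on a 24×24
in-plane grid around the circle-of-Willis slice carry diastolic aBV
1.6–2.2 %v (the >1.5 %v large-vessel regime the ROI selection assumes) and
planted compliances 0.43–1.1 %/mm Hg; systolic arrival is 41 ms later than
diastolic and diastolic dispersion 30 ms wider than systolic (σ_sys
60 ms). Tissue background: CBF 60 mL/100 g/min arriving 350 ms after the
arterial bolus in vessel voxels (an absolute-arrival override exists,
700 ms in plain background voxels). Noise is additive Gaussian on tag and
control images independently, s.d. 5·10⁻⁴ of M0,a — an SNR near 50 for the
peak ΔM of a 2 %v vessel voxel; Rician/complex effects are out of scope in
this high-SNR regime.

Per-territory parameters follow the slice's own cardiac phase through a
C1 piecewise-cosine interpolation that is exact at the diastolic anchor
(center of bin 1, φ = 0.1875) and systolic anchor (center of bin 6,
φ = 0.8125), periodic, and bounded by the anchors. The pulse waveform is a
raised-cosine upstroke with exponential decay whose maximum lags the true
cardiac event by the finger delay, so peak detection plus the delay shift
recovers the planted beats.

What the phantom does *not* emulate: vascular geometry and partial-volume
gradients, motion (a pass-through motion-correction hook is provided, no
registration is implemented), B0/B1 artifacts, arrhythmia, and pulse-wave
propagation delays between territories. Passing tests therefore demonstrate
correctness of the synchronization/fitting/compliance chain under the
stated signal model, not robustness to those real-data effects.

## Contamination study

For each (true aBV, tissue arrival) the noiseless two-compartment signal is
fitted arterial-only at the seven short TIs and the bias
100·(fit − true)/true tabulated. Because the tissue term is a small
additive perturbation, the relative bias falls off essentially as 1/aBV
and decreases with later tissue arrival. Both the arterial arrival
(default: 350 ms before tissue arrival) and the tissue arrival are explicit
arguments, since both relative and absolute conventions are in use for
this protocol; the truth dispersion defaults to σ = 50 ms.

Measured with this implementation: maximum overestimation 3.5% over aBV
1.1–10 %v at tissue arrival 700 ms (under 5%), 2.3% at aBV 1.65 %v, and
0.8% at tissue arrival 800 ms.

## Known limitations and numerical notes

- End-to-end compliance recovery on the phantom carries a systematic ≈ −8%
  relative bias: ≈ −3% because each bin's mean parameter differs from its
  anchor value under smooth modulation (bin-averaging attenuation), and
  ≈ −5% because tissue contamination inflates diastolic aBV more than
  systolic (smaller volume, wider dispersion), deflating the
  diastole-normalized AC. This is a property of the method under these
  conditions, not an implementation artifact; a tissue-free, noiseless,
  modulation-free phantom is recovered to optimizer tolerance.
- Problem sizes in the test suite are scaled for quick runs: 4–6 slice
  phantoms, 30–80 pairs per TI; the protocol's full 14-slice geometry is the
  generator default and is exercised by the CLI tests.
- Tolerances: dispersed-bolus closed form agrees with adaptive quadrature to
  1e-9; optimizer tolerances are 1e-12 (xtol/ftol/gtol) so noiseless
  recovery is exact to ~1e-8 of signal scale.
- Degenerate inputs: flat physio traces raise; empty CSF masks raise; empty
  fit masks, empty ROIs, and constant slices warn and produce missing
  values; zero diastolic aBV yields missing AC.
- Stage outputs are deterministic for a fixed seed and configuration; the
  manifest (package version, seed, config hash) is byte-identical across
  re-runs.
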