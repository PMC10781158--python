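# Methods

## The measurement chain

A beat series is the pair (systogram, tachogram): per-beat systolic blood
pressure SBP_n (mmHg) at systolic time t_n (s) and pulse interval
PI_n = 1000·(t_n − t_{n−1}) (ms). The first beat of a detected recording
has no interval and is dropped, so the three arrays stay aligned.

**Peak detection.** Systolic peaks are local maxima with prominence
≥ 10 mmHg separated by ≥ 120 ms (a 500 bpm refractory ceiling, above any
rat heart rate); when two candidates fall inside one refractory window the
taller wins. This makes detection robust to dicrotic notches without
annotating them. Detection is invariant to a constant pressure offset.
There is no ectopic-beat editing beyond the refractory rule; inputs are
assumed to be clean resting recordings.

**Segmentation.** Endpoints are computed on three 5-min windows per
recording. Window placement defaults to "even" (start, middle, end of the
record) with contiguous-from-start and explicit-starts overrides; for the
stationary series produced by the generator every placement is equivalent,
which is why the default is a convention rather than a finding.

## Time- and frequency-domain variability

Time-domain BPV is the per-window sample SD and variance (denominator
n − 1) of SBP and PI, averaged across the three windows. Because the
average of per-window variances is reported, `var_sbp` need not equal
`sd_sbp`².

For spectra, each window's beat series is cubic-spline interpolated onto a
dense 250 Hz grid and *spline-decimated* — the dense spline is subsampled —
to the 10 Hz analysis rate, then a least-squares linear trend is removed.
No anti-aliasing filter sits between the two rates: the spline through
beats ~170 ms apart carries almost no energy above ~3 Hz, and the 5 Hz
Nyquist of the analysis rate is far above the 0.75 Hz LF upper edge. The
10 Hz rate is conventional for rodent beat-to-beat analysis; a run-time
guard rejects any `fs_out` whose Nyquist falls below the LF band.

Auto- and cross-spectra are Welch averages (Hann window, 50 % overlap,
8 segments by default; for a 300 s window at 10 Hz the segment length is
666 samples, giving ~0.015 Hz resolution and ~37 LF bins). Averaging is
essential for the coherence gate: a single periodogram has squared
coherence identically 1 at every frequency, which would make any coherence
threshold vacuous. With a rectangular window and one segment the PSD
integral reproduces the series variance to well under 1 % (Parseval); with
Hann/Welch the density normalisation preserves integrated power for both
broadband and narrowband signals, which the test suite checks against the
analytic sinusoid power a²/2.

Band powers integrate the one-sided PSD over the closed LF interval
[0.20, 0.75] Hz by the trapezoidal rule over the bins inside the interval;
the closed-interval trapezoidal convention is declared to make results
bit-reproducible.

**Alpha index.** The gate statistic is the mean squared coherence across
LF bins (a "max" option exists); alpha = sqrt(LF_PI / LF_SBP) ms/mmHg is
reported only when the gate exceeds 0.5, otherwise the result is flagged
invalid with a reason. Per recording, LF powers and the gate statistic are
averaged over the three windows before gating. Zero SBP band power is a
distinct invalid reason ("no pressure power in band"). Alpha scales
linearly with the PI series and inversely with the SBP series, and is
monotone in the generator's gain on noise-free inputs; both are property
tests.

## The synthetic generator

The generator is a beat-point process:

    SBP_n = S0 + A_lf sin(2π f_lf t_n) + A_hf sin(2π f_hf t_n + φ) + ε_n
    PI_n  = P0 + g (SBP_{n−delay} − S0) + η_n
    t_n   = t_{n−1} + PI_n / 1000

with ε ~ N(0, σ_SBP²) and η ~ N(0, σ_PI²) independent white sequences and
φ drawn once per series. Beat times advance by the realized interval, so
the output is an honest irregularly-sampled tachogram/systogram pair. The
delay is a whole number of beats, default 1 (fast, vagally mediated
coupling — the assumption underlying the spontaneous-baroreflex alpha
index); a zero-delay configuration is solved by fixed-point iteration
since PI then depends on the pressure at the beat time it itself sets.
Configurations whose deterministic swing plus a 6σ noise allowance could
drive PI to zero are rejected as a degenerate rhythm.

Two modelling consequences matter for interpretation:

- Because PI responds to the *measured* (noisy) pressure, PI–SBP coherence
  is high at every LF bin where g²·S_SBP dominates the independent PI
  noise, so the calibrated arms pass the 0.5 gate with margin (~0.96),
  while setting g = 0 collapses coherence to its no-coupling floor (~1/K
  for K Welch segments, ~0.13) and the gate rejects essentially every
  seed. The independence of η from ε is deliberately the worst case for
  coherence.
- Alpha estimates are biased upward only by the PI-noise power falling in
  the LF band, by the factor sqrt(1 + P_η,LF/(g²·P_SBP,LF)); at the
  default σ_PI = 0.5 ms this bias is below 2 % for gains ≥ 0.3, which is
  what the 50-seed parameter-recovery tests measure.

**Group presets.** Four arms of an ovariectomized-SHR protocol are
shipped, calibrated to reported group means: SD-SBP/VAR-SBP/LF-SBP/alpha =
7.2 mmHg / 52.4 mmHg² / 13.4 mmHg² / 0.40 ms/mmHg (SO, sedentary),
6.8 / 47.8 / 11.4 / 0.57 (SOE, sedentary + enalapril), 5.9 / 36.1 / 7.4 /
0.76 (TO, trained) and 5.9 / 32.9 / 7.4 / 1.02 (TOE, trained + enalapril).
Calibration is simple and invertible: A_lf = sqrt(2·LF_target); the
variance left after the two sinusoids is assigned to white SBP noise
(σ_SBP² = VAR_target − LF_target − A_hf²/2); the gain equals the target
alpha. The respiratory component is fixed at f_hf = 1.3 Hz, A_hf = 2 mmHg
(≈ 2 mmHg² of power, a plausible respiratory contribution well outside the
LF band), the operating point at P0 = 170 ms (~350 bpm) with group-typical
mean pressures, and σ_PI = 0.5 ms as above. Per-animal variation arises
only from seeds (spawned from one `SeedSequence`), not from biological
parameter spread.

**What the generator does and does not emulate.** It reproduces the
spectral geometry that the endpoints measure — narrowband LF and HF
oscillations, broadband beat noise, a linear delayed baroreflex transfer —
under stationarity. It does not model between-animal parameter spread
(within-group SDs of simulated endpoints are estimation noise only, far
smaller than reported biological SDs, which makes group contrasts easier
to detect than in real data), nonstationarity or behavioural state
changes, ectopic beats/artifacts, nonlinear or frequency-dependent
baroreflex transfer, or diastolic/mean-pressure dynamics. Passing the
cohort-level tests therefore shows the *pipeline* orders and separates the
arms correctly when the generating parameters differ as reported — not
that real recordings would yield those significance patterns at n = 8.
One visible consequence of the broadband noise: the measured LF-SBP power
exceeds the sinusoidal target by the noise power falling in the band
(~6–7 mmHg² for the sedentary arm), since the invertible calibration
assigns the full residual variance to white noise.

**Waveform rendering** (for end-to-end peak-detection tests) draws each
beat as a raised-cosine upstroke (40 ms, shortened for short intervals)
peaking exactly at the beat's systolic time and pressure, followed by an
exponential decay (τ = 50 ms) toward a diastolic floor; a round-trip
render→detect recovers every beat time within one sample and every SBP
within 1 mmHg, which the acceptance tests verify over random
configurations.

## Group statistics

One-way ANOVA uses the classical between/within decomposition; an
all-identical input returns F = 0, p = 1 rather than NaN. Levene's test is
the original mean-centered variant by default (median-centered
Brown–Forsythe as an option) and is computed as the ANOVA F on absolute
deviations; if the deviations have zero within-group spread the statistic
is reported as +∞ with a warning instead of failing.

The SNK procedure tests ordered means stepwise from the widest span
downward: for a span of r means, q = |m_j − m_i| / sqrt(MS_within / n_h)
with n_h the harmonic mean of the two group sizes (the study design has
n = 7–8, so a convention for mild imbalance is needed), compared against
the studentized-range quantile q(r, df_within, α) (critical values from
the studentized-range distribution, cached per (α, r, df); an unavailable
quantile raises rather than silently falling back). A non-significant span
blocks every pair inside it. Decisions use p ≤ 0.05 inclusive. Under the
complete null this construction makes the familywise error exactly the
probability that the full-span range test rejects, i.e. the nominal α —
which is what the acceptance script measures empirically. With k = 2 the
procedure reduces algebraically to the two-sided pooled t-test
(q = √2·t), checked over simulated datasets.

The post-hoc stage runs regardless of the omnibus result (the report
carries the omnibus flag) since gating conventions vary between labs; both
behaviours are available to the caller. The compact-letter display
exploits the interval structure of SNK non-significance on ordered means:
maximal non-significant spans become letters.

## Renal computations

Creatinine clearance is the standard UV/P form, (U_cr × V̇)/P_cr with V̇
the 24-h urine volume in mL/min — invariant to the common creatinine
concentration unit. Protein excretion is Bradford concentration × 24-h
volume (zero volume yields 0 mg/24 h with a warning). Tubulointerstitial
fields (277,000 µm² each) are binned by altered-area percentage after
rounding to the nearest integer, so the printed range labels read
literally: ≤ 25 %, 26–50 %, ≥ 51 %; a boundary value of exactly 25 % falls
in the mild bin. Assay endpoints (urea, cytokines, oxidative-stress
markers) enter the pipeline only as per-animal values for the group
statistics; their chemistry is out of scope.

## Problem sizes and numerical conventions

Defaults: 30-min recordings (~10,600 beats at P0 = 170 ms), three 5-min
windows, 10 Hz analysis rate, 8 Welch segments. Monte-Carlo checks use
2000 replicates for the nominal-level estimates (Monte-Carlo SE ≈ 0.005),
50 seeds per gain for parameter recovery, 20 replicate cohorts for the
group-contrast pattern, and 500 datasets for the SNK/t-test equivalence —
sizes chosen so each estimate's Monte-Carlo error is several times smaller
than the tolerance it is checked against. All randomness flows through
`numpy.random.default_rng` seeds or `SeedSequence` spawning; identical
configurations are bit-reproducible. Trapezoidal band integration, the
inclusive closed band interval, the n − 1 variance denominator and the
inclusive p ≤ α decision rule are fixed conventions declared here so that
independent reimplementations can match results exactly.

## Known limitations

- Within-group spread of simulated endpoints reflects estimation noise
  only; simulated ANOVA effect sizes are optimistic relative to animals.
- The LF-SBP calibration target is the sinusoid's power; measured LF power
  additionally contains in-band broadband noise (see above).
- Coherence and alpha assume a linear, stationary PI–SBP relation; the
  gate can only certify linear coupling, not baroreflex causality.
- The renal module consumes per-field alteration percentages; it does not
  segment histology images.
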