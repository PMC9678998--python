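# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Signal conventions

All times are seconds on a single per-sweep clock (t0 = sweep start;
stimulus times on the same clock). Currents are stored as recorded at
−70 mV, inward negative; "amplitude" always means the unsigned deflection
|peak − baseline|. Traces are uniformly sampled (10–20 kHz typical for
patch-clamp; 1 Hz typical for bouton imaging); the reader rejects
non-uniform sampling beyond 1e-6·dt. The canonical interchange format is
two-column CSV (`time_s`, `value`) written at 17 significant digits so
write→read round trips are bit-exact. No filtering is applied by default
anywhere; detection uses only the short boxcar described below.

## Miniature-event detection

The detector works on the deflection d(t) = baseline(t) − I(t), where the
baseline is a causal running median over the preceding 50 ms — robust to
the events themselves at the ≤1 Hz rates typical of TTX recordings. A 0.5 ms
boxcar (short against the ~5 ms decay of a PSC) suppresses single-sample
noise before peak picking. Candidate peaks must exceed the amplitude
threshold in both height and prominence; the prominence requirement is what
rejects noise bumps riding a real event's decay. Two further rules:

* refractory: a new event is accepted only after the deflection has fallen
  below 50% of the previous accepted peak;
* area: the integral of d(t) from onset (last crossing below 10% of peak)
  to the return below that level must exceed the area threshold.

Defaults are data-driven because published analyses rarely state their
thresholds: amplitude = 5x the robust noise SD (1.4826·MAD of the
deflection), area = amplitude x 1 ms. Both are overridable. On simulated
traces (events ≥ 5x noise SD, ≤ 1 Hz) this operating point gives pooled
recall and precision above 0.99/0.99 over 50 seeds.

Kinetics: 10–90% rise time by linear interpolation of the level crossings;
decay time constant by least-squares fit of A·e^(−t/τ) to the segment of
the falling phase between 90% and 10% of peak. For a bi-exponential event
with rise 0.5 ms / decay 5 ms, the residual rising component contaminates
the early decay and biases this conventional fit by ~0.7% relative — the
package keeps the conventional procedure and documents the bias rather than
switching to a full bi-exponential fit. Events whose decay is clipped by
the trace end, or whose fit fails, keep their amplitude but carry a
`kinetics_valid = False` flag.

Time-course summaries (e.g. a 2 min pre-treatment baseline followed by
three 5 min windows after chelator wash-in) report per-window frequency and
amplitude normalised to window 1; an empty first window makes the
normalisation undefined (NaN with a warning) rather than raising.

## Evoked trains and the cumulative-amplitude RRP estimator

Per stimulus: baseline = mean over the 2 ms preceding the stimulus; the
peak is the largest unsigned deflection from that baseline searched from
stimulus + 2 ms (the artifact blank, covering the 0.5 ms somatic
depolarisation with margin) to the next stimulus. At 40 Hz each response
rides the preceding decay tail; with a 5 ms decay this costs ~1.5% of the
preceding amplitude, an inherent property of baseline-referenced
measurement at high rates, not a bug.

The cumulative profile is the running sum of amplitudes indexed by stimulus
time. The fit window (default 0.5–1.0 s after the first stimulus, half-open,
i.e. stimuli 21–40 at 40 Hz) is regressed by OLS and evaluated at the first
stimulus time; Pr = I₁/intercept. Under the depletion model with constant
replenishment ρ (sites/s), pool aₖ₊₁ = aₖ(1−Pr) + ρ·ISI capped at N:

* at Pr = 1 the cumulative curve is exactly linear beyond the first
  stimulus and the intercept equals N·q to machine precision;
* at Pr < 1 the saturated transient gives intercept = q·(N − a_ss·(1−Pr))
  with a_ss = ρ·ISI/Pr: an *underestimate* of N·q whose magnitude shrinks
  monotonically as Pr → 1 (−0.5% at Pr = 0.8, −8% at Pr = 0.2 for the
  default ρ·ISI = 2). This sign and monotonicity are asserted by tests.

Validity flag: a fit is invalid when the intercept is non-positive, Pr > 1,
or the intercept does not exceed one steady-state increment (slope·ISI). The
last condition catches the degenerate no-depression case — for constant
amplitudes the back-extrapolated "pool" collapses onto a single interval's
refill (numerically equal to I₁) and carries no pool information.

Whether the steady-state current of depression is expressed in pA or as a
fraction of I₁ varies between reports; the fitters consume amplitudes
normalised to I₁ and therefore report fractions (the absolute value is
recoverable as SSC·I₁). Cumulative fits operate per cell on a single
(averaged) profile.

## Depression and recovery fits

Depression (sustained trains, e.g. 30 s @ 20 Hz, ≥ 20 points):
y(t) = SSC + A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s), all parameters bounded below
by 0, τ_f < τ_s enforced by post-fit ordering. Initialisation is
deterministic: SSC from the mean of the last 10% of points, time constants
at 1/30 and 1/3 of the train duration, amplitudes splitting the initial
drop 60/40. A mono-exponential is fitted alongside and reported instead
when it has the lower AIC (or when the bi-exponential fails): genuinely
single-exponential decays otherwise produce an arbitrary split.

Recovery (post-train probing at 0.1 Hz, ≥ 4 points, normalised to the
pre-train I₁): y(t) = SSC − (SSC − y₀)·e^(−t/τ) with t measured from train
end. A perfectly flat probe series returns SSC = y₀ with τ = ∞ rather than
a spurious fit.

Noiseless self-consistency for all three exponential fitters (depression,
recovery, endocytosis below) is better than 1e-4 relative; with 5%
multiplicative noise the median recovery of the generating time constants
over 100 seeds is within 3–6%, comfortably inside the 15% working
tolerance used by the tests.

## Fura-2 calibration and conversion

Conversion: [Ca²⁺] = K_d·(R−R_min)/(R_max−R)·β with β = F380_max/F380_min —
strictly increasing in R, exact inverse of the forward model on
[R_min, R_max). R < R_min clamps to 0 nM with a warning. The pure equation
diverges at R_max, so the measurement wrapper flags ratios within 1% of the
R_min–R_max span of R_max as saturated instead of converting them; the
low-level function remains the exact inverse so that calibration round
trips are testable to 1e-9 over the full 1 nM – 10 mM range.

K_d estimation: regress y = log₁₀[(R−R_min)/(R_max−R)·β] on x = log₁₀[Ca²⁺]
and read K_d from the x-intercept (the concentration where the bracketed
term is 1; base-independent at y = 0). The regression is inverse-variance
weighted with σ_y ∝ R·[1/(R−R_min) + 1/(R_max−R)]: under multiplicative
ratio noise the y-uncertainty of points near either asymptote diverges, and
an unweighted fit lets the two ends of a 1 nM–10 mM grid dominate with
almost no information (measured median |Δlog₁₀K_d| 0.078 unweighted vs
0.004 weighted at 1% ratio noise). The noise CV cancels from the weights,
so no noise estimate is needed, and on noiseless data the weighted fit is
identical (and exact). Points outside (R_min, R_max) are excluded with a
warning; ≥ 3 usable points are required. R_min, R_max and β are inputs
(they come from 0-Ca/EGTA and ionomycin-saturation measurements, which are
experimental procedures, not computations).

SyGCaMP: basal = mean F / mean background over a ≥ 15 s unstimulated
baseline at 1 Hz; evoked = (peak − basal)/SD of baseline, both after
background subtraction — the two normalisations ("background signal" for
basal, "background noise" for evoked) are deliberately distinct and the
outputs are labelled accordingly. Both are camera-gain invariant.

## sypHy analysis

ΔF/F₀ with F₀ = mean of the first 5 s after background subtraction (error
if F₀ ≤ 0). Endocytosis: plateau + amp·e^(−t/τ) fitted from the
post-stimulus peak over the following 90 s; a segment with no decaying
component (amplitude ~0, still-rising signal, or peak at the final frame)
is flagged unidentifiable rather than fitted. Pool-fraction normalisation
divides by F_max = mean over the NH₄Cl window (error if F_max ≤ F₀, a
failed alkalinisation). The recovery index is mean(post-train probe peaks)/
mean(pre-train probe peaks); it accepts one or several post probes, both
readings encountered in practice, and is invariant to common normalisation.
No bleaching correction is applied by default (protocols typically insert
rest periods instead); a linear detrend can be applied upstream if needed.

## Synthetic-data generator

Each simulator is the exact forward model its estimator assumes, so
parameter recovery is a meaningful end-to-end test:

* **minis** — homogeneous Poisson events, rate = mini_rate +
  slope·([Ca²⁺]_rest − 100 nM) clamped at 0 (a linear stand-in for the
  calcium dependence of spontaneous release; slope default 0.003 Hz/nM so
  the 110→265 nM scenario contrast roughly doubles the rate), bi-exponential
  kernels (rise 0.5 ms, decay 5 ms), lognormal amplitudes (mean 20 pA — a
  typical hippocampal mEPSC — CV 0.3), white Gaussian noise (SD 2 pA).
* **trains** — the depletion/constant-replenishment pool model, expected
  (deterministic) or binomial mode, pool capped at N_sites; amplitudes are
  released·q. A renderer turns amplitudes into a noisy current trace with a
  3 ms synaptic delay so peaks clear the artifact blank.
* **Fura-2** — channel intensities consistent with the forward Grynkiewicz
  relation (saturation fraction u/(1+u), u = c/(K_d·β); F340 = R·F380),
  multiplicative noise, additive background.
* **sypHy** — surface fraction stepping up per probe, relaxing
  exponentially with τ_endo toward a plateau, NH₄Cl segment pinned at F_max.
* **SyGCaMP** — Hill-saturating basal level (K_d 375 nM) with optional
  evoked step, for normalisation tests only.

Defaults are the study conditions the analyses target: 40 Hz x 2 s
depletion trains (ρ = 80 sites/s, i.e. 2 sites per ISI), 30 s @ 20 Hz
depression with 0.1 Hz recovery probes, 0.5 Hz spontaneous rate, τ_endo
12 s, 1 Hz imaging. Randomness flows through `numpy.random.Generator`
seeded from (seed, per-generator stream tag), so simulators are
bit-reproducible and mutually independent at equal seeds.

What the generator does **not** emulate: coloured recording noise (white
Gaussian is a declared simplification), electrode/stimulation artifacts,
asynchronous release, calcium-dependent (facilitating) Pr, activity- or
calcium-dependent replenishment, bleaching, focus drift, or ROI
segmentation error. Passing parameter-recovery tests therefore demonstrates
estimator correctness under the assumed models, not robustness to every
pathology of real recordings.

One consequence of the constant-rate replenishment model worth knowing:
between 0.1 Hz recovery probes (10 s apart) a pool with ρ ≥ ~10 sites/s
refills completely, making recovery look instantaneous. Genotype contrasts
in recovery steady state are therefore simulated at low ρ (e.g. 4 vs 2
sites/s), where the capped steady state ρ·ISI/Pr < N preserves the
contrast — the recovered SSC then equals the simulator's steady-state ratio.

## Pipeline

`RunConfig` (YAML) lists stages, a cell manifest (synthetic preset or CSV
path, with genotype labels), parameters, a seed and an output directory.
Per-cell failures are recorded in the provenance and do not abort the run.
Group summaries report n, mean ± sem, median and quartiles per genotype;
pairwise comparisons use a D'Agostino–Pearson normality gate selecting
Welch's t-test only when both groups pass and have n ≥ 8, defaulting to
Mann–Whitney otherwise — reporting convenience via scipy, not part of the
scientific core. Outputs are plain CSV/JSON with a config hash (excluding
the output path), seed and version; identical config + seed reproduce all
outputs byte-identically.

## Problem sizes

Tests and the acceptance script simulate at the protocol sizes the analyses
are designed for: 80-stimulus 40 Hz trains (100 cells for the stochastic
recovery check), 600-stimulus 20 Hz depression grids, 8-point decade
calibration grids (100 noise seeds), 100 s miniature traces at 10 kHz
(50 seeds), 90-frame endocytosis decays. These sizes are the package's
standard working set; all are chosen to match the protocols, not to
showcase scale.
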