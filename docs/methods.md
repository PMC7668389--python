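# Methods

## Pulse model

One beat is modeled as a single revolution on the unit circle at angular
velocity `ω = 2π/T`, phase-shifted by `−π` so the revolution starts at the
waveform onset (the valley). The PPG amplitude is the sum of two Gaussians
in the phase variable `θ ∈ [−π, π)` — the systolic wave `(a₁, b₁, θ₁)` and
the diastolic wave `(a₂, b₂, θ₂)`. The phase is computed analytically as
`ω(t − t₀) − π` wrapped to `[−π, π)` rather than through `atan2(sin, cos)`:
the two are identical to machine precision everywhere except at the onset,
where the atan2 branch returns `+π`; we define the onset phase as `−π`.
A unit test checks the equivalence against the atan2 form at 1000 random
times to 1e−12.

Each pulse occupies the half-open interval `[t₀, t₀ + T)` with
`n = round(T·fs)` samples at `t₀ + k/fs`. The half-open convention makes
pulses concatenate without duplicated boundary samples and yields exactly
125 samples at the reference settings (T = 1 s, fs = 125 Hz). The output
stays in model units (≈ [0, a₁ + a₂]); no rescaling is applied.

## Feasible parameter region

The constraint set is `0 ≤ a₂ ≤ a₁ ≤ 1`, `0 ≤ b₁ < b₂ ≤ 3`,
`−π ≤ θ₁ < θ₂ ≤ π`. Two deliberate choices: the phase ordering puts the
systolic centre before the diastolic centre, which is what every default
template row satisfies; and the amplitude inequality is non-strict because
the reset first-beat template has `a₁ = a₂ = 0.774`. Where the optimizer
needs closed sets, the strict inequalities are enforced with a separation
epsilon of 1e−6.

## Template fitting

The objective is the unnormalised sum of squared errors plus a Pearson
decorrelation penalty `1 − r`; it is zero iff the model reproduces the beat
sample-wise, and it is undefined (raised as a degenerate-input error) when
either sequence is constant. Minimisation uses scipy's `trust-constr`
solver — a trust-region interior-point-style method that honours the box
bounds and the three linear inequalities (`a₁ − a₂ ≥ 0`, `b₂ − b₁ ≥ ε`,
`θ₂ − θ₁ ≥ ε`) — with gradient and step tolerances of 1e−9 and at most 500
iterations. The widths are floored at ε > 0 inside the solver so the
Gaussian terms remain defined.

Auto-initialisation: `a₁ = max(s)` (clipped to [0.05, 1]), `a₂ = a₁/2`,
`b₁ = 0.6`, `b₂ = 1.0`, and `θ₁, θ₂` from the phases of the two most
prominent local maxima at least an eighth of a cycle apart, falling back to
the regular-template means when fewer than two peaks are found. For
PPG-shaped beats this lands in the correct basin: noise-free beats from any
well-separated feasible truth (`θ₂ − θ₁ ≥ 0.5`, `a₁ − a₂ ≥ 0.1`) are
recovered to better than 1e−2 per parameter, and the returned point is
always feasible (residual solver tolerance is projected out) and never
worse than the starting point. Non-convergence within the iteration cap is
reported through the `converged` flag, not an exception.

## Rhythm scheduling

Reference durations are i.i.d. `Normal(60000/HR, rr_sd)` ms, truncated to
±3 SD and floored at 250 ms (240 bpm) to exclude non-physiological draws
the model itself says nothing about. Heart rate is accepted in [50, 180]
bpm inclusive. RR variability applies to regular records only; irregular
records use a fixed reference duration derived from the basic heart rate,
so the premature-group duration ratios — and hence the group class — are
exact by construction.

A premature group replaces two consecutive reference beats at a uniformly
random eligible position with `d₁ = r₁·d₀` and `d₂ = r₂·d₀`, where `d₀` is
the replaced beat's duration and `(r₁, r₂)` are fixed per template:
compensation (0.830, 1.170) — summing to exactly `2d₀`; reset
(0.607, 0.596); interpolation (0.561, 0.475). Randomising the ratios could
silently change the class, so they are scalars. Placements keep at least
one reference beat between groups and at both record ends. Group types
whose ratios sum below 2 shorten the record; reference beats resampled from
the schedule's existing reference durations are appended until the original
scheduled length is restored.

Two quirks of the default ratios are kept as printed rather than
reconciled: the interpolation ratios sum to `1.036·d₀` (not exactly `d₀`),
so classifying generated interpolation groups needs a tolerance ≥ 0.04,
and the reset second-beat ratio 0.596 is not a prolonged beat. The
duration classifier's default tolerance is 0.02 of `d₀`, which separates
the canonical exemplars (850+1150, 650+1150, 400+600 ms) unambiguously;
pairs summing beyond `2d₀` plus tolerance fall outside the taxonomy and
are mapped to the nearest class, compensation.

## Assembly and junction smoothing

Beat boundaries are placed by rounding the *cumulative* schedule time to
the sample grid, so quantisation residuals never accumulate (every
boundary is within half a sample of its exact time). Each beat's waveform
is generated independently with its own parameter draw — Gaussian per
parameter, rejection-resampled until feasible (≤ 100 attempts, then the
means with a warning; the default templates reject only a small fraction
of draws).

Because draws are independent, beat endpoints disagree slightly; around
every interior onset a window of `round(0.1·fs)` samples centred on the
onset is replaced by a natural cubic spline fitted through the
`round(0.05·fs)` samples on each flank. The natural end conditions are our
choice of the standard spline family; smoothing runs before noise injection
so noise is not smoothed away. Onsets whose windows would cross the record
ends or a neighbouring window are skipped with a warning. Sampling rates
below 30 Hz are rejected (the flanks would hold fewer than two samples).

## Noise

White Gaussian noise is scaled analytically from the requested SNR against
the clean signal's AC power (mean-removed mean square): the synthetic PPG
rides on a positive baseline, and a DC-inclusive reference would let the
nominal SNR be inflated arbitrarily by shifting the offset. The contract is
the scaling rule, so the realised sample SNR fluctuates and converges to
the request with record length (checked within ±0.3 dB at 1e5 samples).
Multi-frequency noise `Σ Aᵢ sin(2π fᵢ t)` is deterministic and rejects
components at or above Nyquist.

## Reproducibility and I/O

A single seeded generator (numpy PCG64) is threaded through scheduling →
parameter sampling → noise in that fixed order, so identical (config, seed)
pairs give bit-identical records, files included, and disabling a later
stage never perturbs an earlier one. CSV floats are written as the shortest
decimal that round-trips to the same IEEE double, making the CSV + JSON
sidecar pair exactly lossless; the sidecar carries onsets, beat labels and
the full config + seed, so it alone regenerates the record.

## Default study conditions

Defaults: fs = 125 Hz, length 10 s, heart rate 60 bpm, rr_sd 50 ms for
regular records (a typical short-term RR variability; the source GUI's
default is not documented), no noise, seed 0. The morphology templates are
the published per-role means and SDs estimated from real recordings; they
are used verbatim as the package defaults.

## What the synthetic data does and does not show

The generator reproduces the *model's* notion of PPG: smooth two-Gaussian
beats, independent beat-to-beat parameter variation, exact duration-ratio
premature groups, additive stationary noise. It does not emulate baseline
wander, motion artifacts, sensor transfer functions, amplitude trends
across beats, premature ventricular contractions or re-entry groups (no
template exists for the latter). Passing tests therefore certify the
synthesis/fitting machinery and its invariants, not performance of any
downstream algorithm on real recordings.

## Problem sizes

Tests and the acceptance script run at desk scale: single beats at 125–250
Hz, records of 5–30 s (one 120 s drift check and one ~10⁴-beat schedule for
the law-of-large-numbers check), 1e5-sample noise calibrations. These sizes
already pin every identity and tolerance the suite asserts; nothing in the
method scales worse than linearly in record length.
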